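"""Pathway interaction network (PIN) construction and reduction.

Two pathways are connected ("crosstalk") when at least one criterion holds:

* ``shared_deg`` — they share a gene that is differentially expressed
  between disease and control (two-sample t, raw p < alpha);
* ``coexpressed_ppi`` — a protein interaction crosses the two pathways and
  its endpoint genes are highly co-expressed (|Pearson r| > 0.8 within a
  sample group).

Each qualified edge carries a weight: the sum of |PCC| over every protein
interaction crossing the pair (each unordered interaction counted once).
The network is then reduced to the top fraction of edges by weight.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CONTROL, DISEASE, ExpressionStudy, PathwayCollection, PPINetwork
from .preprocess import TargetedInputs

logger = logging.getLogger(__name__)

DEG_ALPHA = 0.05
PCC_EDGE_THRESHOLD = 0.8
TOP_FRACTION = 0.05

CRITERION_SHARED_DEG = "shared_deg"
CRITERION_COEXPRESSED = "coexpressed_ppi"

WEIGHT_CONDITIONS = ("disease", "control", "all_samples", "max_abs")
CRITERION2_CONDITIONS = ("max", "disease", "control")


def differential_expression(
    study: ExpressionStudy, alpha: float = DEG_ALPHA, fdr: bool = False
) -> pd.DataFrame:
    """Per-gene two-sided pooled-variance t test, disease vs control.

    Returns a DataFrame indexed by gene with columns ``t``, ``p`` and
    ``is_deg`` (raw p < alpha; with ``fdr=True`` a Benjamini-Hochberg
    ``q`` column is added and drives the flag instead).  Genes constant in
    both groups get t=0, p=1.
    """
    matrix = study.matrix()
    disease = matrix[study.group_samples(DISEASE)].to_numpy(dtype=float)
    control = matrix[study.group_samples(CONTROL)].to_numpy(dtype=float)
    if disease.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    result = stats.ttest_ind(disease, control, axis=1, equal_var=True)
    t = np.where(np.isnan(result.statistic), 0.0, result.statistic)
    p = np.where(np.isnan(result.pvalue), 1.0, result.pvalue)
    table = pd.DataFrame({"t": t, "p": p}, index=matrix.index)
    if fdr:
        table["q"] = stats.false_discovery_control(table["p"].to_numpy())
        table["is_deg"] = table["q"] < alpha
    else:
        table["is_deg"] = table["p"] < alpha
    return table


def pairwise_pcc(study: ExpressionStudy, ppi: PPINetwork) -> pd.DataFrame:
    """Pearson correlation of each interaction's endpoint genes per condition.

    Indexed by the sorted gene pair; columns ``pcc_disease``,
    ``pcc_control``, ``pcc_all`` plus the diagnostic ``abs_diff`` =
    ||r_disease| - |r_control|| (exported only, drives no decision).  A
    zero-variance endpoint within a condition yields r = 0 with a warning.
    """
    matrix = study.matrix()
    for group in (DISEASE, CONTROL):
        if len(study.group_samples(group)) < 3:
            raise ValueError(f"{group} group needs at least 3 samples for PCC")
    measured = set(matrix.index)
    pairs = sorted(
        (a, b) for a, b, _ in ppi.edges() if a in measured and b in measured
    )
    if not pairs:
        return pd.DataFrame(
            columns=["pcc_disease", "pcc_control", "pcc_all", "abs_diff"],
            index=pd.MultiIndex.from_arrays([[], []], names=["gene_a", "gene_b"]),
        )
    pos = {g: i for i, g in enumerate(matrix.index)}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])

    def corr_over(columns: list[str]) -> np.ndarray:
        x = matrix[columns].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc ** 2).sum(axis=1))
        denom = norms[ia] * norms[ib]
        r = np.zeros(len(pairs))
        ok = denom > 0
        r[ok] = (xc[ia[ok]] * xc[ib[ok]]).sum(axis=1) / denom[ok]
        n_degenerate = int((~ok).sum())
        if n_degenerate:
            logger.warning(
                "%d interaction(s) with a zero-variance endpoint; PCC set to 0",
                n_degenerate,
            )
        return np.clip(r, -1.0, 1.0)

    r_disease = corr_over(study.group_samples(DISEASE))
    r_control = corr_over(study.group_samples(CONTROL))
    r_all = corr_over(study.samples)
    index = pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"])
    return pd.DataFrame(
        {
            "pcc_disease": r_disease,
            "pcc_control": r_control,
            "pcc_all": r_all,
            "abs_diff": np.abs(np.abs(r_disease) - np.abs(r_control)),
        },
        index=index,
    )


def _weight_values(corr: pd.DataFrame, weight_condition: str) -> pd.Series:
    if weight_condition not in WEIGHT_CONDITIONS:
        raise ValueError(f"unknown weight_condition {weight_condition!r}")
    if weight_condition == "max_abs":
        return np.maximum(corr["pcc_disease"].abs(), corr["pcc_control"].abs())
    column = {
        "disease": "pcc_disease",
        "control": "pcc_control",
        "all_samples": "pcc_all",
    }[weight_condition]
    return corr[column].abs()


def _criterion2_values(corr: pd.DataFrame, criterion2_condition: str) -> pd.Series:
    if criterion2_condition not in CRITERION2_CONDITIONS:
        raise ValueError(f"unknown criterion2_condition {criterion2_condition!r}")
    if criterion2_condition == "max":
        return np.maximum(corr["pcc_disease"].abs(), corr["pcc_control"].abs())
    column = {"disease": "pcc_disease", "control": "pcc_control"}[
        criterion2_condition
    ]
    return corr[column].abs()


def _crossing_ppi_pairs(genes_a, genes_b, ppi: PPINetwork):
    """Unordered interaction edges with one endpoint in each pathway.

    An edge both of whose endpoints lie in the intersection of the two
    pathways is yielded exactly once.
    """
    seen: set[tuple[str, str]] = set()
    for a in genes_a:
        for b in ppi.neighbors(a):
            if b in genes_b and b != a:
                key = (a, b) if a < b else (b, a)
                if key not in seen:
                    seen.add(key)
                    yield key


def qualify_edge(
    pa_id: int,
    pb_id: int,
    degs: pd.DataFrame,
    corr: pd.DataFrame,
    pathways: PathwayCollection,
    ppi: PPINetwork,
    pcc_threshold: float = PCC_EDGE_THRESHOLD,
    criterion2_condition: str = "max",
) -> frozenset[str]:
    """Which crosstalk criteria a pathway pair satisfies (possibly none)."""
    if pa_id == pb_id:
        raise ValueError("a pathway cannot crosstalk with itself")
    try:
        pa, pb = pathways.by_id[pa_id], pathways.by_id[pb_id]
    except KeyError as exc:
        raise ValueError(f"unknown pathway id {exc.args[0]}") from exc
    criteria: set[str] = set()
    deg_genes = set(degs.index[degs["is_deg"]])
    if (pa.genes & pb.genes) & deg_genes:
        criteria.add(CRITERION_SHARED_DEG)
    c2 = _criterion2_values(corr, criterion2_condition)
    for key in _crossing_ppi_pairs(pa.genes, pb.genes, ppi):
        if key in c2.index and c2.loc[key] > pcc_threshold:
            criteria.add(CRITERION_COEXPRESSED)
            break
    return frozenset(criteria)


def edge_weight(
    pa_id: int,
    pb_id: int,
    corr: pd.DataFrame,
    pathways: PathwayCollection,
    ppi: PPINetwork,
    weight_condition: str = "disease",
) -> float:
    """Sum of |PCC| over interactions crossing the two pathways."""
    pa, pb = pathways.by_id[pa_id], pathways.by_id[pb_id]
    values = _weight_values(corr, weight_condition)
    total = 0.0
    for key in _crossing_ppi_pairs(pa.genes, pb.genes, ppi):
        if key in values.index:
            total += float(values.loc[key])
    return total


def build_pin(
    inputs: TargetedInputs,
    degs: pd.DataFrame,
    corr: pd.DataFrame,
    pcc_threshold: float = PCC_EDGE_THRESHOLD,
    weight_condition: str = "disease",
    criterion2_condition: str = "max",
) -> nx.Graph:
    """Evaluate both criteria for every unordered pathway pair.

    Nodes are all informative pathway IDs; each qualified edge stores its
    ``weight`` and the ``criteria`` frozenset it satisfied.
    """
    pathways = inputs.informative_pathways
    ppi = inputs.targeted_ppi
    graph = nx.Graph()
    graph.add_nodes_from(pathways.ids)

    deg_genes = set(degs.index[degs["is_deg"]])
    weights = _weight_values(corr, weight_condition)
    c2 = _criterion2_values(corr, criterion2_condition)
    weight_map = {k: float(v) for k, v in weights.items()}
    qualified2 = {k for k, v in c2.items() if v > pcc_threshold}

    entries = sorted(pathways, key=lambda p: p.id)
    for pa, pb in combinations(entries, 2):
        criteria: set[str] = set()
        if (pa.genes & pb.genes) & deg_genes:
            criteria.add(CRITERION_SHARED_DEG)
        weight = 0.0
        coexpressed = False
        for key in _crossing_ppi_pairs(pa.genes, pb.genes, ppi):
            weight += weight_map.get(key, 0.0)
            if not coexpressed and key in qualified2:
                coexpressed = True
        if coexpressed:
            criteria.add(CRITERION_COEXPRESSED)
        if criteria:
            graph.add_edge(
                pa.id, pb.id, weight=weight, criteria=frozenset(criteria)
            )
    logger.info(
        "PIN: %d pathway nodes, %d qualified interactions",
        graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def reduce_top_fraction(pin: nx.Graph, fraction: float = TOP_FRACTION) -> nx.Graph:
    """Keep the floor(fraction * |E|) heaviest edges; ties break on (idA, idB).

    Isolated nodes stay in the graph.  The small epsilon inside the floor
    undoes binary-float artifacts (0.29 * 100 = 28.999999999999996) so the
    kept count matches the mathematical floor of the product.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    edges = []
    for a, b, data in pin.edges(data=True):
        ia, ib = sorted((a, b))
        edges.append((ia, ib, data))
    keep = math.floor(fraction * len(edges) + 1e-9)
    edges.sort(key=lambda e: (-e[2].get("weight", 0.0), e[0], e[1]))
    reduced = nx.Graph()
    reduced.add_nodes_from(pin.nodes)
    for ia, ib, data in edges[:keep]:
        reduced.add_edge(ia, ib, **data)
    logger.info(
        "reduced PIN: kept %d of %d interactions (top %.1f%%)",
        keep, len(edges), 100 * fraction,
    )
    return reduced
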