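"""Naive, independent reference computations used as test oracles.

These deliberately re-derive results with plain loops and direct formulas,
staying independent of the library's implementation paths.
"""

from itertools import combinations

import numpy as np


def reference_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r by direct covariance / (sigma_x * sigma_y)."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def reference_pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample pooled-variance t by the textbook formula."""
    na, nb = len(a), len(b)
    ssa = ((a - a.mean()) ** 2).sum()
    ssb = ((b - b.mean()) ** 2).sum()
    sp2 = (ssa + ssb) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def reference_pin(pathways, ppi, degs, corr, pcc_threshold=0.8,
                  weight_condition="disease"):
    """Exhaustive double-loop pathway network construction.

    Returns {(id_a, id_b): (weight, criteria frozenset)} over qualified pairs.
    """
    deg_genes = {g for g in degs.index if bool(degs.loc[g, "is_deg"])}
    ppi_edges = list(ppi.edges())
    result = {}
    for pa, pb in combinations(sorted(pathways, key=lambda p: p.id), 2):
        criteria = set()
        if any(g in deg_genes for g in (pa.genes & pb.genes)):
            criteria.add("shared_deg")
        weight = 0.0
        coexpressed = False
        for a, b, _conf in ppi_edges:
            if a == b:
                continue
            crosses = (a in pa.genes and b in pb.genes) or (
                a in pb.genes and b in pa.genes
            )
            if not crosses:
                continue
            key = tuple(sorted((a, b)))
            if key not in corr.index:
                continue
            row = corr.loc[key]
            if weight_condition == "disease":
                weight += abs(row["pcc_disease"])
            elif weight_condition == "control":
                weight += abs(row["pcc_control"])
            elif weight_condition == "all_samples":
                weight += abs(row["pcc_all"])
            else:
                weight += max(abs(row["pcc_disease"]), abs(row["pcc_control"]))
            if max(abs(row["pcc_disease"]), abs(row["pcc_control"])) > pcc_threshold:
                coexpressed = True
        if coexpressed:
            criteria.add("coexpressed_ppi")
        if criteria:
            result[(pa.id, pb.id)] = (weight, frozenset(criteria))
    return result


def random_toy_instance(rng, max_pathways=10, max_genes=100):
    """A small random study + pathways + PPI for oracle comparisons."""
    from pathpin import PathwayCollection, PPINetwork
    from tests.conftest import make_study

    n_genes = int(rng.integers(20, max_genes + 1))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    n_pathways = int(rng.integers(3, max_pathways + 1))
    sets = {}
    for k in range(n_pathways):
        size = int(rng.integers(3, 9))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"p{k:02d}"] = [str(g) for g in members]
    pathways = PathwayCollection(sets)
    ppi = PPINetwork()
    n_edges = int(rng.integers(10, 60))
    for _ in range(n_edges):
        a, b = rng.choice(genes, size=2, replace=False)
        ppi.add_interaction(str(a), str(b), float(rng.uniform(0.21, 1.0)))
    n_d, n_c = 8, 5
    values = rng.standard_normal((n_genes, n_d + n_c))
    # sprinkle group shifts so some genes are differentially expressed
    shifted = rng.choice(n_genes, size=max(2, n_genes // 6), replace=False)
    values[shifted, :n_d] += 2.0
    study = make_study(values, n_disease=n_d, n_control=n_c, genes=genes)
    return study, pathways, ppi
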