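"""Synthetic case/control studies with planted dysregulated pathways.

The generator emulates the statistical structure the analysis assumes:

* a two-group expression matrix (disease vs control) whose baseline is
  i.i.d. standard normal per gene and sample;
* a pathway collection with controlled overlap between adjacent pathways,
  so pathway crosstalk through shared genes exists by construction;
* a scored protein-interaction network whose edges preferentially connect
  co-pathway genes;
* elevated co-expression between interaction partners, induced by one
  shared latent factor per interaction edge;
* a contiguous block of "planted" dysregulated pathways in which a stated
  fraction of member genes gains a mean shift (in SD units) in disease
  samples only.

Defaults mirror a small colorectal-cancer style design: 15 disease vs 8
control samples, 50 overlapping pathways of 8-14 genes each, 5 planted
pathways shifted by 2 SD on half of their genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CONTROL,
    DISEASE,
    ExpressionStudy,
    PathwayCollection,
    PPINetwork,
    write_expression_tsv,
    write_gmt,
    write_ppi_tsv,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's reference scenario."""

    n_genes: int = 600
    n_disease: int = 15
    n_control: int = 8
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (8, 14)
    overlap_fraction: float = 0.25
    n_planted: int = 5
    effect_size: float = 2.0
    affected_gene_fraction: float = 0.5
    dose_cv: float = 0.3
    ppi_within_pathway_prob: float = 0.35
    ppi_background_prob: float = 0.02
    coexpression_rho: float = 0.8
    confidence_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_disease < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_genes < 1 or self.n_pathways < 0:
            raise ValueError("n_genes must be >=1 and n_pathways >=0")
        if lo < 5 or hi < lo:
            raise ValueError(
                "pathway_size_range must satisfy 5 <= min <= max "
                "(the size filter discards pathways under 5 genes)"
            )
        for name in ("overlap_fraction", "ppi_within_pathway_prob",
                     "ppi_background_prob", "coexpression_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.affected_gene_fraction <= 1.0:
            raise ValueError("affected_gene_fraction must be in (0,1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dose_cv < 0:
            raise ValueError("dose_cv must be >= 0")
        clo, chi = self.confidence_range
        if not 0.0 <= clo <= chi <= 1.0:
            raise ValueError("confidence_range must satisfy 0 <= low <= high <= 1")
        if self.n_planted < 0 or self.n_planted > self.n_pathways:
            raise ValueError("n_planted must be between 0 and n_pathways")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Which pathways were planted and which genes were shifted."""

    planted_pathway_ids: set[int]
    affected_genes: set[str]

    def to_dict(self) -> dict:
        return {
            "planted_pathway_ids": sorted(self.planted_pathway_ids),
            "affected_genes": sorted(self.affected_genes),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        return cls(
            planted_pathway_ids=set(payload["planted_pathway_ids"]),
            affected_genes=set(payload["affected_genes"]),
        )


def gene_names(config: SyntheticConfig) -> list[str]:
    # zero-padded so alphabetical and numeric order coincide
    width = max(2, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _pathway_names(config: SyntheticConfig) -> list[str]:
    width = max(2, len(str(max(config.n_pathways - 1, 0))))
    return [f"PW{i:0{width}d}" for i in range(config.n_pathways)]


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    # independent, order-insensitive streams per generation stage
    return np.random.default_rng([config.seed, stage])


def generate_pathways(config: SyntheticConfig) -> PathwayCollection:
    """Draw overlapping gene sets; adjacent pathways share a fixed gene count.

    Pathway i shares ceil(overlap_fraction * size_i) genes with pathway i-1;
    all other members are fresh draws from the unused gene pool, so
    non-adjacent pathways intersect only through propagated shared genes.
    """
    rng = _rng(config, 0)
    genes = gene_names(config)
    order = rng.permutation(config.n_genes)
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    names = _pathway_names(config)

    sets: dict[str, list[str]] = {}
    prev: list[str] = []
    ptr = 0
    for i in range(config.n_pathways):
        size = int(sizes[i])
        n_shared = 0
        if i > 0 and config.overlap_fraction > 0:
            n_shared = min(math.ceil(config.overlap_fraction * size),
                           len(prev), size)
        shared = (
            list(rng.choice(prev, size=n_shared, replace=False))
            if n_shared
            else []
        )
        n_new = size - n_shared
        if ptr + n_new > config.n_genes:
            raise ValueError(
                "capacity error: pathways demand more fresh genes "
                f"({ptr + n_new}) than the universe provides ({config.n_genes})"
            )
        fresh = [genes[order[ptr + k]] for k in range(n_new)]
        ptr += n_new
        members = sorted(set(shared) | set(fresh))
        sets[names[i]] = members
        prev = members
    return PathwayCollection(sets)


def generate_ppi(
    config: SyntheticConfig, pathways: PathwayCollection
) -> PPINetwork:
    """Bernoulli interaction graph enriched within pathways, scored uniformly.

    Within-pathway gene pairs are included with ``ppi_within_pathway_prob``,
    all other pairs with ``ppi_background_prob``; every edge carries a
    confidence drawn uniformly from ``confidence_range``.
    """
    rng = _rng(config, 1)
    genes = gene_names(config)
    index = {g: i for i, g in enumerate(genes)}
    n = config.n_genes
    n_pairs = n * (n - 1) // 2
    prob = np.full(n_pairs, config.ppi_background_prob)

    def flat(i: int, j: int) -> int:
        # position of (i, j), i < j, in row-major upper-triangle order
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    for p in pathways:
        members = sorted(index[g] for g in p.genes if g in index)
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1:]:
                prob[flat(i, j)] = config.ppi_within_pathway_prob

    draws = rng.random(n_pairs) < prob
    ii, jj = np.triu_indices(n, k=1)
    sel_i, sel_j = ii[draws], jj[draws]
    clo, chi = config.confidence_range
    confs = rng.uniform(clo, chi, size=sel_i.shape[0])

    net = PPINetwork()
    for i, j, c in zip(sel_i, sel_j, confs):
        net.add_interaction(genes[int(i)], genes[int(j)], float(c))
    return net


def generate_expression(
    config: SyntheticConfig,
    pathways: PathwayCollection,
    ppi: PPINetwork,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Baseline N(0,1) expression + co-regulation latents + planted shifts.

    Co-expression between interaction partners is induced by shared latent
    factors while keeping every marginal N(0,1):

    * a gene in m pathways is x_g = sqrt(1-rho)*eps_g +
      sqrt(rho/m) * sum(pathway factors), so two partners whose only
      membership is one common pathway correlate at exactly rho (multi-
      membership genes are attenuated by 1/sqrt(m_a m_b)) — co-expression
      of co-pathway partners reflects shared pathway co-regulation;
    * a pathway-free gene with b interaction edges to other pathway-free
      genes is x_g = sqrt(1-rho)*eps_g + sqrt(rho/b) * sum(edge latents),
      so isolated interacting pairs also reach rho.

    Interactions that cross from a pathway gene to a pathway-free gene (or
    between different pathways) carry no shared latent: with independent
    pathway programs their co-expression is the background level.

    Planting: a contiguous block of ``n_planted`` pathway IDs is chosen;
    within each, ceil(affected_gene_fraction * size) genes are shifted in
    disease samples only.  The shift is a per-(pathway, disease sample)
    dysregulation dose D ~ N(effect_size, (dose_cv * effect_size)^2),
    shared by the pathway's affected genes in that sample — cohorts are
    heterogeneous in how strongly each sample expresses each aberration.
    A gene affected by several planted pathways receives the mean of their
    doses.  ``dose_cv=0`` recovers a constant mean shift; ``effect_size=0``
    is an exact null (no dose noise).
    """
    rng = _rng(config, 2)
    genes = gene_names(config)
    index = {g: i for i, g in enumerate(genes)}
    n_s = config.n_disease + config.n_control
    samples = [f"D{k:02d}" for k in range(1, config.n_disease + 1)] + [
        f"C{k:02d}" for k in range(1, config.n_control + 1)
    ]
    labels = pd.Series(
        [DISEASE] * config.n_disease + [CONTROL] * config.n_control,
        index=samples,
    )

    values = rng.standard_normal((config.n_genes, n_s))
    rho = config.coexpression_rho
    if rho > 0:
        shared = np.zeros_like(values)
        n_factors = np.zeros(config.n_genes)
        membership = pathways.gene_to_pathways()
        # one co-regulation factor per pathway, shared by all member genes
        for pid in sorted(p.id for p in pathways):
            factor = rng.standard_normal(n_s)
            pathway = pathways.by_id[pid]
            rows = [index[g] for g in sorted(pathway.genes) if g in index]
            shared[rows] += factor
            n_factors[rows] += 1.0
        # per-edge factors for interactions between pathway-free genes
        free_edges = sorted(
            (a, b)
            for a, b, _ in ppi.edges()
            if a not in membership and b not in membership
            and a in index and b in index
        )
        if free_edges:
            latents = rng.standard_normal((len(free_edges), n_s))
            ia = np.array([index[a] for a, _ in free_edges])
            ib = np.array([index[b] for _, b in free_edges])
            np.add.at(shared, ia, latents)
            np.add.at(shared, ib, latents)
            np.add.at(n_factors, ia, 1.0)
            np.add.at(n_factors, ib, 1.0)
        connected = n_factors > 0
        scale = np.zeros(config.n_genes)
        scale[connected] = np.sqrt(rho / n_factors[connected])
        values[connected] = (
            math.sqrt(1.0 - rho) * values[connected]
            + scale[connected, None] * shared[connected]
        )

    planted_ids: set[int] = set()
    affected: set[str] = set()
    if config.n_planted:
        start = int(rng.integers(0, config.n_pathways - config.n_planted + 1))
        planted_ids = set(range(start, start + config.n_planted))
        affected_by: dict[str, list[int]] = {}
        for pid in sorted(planted_ids):
            members = sorted(pathways.by_id[pid].genes)
            k = math.ceil(config.affected_gene_fraction * len(members))
            picked = rng.choice(members, size=k, replace=False)
            for g in picked:
                affected_by.setdefault(str(g), []).append(pid)
        affected = set(affected_by)
        if config.effect_size > 0:
            dose_sd = config.dose_cv * config.effect_size
            doses = {
                pid: rng.normal(config.effect_size, dose_sd, config.n_disease)
                for pid in sorted(planted_ids)
            }
            for g in sorted(affected):
                gene_dose = np.mean([doses[pid] for pid in affected_by[g]], axis=0)
                values[index[g], : config.n_disease] += gene_dose

    study = ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples),
        labels=labels,
    )
    return study, GroundTruth(planted_pathway_ids=planted_ids, affected_genes=affected)


@dataclass
class SyntheticInputs:
    """One fully generated study: pathways, interactions, expression, truth."""

    config: SyntheticConfig
    pathways: PathwayCollection
    ppi: PPINetwork
    study: ExpressionStudy
    truth: GroundTruth


def generate_inputs(config: SyntheticConfig) -> SyntheticInputs:
    pathways = generate_pathways(config)
    ppi = generate_ppi(config, pathways)
    study, truth = generate_expression(config, pathways, ppi)
    return SyntheticInputs(
        config=config, pathways=pathways, ppi=ppi, study=study, truth=truth
    )


def write_synthetic_inputs(inputs: SyntheticInputs, out_dir: str | Path) -> list[Path]:
    """Write the standard input files plus the ground truth; returns the paths."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression = out / "expression.tsv"
    labels = out / "labels.tsv"
    gmt = out / "pathways.gmt"
    ppi_path = out / "ppi.tsv"
    truth_path = out / "ground_truth.json"
    write_expression_tsv(inputs.study, expression, labels_path=labels)
    write_gmt(inputs.pathways, gmt)
    write_ppi_tsv(inputs.ppi, ppi_path, score_scale="unit")
    with open(truth_path, "w", encoding="utf-8") as handle:
        payload = {
            "config": inputs.config.to_dict(),
            **inputs.truth.to_dict(),
        }
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return [expression, labels, gmt, ppi_path, truth_path]
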