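"""Filters and standardization that turn raw inputs into analysis-ready ones.

The preprocessing contract: expression values are z-scored per gene across
all samples pooled (both groups), pathways are restricted to measured genes
and must retain at least ``min_genes`` of them, and protein interactions
must have confidence strictly greater than the threshold with both
endpoints measured.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionStudy, PathwayCollection, PPINetwork

logger = logging.getLogger(__name__)

MIN_PATHWAY_GENES = 5
PPI_CONFIDENCE_THRESHOLD = 0.2


@dataclass
class TargetedInputs:
    """Analysis-ready study, informative pathways, and targeted PPI network."""

    study: ExpressionStudy
    informative_pathways: PathwayCollection
    targeted_ppi: PPINetwork


def collapse_probes(
    raw: ExpressionStudy, probe_to_gene: Mapping[str, str]
) -> ExpressionStudy:
    """Collapse probe-level rows to gene symbols by per-sample mean.

    Probes absent from the mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in raw.values.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probes matched the mapping")
    sub = raw.values.loc[mapped]
    symbols = np.array([probe_to_gene[p] for p in mapped])
    collapsed = sub.groupby(symbols).mean()
    collapsed.index.name = raw.values.index.name
    return ExpressionStudy(values=collapsed, labels=raw.labels)


def standardize_expression(study: ExpressionStudy, ddof: int = 1) -> ExpressionStudy:
    """Z-score each gene across all samples: Z_mn = (g_mn - mean_m) / SD_m.

    SD uses the sample (n-1) denominator.  Genes with zero variance carry no
    contrast information and are dropped with a logged count.
    """
    if study.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    values = study.values
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all genes have zero variance; nothing to standardize")
    if n_dropped:
        logger.info("dropped %d zero-variance genes during standardization", n_dropped)
    retained = values.loc[keep]
    z = retained.sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionStudy(values=retained, labels=study.labels, standardized=z)


def filter_pathways_by_size(
    pathways: PathwayCollection,
    study: ExpressionStudy,
    min_genes: int = MIN_PATHWAY_GENES,
) -> PathwayCollection:
    """Keep pathways with >= min_genes measured genes, restricted to those genes.

    IDs of the returned collection are the alphabetical ranks over the
    surviving name set (ID assignment is always a pure function of the
    names present).
    """
    measured = set(study.matrix().index)
    surviving: dict[str, frozenset[str]] = {}
    for p in pathways:
        usable = p.genes & measured
        if len(usable) >= min_genes:
            surviving[p.name] = frozenset(usable)
    descriptions = {
        name: pathways.descriptions.get(name, "") for name in surviving
    }
    return PathwayCollection(surviving, descriptions)


def filter_ppi_by_confidence(
    ppi: PPINetwork,
    study: ExpressionStudy,
    threshold: float = PPI_CONFIDENCE_THRESHOLD,
) -> PPINetwork:
    """Keep interactions with confidence strictly > threshold and both
    endpoints among measured genes."""
    measured = set(study.matrix().index)
    out = PPINetwork()
    for a, b, conf in ppi.edges():
        if conf > threshold and a in measured and b in measured:
            out.add_interaction(a, b, conf)
    return out


def prepare_inputs(
    study: ExpressionStudy,
    pathways: PathwayCollection,
    ppi: PPINetwork,
    min_genes: int = MIN_PATHWAY_GENES,
    ppi_confidence_threshold: float = PPI_CONFIDENCE_THRESHOLD,
    probe_to_gene: Mapping[str, str] | None = None,
) -> TargetedInputs:
    """Full preprocessing: optional probe collapse, z-scoring, both filters."""
    if probe_to_gene is not None:
        study = collapse_probes(study, probe_to_gene)
    study = standardize_expression(study)
    informative = filter_pathways_by_size(pathways, study, min_genes=min_genes)
    targeted = filter_ppi_by_confidence(
        ppi, study, threshold=ppi_confidence_threshold
    )
    logger.info(
        "preprocess: %d genes, %d informative pathways, %d targeted interactions",
        len(study.matrix()), len(informative), targeted.n_edges,
    )
    return TargetedInputs(
        study=study, informative_pathways=informative, targeted_ppi=targeted
    )
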