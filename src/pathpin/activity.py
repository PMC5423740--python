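"""PCA-based pathway activity scores and seed-pathway selection.

The activity of pathway k in sample n is the sample's coordinate on the
first principal component of the standardized member-gene submatrix
(genes as variables, samples as observations):

    P_kn = w_1k * z_1n + w_2k * z_2n + ... + w_mk * z_mn

with the loading vector w constrained to unit Euclidean norm.  The seed
pathway is the one whose activity differs most between disease and control,
measured by the absolute two-sample t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CONTROL, DISEASE
from .preprocess import TargetedInputs


@dataclass
class ActivityMatrix:
    """Pathways x samples activity scores plus the per-pathway loadings."""

    scores: pd.DataFrame              # index: pathway id, columns: samples
    loadings: dict[int, pd.Series]    # pathway id -> unit-norm gene weights
    names: dict[int, str]             # pathway id -> pathway name


@dataclass
class SeedResult:
    seed_id: int
    statistic: float
    per_pathway_statistics: pd.DataFrame  # columns: id, name, statistic


def _pc1(submatrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of a genes x samples block.

    Returns (scores over samples, unit-norm loading over genes).  The sign
    is fixed by orienting the loading so its largest-|coefficient| entry is
    positive; on ties the first gene in alphabetical order wins (the caller
    passes rows sorted by gene name).
    """
    X = submatrix.to_numpy(dtype=float).T      # samples x genes
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return Xc @ v, v


def compute_activity_matrix(
    inputs: TargetedInputs, min_genes: int = 2
) -> ActivityMatrix:
    """PC1 activity scores for every informative pathway.

    Requires a standardized study.  A pathway with fewer than ``min_genes``
    usable (measured, standardized) genes raises an error naming it; the
    single-gene case is well-defined (loading = (1), scores = the gene's
    z-row) and can be enabled with ``min_genes=1``.
    """
    z = inputs.study.standardized
    if z is None:
        raise ValueError("study must be standardized before computing activity")
    measured = set(z.index)
    rows: list[np.ndarray] = []
    ids: list[int] = []
    loadings: dict[int, pd.Series] = {}
    names: dict[int, str] = {}
    for pathway in inputs.informative_pathways:
        genes = sorted(pathway.genes & measured)
        if len(genes) < min_genes:
            raise ValueError(
                f"pathway {pathway.name!r} (id {pathway.id}) has only "
                f"{len(genes)} usable genes (< {min_genes})"
            )
        scores, loading = _pc1(z.loc[genes])
        ids.append(pathway.id)
        rows.append(scores)
        loadings[pathway.id] = pd.Series(loading, index=genes)
        names[pathway.id] = pathway.name
    if not ids:
        raise ValueError("no pathways to score")
    scores = pd.DataFrame(rows, index=ids, columns=z.columns).sort_index()
    return ActivityMatrix(scores=scores, loadings=loadings, names=names)


def activity_change_statistic(
    scores_row: pd.Series,
    labels: pd.Series,
    statistic: str = "pooled_t",
) -> float:
    """|two-sample t| of a pathway's activity, disease vs control.

    ``pooled_t`` (default) uses the pooled-variance Student t; ``welch_t``
    the unequal-variance form.  Identical constant groups give 0.
    """
    if statistic not in {"pooled_t", "welch_t"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    row = pd.Series(scores_row)
    disease = row[labels.reindex(row.index) == DISEASE].to_numpy(dtype=float)
    control = row[labels.reindex(row.index) == CONTROL].to_numpy(dtype=float)
    if len(disease) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    result = stats.ttest_ind(disease, control, equal_var=(statistic == "pooled_t"))
    t = float(result.statistic)
    if np.isnan(t):  # zero variance in both groups
        t = 0.0
    return abs(t)


def select_seed(
    activity: ActivityMatrix,
    labels: pd.Series,
    statistic: str = "pooled_t",
) -> SeedResult:
    """Pathway with the maximum activity-change statistic; ties -> lowest ID."""
    if activity.scores.empty:
        raise ValueError("empty activity matrix")
    records = []
    best_id: int | None = None
    best_stat = -np.inf
    for pid in sorted(activity.scores.index):
        value = activity_change_statistic(
            activity.scores.loc[pid], labels, statistic=statistic
        )
        records.append(
            {"id": pid, "name": activity.names.get(pid, ""), "statistic": value}
        )
        if value > best_stat:  # strict: first (lowest) id wins ties
            best_id, best_stat = pid, value
    table = pd.DataFrame.from_records(records).set_index("id")
    return SeedResult(
        seed_id=int(best_id), statistic=float(best_stat),
        per_pathway_statistics=table,
    )


def make_fold_refitter(inputs: TargetedInputs, pathway_ids: list[int]):
    """Build a cross-validation refitter that re-derives PC1 loadings on the
    training fold only, avoiding activity-score leakage into held-out folds.

    Returns a callable (train_idx, test_idx) -> (X_train, X_test) of
    per-fold pathway-activity features.
    """
    z = inputs.study.standardized
    if z is None:
        raise ValueError("study must be standardized")
    measured = set(z.index)
    blocks: list[np.ndarray] = []
    for pid in pathway_ids:
        pathway = inputs.informative_pathways.by_id[pid]
        genes = sorted(pathway.genes & measured)
        blocks.append(z.loc[genes].to_numpy(dtype=float).T)  # samples x genes

    def refit(train_idx: np.ndarray, test_idx: np.ndarray):
        cols_tr, cols_te = [], []
        for block in blocks:
            tr = block[train_idx]
            mu = tr.mean(axis=0)
            trc = tr - mu
            _, _, vt = np.linalg.svd(trc, full_matrices=False)
            v = vt[0]
            pivot = int(np.argmax(np.abs(v)))
            if v[pivot] < 0:
                v = -v
            cols_tr.append(trc @ v)
            cols_te.append((block[test_idx] - mu) @ v)
        return np.column_stack(cols_tr), np.column_stack(cols_te)

    return refit
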