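"""Greedy dysregulated-pathway selection by repeated cross-validated SVM AUC.

Starting from the seed pathway, the candidate set is every pathway adjacent
in the reduced pathway interaction network to any already-selected member.
At each step all candidates are scored with the same fold splits (common
random numbers); the best one is added if it improves the mean AUC by more
than ``min_improvement``, so the AUC trace is strictly increasing by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .activity import ActivityMatrix, SeedResult
from .data_io import DISEASE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings for the SVM/AUC wrapper."""

    n_folds: int = 5
    n_repeats: int = 100
    base_seed: int = 0
    stratified: bool = True
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    min_improvement: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")


@dataclass
class SelectionResult:
    """Ordered selected pathways with the AUC trace of the greedy growth."""

    seed_id: int
    seed_statistic: float
    selected_ids: list[int]
    auc_trace: list[float]
    final_auc: float
    n_pathways: int

    def to_dict(self) -> dict:
        return {
            "seed_id": self.seed_id,
            "seed_statistic": self.seed_statistic,
            "selected_ids": list(self.selected_ids),
            "auc_trace": list(self.auc_trace),
            "final_auc": self.final_auc,
            "n_pathways": self.n_pathways,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SelectionResult":
        return cls(
            seed_id=payload["seed_id"],
            seed_statistic=payload["seed_statistic"],
            selected_ids=list(payload["selected_ids"]),
            auc_trace=list(payload["auc_trace"]),
            final_auc=payload["final_auc"],
            n_pathways=payload["n_pathways"],
        )


def cv_auc(
    features,
    labels: pd.Series,
    cv: CVConfig,
    refitter=None,
) -> float:
    """Mean AUC of a linear SVM over repeated k-fold cross-validation.

    ``features`` is samples x features (1-D input is treated as a single
    feature), aligned with ``labels``.  For repeat r the fold split is
    seeded with base_seed + r; decision values of all held-out folds of a
    repeat are pooled into one AUC (robust when a fold holds few minority
    samples), and repeats are averaged.

    ``refitter`` (optional) maps (train_idx, test_idx) to per-fold feature
    matrices, letting callers re-derive features inside each training fold.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = (np.asarray(labels) == DISEASE).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise ValueError("each class needs at least 2 samples")
    n = len(y)
    aucs = np.empty(cv.n_repeats)
    for r in range(cv.n_repeats):
        seed = cv.base_seed + r
        if cv.stratified:
            splitter = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
        else:
            splitter = KFold(cv.n_folds, shuffle=True, random_state=seed)
        decision = np.empty(n)
        for train_idx, test_idx in splitter.split(X, y):
            if refitter is None:
                x_train, x_test = X[train_idx], X[test_idx]
            else:
                x_train, x_test = refitter(train_idx, test_idx)
            # standardize features on the training fold only
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel=cv.svm_kernel, C=cv.svm_c)
            clf.fit((x_train - mu) / sd, y[train_idx])
            decision[test_idx] = clf.decision_function((x_test - mu) / sd)
        aucs[r] = roc_auc_score(y, decision)
    return float(aucs.mean())


def greedy_select(
    seed: SeedResult,
    pin_reduced: nx.Graph,
    activity: ActivityMatrix,
    labels: pd.Series,
    cv: CVConfig,
    refitter_factory=None,
) -> SelectionResult:
    """Grow a pathway set from the seed, maximizing repeated-CV mean AUC.

    ``refitter_factory`` (optional) maps a list of pathway IDs to a per-fold
    feature refitter (see :func:`pathpin.activity.make_fold_refitter`).
    """
    seed_id = seed.seed_id
    if seed_id not in activity.scores.index:
        raise ValueError(f"seed pathway {seed_id} missing from activity matrix")

    def score(ids: list[int]) -> float:
        feats = activity.scores.loc[ids].T  # samples x pathways
        refitter = refitter_factory(ids) if refitter_factory is not None else None
        return cv_auc(feats, labels, cv, refitter=refitter)

    selected = [seed_id]
    trace = [score(selected)]
    if seed_id not in pin_reduced:
        logger.warning(
            "seed pathway %d has no node in the reduced PIN; "
            "returning the singleton set", seed_id,
        )
    while True:
        frontier = sorted(
            {
                neighbor
                for member in selected
                if member in pin_reduced
                for neighbor in pin_reduced.neighbors(member)
            }
            - set(selected)
        )
        frontier = [c for c in frontier if c in activity.scores.index]
        if not frontier:
            break
        best_id: int | None = None
        best_auc = -np.inf
        for candidate in frontier:  # ascending ids: strict > keeps lowest on ties
            auc = score(selected + [candidate])
            if auc > best_auc:
                best_id, best_auc = candidate, auc
        if best_auc - trace[-1] > cv.min_improvement:
            selected.append(int(best_id))
            trace.append(best_auc)
        else:
            break
    logger.info(
        "greedy selection: %d pathways, final AUC %.4f", len(selected), trace[-1]
    )
    return SelectionResult(
        seed_id=int(seed_id),
        seed_statistic=float(seed.statistic),
        selected_ids=[int(i) for i in selected],
        auc_trace=[float(a) for a in trace],
        final_auc=float(trace[-1]),
        n_pathways=len(selected),
    )
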