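"""Recursive Feature Addition: greedy forward selection by cross-validated AUC.

Starting from an empty set, every remaining candidate (in sorted-name
order) is evaluated by the mean AUC of a stratified 5-fold CV of a
logistic-regression base classifier; the best candidate is permanently
added iff it raises the incumbent mean AUC by more than the tolerance
(default 0.001). Selection stops on tolerance failure, decline, or
candidate exhaustion.

Determinism: folds are fixed once per call from the seed and reused for
every candidate evaluation (paired comparisons); argmax ties break toward
the earliest sorted name, so the result is invariant to the column order
of the input table. Class imbalance is handled by random oversampling of
the minority class inside each training fold only (never the held-out
fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = ["SelectionResult", "cv_auc", "rfa"]

# effectively unpenalized LR ("logistic regression" unqualified)
LR_KWARGS = dict(C=1e6, max_iter=1000, solver="lbfgs")


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":  # "low"/"high" strings -> 0/1
        y = (y == "high").astype(int)
    return y.astype(int)


def _oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices resampling the minority class with replacement to 1:1."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present")
    minority, majority = (idx1, idx0) if len(idx1) < len(idx0) else (idx0, idx1)
    if len(minority) == len(majority):
        return np.arange(len(y))
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
    return np.concatenate([np.arange(len(y)), extra])


def make_folds(y: np.ndarray, folds: int, seed: int):
    """Seeded stratified folds, fixed once and reused across candidates."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _fold_auc(x: np.ndarray, y: np.ndarray, train, test, rng) -> float:
    res = _oversample_indices(y[train], rng)
    xt, yt = x[train][res], y[train][res]
    scaler = StandardScaler().fit(xt)
    lr = LogisticRegression(**LR_KWARGS).fit(scaler.transform(xt), yt)
    scores = lr.predict_proba(scaler.transform(x[test]))[:, 1]
    return float(roc_auc_score(y[test], scores))


def cv_auc(
    feature_subset: pd.DataFrame | np.ndarray,
    labels,
    folds: int = 5,
    seed: int = 0,
    fold_indices=None,
) -> float:
    """Mean held-out AUC of LR over stratified K folds (seeded).

    Oversampling (to 1:1) and feature standardization are fit inside each
    training fold; the held-out fold is scored untouched.
    """
    x = np.asarray(feature_subset, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] == 0:
        raise ValueError("feature subset must be non-empty")
    y = _as_labels(labels)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 cases per class")
    if fold_indices is None:
        fold_indices = make_folds(y, folds, seed)
    aucs = []
    for f, (train, test) in enumerate(fold_indices):
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError("a fold contains a single class (stratification error)")
        rng = np.random.default_rng(np.random.SeedSequence((seed, f)))
        aucs.append(_fold_auc(x, y, train, test, rng))
    return float(np.mean(aucs))


@dataclass
class SelectionResult:
    """Ordered selected features with the accepted-step CV-AUC trajectory."""

    selected: list[str]
    trajectory: list[float]
    stopping_reason: str  # "tolerance" | "decline" | "exhausted"
    candidate_history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "trajectory": self.trajectory,
            "stopping_reason": self.stopping_reason,
        }


def rfa(
    table: pd.DataFrame,
    labels,
    folds: int = 5,
    tol: float = 0.001,
    seed: int = 0,
    max_features: int | None = None,
) -> SelectionResult:
    """Greedy forward selection maximizing mean CV AUC (see module docs)."""
    y = _as_labels(labels)
    fold_indices = make_folds(y, folds, seed)
    candidates = sorted(table.columns)
    selected: list[str] = []
    trajectory: list[float] = []
    history: list[dict] = []
    incumbent = 0.5  # chance level for the empty model

    while candidates:
        best_name, best_auc = None, -np.inf
        for name in candidates:  # sorted order; strict > keeps earliest on ties
            auc = cv_auc(
                table[selected + [name]], y, folds=folds, seed=seed,
                fold_indices=fold_indices,
            )
            if auc > best_auc:
                best_name, best_auc = name, auc
        history.append({"step": len(selected) + 1, "best": best_name, "auc": best_auc})
        if best_auc < incumbent:
            reason = "decline"
            break
        if best_auc - incumbent <= tol:
            reason = "tolerance"
            break
        selected.append(best_name)
        trajectory.append(best_auc)
        candidates.remove(best_name)
        incumbent = best_auc
        if max_features is not None and len(selected) >= max_features:
            reason = "exhausted"
            break
    else:
        reason = "exhausted"
    return SelectionResult(selected, trajectory, reason, history)
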