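"""Model fitting, evaluation and interpretability.

Logistic-regression models are trained on oversampled (1:1), standardized
features; the decision threshold is fixed on the training ROC by Youden's
J and carried unchanged to validation and external test. Reports give AUC
with a stratified-bootstrap percentile 95% CI, ACC/SEN/SPE and the
redundant TPR/FPR columns (SEN = TPR, FPR = 1 - SPE), plus ROC and
precision-recall curve points. Decision-curve analysis uses
NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t). Feature attributions use the
exact closed-form Shapley values of a linear model with an independence
baseline: phi_ij = w_j * (x_ij - mean_j) on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .rfa_select import LR_KWARGS, _as_labels, _oversample_indices

__all__ = [
    "FittedModel",
    "EvaluationReport",
    "DCACurve",
    "ShapReport",
    "oversample",
    "fit_lr",
    "evaluate",
    "decision_curve",
    "shap_linear",
]


def oversample(train_indices, labels, seed: int = 0) -> np.ndarray:
    """Balanced index multiset: minority resampled with replacement to 1:1.

    ``train_indices`` are positions into ``labels``; the returned multiset
    contains every original index once plus resampled minority indices.
    """
    idx = np.asarray(train_indices)
    y = _as_labels(labels)[idx]
    rng = np.random.default_rng(seed)
    return idx[_oversample_indices(y, rng)]


@dataclass
class FittedModel:
    feature_names: list[str]
    coef: np.ndarray                 # per standardized feature
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    threshold: float                 # probability threshold (Youden on training)
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.feature_names):
            raise ValueError("coefficient count must equal feature count")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def _x(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in table.columns]
            if missing:
                raise ValueError(f"feature schema mismatch, missing {missing}")
            x = table[self.feature_names].to_numpy(float)
        else:
            x = np.asarray(table, float)
            if x.shape[1] != len(self.feature_names):
                raise ValueError("feature schema mismatch")
        return (x - self.scaler_mean) / self.scaler_scale

    def decision_function(self, table) -> np.ndarray:
        return self._x(table) @ self.coef + self.intercept

    def predict_proba(self, table) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(table)))

    def predict(self, table) -> np.ndarray:
        return (self.predict_proba(table) >= self.threshold).astype(int)


def fit_lr(table, labels, sample_indices=None) -> FittedModel:
    """Fit LR on (already oversampled) training data; Youden threshold.

    ``sample_indices`` may carry an oversampled index multiset; when None
    the rows are used as-is. Features are standardized internally.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        x = table.to_numpy(float)
    else:
        x = np.asarray(table, float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = _as_labels(labels)
    if sample_indices is not None:
        x, y = x[sample_indices], y[sample_indices]
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    lr = LogisticRegression(**LR_KWARGS).fit(xs, y)
    converged = bool(np.all(lr.n_iter_ < LR_KWARGS["max_iter"]))

    prob = lr.predict_proba(xs)[:, 1]
    fpr, tpr, thr = roc_curve(y, prob)
    youden = np.argmax(tpr - fpr)
    threshold = float(np.clip(thr[youden], 1e-9, 1 - 1e-9))
    model = FittedModel(
        feature_names=names,
        coef=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        threshold=threshold,
        converged=converged,
    )
    if not converged:
        import warnings

        warnings.warn(
            f"LR did not converge in {LR_KWARGS['max_iter']} iterations "
            f"(n={len(y)}, p={len(names)})"
        )
    return model


# ------------------------------------------------------------ evaluation --

def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC (equals the all-pairs count with ties = 1/2)."""
    return float(roc_auc_score(y, scores))


def _rates(y: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sen = tp / (tp + fn) if tp + fn else np.nan
    spe = tn / (tn + fp) if tn + fp else np.nan
    return {
        "ACC": (tp + tn) / len(y),
        "SEN": sen,
        "SPE": spe,
        "TPR": sen,            # identities enforced by construction
        "FPR": 1.0 - spe,
    }


@dataclass
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    metrics: dict[str, float]          # ACC/SEN/SPE/TPR/FPR
    roc: tuple[np.ndarray, np.ndarray]            # (FPR, TPR)
    pr: tuple[np.ndarray, np.ndarray]             # (recall, precision)
    n: int = 0

    def row(self) -> dict[str, float]:
        return {
            "AUC": self.auc,
            "CI_low": self.auc_ci[0],
            "CI_high": self.auc_ci[1],
            **self.metrics,
        }


def evaluate(model_or_scores, table=None, labels=None, n_boot: int = 2000, seed: int = 0,
             threshold: float | None = None) -> EvaluationReport:
    """Evaluate a fitted model (or raw scores) against labels.

    Accepts either ``evaluate(model, table, labels)`` or
    ``evaluate(scores, labels=...)`` for precomputed probabilities (pooled
    out-of-fold validation). The 95% CI is a stratified bootstrap
    percentile interval with ``n_boot`` replicates.
    """
    if isinstance(model_or_scores, FittedModel):
        scores = model_or_scores.predict_proba(table)
        thr = model_or_scores.threshold if threshold is None else threshold
    else:
        scores = np.asarray(model_or_scores, float)
        if threshold is None:
            raise ValueError("threshold required when evaluating raw scores")
        thr = threshold
    y = _as_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation set contains a single class: AUC undefined")

    auc = auc_rank(y, scores)
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    boots = np.empty(n_boot)
    for b in range(n_boot):  # stratified: resample within each class
        i0 = rng.choice(idx0, len(idx0), replace=True)
        i1 = rng.choice(idx1, len(idx1), replace=True)
        ii = np.concatenate([i0, i1])
        boots[b] = roc_auc_score(y[ii], scores[ii])
    ci = tuple(np.percentile(boots, [2.5, 97.5]))

    pred = (scores >= thr).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    precision, recall, _ = precision_recall_curve(y, scores)
    return EvaluationReport(
        auc=auc, auc_ci=(float(ci[0]), float(ci[1])), metrics=_rates(y, pred),
        roc=(fpr, tpr), pr=(recall, precision), n=len(y),
    )


# ------------------------------------------------------------------ DCA --

@dataclass
class DCACurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    prevalence: float


def decision_curve(model_or_scores, table=None, labels=None, pt_grid=None) -> DCACurve:
    """Net benefit of acting on model predictions across threshold probabilities.

    NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t), classifying positive at
    score >= p_t. Treat-all and treat-none references included.
    """
    if isinstance(model_or_scores, FittedModel):
        scores = model_or_scores.predict_proba(table)
    else:
        scores = np.asarray(model_or_scores, float)
    y = _as_labels(labels)
    if pt_grid is None:
        pt_grid = np.linspace(0.01, 0.99, 99)
    pt = np.asarray(pt_grid, float)
    if (pt <= 0).any() or (pt >= 1).any():
        raise ValueError("pt_grid must lie strictly inside (0, 1)")
    n = len(y)
    prev = float(y.mean())
    odds = pt / (1.0 - pt)
    nb_model = np.empty_like(pt)
    for k, p in enumerate(pt):
        pred = scores >= p
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        nb_model[k] = tp - fp * odds[k]
    nb_all = prev - (1.0 - prev) * odds
    return DCACurve(pt, nb_model, nb_all, np.zeros_like(pt), prev)


def net_benefit(tp: int, fp: int, n: int, pt: float) -> float:
    """Closed-form net benefit of a fixed 2x2 classification at p_t."""
    return tp / n - (fp / n) * pt / (1.0 - pt)


# ----------------------------------------------------------------- SHAP --

@dataclass
class ShapReport:
    feature_names: list[str]
    values: np.ndarray               # (n_cases, n_features), logit scale
    baseline: float                  # expected logit at the feature means
    ranking: list[str] = field(default_factory=list)  # by mean |attribution|

    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=self.feature_names
        ).sort_values(ascending=False)


def shap_linear(model: FittedModel, table) -> ShapReport:
    """Exact Shapley attributions of a linear model (independence baseline).

    phi_ij = w_j * (z_ij - mean(z_j)) on the logit scale, where z is the
    model's standardized feature space; attributions plus the baseline
    reproduce each case's logit exactly.
    """
    z = model._x(table)
    ref = z.mean(axis=0)
    values = model.coef[None, :] * (z - ref[None, :])
    baseline = float(ref @ model.coef + model.intercept)
    report = ShapReport(list(model.feature_names), values, baseline)
    report.ranking = list(report.mean_abs().index)
    return report
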