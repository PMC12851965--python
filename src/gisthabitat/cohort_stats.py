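"""Cohort-characteristics summary with the standard clinical test battery.

Continuous variables are compared low- vs high-mitotic within each center
(and center 1 vs center 2 overall) with a t-test when both groups pass
Shapiro-Wilk normality at alpha = 0.05, else Mann-Whitney U. Categorical
variables use the (uncorrected Pearson) chi-square test unless any expected
cell is below 5, in which case Fisher's exact test is used (2x2: exact;
r x c: seeded Monte-Carlo Freeman-Halton). Cells are printed as
``count(percent)`` with percentages rounded half-up to two decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["percent", "chi_square", "fisher_exact_rc", "summarize_cohort", "CohortSummary"]

ALPHA_NORMALITY = 0.05
CONTINUOUS = ("age", "bmi", "cea", "afp", "ca199", "ca125", "size_cm")
CATEGORICAL = {"sex": ("M", "F"), "location": ("cardia", "fundus", "body", "antrum")}


def percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to two decimals (table cell format)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be in [0, total]")
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def format_count(count: int, total: int) -> str:
    return f"{count}({percent(count, total):.2f})"


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction): sum (O-E)^2 / E."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def _table_logprob(table: np.ndarray) -> float:
    """Log-probability of a contingency table under fixed margins."""
    from scipy.special import gammaln

    t = np.asarray(table)
    n = t.sum()
    return float(
        gammaln(t.sum(1) + 1).sum()
        + gammaln(t.sum(0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact_rc(table: np.ndarray, n_mc: int = 5000, seed: int = 0) -> float:
    """Fisher-Freeman-Halton p-value for an r x c table.

    2x2 tables use scipy's exact test; larger tables a seeded Monte-Carlo
    permutation over tables with the observed margins.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t)[1])
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    lp_obs = _table_logprob(t)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1)
        if _table_logprob(sim) <= lp_obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def _compare_continuous(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Normality-routed two-group comparison; returns (p, test name)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    def normal(x):
        if len(x) < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > ALPHA_NORMALITY
    if normal(a) and normal(b):
        return float(stats.ttest_ind(a, b).pvalue), "t-test"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue), "Mann-Whitney U"


def _compare_categorical(a: pd.Series, b: pd.Series, levels, seed: int = 0):
    tab = np.array(
        [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
    ).T
    tab = tab[tab.sum(axis=1) > 0]  # drop empty levels
    if tab.shape[0] < 2:
        return np.nan, "n/a"
    expected = stats.contingency.expected_freq(tab)
    if (expected < 5).any():
        return fisher_exact_rc(tab, seed=seed), "Fisher exact"
    return chi_square(tab)[1], "chi-square"


@dataclass
class CohortSummary:
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize_cohort(manifest_or_frame, seed: int = 0) -> CohortSummary:
    """Cohort-characteristics table: per-variable group summaries with
    within-center (low vs high) and between-center p-values."""
    if isinstance(manifest_or_frame, pd.DataFrame):
        df = manifest_or_frame
    else:
        df = manifest_or_frame.to_frame()

    rows = []
    groups = {
        (center, label): df[(df.center == center) & (df.label == label)]
        for center in (1, 2)
        for label in ("low", "high")
    }
    c1 = df[df.center == 1]
    c2 = df[df.center == 2]

    for var in CONTINUOUS:
        row = {"variable": var, "category": ""}
        for center in (1, 2):
            lo, hi = groups[(center, "low")][var], groups[(center, "high")][var]
            for label, series in (("low", lo), ("high", hi)):
                row[f"center{center}_{label}"] = f"{series.mean():.2f} ± {series.std():.2f}"
            if len(lo) >= 2 and len(hi) >= 2:
                p, test = _compare_continuous(lo, hi)
            else:
                p, test = np.nan, "skipped"
                warnings.warn(f"{var}: a center-{center} group is empty/too small")
            row[f"center{center}_p"] = p
            row[f"center{center}_test"] = test
        p, test = _compare_continuous(c1[var], c2[var])
        row["between_center_p"], row["between_center_test"] = p, test
        row["significant"] = bool(
            np.nanmin([row.get("center1_p", np.nan), row.get("center2_p", np.nan), p]) < 0.05
        )
        rows.append(row)

    for var, levels in CATEGORICAL.items():
        head = {"variable": var, "category": ""}
        for center in (1, 2):
            lo, hi = groups[(center, "low")], groups[(center, "high")]
            p, test = _compare_categorical(lo[var], hi[var], levels, seed=seed)
            head[f"center{center}_p"], head[f"center{center}_test"] = p, test
        p, test = _compare_categorical(c1[var], c2[var], levels, seed=seed)
        head["between_center_p"], head["between_center_test"] = p, test
        rows.append(head)
        for lv in levels:
            row = {"variable": var, "category": lv}
            for center in (1, 2):
                for label in ("low", "high"):
                    g = groups[(center, label)]
                    if len(g):
                        row[f"center{center}_{label}"] = format_count(
                            int((g[var] == lv).sum()), len(g)
                        )
            rows.append(row)

    return CohortSummary(pd.DataFrame(rows))
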