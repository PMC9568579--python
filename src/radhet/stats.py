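"""Cohort-level hypothesis tests on CV profiles.

Per feature: a two-sided one-sample t-test of the per-patient mean CVs
against 0 (is the captured variation non-null?), and an exact two-sided
Wilcoxon rank-sum comparison of the oligometastatic versus multimetastatic
per-patient CVs.  The significance threshold is Bonferroni-corrected by
the number of tests actually run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "test_cv_nonzero",
    "compare_cohorts",
    "bonferroni_threshold",
    "StatsReport",
    "cv_stats_report",
]

_EXACT_MAX_N = 16  # full enumeration of C(n, n_a) assignments up to here


def test_cv_nonzero(values) -> float:
    """Two-sided one-sample t-test p-value against a zero mean.

    Zero-variance degenerate inputs use the limiting conventions: all
    zeros -> p = 1 (nothing to detect); constant nonzero -> p = 0.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise InsufficientDataError("t-test needs n >= 3")
    if x.std(ddof=1) == 0:
        return 1.0 if x.mean() == 0 else 0.0
    return float(sps.ttest_1samp(x, 0.0).pvalue)


def _rank_sum_enumeration(pooled_ranks: np.ndarray, n_a: int, observed: float) -> float:
    n = len(pooled_ranks)
    center = n_a * (n + 1) / 2.0
    dev = abs(observed - center)
    hits = 0
    for idx in combinations(range(n), n_a):
        w = pooled_ranks[list(idx)].sum()
        if abs(w - center) >= dev - 1e-9:
            hits += 1
    return hits / comb(n, n_a)


def compare_cohorts(cv_a, cv_b) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value.

    For total n <= 16 the permutation distribution of the rank sum is
    enumerated in full (midranks handle ties, so ties shrink the attainable
    deviations rather than needing a continuity correction); larger
    samples fall back to the normal approximation with tie correction.
    """
    a = np.asarray(cv_a, dtype=np.float64)
    b = np.asarray(cv_b, dtype=np.float64)
    if a.size == 0 or b.size == 0 or a.size + b.size < 4:
        raise InsufficientDataError("need nonempty groups with n_a + n_b >= 4")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    observed = float(ranks[: a.size].sum())
    if pooled.size <= _EXACT_MAX_N:
        return float(_rank_sum_enumeration(ranks, a.size, observed))
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Corrected per-test significance level ``alpha / m``."""
    if m < 1:
        raise ConfigurationError("number of tests must be >= 1")
    return alpha / m


@dataclass
class StatsReport:
    """Per-feature test results with the Bonferroni-corrected threshold."""

    table: pd.DataFrame
    alpha: float
    n_tests: int
    alpha_corrected: float


def cv_stats_report(cv_per_patient: pd.DataFrame,
                    groups: pd.Series | None = None,
                    alpha: float = 0.05) -> StatsReport:
    """Run the cohort tests on a patients x features CV table.

    ``groups`` (optional) labels each patient ``oligo`` or ``multi`` for
    the between-cohort rank-sum comparison.  ``m`` for the Bonferroni
    correction is the number of p-values actually computed, recorded in
    the report rather than assumed.
    """
    rows = []
    n_tests = 0
    for feat in cv_per_patient.columns:
        col = cv_per_patient[feat].to_numpy(dtype=np.float64)
        col = col[np.isfinite(col)]
        row = {"feature": feat, "mean_cv_pct": float(col.mean()) if col.size else float("nan")}
        if col.size >= 3:
            row["p_nonzero"] = test_cv_nonzero(col)
            n_tests += 1
        else:
            row["p_nonzero"] = float("nan")
        if groups is not None:
            ga = cv_per_patient.loc[groups == "oligo", feat].dropna().to_numpy()
            gb = cv_per_patient.loc[groups == "multi", feat].dropna().to_numpy()
            if ga.size and gb.size and ga.size + gb.size >= 4:
                row["p_oligo_vs_multi"] = compare_cohorts(ga, gb)
                n_tests += 1
            else:
                row["p_oligo_vs_multi"] = float("nan")
        rows.append(row)
    thr = bonferroni_threshold(alpha, max(n_tests, 1))
    table = pd.DataFrame(rows)
    for col in ("p_nonzero", "p_oligo_vs_multi"):
        if col in table.columns:
            table[f"significant_{col[2:]}"] = table[col] < thr
    return StatsReport(table=table, alpha=alpha, n_tests=n_tests,
                       alpha_corrected=thr)
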