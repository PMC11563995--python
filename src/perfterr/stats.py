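"""Rank-based two-sample comparison and normality screening.

The central tool is an exact small-sample Mann-Whitney U test: for pooled
sample sizes up to :data:`EXACT_MAX_N` the two-sided p-value is computed by
enumerating every C(n_a + n_b, n_a) assignment of the observed pooled values
to groups, which handles ties (frequent here, because contribution
percentages clip at 0 and 100) without any correction terms. Larger samples
fall back to the tie- and continuity-corrected normal approximation.

Two-sided p is defined symmetrically: the probability mass of assignments
whose U deviates from the null mean n_a*n_b/2 at least as far as observed.
The enumeration works on doubled mid-ranks (always integers), so all
comparisons are exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu, rankdata, shapiro

from .contribution import ContributionEstimate, _cell_values
from .errors import ValidationError
from .regions import TABLE_CELLS

__all__ = ["TestResult", "mann_whitney", "normality_test", "compare_regions", "EXACT_MAX_N"]

#: Largest pooled sample size handled by exact enumeration (C(20,10) ~ 1.8e5).
EXACT_MAX_N = 20

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


_comb_cache: dict[tuple[int, int], np.ndarray] = {}
_null_cache: dict[tuple[int, tuple], tuple[np.ndarray, int]] = {}


def _combination_indices(n: int, k: int) -> np.ndarray:
    key = (n, k)
    if key not in _comb_cache:
        _comb_cache[key] = np.fromiter(
            (i for combo in combinations(range(n), k) for i in combo),
            dtype=np.intp,
        ).reshape(-1, k)
    return _comb_cache[key]


def _exact_deviations(r2: np.ndarray, n_a: int) -> tuple[np.ndarray, int]:
    """Sorted |2U - n_a*n_b| over all group-a assignments of the pooled
    doubled mid-ranks ``r2`` (memoized on the rank multiset)."""
    n = len(r2)
    key = (n_a, tuple(np.sort(r2).tolist()))
    if key not in _null_cache:
        combs = _combination_indices(n, n_a)
        sums2 = r2[combs].sum(axis=1)
        u2 = sums2 - n_a * (n_a + 1)  # doubled U for group a
        dev = np.abs(u2 - n_a * (n - n_a))
        dev.sort()
        if len(_null_cache) > 64:
            _null_cache.clear()
        _null_cache[key] = (dev, len(dev))
    return _null_cache[key]


def mann_whitney(a, b, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns U for the first sample, computed from mid-ranks. With
    ``method="auto"`` the p-value is exact by complete enumeration of group
    assignments for pooled n <= 20, otherwise the normal approximation with
    tie correction and continuity correction; ``"exact"`` or
    ``"normal_approx"`` force a path.
    """
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"method must be auto|exact|normal_approx, got {method!r}")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    u2_obs = int(r2[:n_a].sum()) - n_a * (n_a + 1)
    u_a = u2_obs / 2.0
    n = n_a + n_b
    if method == "exact" or (method == "auto" and n <= EXACT_MAX_N):
        if n > 28:  # enumeration size guard: C(n, n/2) grows combinatorially
            raise ValidationError(f"exact enumeration not supported for pooled n = {n}")
        dev, total = _exact_deviations(r2, n_a)
        obs = abs(u2_obs - n_a * n_b)
        p = float((total - np.searchsorted(dev, obs, side="left")) / total)
        method = "exact"
    else:
        p = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "normal_approx"
    return TestResult(
        test_name="mann_whitney_u",
        statistic=u_a,
        p_value=p,
        method=method,
        n_a=n_a,
        n_b=n_b,
        significant=p < ALPHA,
    )


def normality_test(values) -> TestResult:
    """Shapiro-Wilk normality screen (Royston approximation, via SciPy).

    Descriptive only — it gates nothing downstream. Requires 3 <= n <= 5000
    and a non-constant sample.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    if n < 3 or n > 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {n}")
    if np.ptp(values) == 0:
        raise ValidationError("Shapiro-Wilk W is undefined for a constant sample")
    w, p = shapiro(values)
    return TestResult(
        test_name="shapiro_wilk",
        statistic=float(w),
        p_value=float(p),
        method="reference",
        n_a=n,
        n_b=0,
        significant=p < ALPHA,
    )


def compare_regions(
    estimates: list[ContributionEstimate],
) -> dict[tuple[str, str | None], TestResult]:
    """Mann-Whitney comparison of MFCA% vs LFCA% per report cell.

    Mirrors the study's analysis: an unpaired test of the cohort's MFCA
    percentages against the (complementary) LFCA percentages, flagged at
    alpha = 0.05 with no multiplicity adjustment.
    """
    out: dict[tuple[str, str | None], TestResult] = {}
    for region, sub in TABLE_CELLS:
        mfca = _cell_values(estimates, region, sub, "MFCA")
        lfca = _cell_values(estimates, region, sub, "LFCA")
        if len(mfca) == 0:
            raise ValidationError(f"no usable estimates for cell ({region}, {sub})")
        out[(region, sub)] = mann_whitney(mfca, lfca)
    return out
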