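"""Rank-based and parametric group comparisons.

The central inference is a two-sided Mann-Whitney U test among three
samples of mean entropies: the with-site flank windows, the
without-site flank windows, and the fourfold-site resampling null.
Method selection is explicit and recorded in the result: the exact U
distribution for small tie-free samples, an exact midrank
label-permutation enumeration for small tied samples, and the normal
approximation with tie and continuity corrections otherwise.

One-sided Student's t-tests (equal-variance by default, Welch behind a
flag) with the conventional */**/*** star coding serve the phenotype and
expression comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .entropy import EntropyProfile, pooled_window_values
from .nulls import NullEnsemble

_ALTERNATIVES = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample rank test with the method spelled out."""

    statistic: float        # U of the first sample
    p_value: float
    n1: int
    n2: int
    method: str             # exact | normal_approximation
    tie_corrected: bool
    sidedness: str          # two | greater | less

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.statistic <= self.n1 * self.n2 + 1e-9):
            raise ValueError("U must lie in [0, n1*n2]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _exact_permutation_u(
    x: np.ndarray, y: np.ndarray, sided: str
) -> tuple[float, float]:
    """Exact midrank permutation test: enumerate all group labelings."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    us = np.array(
        [ranks[list(idx)].sum() - offset
         for idx in combinations(range(n1 + n2), n1)]
    )
    mu = n1 * n2 / 2
    eps = 1e-9
    if sided == "two":
        p = float(np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - eps))
    elif sided == "greater":
        p = float(np.mean(us >= u_obs - eps))
    else:
        p = float(np.mean(us <= u_obs + eps))
    return float(u_obs), p


def mann_whitney(
    sample1: Sequence[float],
    sample2: Sequence[float],
    sided: str = "two",
    exact_bound: int = 400,
    enumeration_limit: int = 20000,
) -> TestResult:
    """Mann-Whitney U test with explicit, recorded method selection.

    Tie-free samples with n1*n2 <= ``exact_bound`` use the exact U
    distribution; tied samples small enough to enumerate
    (C(n1+n2, n1) <= ``enumeration_limit``) use an exact midrank
    label-permutation; everything else uses the normal approximation
    with tie and continuity corrections.  The reported U is that of
    ``sample1``.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if sided not in _ALTERNATIVES:
        raise ValueError(f"sided must be one of {sorted(_ALTERNATIVES)}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties and n1 * n2 <= exact_bound:
        res = sps.mannwhitneyu(x, y, alternative=_ALTERNATIVES[sided], method="exact")
        return TestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue),
            n1=n1, n2=n2, method="exact", tie_corrected=False, sidedness=sided,
        )
    if has_ties and comb(n1 + n2, n1) <= enumeration_limit:
        u_obs, p = _exact_permutation_u(x, y, sided)
        return TestResult(
            statistic=u_obs, p_value=max(p, np.finfo(float).tiny),
            n1=n1, n2=n2, method="exact", tie_corrected=True, sidedness=sided,
        )
    res = sps.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[sided], method="asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=n1, n2=n2, method="normal_approximation",
        tie_corrected=has_ties, sidedness=sided,
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    direction: str
    equal_variance: bool
    stars: str


def significance_stars(p: float) -> str:
    """Conventional star coding: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def one_sided_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str = "greater",
    equal_variance: bool = True,
) -> TTestResult:
    """One-sided Student's t-test of ``group_a`` against ``group_b``.

    ``direction='greater'`` tests whether A's mean exceeds B's.
    Equal-variance Student's t by default; Welch with
    ``equal_variance=False``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if direction not in {"greater", "less"}:
        raise ValueError("direction must be 'greater' or 'less'")
    res = sps.ttest_ind(a, b, equal_var=equal_variance, alternative=direction)
    p = float(res.pvalue)
    return TTestResult(
        statistic=float(res.statistic), p_value=p, n1=a.size, n2=b.size,
        direction=direction, equal_variance=equal_variance,
        stars=significance_stars(p),
    )


def compare_groups(
    with_profiles: Iterable[EntropyProfile] | Mapping[str, EntropyProfile],
    without_profiles: Iterable[EntropyProfile] | Mapping[str, EntropyProfile],
    null: NullEnsemble | None = None,
    sided: str = "two",
) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """All pairwise rank tests among the two groups and the resampling null.

    Samples are the window mean-entropy values pooled across both flanks
    within each group (the pooling convention is recorded in run
    metadata by the pipeline).  Returns the test dictionary plus a
    summary table of per-sample sizes and medians.
    """
    def _values(profiles):
        if isinstance(profiles, Mapping):
            profiles = profiles.values()
        return pooled_window_values(list(profiles))

    w = _values(with_profiles)
    wo = _values(without_profiles)
    samples = {"with_site": w, "without_site": wo}
    if null is not None:
        samples["null"] = np.asarray(null.values, dtype=float)

    tests = {"with_vs_without": mann_whitney(w, wo, sided=sided)}
    if null is not None:
        tests["with_vs_null"] = mann_whitney(w, samples["null"], sided=sided)
        tests["without_vs_null"] = mann_whitney(wo, samples["null"], sided=sided)

    summary = pd.DataFrame(
        {
            "sample": list(samples),
            "n": [len(v) for v in samples.values()],
            "median_entropy": [float(np.median(v)) for v in samples.values()],
            "mean_entropy": [float(np.mean(v)) for v in samples.values()],
        }
    )
    return tests, summary
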