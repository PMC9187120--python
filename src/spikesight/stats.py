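"""Shared inferential machinery: permutation tests, FDR, proportion tests.

Per-neuron modulation is assessed with nonparametric permutation tests:
paired comparisons (response vs. baseline within trials) use random sign
flips of the per-trial differences; unpaired group comparisons shuffle group
labels.  When the number of distinct permutations is small enough the null
distribution is enumerated exhaustively and the p-value is exact; otherwise
a Monte Carlo sample is drawn and the add-one estimator
``p = (1 + #{|null| >= |obs|}) / (1 + n_draws)`` is used so that p can never
be exactly zero.

Counts of modulated neurons are compared with a 2x2 chi-squared test of
equal proportions with Yates continuity correction, and families of
p-values are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError

DEFAULT_N_PERM = 10_000

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: Optional[int] = None
    alternative: str = "two-sided"
    seed: Optional[int] = None
    exhaustive: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _pvalue(null: np.ndarray, obs: float, alternative: str,
            exhaustive: bool) -> float:
    if alternative == "two-sided":
        hits = np.count_nonzero(np.abs(null) >= abs(obs) - 1e-12)
    elif alternative == "greater":
        hits = np.count_nonzero(null >= obs - 1e-12)
    else:
        hits = np.count_nonzero(null <= obs + 1e-12)
    if exhaustive:
        # the identity permutation is one of the enumerated draws
        return hits / null.size
    return (1 + hits) / (1 + null.size)


def permutation_test_paired(differences, n_perm: int = DEFAULT_N_PERM,
                            seed: Optional[int] = None,
                            alternative: str = "two-sided") -> TestResult:
    """Sign-flip permutation test on paired differences.

    The statistic is the mean difference.  The null distribution flips the
    sign of each difference independently; with ``2**n <= n_perm`` all sign
    patterns are enumerated and the p-value is exact.
    """
    _check_alternative(alternative)
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise AnalysisError("paired permutation test needs >= 1 non-missing difference")
    obs = float(d.mean())
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n_permutations=0,
                          alternative=alternative, seed=seed, exhaustive=True)

    n = d.size
    if n <= 62 and 2 ** n <= n_perm:
        idx = np.arange(2 ** n, dtype=np.uint64)
        bits = (idx[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        signs = 2.0 * bits - 1.0
        null = signs @ d / n
        p = _pvalue(null, obs, alternative, exhaustive=True)
        return TestResult(statistic=obs, p_value=p, n_permutations=int(2 ** n),
                          alternative=alternative, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    null = signs @ d / n
    p = _pvalue(null, obs, alternative, exhaustive=False)
    return TestResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      alternative=alternative, seed=seed, exhaustive=False)


def permutation_test_unpaired(group_a, group_b, n_perm: int = DEFAULT_N_PERM,
                              seed: Optional[int] = None,
                              alternative: str = "two-sided") -> TestResult:
    """Label-shuffle permutation test on two independent groups.

    The statistic is ``mean(a) - mean(b)``.  When the number of distinct
    labelings C(na+nb, na) is at most ``n_perm`` the null is enumerated
    exhaustively.
    """
    _check_alternative(alternative)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise AnalysisError("unpaired permutation test needs both groups non-empty")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    obs = float(a.mean() - b.mean())
    total = pooled.sum()

    def stat_from_sum_a(sum_a):
        # mean(a) - mean(b) expressed through the sum of the a-labeled values
        return sum_a / na - (total - sum_a) / (n - na)

    n_comb = math.comb(n, na)
    if n_comb <= n_perm:
        from itertools import combinations
        sums = np.array([pooled[list(c)].sum()
                         for c in combinations(range(n), na)])
        null = stat_from_sum_a(sums)
        p = _pvalue(null, obs, alternative, exhaustive=True)
        return TestResult(statistic=obs, p_value=p, n_permutations=n_comb,
                          alternative=alternative, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    # vectorized shuffles: rank of random keys picks the a-labeled subset
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
    sums = pooled[idx].sum(axis=1)
    null = stat_from_sum_a(sums)
    p = _pvalue(null, obs, alternative, exhaustive=False)
    return TestResult(statistic=obs, p_value=p, n_permutations=n_perm,
                      alternative=alternative, seed=seed, exhaustive=False)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Chi-squared test of equal proportions (2x2, Yates-corrected).

    Compares ``k1/n1`` against ``k2/n2``; symmetric under swapping the
    groups.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise AnalysisError("chi2_proportion_test needs n > 0 in both groups")
        if not 0 <= k <= n:
            raise AnalysisError("chi2_proportion_test needs 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        # degenerate margin: identical proportions by construction
        return TestResult(statistic=0.0, p_value=1.0, alternative="two-sided")
    res = sps.chi2_contingency(table, correction=True)
    return TestResult(statistic=float(res.statistic),
                      p_value=max(float(res.pvalue), np.nextafter(0, 1)),
                      alternative="two-sided")
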