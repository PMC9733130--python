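"""Permutation significance for rhythmicity scores and multiple-test correction.

A transcript's p-value compares its observed 24-hour power against the
distribution obtained by randomly shuffling the expression values across time
points.  Because shuffling preserves the value multiset, the total non-DC
power (the profile variance) is invariant, so ranking by P(24), RP24 or F24
gives the identical permutation p-value; the implementation ranks P(24).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral import ExpressionProfile, p24_of_values

__all__ = [
    "PermutationEnsemble",
    "permutation_ensemble",
    "permutation_pvalue",
    "exhaustive_pvalue",
    "bh_qvalues",
    "ks_compare",
]


@dataclass(frozen=True)
class PermutationEnsemble:
    """Null P(24) values from random time-point shuffles of one profile."""

    n_perm: int
    seed: int | None
    observed_p24: float
    null_p24: np.ndarray

    @property
    def mean_null_p24(self) -> float:
        return float(np.mean(self.null_p24))

    @property
    def p_value(self) -> float:
        """(1 + #{null ≥ observed}) / (1 + n_perm); ties count against the observed."""
        r = int(np.sum(self.null_p24 >= self.observed_p24))
        return (1 + r) / (1 + self.n_perm)

    @property
    def f24(self) -> float:
        mean = self.mean_null_p24
        if mean == 0.0:
            return float("nan") if self.observed_p24 == 0.0 else float("inf")
        return self.observed_p24 / mean


def permutation_ensemble(
    profile: ExpressionProfile,
    n_perm: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationEnsemble:
    """Draw ``n_perm`` uniform shuffles of the profile and record their P(24)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = profile.n_points
    observed = float(p24_of_values(profile.values, n, profile.duration))
    perms = np.tile(profile.values, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    null = p24_of_values(perms, n, profile.duration)
    return PermutationEnsemble(
        n_perm=n_perm, seed=seed, observed_p24=observed, null_p24=null
    )


def permutation_pvalue(
    profile: ExpressionProfile,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for 24-hour rhythmicity.

    p = (1 + #{null P(24) ≥ observed P(24)}) / (1 + n_perm).  Constant profiles
    get p = 1 (no rhythm to test).  Deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable p resolution")
    if profile.is_constant():
        return 1.0
    return permutation_ensemble(profile, n_perm, seed=seed, rng=rng).p_value


def exhaustive_pvalue(profile: ExpressionProfile) -> float:
    """Exact permutation p-value by enumerating all N! orderings (N ≤ 8 only)."""
    n = profile.n_points
    if n > 8:
        raise ValueError("exhaustive enumeration limited to N <= 8")
    observed = float(p24_of_values(profile.values, n, profile.duration))
    vals = profile.values
    count = 0
    total = 0
    for perm in _iter_permutations(range(n)):
        total += 1
        if float(p24_of_values(vals[list(perm)], n, profile.duration)) >= observed - 1e-12:
            count += 1
    return count / total


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_compare(scores_a, scores_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions.

    Infinite scores are legal (they rank above every finite value).  Returns
    (D, p) with the asymptotic p-value.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)
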