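"""Discrete Fourier decomposition of expression time series and the RP24 family of scores.

An expression profile :math:`E(t)` sampled at *N* equally spaced times
:math:`t_n = n\\Delta t` over a span of *T* hours is decomposed with the
discrete Fourier transform

.. math:: \\hat E_k = \\sum_{n=0}^{N-1} E_n e^{-2\\pi i k n / N}

whose index *k* corresponds to the period :math:`T_k = T/k`.  The folded
power spectrum :math:`P(T_k)` (k = 0..N/2) carries the strength of each
period; RP24 is the power at the 24-hour period divided by the summed power
of every other non-DC period, a per-transcript signal-to-noise ratio for
diurnal rhythmicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionProfile",
    "FourierCoefficients",
    "PowerSpectrum",
    "RhythmStats",
    "dft",
    "power_spectrum",
    "period_grid",
    "nyquist_index",
    "rp24",
    "rpT",
    "f24",
    "phase24",
]

#: Sentinel for scores that are undefined (e.g. on a constant profile).
UNDEFINED = float("nan")


def _is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class ExpressionProfile:
    """One transcript's expression values at regularly spaced times.

    Parameters
    ----------
    transcript_id : str
    times : array of sample times in hours, t_n = n*dt, strictly increasing
        and equally spaced.
    values : non-negative expression levels (FPKM), one per time.  Negative
        values are tolerated for simulated profiles (the sinusoid-plus-noise
        model permits them at low baseline).
    duration : total span T in hours (N * dt).
    condition : free label, e.g. ``"young"`` or ``"old"``.
    """

    transcript_id: str
    times: np.ndarray
    values: np.ndarray
    duration: float
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValueError("times and values must be 1-D and equal length")
        if len(times) < 4:
            raise ValueError("need at least 4 time points")
        if len(times) % 2:
            raise ValueError("N must be even (k = N/2 power-spectrum branch)")
        diffs = np.diff(times)
        if not np.all(diffs > 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
            raise ValueError(
                "times must be equally spaced; got spacings "
                f"{np.unique(np.round(diffs, 9))}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    @property
    def n_points(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0)


@dataclass(frozen=True)
class FourierCoefficients:
    """All N complex DFT coefficients of a real profile (negative-exponent convention)."""

    coefficients: np.ndarray
    duration: float

    @property
    def n_points(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class PowerSpectrum:
    """Folded power spectrum P(T_k), k = 0..N/2, with periods T_k = T/k (T_0 = DC)."""

    periods: np.ndarray  # periods[0] is inf (DC); periods[k] = T/k
    powers: np.ndarray
    duration: float

    @property
    def nyquist(self) -> int:
        return len(self.powers) - 1

    def power_at(self, period: float) -> float:
        k = self.index_of(period)
        return float(self.powers[k])

    def index_of(self, period: float) -> int:
        """Frequency index k with T_k == period, or raise ValueError."""
        matches = np.nonzero(np.isclose(self.periods[1:], period, rtol=1e-9))[0]
        if len(matches) == 0:
            raise ValueError(
                f"period {period} h is not on the Fourier grid "
                f"{np.round(self.periods[1:], 6).tolist()}"
            )
        return int(matches[0]) + 1


@dataclass
class RhythmStats:
    """Per-transcript, per-condition rhythmicity score bundle."""

    transcript_id: str
    condition: str
    rp24: float = UNDEFINED
    f24: float = UNDEFINED
    phase_hours: float = UNDEFINED
    p_value: float = 1.0
    q_value: float = 1.0
    max_min_fold: float = UNDEFINED
    median_expr: float = UNDEFINED
    sp: float = UNDEFINED
    pvec: float = UNDEFINED
    spike_var_fraction: float = UNDEFINED
    extra: dict = field(default_factory=dict)


def dft(profile: ExpressionProfile) -> FourierCoefficients:
    """Discrete Fourier transform of an expression profile.

    Uses the negative-exponent convention Ê_k = Σ_n E_n exp(−2πikn/N), so the
    DC term Ê_0 equals the sum of the values.
    """
    coeffs = np.fft.fft(profile.values)
    return FourierCoefficients(coefficients=coeffs, duration=profile.duration)


def power_spectrum(coeffs: FourierCoefficients, duration: float | None = None) -> PowerSpectrum:
    """Fold DFT coefficients into the one-sided power spectrum.

    P(T_k) = |Ê_k|²/N² for k ∈ {0, N/2} and (|Ê_k|² + |Ê_{N−k}|²)/N² for
    1 ≤ k ≤ N/2 − 1.  Parseval: Σ_k P(T_k) = mean(E_n²).
    """
    if duration is None:
        duration = coeffs.duration
    c = np.asarray(coeffs.coefficients)
    n = len(c)
    if n % 2:
        raise ValueError("power spectrum fold requires even N")
    half = n // 2
    mag2 = np.abs(c) ** 2
    powers = np.empty(half + 1)
    powers[0] = mag2[0] / n**2
    powers[half] = mag2[half] / n**2
    ks = np.arange(1, half)
    powers[ks] = (mag2[ks] + mag2[n - ks]) / n**2
    periods = np.empty(half + 1)
    periods[0] = np.inf
    periods[1:] = duration / np.arange(1, half + 1)
    return PowerSpectrum(periods=periods, powers=powers, duration=duration)


def period_grid(n_points: int, duration: float) -> np.ndarray:
    """Valid Fourier periods T/k for k = 1..N/2 (up to the Nyquist frequency).

    For the 12-point, 48-hour design this is {48, 24, 16, 12, 9.6, 8} hours.
    """
    if n_points % 2:
        raise ValueError("N must be even")
    return duration / np.arange(1, n_points // 2 + 1)


def nyquist_index(n_points: int) -> int:
    """Highest resolvable frequency index, N/2."""
    if n_points % 2:
        raise ValueError("N must be even")
    return n_points // 2


def rpT(spectrum: PowerSpectrum, k: int) -> float:
    """Relative power of period T_k: P(T_k) / Σ_{j ∉ {0, k}} P(T_j).

    Returns +inf when every other non-DC power is exactly zero and P(T_k) > 0,
    and NaN (undefined) for a constant profile (0/0).
    """
    if not 1 <= k <= spectrum.nyquist:
        raise ValueError(f"k must be in [1, {spectrum.nyquist}], got {k}")
    signal = spectrum.powers[k]
    noise = float(np.sum(spectrum.powers[1:]) - signal)
    if noise == 0.0:
        return float("inf") if signal > 0 else UNDEFINED
    return float(signal / noise)


def rp24(spectrum: PowerSpectrum) -> float:
    """RP24: relative power of the 24-hour period.

    Equals ``rpT(spectrum, k)`` with k the index whose period is 24 h (k = 2
    for the 12-point/48-hour design).  Raises if 24 h is not on the grid.
    """
    k = spectrum.index_of(24.0)
    return rpT(spectrum, k)


def _p24(values: np.ndarray, k: int) -> float:
    """Folded power at frequency index k for a batch-friendly inner loop."""
    n = values.shape[-1]
    w = np.exp(-2j * np.pi * k * np.arange(n) / n)
    ck = values @ w
    if k == n // 2 or k == 0:
        return np.abs(ck) ** 2 / n**2
    return 2 * np.abs(ck) ** 2 / n**2


def p24_of_values(values: np.ndarray, n_points: int, duration: float) -> np.ndarray:
    """P(24 h) for an array of profiles with shape (..., N); vectorized.

    For real input the folded power at 1 ≤ k < N/2 is 2|Ê_k|²/N².
    """
    k24 = _k24_index(n_points, duration)
    vals = np.asarray(values, dtype=float)
    w = np.exp(-2j * np.pi * k24 * np.arange(n_points) / n_points)
    ck = vals @ w
    scale = 1.0 if k24 == n_points // 2 else 2.0
    return scale * np.abs(ck) ** 2 / n_points**2


def _k24_index(n_points: int, duration: float) -> int:
    """Frequency index whose period is 24 h; errors if 24 h is off-grid."""
    grid = period_grid(n_points, duration)
    matches = np.nonzero(np.isclose(grid, 24.0, rtol=1e-9))[0]
    if len(matches) == 0:
        raise ValueError(
            f"no 24-hour period on the Fourier grid for N={n_points}, T={duration}"
        )
    return int(matches[0]) + 1


def f24(
    profile: ExpressionProfile,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """F24: P(24) of the observed profile over its mean across random permutations.

    The permutation distribution shuffles the expression values across time
    points; a seeded generator makes the statistic reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if profile.is_constant():
        return UNDEFINED
    if rng is None:
        rng = np.random.default_rng(seed)
    n = profile.n_points
    observed = float(p24_of_values(profile.values, n, profile.duration))
    perms = np.tile(profile.values, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    null = p24_of_values(perms, n, profile.duration)
    mean_null = float(np.mean(null))
    if mean_null == 0.0:
        # every permutation kills the 24-h power exactly; degenerate
        return UNDEFINED if observed == 0.0 else float("inf")
    return observed / mean_null


def phase24(profile: ExpressionProfile) -> float:
    """Phase of peak expression on the 24-h clock, in hours in [0, 24).

    For E_24(t) = A cos((2π/24)t + φ) the 24-hour Fourier coefficient has
    argument φ, and the peak time is Phase = −12φ/π, reduced modulo 24.
    Undefined (NaN) for a constant profile.
    """
    if profile.is_constant():
        return UNDEFINED
    coeffs = dft(profile)
    k24 = _k24_index(profile.n_points, profile.duration)
    c = coeffs.coefficients[k24]
    if c == 0:
        return UNDEFINED
    phi = float(np.angle(c))
    # the DFT indexes samples from n = 0; shift back to absolute clock time
    return float((-12.0 * phi / np.pi + profile.times[0]) % 24.0)
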