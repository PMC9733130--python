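"""Detectability and staccato filtering, and two-age rhythmicity classification.

Transcripts scored in two conditions (young and old) are partitioned into
early life cyclers (rhythmic only in young), late life cyclers (rhythmic only
in old), robust life cyclers (rhythmic in both), and not-rhythmic, after
removing profiles whose q-value falls in the indeterminate band and profiles
that look like periodic single-time-point expression spikes ("staccato").

Staccato profiles spike at one time point per 24-hour cycle.  Their DFT has
exactly zero odd coefficients, which motivates two screening scores: the
spectral parity SP = log(Σ_{k even} P / Σ_{k odd} P), and PVEC, the circular
variance of the arguments of the even coefficients after aligning out the
spike position (for an ideal spike train the aligned arguments are all equal,
so PVEC = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectral import (
    UNDEFINED,
    ExpressionProfile,
    FourierCoefficients,
    PowerSpectrum,
    RhythmStats,
    dft,
)

__all__ = [
    "ClassificationThresholds",
    "RHYTHM_CLASSES",
    "spectral_parity",
    "pvec",
    "max_min_fold",
    "is_detectable",
    "spike_variance_fraction",
    "is_staccato",
    "classify_transcript",
    "euler_counts",
]

RHYTHM_CLASSES = ("ELC", "RLC", "LLC", "NR", "indeterminate", "staccato_filtered")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs for rhythmicity calls.

    q_rhythmic / q_arrhythmic bound the q-value bands (the open interval
    between them is the indeterminate band).  fold_detectable and
    median_fpkm_min define a "detectable" rhythmic transcript; fold_relaxed
    is the looser fold allowed in the second age for robust life cyclers.
    The staccato cutoffs were calibrated once on simulated noisy sinusoids
    versus noisy spike trains and frozen.
    """

    q_rhythmic: float = 0.05
    q_arrhythmic: float = 0.075
    fold_detectable: float = 1.5
    fold_relaxed: float = 1.4
    median_fpkm_min: float = 1.0
    sp_threshold: float = 1.5
    pvec_threshold: float = 0.15
    spike_var_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not self.q_rhythmic < self.q_arrhythmic:
            raise ValueError("q_rhythmic must be < q_arrhythmic")
        if not self.fold_relaxed < self.fold_detectable:
            raise ValueError("fold_relaxed must be < fold_detectable")


def spectral_parity(spectrum: PowerSpectrum) -> float:
    """SP: natural-log ratio of even to odd non-DC folded powers.

    +inf when the odd powers are exactly zero and some even power is positive
    (true for both an ideal spike train and a pure 24-h cosine — SP alone does
    not separate them); NaN for a constant profile.
    """
    ks = np.arange(1, spectrum.nyquist + 1)
    even = float(np.sum(spectrum.powers[ks[ks % 2 == 0]]))
    odd = float(np.sum(spectrum.powers[ks[ks % 2 == 1]]))
    if even == 0.0 and odd == 0.0:
        return UNDEFINED
    if odd == 0.0:
        return float("inf")
    if even == 0.0:
        return float("-inf")
    return math.log(even / odd)


def _spike_index_estimate(values: np.ndarray) -> int:
    """Most likely spike position, reduced modulo the half-cycle N/2."""
    return int(np.argmax(values)) % (len(values) // 2)


def pvec(
    coeffs: FourierCoefficients,
    values: np.ndarray | None = None,
    rel_tol: float = 1e-9,
) -> float:
    """Phase variance of the even Fourier coefficients.

    An ideal spike at position φ gives Ê_k = 2ΔE·e^(−2πikφ/N) for even k ≠ 0,
    so after multiplying by e^(+2πikφ̂/N) (φ̂ the spike-position estimate, the
    argmax of the profile modulo N/2) the arguments coincide.  The dispersion
    of the aligned arguments is measured as the circular variance
    1 − |mean resultant|, which is 0 for perfectly coordinated phases and
    approaches 1 for scattered ones.  Coefficients with zero magnitude are
    excluded; fewer than two usable coefficients → NaN.
    """
    c = np.asarray(coeffs.coefficients)
    n = len(c)
    ks = np.arange(2, n // 2 + 1, 2)
    mags = np.abs(c[ks])
    scale = float(np.max(np.abs(c[1:]))) if n > 1 else 0.0
    usable = ks[mags > rel_tol * max(scale, 1e-300)]
    if len(usable) < 2:
        return UNDEFINED
    if values is None:
        phi_hat = 0
    else:
        phi_hat = _spike_index_estimate(np.asarray(values))
    aligned = c[usable] * np.exp(2j * np.pi * usable * phi_hat / n)
    angles = np.angle(aligned)
    resultant = np.abs(np.mean(np.exp(1j * angles)))
    return float(1.0 - resultant)


def max_min_fold(profile: ExpressionProfile) -> float:
    """max(values)/min(values); +inf when min = 0 < max; NaN for an all-zero profile."""
    vmax = float(np.max(profile.values))
    vmin = float(np.min(profile.values))
    if vmax == 0.0 and vmin == 0.0:
        return UNDEFINED
    if vmin <= 0.0:
        return float("inf")
    return vmax / vmin


def is_detectable(
    profile: ExpressionProfile,
    thresholds: ClassificationThresholds,
    fold_key: str = "fold_detectable",
) -> bool:
    """Fold change ≥ the chosen fold threshold and median expression ≥ 1 FPKM."""
    if fold_key not in ("fold_detectable", "fold_relaxed"):
        raise ValueError("fold_key must be 'fold_detectable' or 'fold_relaxed'")
    fold = max_min_fold(profile)
    if math.isnan(fold):
        return False
    threshold = getattr(thresholds, fold_key)
    return fold >= threshold and float(np.median(profile.values)) >= thresholds.median_fpkm_min


def spike_variance_fraction(profile: ExpressionProfile) -> float:
    """Fraction of profile variance explained by the best two-spike model.

    Fits E_n = E0 + ΔE·[n ∈ {φ, φ+N/2}] by least squares over all spike
    positions φ and returns 1 − SS_resid/SS_total.  NaN for constant profiles.
    """
    v = profile.values
    n = len(v)
    sstot = float(np.sum((v - v.mean()) ** 2))
    if sstot == 0.0:
        return UNDEFINED
    best = -np.inf
    for phi in range(n // 2):
        mask = np.zeros(n, dtype=bool)
        mask[phi::n // 2] = True
        spike_mean = v[mask].mean()
        base_mean = v[~mask].mean()
        resid = float(np.sum((v[mask] - spike_mean) ** 2) + np.sum((v[~mask] - base_mean) ** 2))
        best = max(best, 1.0 - resid / sstot)
    return float(best)


def is_staccato(stats: RhythmStats, thresholds: ClassificationThresholds) -> bool:
    """Flag a profile as a periodic expression spike.

    Requires all three signatures: even-biased power (SP high), coordinated
    even-coefficient phases (PVEC low), and the two-spike model explaining
    most of the variance.  Undefined scores never flag.
    """
    sp, pv, svf = stats.sp, stats.pvec, stats.spike_var_fraction
    if any(isinstance(x, float) and math.isnan(x) for x in (sp, pv, svf)):
        return False
    return (
        sp >= thresholds.sp_threshold
        and pv <= thresholds.pvec_threshold
        and svf >= thresholds.spike_var_threshold
    )


def staccato_scores(profile: ExpressionProfile) -> tuple[float, float, float]:
    """(SP, PVEC, spike variance fraction) for one profile."""
    from .spectral import power_spectrum

    coeffs = dft(profile)
    spec = power_spectrum(coeffs)
    return (
        spectral_parity(spec),
        pvec(coeffs, values=profile.values),
        spike_variance_fraction(profile),
    )


def _in_indeterminate_band(q: float, thr: ClassificationThresholds) -> bool:
    return thr.q_rhythmic < q < thr.q_arrhythmic


def classify_transcript(
    stats_young: RhythmStats,
    stats_old: RhythmStats,
    thresholds: ClassificationThresholds,
    profile_young: ExpressionProfile | None = None,
    profile_old: ExpressionProfile | None = None,
) -> str:
    """Assign one of ELC / RLC / LLC / NR / indeterminate / staccato_filtered.

    Detectability (fold and median FPKM) is evaluated from the stats bundles;
    profiles may be passed to recompute fold/median if the bundles lack them.

    ELC: rhythmic (q ≤ q_rhythmic) and detectable at the 1.5-fold rule in
    young, arrhythmic (q ≥ q_arrhythmic) in old.  LLC: the mirror image.
    RLC: rhythmic in both ages, detectable at 1.5-fold in at least one age
    with the other age passing the relaxed 1.4-fold (median rule applies to
    both).  Staccato-flagged profiles in either age remove the transcript
    before any q-value logic; q-values in the open indeterminate band do the
    same afterwards.
    """
    if stats_young is None or stats_old is None:
        raise ValueError("both conditions are required for classification")

    def _fill(stats: RhythmStats, profile: ExpressionProfile | None) -> RhythmStats:
        if profile is not None and math.isnan(stats.max_min_fold):
            stats.max_min_fold = max_min_fold(profile)
            stats.median_expr = float(np.median(profile.values))
        return stats

    sy = _fill(stats_young, profile_young)
    so = _fill(stats_old, profile_old)

    if is_staccato(sy, thresholds) or is_staccato(so, thresholds):
        return "staccato_filtered"
    if _in_indeterminate_band(sy.q_value, thresholds) or _in_indeterminate_band(
        so.q_value, thresholds
    ):
        return "indeterminate"

    def _detect(stats: RhythmStats, fold_threshold: float) -> bool:
        fold = stats.max_min_fold
        if math.isnan(fold):
            return False
        return fold >= fold_threshold and stats.median_expr >= thresholds.median_fpkm_min

    rhythmic_y = sy.q_value <= thresholds.q_rhythmic
    rhythmic_o = so.q_value <= thresholds.q_rhythmic
    arrhythmic_y = sy.q_value >= thresholds.q_arrhythmic
    arrhythmic_o = so.q_value >= thresholds.q_arrhythmic
    det_y = _detect(sy, thresholds.fold_detectable)
    det_o = _detect(so, thresholds.fold_detectable)
    det_y_relaxed = _detect(sy, thresholds.fold_relaxed)
    det_o_relaxed = _detect(so, thresholds.fold_relaxed)

    if rhythmic_y and det_y and arrhythmic_o:
        return "ELC"
    if rhythmic_o and det_o and arrhythmic_y:
        return "LLC"
    if rhythmic_y and rhythmic_o and (
        (det_y and det_o_relaxed) or (det_o and det_y_relaxed)
    ):
        return "RLC"
    return "NR"


def euler_counts(labels, stats_young=None, stats_old=None, thresholds=None) -> dict:
    """Summary counts for the young/old rhythmic-overlap diagram.

    From classification labels: young-only = ELC, old-only = LLC,
    both = RLC.
    """
    labels = list(labels)
    return {
        "young_only": labels.count("ELC"),
        "old_only": labels.count("LLC"),
        "both": labels.count("RLC"),
        "not_rhythmic": labels.count("NR"),
        "indeterminate": labels.count("indeterminate"),
        "staccato_filtered": labels.count("staccato_filtered"),
        "total": len(labels),
    }
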