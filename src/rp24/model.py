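"""Model/Results surface tying the scoring pipeline together.

``RhythmicityModel`` wraps a set of expression profiles (per condition) and
``fit()`` runs the full per-transcript analysis — Fourier power spectrum,
RP24, F24, phase, permutation p-value, BH q-value, detectability quantities
and staccato screening scores — returning a ``RhythmicityResults`` object
that carries the score table and exposes classification, summaries and the
phase-geometry plots.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import classify as _classify
from . import phasegeom as _pg
from .classify import ClassificationThresholds, classify_transcript, euler_counts
from .inference import bh_qvalues, permutation_ensemble
from .io import profiles_from_dataframe, read_expression_matrix
from .spectral import (
    ExpressionProfile,
    RhythmStats,
    dft,
    phase24,
    power_spectrum,
    rp24 as _rp24,
)

__all__ = ["RhythmicityModel", "RhythmicityResults"]

SCORE_COLUMNS = [
    "transcript_id", "condition", "rp24", "f24", "phase", "p", "q",
    "max_min_fold", "median_expr", "sp", "pvec", "spike_var_fraction",
]


class RhythmicityModel:
    """Diurnal rhythmicity model for a collection of expression time series.

    Parameters
    ----------
    profiles : mapping {condition: {transcript_id: ExpressionProfile}}
    thresholds : ClassificationThresholds, optional
    """

    def __init__(self, profiles: dict, thresholds: ClassificationThresholds | None = None):
        if not profiles:
            raise ValueError("no profiles supplied")
        self.profiles = profiles
        self.thresholds = thresholds or ClassificationThresholds()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        collapse: str = "mean",
        log_transform: bool = False,
        thresholds: ClassificationThresholds | None = None,
    ) -> "RhythmicityModel":
        """Build from a wide matrix with ``{condition}_ZT{time}[_r{rep}]`` columns."""
        return cls(
            profiles_from_dataframe(df, collapse=collapse, log_transform=log_transform),
            thresholds=thresholds,
        )

    @classmethod
    def from_tsv(cls, path: str, **kwargs) -> "RhythmicityModel":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), **kwargs)

    @property
    def conditions(self) -> list:
        return list(self.profiles)

    def fit(self, n_perm: int = 10_000, seed: int | None = 0) -> "RhythmicityResults":
        """Score every profile and correct p-values per condition (BH).

        The permutation null (shared by the p-value and F24) shuffles each
        profile's values across time points with a single seeded generator, so
        identical (data, n_perm, seed) reruns are byte-identical.
        """
        rows = []
        stats_store: dict = {}
        for condition in self.conditions:
            rng = np.random.default_rng(seed)
            cond_profiles = self.profiles[condition]
            pvals = []
            cond_rows = []
            for tid, profile in cond_profiles.items():
                stats = self._score_one(profile, n_perm, rng)
                stats_store[(tid, condition)] = stats
                pvals.append(stats.p_value)
                cond_rows.append(stats)
            qvals = bh_qvalues(pvals)
            for stats, q in zip(cond_rows, qvals):
                stats.q_value = float(q)
                rows.append(
                    {
                        "transcript_id": stats.transcript_id,
                        "condition": stats.condition,
                        "rp24": stats.rp24,
                        "f24": stats.f24,
                        "phase": stats.phase_hours,
                        "p": stats.p_value,
                        "q": stats.q_value,
                        "max_min_fold": stats.max_min_fold,
                        "median_expr": stats.median_expr,
                        "sp": stats.sp,
                        "pvec": stats.pvec,
                        "spike_var_fraction": stats.spike_var_fraction,
                    }
                )
        scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
        return RhythmicityResults(
            model=self, scores=scores, stats=stats_store, n_perm=n_perm, seed=seed
        )

    def _score_one(self, profile: ExpressionProfile, n_perm: int, rng) -> RhythmStats:
        stats = RhythmStats(transcript_id=profile.transcript_id, condition=profile.condition)
        stats.max_min_fold = _classify.max_min_fold(profile)
        stats.median_expr = float(np.median(profile.values))
        if profile.is_constant():
            stats.p_value = 1.0
            return stats
        coeffs = dft(profile)
        spectrum = power_spectrum(coeffs)
        stats.rp24 = _rp24(spectrum)
        stats.phase_hours = phase24(profile)
        stats.sp = _classify.spectral_parity(spectrum)
        stats.pvec = _classify.pvec(coeffs, values=profile.values)
        stats.spike_var_fraction = _classify.spike_variance_fraction(profile)
        ens = permutation_ensemble(profile, n_perm, rng=rng)
        stats.p_value = ens.p_value
        stats.f24 = ens.f24
        return stats


class RhythmicityResults:
    """Fitted per-transcript rhythmicity scores and downstream analyses."""

    def __init__(self, model, scores: pd.DataFrame, stats: dict, n_perm: int, seed):
        self.model = model
        self.scores = scores
        self._stats = stats
        self.n_perm = n_perm
        self.seed = seed

    # -- access -----------------------------------------------------------
    def stats_for(self, transcript_id: str, condition: str) -> RhythmStats:
        return self._stats[(transcript_id, condition)]

    def condition_scores(self, condition: str) -> pd.DataFrame:
        return self.scores[self.scores["condition"] == condition].set_index("transcript_id")

    # -- classification ---------------------------------------------------
    def classify(self, young: str = "young", old: str = "old") -> pd.DataFrame:
        """Assign each transcript a rhythmicity-change class between two ages."""
        for cond in (young, old):
            if cond not in self.model.profiles:
                raise ValueError(f"condition {cond!r} not in the model")
        thresholds = self.model.thresholds
        ids = sorted(self.model.profiles[young])
        if set(ids) != set(self.model.profiles[old]):
            raise ValueError("conditions cover different transcript sets")
        records = []
        for tid in ids:
            sy = self._stats[(tid, young)]
            so = self._stats[(tid, old)]
            label = classify_transcript(sy, so, thresholds)
            records.append(
                {
                    "transcript_id": tid,
                    "class": label,
                    "rp24_young": sy.rp24, "q_young": sy.q_value,
                    "phase_young": sy.phase_hours, "fold_young": sy.max_min_fold,
                    "median_young": sy.median_expr,
                    "rp24_old": so.rp24, "q_old": so.q_value,
                    "phase_old": so.phase_hours, "fold_old": so.max_min_fold,
                    "median_old": so.median_expr,
                }
            )
        return pd.DataFrame(records)

    def euler_counts(self, young: str = "young", old: str = "old") -> dict:
        """Rhythmic-overlap counts (young-only / old-only / both), Euler-diagram style."""
        return euler_counts(self.classify(young=young, old=old)["class"])

    # -- plots ------------------------------------------------------------
    def plot_dot_and_arrow(self, transcript_ids, young: str = "young", old: str = "old", ax=None):
        sy = [self._stats[(t, young)] for t in transcript_ids]
        so = [self._stats[(t, old)] for t in transcript_ids]
        return _pg.dot_and_arrow(sy, so, ax=ax)

    def plot_phase_histogram(self, condition: str, transcript_ids=None, bin_minutes: int = 30, ax=None):
        sub = self.condition_scores(condition)
        if transcript_ids is not None:
            sub = sub.loc[list(transcript_ids)]
        phases = sub["phase"].dropna().values
        return _pg.plot_circular_histogram(phases, bin_minutes=bin_minutes, ax=ax)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of the fit, statsmodels-style."""
        lines = []
        lines.append("Diurnal Rhythmicity Model Results")
        lines.append("=" * 56)
        lines.append(f"{'Permutations:':<24}{self.n_perm}")
        lines.append(f"{'Seed:':<24}{self.seed}")
        lines.append(f"{'Min achievable p:':<24}{1.0 / (self.n_perm + 1):.3g}")
        thr = self.model.thresholds
        lines.append(
            f"{'q bands:':<24}rhythmic <= {thr.q_rhythmic}, arrhythmic >= {thr.q_arrhythmic}"
        )
        lines.append("-" * 56)
        lines.append(f"{'condition':<12}{'n':>6}{'rhythmic':>10}{'median RP24':>14}{'median phase':>14}")
        for cond in self.model.conditions:
            sub = self.condition_scores(cond)
            n_rhythmic = int((sub["q"] <= thr.q_rhythmic).sum())
            finite = sub["rp24"].replace([np.inf, -np.inf], np.nan).dropna()
            med_rp = float(np.median(finite)) if len(finite) else float("nan")
            phases = sub["phase"].dropna().values
            med_phase = _pg.circular_median(phases) if len(phases) else float("nan")
            lines.append(
                f"{cond:<12}{len(sub):>6}{n_rhythmic:>10}{med_rp:>14.4g}{med_phase:>14.4g}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        from .io import write_scores

        write_scores(self.scores, path)
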