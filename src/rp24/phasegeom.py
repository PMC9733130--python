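"""Phase geometry: the 24-hour clock face, circular histograms, dot-and-arrow plots.

Rhythmicity states are drawn on a clock face with lights-on (ZT0) at the top
and lights-off (ZT12) at the bottom: the angle from the positive y-axis is
the phase (clockwise) and the distance from the origin is the logistic-scaled
RP24, σ(RP24) = RP24/(1 + RP24) ∈ [0, 1].  A transcript's change between two
ages is a dot (young state) with an arrow to the old state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "PolarState",
    "logistic_scale",
    "polar_state",
    "circular_histogram",
    "circular_median",
    "signed_phase_difference",
    "dot_and_arrow",
    "plot_circular_histogram",
]


@dataclass(frozen=True)
class PolarState:
    """A point on the clock face: radius σ(RP24), angle θ, complex coordinate z."""

    radius: float
    theta: float

    @property
    def z(self) -> complex:
        return self.radius * complex(math.cos(self.theta), math.sin(self.theta))

    @property
    def x(self) -> float:
        return self.z.real

    @property
    def y(self) -> float:
        return self.z.imag


def logistic_scale(rp24: float) -> float:
    """σ(RP24) = RP24/(1 + RP24): strictly increasing bijection [0, ∞] → [0, 1]."""
    if isinstance(rp24, float) and math.isnan(rp24):
        raise ValueError("undefined RP24 cannot be plotted")
    if rp24 < 0:
        raise ValueError("RP24 must be >= 0")
    if math.isinf(rp24):
        return 1.0
    return rp24 / (1.0 + rp24)


def polar_state(rp24: float, phase_hours: float) -> PolarState:
    """Clock-face coordinates: θ = π/2 − Phase·π/12, radius σ(RP24).

    ZT0 maps to the positive y-axis and ZT6 to the positive x-axis, so the
    clock runs clockwise.
    """
    theta = math.pi / 2 - phase_hours * math.pi / 12.0
    return PolarState(radius=logistic_scale(rp24), theta=theta)


def circular_histogram(phases, bin_minutes: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Bin phases (hours in [0, 24)) on the 24-h circle.

    Returns (edges, counts) with half-open bins [b, b + width); the default
    30-minute bins give 48 bins.  The bin width must divide 24 h evenly.
    """
    width = bin_minutes / 60.0
    n_bins = 24.0 / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_minutes} min does not divide 24 h evenly")
    n_bins = int(round(n_bins))
    phases = np.asarray(phases, dtype=float) % 24.0
    edges = np.arange(n_bins + 1) * width
    counts, _ = np.histogram(phases, bins=edges)
    return edges, counts


def circular_median(phases) -> float:
    """Circular median phase in hours: the sample point minimizing the summed
    circular distance to all others (ties broken by the smaller value)."""
    phases = np.asarray(phases, dtype=float) % 24.0
    if phases.size == 0:
        raise ValueError("empty phase sample")
    diffs = np.abs(phases[:, None] - phases[None, :])
    diffs = np.minimum(diffs, 24.0 - diffs)
    totals = diffs.sum(axis=1)
    order = np.lexsort((phases, totals))
    return float(phases[order[0]])


def signed_phase_difference(phase_young: float, phase_old: float) -> float:
    """Shortest signed arc old − young on the 24-h circle, in hours in (−12, 12].

    Positive values are phase delays (peak moves later), negative values are
    advances.  An exact 12-h shift is reported as +12 (delay).
    """
    d = (phase_old - phase_young) % 24.0
    if d > 12.0:
        d -= 24.0
    return d


def dot_and_arrow(
    stats_young,
    stats_old,
    ax=None,
    arrow_kwargs: dict | None = None,
) -> tuple[plt.Figure, pd.DataFrame]:
    """Dot-and-arrow plot of rhythmicity-state changes between two ages.

    ``stats_young`` and ``stats_old`` are RhythmStats sequences with matched
    transcript ids; the dot sits at the young state and the arrow tip at the
    old state.  Returns the figure and a coordinate table with the signed
    circular phase change and its advance/delay direction.
    """
    young = {s.transcript_id: s for s in stats_young}
    old = {s.transcript_id: s for s in stats_old}
    if set(young) != set(old):
        missing = sorted(set(young) ^ set(old))
        raise ValueError(f"unmatched transcript ids across ages: {missing}")

    records = []
    for tid in sorted(young):
        sy, so = young[tid], old[tid]
        for s in (sy, so):
            if isinstance(s.phase_hours, float) and math.isnan(s.phase_hours):
                raise ValueError(f"phase undefined for {tid} in {s.condition or 'a condition'}")
        zy = polar_state(sy.rp24, sy.phase_hours)
        zo = polar_state(so.rp24, so.phase_hours)
        delta = signed_phase_difference(sy.phase_hours, so.phase_hours)
        records.append(
            {
                "transcript_id": tid,
                "x_young": zy.x,
                "y_young": zy.y,
                "x_old": zo.x,
                "y_old": zo.y,
                "delta_phase_hours": delta,
                "direction": "delay" if delta >= 0 else "advance",
            }
        )
    table = pd.DataFrame(records)

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    _draw_clock_face(ax)
    kwargs = {"color": "0.4", "lw": 0.8, "length_includes_head": True,
              "head_width": 0.02} | (arrow_kwargs or {})
    for rec in records:
        ax.plot(rec["x_young"], rec["y_young"], "o", ms=4, color="tab:red")
        dx = rec["x_old"] - rec["x_young"]
        dy = rec["y_old"] - rec["y_young"]
        if dx or dy:
            ax.arrow(rec["x_young"], rec["y_young"], dx, dy, **kwargs)
    return fig, table


def _draw_clock_face(ax) -> None:
    theta = np.linspace(0, 2 * np.pi, 361)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=1)
    for zt in range(0, 24, 6):
        st = polar_state(float("inf"), float(zt))
        ax.annotate(f"ZT{zt}", (1.08 * st.x, 1.08 * st.y), ha="center", va="center")
    ax.set_aspect("equal")
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.axis("off")


def plot_circular_histogram(phases, bin_minutes: int = 30, ax=None, **bar_kwargs):
    """Polar histogram of phases on the clock face (ZT0 up, clockwise)."""
    edges, counts = circular_histogram(phases, bin_minutes=bin_minutes)
    if ax is None:
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(projection="polar")
    else:
        fig = ax.figure
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    width = (edges[1] - edges[0]) * np.pi / 12.0
    angles = edges[:-1] * np.pi / 12.0
    ax.bar(angles, counts, width=width, align="edge", **bar_kwargs)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 2))
    ax.set_xticklabels(["ZT0", "ZT6", "ZT12", "ZT18"])
    return fig, (edges, counts)
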