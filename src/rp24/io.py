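"""Readers and writers for the tabular formats the pipeline exchanges.

Expression matrices are tab-separated with a ``transcript_id`` first column
and remaining columns named ``{condition}_ZT{time}`` or
``{condition}_ZT{time}_r{replicate}`` (e.g. ``young_ZT0_r1``).  Replicates
are collapsed to one value per time point (mean by default) before scoring.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .spectral import ExpressionProfile

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_expression_matrix", "profiles_from_dataframe",
           "write_scores", "write_classification"]

_COLUMN_RE = re.compile(
    r"^(?P<condition>.+?)_ZT(?P<time>\d+(?:\.\d+)?)(?:_r(?P<rep>\d+))?$"
)


@dataclass
class RunConfig:
    """Resolved run configuration; serialized beside every run's outputs."""

    n_perm: int = 10_000
    seed: int = 0
    q_rhythmic: float = 0.05
    q_arrhythmic: float = 0.075
    fold_detectable: float = 1.5
    fold_relaxed: float = 1.4
    median_fpkm_min: float = 1.0
    sp_threshold: float = 1.5
    pvec_threshold: float = 0.15
    spike_var_threshold: float = 0.75
    replicate_collapse: str = "mean"  # or "median"
    log_transform: bool = False  # optionally score log2(FPKM + 1)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.q_rhythmic >= self.q_arrhythmic:
            raise ValueError("q_rhythmic must be < q_arrhythmic")
        if self.fold_relaxed >= self.fold_detectable:
            raise ValueError("fold_relaxed must be < fold_detectable")
        if self.replicate_collapse not in ("mean", "median"):
            raise ValueError("replicate_collapse must be 'mean' or 'median'")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self):
        from .classify import ClassificationThresholds

        return ClassificationThresholds(
            q_rhythmic=self.q_rhythmic,
            q_arrhythmic=self.q_arrhythmic,
            fold_detectable=self.fold_detectable,
            fold_relaxed=self.fold_relaxed,
            median_fpkm_min=self.median_fpkm_min,
            sp_threshold=self.sp_threshold,
            pvec_threshold=self.pvec_threshold,
            spike_var_threshold=self.spike_var_threshold,
        )


def _parse_columns(columns) -> pd.DataFrame:
    parsed = []
    for col in columns:
        m = _COLUMN_RE.match(col)
        if m is None:
            raise ValueError(
                f"column {col!r} does not match '<condition>_ZT<time>[_r<rep>]'"
            )
        parsed.append(
            {
                "column": col,
                "condition": m["condition"],
                "time": float(m["time"]),
                "replicate": int(m["rep"]) if m["rep"] else 1,
            }
        )
    return pd.DataFrame(parsed)


def profiles_from_dataframe(
    df: pd.DataFrame,
    collapse: str = "mean",
    log_transform: bool = False,
) -> dict:
    """Build per-condition ExpressionProfile maps from a wide matrix.

    Returns ``{condition: {transcript_id: ExpressionProfile}}``.  Rejects
    duplicate transcript ids, non-numeric cells, and time grids with gaps
    (unequal spacing), naming the offender.
    """
    df = df.copy()
    if "transcript_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "transcript_id"})
    ids = df["transcript_id"].astype(str)
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate transcript ids: {list(dupes[:5])}")
    data_cols = [c for c in df.columns if c != "transcript_id"]
    meta = _parse_columns(data_cols)

    values = df[data_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at transcript {ids.iloc[r]!r}, column {data_cols[c]!r}: "
            f"{values.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(f"missing value at transcript {ids.iloc[r]!r}, column {data_cols[c]!r}")

    out: dict = {}
    collapse_fn = np.mean if collapse == "mean" else np.median
    for condition, cmeta in meta.groupby("condition", sort=False):
        times = np.sort(cmeta["time"].unique())
        if len(times) < 4:
            raise ValueError(f"condition {condition!r} has only {len(times)} time points")
        spacings = np.diff(times)
        if not np.allclose(spacings, spacings[0]):
            gap = times[np.argmax(spacings)]
            raise ValueError(
                f"condition {condition!r}: unequal time spacing (gap after ZT{gap:g}); "
                "a time point appears to be missing"
            )
        dt = spacings[0]
        duration = float(times[-1] - times[0] + dt)
        # columns per time, in time order
        cols_by_time = [
            list(cmeta.loc[cmeta["time"] == t, "column"]) for t in times
        ]
        mat = np.stack(
            [collapse_fn(numeric[cols].values, axis=1) for cols in cols_by_time], axis=1
        )
        if log_transform:
            mat = np.log2(mat + 1.0)
        cond_map = {}
        for i, tid in enumerate(ids):
            cond_map[tid] = ExpressionProfile(
                transcript_id=tid,
                times=times,
                values=mat[i],
                duration=duration,
                condition=condition,
            )
        out[condition] = cond_map
        logger.info("condition %s: %d profiles at %d time points", condition, len(ids), len(times))
    return out


def read_expression_matrix(
    path: str, collapse: str = "mean", log_transform: bool = False
) -> dict:
    """Read a TSV expression matrix into per-condition profile maps."""
    df = pd.read_csv(path, sep="\t")
    return profiles_from_dataframe(df, collapse=collapse, log_transform=log_transform)


def write_scores(scores: pd.DataFrame, path: str) -> None:
    """Write the per-transcript score table as TSV."""
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_classification(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
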