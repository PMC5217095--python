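"""Framewise displacement and the run / task / all-task summary hierarchy.

Framewise displacement (FD) at frame t is the sum of absolute first
differences of the six rigid-body parameters, with rotations first
converted from radians to arc length on a sphere of radius 50 mm (the
approximate distance from cerebral cortex to the centre of the head).  FD
is defined for frames 2..T, so a T-frame run yields T-1 values; run
summaries average those T-1 values unless ``include_leading_zero`` asks
for the alternative convention of prepending a structural zero.

The participant-level summary averages run means within task, then task
means across tasks, so that tasks with more runs or longer runs carry no
extra weight.  A participant whose all-task mean exceeds the sample mean
by more than ``k`` sample standard deviations (default 1.5) is flagged as
a high mover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import RealignmentSeries

DEFAULT_RADIUS_MM = 50.0


@dataclass
class FDSeries:
    """Per-frame displacement (mm) for one run; length n_frames - 1."""

    participant_id: str
    run_id: str
    fd: np.ndarray
    radius: float = DEFAULT_RADIUS_MM

    def __post_init__(self):
        self.fd = np.asarray(self.fd, float)
        if (self.fd < 0).any():
            raise ValueError("framewise displacement cannot be negative")


@dataclass
class HighMoverFlags:
    """High-motion flags from the mean + k*SD rule on all-task FD."""

    threshold: float
    k: float
    sample_mean: float
    sample_sd: float
    flags: dict[str, bool]

    @property
    def flagged_ids(self) -> set[str]:
        return {p for p, f in self.flags.items() if f}


def compute_fd(
    series: RealignmentSeries,
    radius: float = DEFAULT_RADIUS_MM,
    include_leading_zero: bool = False,
) -> FDSeries:
    """Framewise displacement from a realignment series.

    Rotations are scaled by ``radius`` (mm per radian of arc), the
    six-dimensional series is differenced, and FD is the per-frame sum of
    absolute differences.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to define displacement")
    if radius <= 0:
        raise ValueError("radius must be positive")
    params = np.hstack([series.translations, series.rotations * radius])
    fd = np.abs(np.diff(params, axis=0)).sum(axis=1)
    if include_leading_zero:
        fd = np.concatenate([[0.0], fd])
    return FDSeries(series.participant_id, series.run_id, fd, radius)


def summarize_run(fd: FDSeries, stat: str = "mean") -> float:
    """Summarise a run's FD series by its mean (default) or median."""
    if fd.fd.size == 0:
        raise ValueError("cannot summarise an empty FD series")
    if stat == "mean":
        return float(np.mean(fd.fd))
    if stat == "median":
        return float(np.median(fd.fd))
    raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")


def aggregate(run_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-run FD summaries to task and all-task means.

    ``run_table`` is tidy with columns participant_id, task, run_id,
    fd_bar; missing runs are simply absent (never imputed).  Returns one
    row per participant with one column per task plus ``all_task``.
    """
    required = {"participant_id", "task", "run_id", "fd_bar"}
    missing = required - set(run_table.columns)
    if missing:
        raise ValueError(f"run table missing columns: {sorted(missing)}")
    if run_table.empty:
        raise ValueError("run table is empty")
    per_task = (
        run_table.groupby(["participant_id", "task"], sort=False)["fd_bar"]
        .mean()
        .unstack("task")
    )
    out = per_task.copy()
    out["all_task"] = per_task.mean(axis=1, skipna=True)
    empty = per_task.isna().all(axis=1)
    if empty.any():
        raise ValueError(
            f"participants with zero available runs: {list(out.index[empty])}"
        )
    return out


def flag_high_movers(all_task: pd.Series | dict, k: float = 1.5) -> HighMoverFlags:
    """Flag participants whose all-task FD exceeds mean + k*SD (strict).

    The sample mean and SD (n-1 denominator) are computed from exactly the
    supplied values; ties at the threshold are not flagged.
    """
    s = pd.Series(all_task, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 participants to set a threshold")
    if k <= 0:
        raise ValueError("k must be positive")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    threshold = mean + k * sd
    flags = {str(p): bool(v > threshold) for p, v in s.items()}
    return HighMoverFlags(threshold, k, mean, sd, flags)


def motion_summary_table(
    fd_series: list[FDSeries],
    manifest: pd.DataFrame,
    stat: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the tidy run table and aggregated summary from FD series.

    Returns (run_table, summary); runs present in the manifest but without
    an FD series are dropped with a warning.
    """
    by_run = {(f.participant_id, f.run_id): f for f in fd_series}
    rows = []
    missing = []
    for r in manifest.itertuples():
        key = (str(r.participant_id), str(r.run_id))
        if key in by_run:
            rows.append(
                (key[0], r.task, key[1], summarize_run(by_run[key], stat=stat))
            )
        else:
            missing.append(key)
    if missing:
        warnings.warn(f"manifest runs without realignment data skipped: {missing}")
    run_table = pd.DataFrame(
        rows, columns=["participant_id", "task", "run_id", "fd_bar"]
    )
    return run_table, aggregate(run_table)
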