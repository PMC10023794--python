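"""Functional-connectivity construction from regional BOLD time series.

Static FC is the Pearson correlation matrix of the regional series with
negative entries clipped to zero and the diagonal fixed at one; dynamic FC
applies the same estimator inside sliding windows; group-stable FC
concatenates the standardized series of every subject in a group so the
correlation is estimated on a long effective record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RegionalTimeSeries:
    """A subject's parcellated BOLD record: frames x regions."""

    values: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = "sub-000"
    region_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be 2-D (frames x regions)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two regions")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.region_ids is None:
            self.region_ids = tuple(
                f"R{i + 1:03d}" for i in range(self.values.shape[1])
            )
        elif len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length does not match columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Nonnegative symmetric connectivity matrix with unit diagonal."""

    C: np.ndarray
    region_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = self.C.shape[0]
        if self.C.shape != (n, n):
            raise ValueError("FC matrix must be square")
        if self.region_ids is None:
            self.region_ids = tuple(f"R{i + 1:03d}" for i in range(n))

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry, in frames.

    Defaults follow the common resting-state choice of a 60 s window with
    a one-TR step (30 frames wide, step 1 at TR = 2 s).
    """

    width_frames: int = 30
    step_frames: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.step_frames <= self.width_frames):
            raise ValueError("require 1 <= step <= width")

    def n_windows(self, n_frames: int) -> int:
        if self.width_frames > n_frames:
            raise ValueError(
                f"window width {self.width_frames} exceeds series length {n_frames}"
            )
        return (n_frames - self.width_frames) // self.step_frames + 1

    def starts(self, n_frames: int) -> np.ndarray:
        return np.arange(self.n_windows(n_frames)) * self.step_frames


@dataclass
class FCWindowSeries:
    """Ordered windowed FC matrices for one subject."""

    matrices: list[FCMatrix]
    starts: np.ndarray
    spec: WindowSpec
    subject_id: str = "sub-000"

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


def _clip_corr(r: np.ndarray) -> np.ndarray:
    C = np.where(r < 0.0, 0.0, r)
    np.fill_diagonal(C, 1.0)
    return C


def pearson_fc(
    ts: RegionalTimeSeries | np.ndarray,
    region_ids: tuple[str, ...] | None = None,
    strict: bool = True,
) -> FCMatrix:
    """Pearson-correlation FC with negatives clipped to zero, diagonal one.

    Parameters
    ----------
    ts
        Time series (frames x regions) or a :class:`RegionalTimeSeries`.
    strict
        A zero-variance region raises by default; in lenient mode its
        correlations are defined as 0 with a warning.
    """
    if isinstance(ts, RegionalTimeSeries):
        values, region_ids = ts.values, ts.region_ids
    else:
        values = np.asarray(ts, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 frames to estimate correlations")
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [region_ids[i] for i in dead] if region_ids is not None else list(dead)
        )
        if strict:
            raise ValueError(f"zero-variance region(s): {names}")
        warnings.warn(f"zero-variance region(s) {names}: correlations set to 0")
    # a constant column yields nan correlations; nan_to_num maps them to 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    return FCMatrix(_clip_corr(r), region_ids=region_ids)


def sliding_windows(ts: RegionalTimeSeries, spec: WindowSpec) -> FCWindowSeries:
    """One clipped Pearson FC matrix per sliding window."""
    starts = spec.starts(ts.n_frames)
    mats = [
        pearson_fc(
            ts.values[s : s + spec.width_frames], region_ids=ts.region_ids
        )
        for s in starts
    ]
    return FCWindowSeries(mats, starts, spec, subject_id=ts.subject_id)


def group_stable_fc(series_list: list[RegionalTimeSeries]) -> FCMatrix:
    """Group-stable FC from per-subject standardized, concatenated series.

    Each subject's every region is z-scored (mean 0, SD 1) before
    concatenation so between-subject offset or scale differences cannot
    inflate the pooled correlations; the clipped Pearson estimator is then
    applied to the long concatenated record.
    """
    if not series_list:
        raise ValueError("empty series list")
    ref = series_list[0].region_ids
    for ts in series_list[1:]:
        if ts.region_ids != ref:
            raise ValueError("all subjects must share the same region ids")
    standardized = []
    for ts in series_list:
        sd = ts.values.std(axis=0)
        if (sd == 0).any():
            bad = [ref[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance region(s) in {ts.subject_id}: {bad}")
        standardized.append((ts.values - ts.values.mean(axis=0)) / sd)
    stacked = np.concatenate(standardized, axis=0)
    assert stacked.shape[0] == sum(ts.n_frames for ts in series_list)
    return pearson_fc(stacked, region_ids=ref)
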