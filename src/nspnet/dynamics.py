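"""Time-resolved segregation/integration and finite-length calibration.

Sliding-window FC gives each subject a time series of integration and
segregation components (globally and per region). Because short records
bias the apparent segregation upward, every subject's static component is
multiplicatively calibrated so the group mean matches the component of the
group-stable FC (computed on the concatenated group record):

    H'(n) = H(n) * H^S / <H>,

with ``<.>`` the group average. Regional loadings are rescaled by the same
subject-level factor (preserving each region's relative contribution), and
each dynamic trace is rescaled so its time-mean equals the subject's
calibrated static component. Strength is the time-mean of the calibrated
trace; variability is its sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasMap, aggregate_by_system
from .fc import FCWindowSeries, RegionalTimeSeries, WindowSpec, group_stable_fc, pearson_fc, sliding_windows
from .nsp import SIProfile, si_components


@dataclass
class DynamicSITrace:
    """Windowed components for one subject: global and per-region."""

    h_in: np.ndarray  # (n_windows,)
    h_se: np.ndarray
    regional_in: np.ndarray  # (n_windows, n_regions)
    regional_se: np.ndarray
    subject_id: str = "sub-000"

    @property
    def n_windows(self) -> int:
        return self.h_in.shape[0]


@dataclass
class CalibrationReference:
    """Group-stable components used as the calibration anchor."""

    stable_in: float
    stable_se: float
    group: str = ""


def dynamic_trace(windows: FCWindowSeries) -> DynamicSITrace:
    """Apply the component decomposition to every window."""
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for a dynamic trace")
    profiles = [si_components(w) for w in windows]
    return DynamicSITrace(
        h_in=np.array([p.h_in for p in profiles]),
        h_se=np.array([p.h_se for p in profiles]),
        regional_in=np.stack([p.regional_in for p in profiles]),
        regional_se=np.stack([p.regional_se for p in profiles]),
        subject_id=windows.subject_id,
    )


def strength_and_variability(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Time-mean (strength) and sample SD (variability) along axis 0."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 2:
        raise ValueError("variability undefined for a single window")
    return trace.mean(axis=0), trace.std(axis=0, ddof=1)


def calibrate_group(values: np.ndarray, stable: float) -> np.ndarray:
    """Rescale subject values so their group mean equals the stable value."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("group mean must be positive for calibration")
    return values * (stable / mean)


def calibrate_regional(
    loadings: np.ndarray, static: float, calibrated_static: float
) -> np.ndarray:
    """Rescale a subject's regional loadings by the subject's calibration factor.

    Regional proportions are untouched; the loadings' sum becomes
    ``N * calibrated_static`` when it was ``N * static`` before.
    """
    if static <= 0:
        raise ValueError("subject static component must be positive")
    return np.asarray(loadings, dtype=float) * (calibrated_static / static)


def calibrate_dynamic(trace: np.ndarray, calibrated_static: float) -> np.ndarray:
    """Rescale a windowed trace so its time-mean equals the calibrated static."""
    trace = np.asarray(trace, dtype=float)
    mean = trace.mean(axis=0)
    if np.any(mean <= 0):
        raise ValueError("trace time-mean must be positive")
    return trace * (calibrated_static / mean)


def cohort_si_metrics(
    groups: dict[str, list[RegionalTimeSeries]],
    window: WindowSpec,
    atlas: AtlasMap | None = None,
) -> pd.DataFrame:
    """Full per-subject metric table for a two-group (or any-group) cohort.

    For each group: build the group-stable FC, decompose it, then per
    subject compute static and windowed components, calibrate (group →
    regional → dynamic), and derive strengths and variabilities from the
    calibrated traces.

    Returns a tidy frame with columns ``subject, group, scope, unit,
    measure, value`` where scope is ``global``/``system``/``region``.
    """
    rows: list[tuple] = []
    for group, series_list in groups.items():
        stable_profile = si_components(group_stable_fc(series_list))
        ref = CalibrationReference(
            stable_in=stable_profile.h_in, stable_se=stable_profile.h_se, group=group
        )
        statics: list[SIProfile] = []
        traces: list[DynamicSITrace] = []
        for ts in series_list:
            statics.append(si_components(pearson_fc(ts)))
            traces.append(dynamic_trace(sliding_windows(ts, window)))
        cal_in = calibrate_group(np.array([p.h_in for p in statics]), ref.stable_in)
        cal_se = calibrate_group(np.array([p.h_se for p in statics]), ref.stable_se)
        for k, ts in enumerate(series_list):
            prof, trace = statics[k], traces[k]
            reg_in = calibrate_regional(prof.regional_in, prof.h_in, cal_in[k])
            reg_se = calibrate_regional(prof.regional_se, prof.h_se, cal_se[k])
            g_in = calibrate_dynamic(trace.h_in, cal_in[k])
            g_se = calibrate_dynamic(trace.h_se, cal_se[k])
            # per-region traces calibrated to the calibrated regional statics
            r_in = calibrate_dynamic(trace.regional_in, reg_in)
            r_se = calibrate_dynamic(trace.regional_se, reg_se)
            sid = ts.subject_id
            _, f_in = strength_and_variability(g_in)
            _, f_se = strength_and_variability(g_se)
            _, f_in_reg = strength_and_variability(r_in)
            _, f_se_reg = strength_and_variability(r_se)
            rows.append((sid, group, "global", "ALL", "H_In", cal_in[k]))
            rows.append((sid, group, "global", "ALL", "H_Se", cal_se[k]))
            rows.append((sid, group, "global", "ALL", "F_In", float(f_in)))
            rows.append((sid, group, "global", "ALL", "F_Se", float(f_se)))
            for j, rid in enumerate(ts.region_ids):
                rows.append((sid, group, "region", rid, "H_In", reg_in[j]))
                rows.append((sid, group, "region", rid, "H_Se", reg_se[j]))
                rows.append((sid, group, "region", rid, "F_In", f_in_reg[j]))
                rows.append((sid, group, "region", rid, "F_Se", f_se_reg[j]))
    df = pd.DataFrame(
        rows, columns=["subject", "group", "scope", "unit", "measure", "value"]
    )
    if atlas is not None:
        df = pd.concat([df, _system_rows(df, atlas)], ignore_index=True)
    return df


def _system_rows(df: pd.DataFrame, atlas: AtlasMap) -> pd.DataFrame:
    regional = df[df["scope"] == "region"]
    out = []
    for (sid, group, measure), sub in regional.groupby(
        ["subject", "group", "measure"], sort=False
    ):
        sub = sub.set_index("unit").loc[list(atlas.region_ids)]
        means = aggregate_by_system(sub["value"].to_numpy(), atlas)
        for system, val in means.items():
            out.append((sid, group, "system", system, measure, val))
    return pd.DataFrame(
        out, columns=["subject", "group", "scope", "unit", "measure", "value"]
    )
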