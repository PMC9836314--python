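"""Head-orienting response detection from azimuth-vs-time traces.

A head-orienting response to a sound is saccade-like: a rapid, step-like
rotation with a monophasic (bell-shaped) velocity profile.  Detection follows
the velocity-threshold approach: movement onset where head velocity exceeds
20 deg/s, offset where it falls and stays below, endpoint from the static
position after offset.  Reaction time (RT) is the onset latency relative to
stimulus onset at t=0; promptness is its reciprocal (1/s), which is close to
normally distributed and therefore suitable for parametric analysis.

Two thresholds are used in practice: detection at the main threshold, then the
onset marker is walked back to the last sample below a low threshold so that
the reported onset is the start of the movement rather than the (amplitude-
dependent, ~20-25 ms later) time the main threshold is crossed.  Setting
``onset_backtrack_threshold=None`` yields the literal single-threshold marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .design import wrap_angle

__all__ = ["HeadTrace", "OrientingResponse", "estimate_velocity",
           "detect_response", "detect_batch", "qc_review_table"]

DEFAULT_THRESHOLD_DEG_S = 20.0


@dataclass
class HeadTrace:
    """Sampled head azimuth (degrees, (-180, 180]) over time (seconds)."""

    time_s: np.ndarray
    azimuth_deg: np.ndarray
    trial_id: int | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.azimuth_deg = np.asarray(self.azimuth_deg, dtype=float)
        if self.time_s.shape != self.azimuth_deg.shape:
            raise ValueError("time and azimuth must have equal length")
        if len(self.time_s) >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    @property
    def has_gaps(self) -> bool:
        """True when any inter-sample interval exceeds 2x the nominal period."""
        dt = np.diff(self.time_s)
        return bool(np.any(dt > 2.0 * np.median(dt)))


@dataclass
class OrientingResponse:
    """Detected head-orienting movement markers for one trial."""

    trial_id: int | None = None
    onset_s: float | None = None
    offset_s: float | None = None
    endpoint_deg: float | None = None
    qc_flags: set = field(default_factory=set)

    @property
    def rt_s(self) -> float | None:
        return self.onset_s

    @property
    def promptness_inv_s(self) -> float | None:
        if self.onset_s is None or self.onset_s <= 0:
            return None
        return 1.0 / self.onset_s

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "onset_s": self.onset_s,
            "offset_s": self.offset_s,
            "endpoint_deg": self.endpoint_deg,
            "rt_s": self.rt_s,
            "promptness_inv_s": self.promptness_inv_s,
            "qc_flags": ";".join(sorted(self.qc_flags)),
        }


def estimate_velocity(trace: HeadTrace, smoothing_window: int = 5,
                      position_window: int = 5) -> np.ndarray:
    """Angular velocity (deg/s), same length as the trace.

    Position is unwrapped across the +/-180 seam, moving-average pre-smoothed,
    differentiated with central differences (one-sided at the edges), and the
    velocity moving-average smoothed.  Windows of 1 disable smoothing.
    """
    if len(trace.time_s) < 5:
        raise ValueError("need at least 5 samples to estimate velocity")
    pos = np.unwrap(trace.azimuth_deg, period=360.0)
    if position_window > 1:
        pos = uniform_filter1d(pos, size=position_window, mode="nearest")
    vel = np.gradient(pos, trace.time_s)
    if smoothing_window > 1:
        vel = uniform_filter1d(vel, size=smoothing_window, mode="nearest")
    return vel


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (stop exclusive) of True runs in a boolean mask."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for s, e in zip(idx[::2], idx[1::2]):
        out.append((int(s), int(e)))
    return out


def _circular_median(angles_deg: np.ndarray) -> float:
    """Median of angles that are clustered (static head); robust to the seam."""
    a = np.unwrap(np.asarray(angles_deg, dtype=float), period=360.0)
    return float(wrap_angle(np.median(a)))


def detect_response(
    trace: HeadTrace,
    threshold_deg_s: float = DEFAULT_THRESHOLD_DEG_S,
    min_supra: int = 3,
    min_sub: int = 5,
    window_end_s: float | None = None,
    onset_backtrack_threshold: float | None = 8.0,
    endpoint_window_s: float = 0.1,
    smoothing_window: int = 5,
    position_window: int = 5,
) -> OrientingResponse:
    """Detect the head-orienting response in one trace.

    Onset: first sample of the first run of >= ``min_supra`` consecutive
    samples with |velocity| above threshold (optionally walked back to the last
    sample below ``onset_backtrack_threshold``).  Offset: start of the first
    subsequent run of >= ``min_sub`` samples below threshold.  Endpoint:
    circular median of position over ``endpoint_window_s`` after offset.
    Degenerate traces come back flagged (no_movement, multiple_movements,
    moving_at_end, gap) with the unavailable fields left as None.
    """
    resp = OrientingResponse(trial_id=trace.trial_id)
    if trace.has_gaps:
        resp.qc_flags.add("gap")

    vel = estimate_velocity(trace, smoothing_window, position_window)
    t = trace.time_s
    if window_end_s is not None:
        in_window = t <= window_end_s
    else:
        in_window = np.ones_like(t, dtype=bool)

    supra = (np.abs(vel) > threshold_deg_s) & in_window
    supra_runs = [r for r in _runs(supra) if r[1] - r[0] >= min_supra]
    if not supra_runs:
        resp.qc_flags.add("no_movement")
        return resp
    if len(supra_runs) > 1:
        resp.qc_flags.add("multiple_movements")

    onset_idx, first_end = supra_runs[0]
    if onset_backtrack_threshold is not None:
        low = np.abs(vel[:onset_idx]) < onset_backtrack_threshold
        below = np.flatnonzero(low)
        if len(below):
            onset_idx = int(below[-1])
    resp.onset_s = float(t[onset_idx])

    # offset: after the LAST supra-threshold run (the head static again)
    last_end = supra_runs[-1][1]
    sub = (np.abs(vel) < threshold_deg_s)
    sub[:last_end] = False
    sub_runs = [r for r in _runs(sub) if r[1] - r[0] >= min_sub]
    if not sub_runs:
        resp.qc_flags.add("moving_at_end")
        return resp
    offset_idx = sub_runs[0][0]
    resp.offset_s = float(t[offset_idx])

    end_mask = (t >= resp.offset_s) & (t <= resp.offset_s + endpoint_window_s)
    resp.endpoint_deg = _circular_median(trace.azimuth_deg[end_mask])
    return resp


def detect_batch(traces, **kwargs) -> pd.DataFrame:
    """Run :func:`detect_response` over an iterable of traces; one row per trial."""
    rows = [detect_response(tr, **kwargs).to_dict() for tr in traces]
    return pd.DataFrame(rows)


def qc_review_table(responses: pd.DataFrame, overrides: pd.DataFrame | None = None,
                    trace_duration_s: float | None = None) -> pd.DataFrame:
    """Per-trial marker table for offline visual review, flagged trials first.

    ``overrides`` (columns: trial_id plus any of onset_s, offset_s,
    endpoint_deg) replaces markers for the named trials, mirroring the
    trial-by-trial manual check of automatic markers; RT/promptness are
    recomputed and the trial is tagged ``manual_override``.
    """
    table = responses.copy()
    if overrides is not None and len(overrides):
        unknown = set(overrides["trial_id"]) - set(table["trial_id"])
        if unknown:
            raise ValueError(f"override references unknown trial ids: {sorted(unknown)}")
        table = table.set_index("trial_id")
        for _, ov in overrides.iterrows():
            tid = ov["trial_id"]
            for col in ("onset_s", "offset_s", "endpoint_deg"):
                if col in ov.index and pd.notna(ov[col]):
                    val = float(ov[col])
                    if col in ("onset_s", "offset_s"):
                        if val < 0 or (trace_duration_s is not None and val > trace_duration_s):
                            raise ValueError(
                                f"override {col}={val} for trial {tid} outside trace time range"
                            )
                    table.loc[tid, col] = val
            flags = set(str(table.loc[tid, "qc_flags"]).split(";")) - {"", "nan"}
            table.loc[tid, "qc_flags"] = ";".join(sorted(flags | {"manual_override"}))
        table = table.reset_index()
        table["rt_s"] = table["onset_s"]
        with np.errstate(divide="ignore"):
            table["promptness_inv_s"] = np.where(table["rt_s"] > 0, 1.0 / table["rt_s"], np.nan)
    flagged = table["qc_flags"].fillna("").astype(str).str.len() > 0
    return pd.concat([table[flagged], table[~flagged]]).reset_index(drop=True)
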