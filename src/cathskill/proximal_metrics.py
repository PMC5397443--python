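"""Per-phase kinematic and proximal force/torque metrics.

Twelve metrics per phase are extracted from the synchronized tip-position,
axial-force and torque channels:

median/max tip speed (mm/s), median/max tip acceleration (mm/s²),
smoothness of motion (mm/s², accumulated absolute rate of change of the
displacement slope — lower is smoother), number of displacement peaks
(back-and-forth movements), 3-D path length (mm), mean push and pull
forces (N), mean clockwise and counterclockwise torques (N·mm), and the
phase duration (s).

Derivatives are first differences on the uniform clock with no
pre-smoothing by default; any filtering materially changes maximum-speed
values, so the default stays transparent (an optional moving-average
window is available).  Displacement for peak counting is distance from the
phase start ``||p_i - p_0||`` — cumulative path is monotone and peak-free
by construction.  Push/pull and CW/CCW means are episode-conditional:
the mean over positive samples and the mean magnitude over negative
samples, each 0 when the side is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trial_model import (
    PHASES,
    PhaseSegmentation,
    TimeSeriesChannel,
    Trial,
    ValidationError,
    segment,
)

__all__ = [
    "MetricRecord",
    "MetricError",
    "speed_stats",
    "accel_stats",
    "smoothness",
    "displacement_peaks",
    "path_length",
    "directional_means",
    "phase_max_summary",
    "compute_proximal_metrics",
    "records_to_frame",
    "PROXIMAL_METRICS",
]

#: metric name -> unit
PROXIMAL_METRICS = {
    "median_speed": "mm/s",
    "max_speed": "mm/s",
    "median_accel": "mm/s^2",
    "max_accel": "mm/s^2",
    "smoothness": "mm/s^2",
    "n_peaks": "count",
    "path_length": "mm",
    "push_force_mean": "N",
    "pull_force_mean": "N",
    "torque_cw_mean": "N·mm",
    "torque_ccw_mean": "N·mm",
    "phase_time": "s",
}


class MetricError(ValueError):
    """A metric's preconditions (sample count, channels) are not met."""


@dataclass(frozen=True)
class MetricRecord:
    """One (trial, phase, metric) value."""

    trial_id: str
    phase: str
    metric: str
    value: float
    unit: str


def _uniform_dt(timestamps: np.ndarray) -> float:
    dt = np.diff(timestamps)
    if dt.size == 0:
        raise MetricError("need at least 2 samples")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise MetricError("timestamps are not on a uniform clock; synchronize first")
    return float(dt[0])


def _speeds(positions: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    dt = _uniform_dt(timestamps)
    return np.linalg.norm(np.diff(positions, axis=0), axis=1) / dt


def speed_stats(
    positions: np.ndarray, timestamps: np.ndarray
) -> tuple[float, float]:
    """Median and maximum tip speed (mm/s) from first differences."""
    if len(positions) < 3:
        raise MetricError("speed_stats needs at least 3 samples")
    sp = _speeds(np.asarray(positions, dtype=float), timestamps)
    return float(np.median(sp)), float(sp.max())


def accel_stats(
    positions: np.ndarray, timestamps: np.ndarray
) -> tuple[float, float]:
    """Median and maximum tip acceleration (mm/s²), |Δspeed|/Δt."""
    if len(positions) < 4:
        raise MetricError("accel_stats needs at least 4 samples")
    dt = _uniform_dt(timestamps)
    sp = _speeds(np.asarray(positions, dtype=float), timestamps)
    acc = np.abs(np.diff(sp)) / dt
    return float(np.median(acc)), float(acc.max())


def smoothness(positions: np.ndarray, timestamps: np.ndarray) -> float:
    """Accumulated absolute slope change of the tip displacement signal.

    With s_i the cumulative displacement and v_i = (s_{i+1}-s_i)/Δt its
    slope, smoothness = Σ|v_{i+1}-v_i| / Δt  (mm/s²; 0 for constant-speed
    motion, larger for jerky motion).
    """
    if len(positions) < 4:
        raise MetricError("smoothness needs at least 4 samples")
    dt = _uniform_dt(timestamps)
    step = np.linalg.norm(np.diff(np.asarray(positions, dtype=float), axis=0), axis=1)
    v = step / dt
    return float(np.sum(np.abs(np.diff(v))) / dt)


def displacement_peaks(
    positions: np.ndarray,
    timestamps: np.ndarray,
    prominence_mm: float = 1.0,
) -> int:
    """Number of local maxima of distance-from-start, i.e. back-and-forth
    movements of the tip.

    The default prominence of 1 mm sits above EM tracking jitter and below
    retraction depths of interest.
    """
    if len(positions) < 3:
        raise MetricError("displacement_peaks needs at least 3 samples")
    p = np.asarray(positions, dtype=float)
    d = np.linalg.norm(p - p[0], axis=1)
    peaks, _ = find_peaks(d, prominence=prominence_mm)
    return int(peaks.size)


def path_length(positions: np.ndarray) -> float:
    """Total 3-D path length Σ||p_{i+1}-p_i|| (mm)."""
    p = np.asarray(positions, dtype=float)
    if len(p) < 2:
        raise MetricError("path_length needs at least 2 samples")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def directional_means(signed_series: np.ndarray) -> tuple[float, float]:
    """Episode-conditional means of a signed channel.

    Returns ``(mean over positive samples, mean magnitude over negative
    samples)``; a side with no samples contributes 0.  With the package's
    sign conventions this gives (push, pull) for axial force and
    (CW, CCW) for torque.
    """
    x = np.asarray(signed_series, dtype=float)
    pos = x[x > 0]
    neg = x[x < 0]
    return (
        float(pos.mean()) if pos.size else 0.0,
        float(-neg.mean()) if neg.size else 0.0,
    )


def _moving_average(positions: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(positions[:, k], kernel, mode="same") for k in range(3)]
    )
    h = window // 2
    sm[:h] = positions[:h]
    if h:
        sm[-h:] = positions[-h:]
    return sm


def compute_proximal_metrics(
    trial: Trial,
    segmentation: PhaseSegmentation | None = None,
    prominence_mm: float = 1.0,
    smooth_window: int | None = None,
) -> list[MetricRecord]:
    """All 12 proximal metrics for each phase of a synchronized trial.

    ``smooth_window`` optionally moving-averages the positions before
    differentiation; the default is no smoothing, which keeps maximum
    speed/acceleration values transparent.
    """
    for name in ("tip_position", "axial_force", "torque"):
        if name not in trial.channels:
            raise MetricError(f"trial {trial.trial_id!r} missing channel {name!r}")
    seg = segmentation or segment(trial)
    pos_ch = trial.channels["tip_position"]
    if smooth_window and smooth_window > 1:
        pos_ch = TimeSeriesChannel(
            pos_ch.name, pos_ch.unit, pos_ch.timestamps.copy(),
            _moving_average(pos_ch.values, smooth_window),
            pos_ch.nominal_rate_hz,
        )
    force_ch = trial.channels["axial_force"]
    torque_ch = trial.channels["torque"]
    records: list[MetricRecord] = []
    for phase in PHASES:
        m = seg.mask(pos_ch.timestamps, phase)
        pos = pos_ch.values[m]
        ts = pos_ch.timestamps[m]
        med_v, max_v = speed_stats(pos, ts)
        med_a, max_a = accel_stats(pos, ts)
        sm = smoothness(pos, ts)
        n_pk = displacement_peaks(pos, ts, prominence_mm)
        plen = path_length(pos)
        fm = seg.mask(force_ch.timestamps, phase)
        push, pull = directional_means(force_ch.values[fm])
        tm = seg.mask(torque_ch.timestamps, phase)
        cw, ccw = directional_means(torque_ch.values[tm])
        a, b = seg.intervals[phase]
        values = {
            "median_speed": med_v,
            "max_speed": max_v,
            "median_accel": med_a,
            "max_accel": max_a,
            "smoothness": sm,
            "n_peaks": float(n_pk),
            "path_length": plen,
            "push_force_mean": push,
            "pull_force_mean": pull,
            "torque_cw_mean": cw,
            "torque_ccw_mean": ccw,
            "phase_time": b - a,
        }
        for metric, unit in PROXIMAL_METRICS.items():
            records.append(
                MetricRecord(trial.trial_id, phase, metric, float(values[metric]), unit)
            )
    return records


def phase_max_summary(
    trials: Sequence[Trial],
    channel: str,
    segmentations: Sequence[PhaseSegmentation] | None = None,
) -> pd.DataFrame:
    """Group means of per-trial maximum |channel| value, per phase.

    Rows are (skill group, phase); vector channels use the Euclidean norm.
    """
    if not trials:
        raise MetricError("phase_max_summary needs at least one trial")
    rows = []
    for i, trial in enumerate(trials):
        if channel not in trial.channels:
            raise MetricError(f"trial {trial.trial_id!r} missing channel {channel!r}")
        seg = segmentations[i] if segmentations else segment(trial)
        ch = trial.channels[channel]
        mag = (
            np.linalg.norm(ch.values, axis=1) if ch.is_vector else np.abs(ch.values)
        )
        for phase in PHASES:
            m = seg.mask(ch.timestamps, phase)
            if not m.any():
                raise MetricError(
                    f"trial {trial.trial_id!r} has no samples in phase {phase}"
                )
            rows.append(
                {"skill": trial.skill, "phase": phase, "max": float(mag[m].max())}
            )
    df = pd.DataFrame(rows)
    for group in df["skill"].unique():
        if (df["skill"] == group).sum() == 0:  # pragma: no cover - defensive
            raise MetricError(f"empty group {group}")
    return (
        df.groupby(["skill", "phase"], as_index=False)["max"]
        .mean()
        .rename(columns={"max": "mean_of_max"})
    )


def records_to_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Long-format DataFrame ``trial_id,phase,metric,value,unit``."""
    return pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "phase": r.phase,
                "metric": r.metric,
                "value": r.value,
                "unit": r.unit,
            }
            for r in records
        ]
    )
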