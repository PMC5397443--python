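"""Contact-force metrics from the 3-axis distal sensing platform.

The pipeline per run: combine the three force axes into the RMS force
modulus √(Fx²+Fy²+Fz²), subtract the minimum recorded modulus for that run
(the sensor is zeroed at the start of each procedure, so the run minimum
corresponds to no tissue interaction), then extract per phase: mean,
median and maximum force, force impact over time (FIT, the trapezoidal
force–time integral in N·s), standard deviation of force, and the number
of significant wall contacts — maximal contiguous excursions of the
modulus above a 1 N threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .trial_model import (
    PHASES,
    PhaseSegmentation,
    Trial,
    segment,
)
from .proximal_metrics import MetricError, MetricRecord

__all__ = [
    "ForceModulusSeries",
    "force_modulus",
    "baseline_subtract",
    "force_summary",
    "force_impact",
    "count_force_peaks",
    "compute_distal_metrics",
    "DISTAL_METRICS",
]

DISTAL_METRICS = {
    "mean_force": "N",
    "median_force": "N",
    "max_force": "N",
    "fit": "N·s",
    "stdev_force": "N",
    "n_peaks": "count",
}


@dataclass(frozen=True)
class ForceModulusSeries:
    """RMS force modulus over time; non-negative by construction."""

    timestamps: np.ndarray
    modulus: np.ndarray
    baseline_removed: bool = False

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        mod = np.asarray(self.modulus, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "modulus", mod)
        if ts.shape != mod.shape:
            raise MetricError("timestamps and modulus length mismatch")
        if mod.size and mod.min() < 0:
            raise MetricError("force modulus must be non-negative")

    def window(self, mask: np.ndarray) -> "ForceModulusSeries":
        return replace(self, timestamps=self.timestamps[mask], modulus=self.modulus[mask])


def force_modulus(
    fx: np.ndarray, fy: np.ndarray, fz: np.ndarray, timestamps: np.ndarray
) -> ForceModulusSeries:
    """Per-sample Euclidean modulus of the three force axes."""
    fx, fy, fz = (np.asarray(a, dtype=float) for a in (fx, fy, fz))
    if not (fx.shape == fy.shape == fz.shape):
        raise MetricError("force channels must have equal length")
    if np.asarray(timestamps).shape != fx.shape:
        raise MetricError("timestamps must match channel length")
    return ForceModulusSeries(timestamps, np.sqrt(fx**2 + fy**2 + fz**2))


def baseline_subtract(series: ForceModulusSeries) -> ForceModulusSeries:
    """Remove the run's force bias: subtract the minimum recorded modulus.

    Applied per run (not per phase), so constant sensor offsets cancel and
    the resulting signal reflects only tool–tissue interaction.  Idempotent.
    """
    if series.modulus.size == 0:
        raise MetricError("cannot baseline-subtract an empty series")
    return ForceModulusSeries(
        series.timestamps,
        series.modulus - series.modulus.min(),
        baseline_removed=True,
    )


def _require_baseline(series: ForceModulusSeries, what: str) -> None:
    if not series.baseline_removed:
        raise MetricError(f"{what} expects a baseline-subtracted series")


def force_summary(
    series: ForceModulusSeries,
) -> tuple[float, float, float, float]:
    """(mean, median, max, sample stdev) of the modulus over a window."""
    _require_baseline(series, "force_summary")
    x = series.modulus
    if x.size == 0:
        raise MetricError("force_summary on an empty window")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), float(np.median(x)), float(x.max()), sd


def force_impact(series: ForceModulusSeries) -> float:
    """Force impact over time (FIT): trapezoidal ∫ modulus dt, N·s."""
    _require_baseline(series, "force_impact")
    if series.modulus.size < 2:
        raise MetricError("force_impact needs at least 2 samples")
    return float(np.trapezoid(series.modulus, series.timestamps))


def count_force_peaks(
    series: ForceModulusSeries, threshold_N: float = 1.0
) -> int:
    """Number of significant wall contacts: maximal contiguous excursions
    of the modulus above ``threshold_N`` (rising-edge count)."""
    _require_baseline(series, "count_force_peaks")
    if threshold_N < 0:
        raise MetricError("threshold must be non-negative")
    above = series.modulus > threshold_N
    if above.size == 0:
        return 0
    rises = int(np.count_nonzero(above[1:] & ~above[:-1]))
    return rises + int(above[0])


def compute_distal_metrics(
    trial: Trial,
    segmentation: PhaseSegmentation | None = None,
    peak_threshold_N: float = 1.0,
) -> list[MetricRecord]:
    """Six distal metrics per phase: modulus → per-run baseline subtraction
    → per-phase statistics.

    FIT windows share the boundary sample between adjacent phases so the
    three phase integrals sum exactly to the whole-run integral; the other
    statistics use half-open phase windows.
    """
    ch = trial.channels.get("contact_force_xyz")
    if ch is None:
        raise MetricError(
            f"trial {trial.trial_id!r} missing channel 'contact_force_xyz'"
        )
    seg = segmentation or segment(trial)
    mod = force_modulus(
        ch.values[:, 0], ch.values[:, 1], ch.values[:, 2], ch.timestamps
    )
    mod = baseline_subtract(mod)
    i_b, i_c = seg.boundary_indices(ch.timestamps)
    fit_slices = {
        "A": slice(0, i_b + 1),
        "B": slice(i_b, i_c + 1),
        "C": slice(i_c, len(ch.timestamps)),
    }
    records: list[MetricRecord] = []
    for phase in PHASES:
        win = mod.window(seg.mask(ch.timestamps, phase))
        mean, median, mx, sd = force_summary(win)
        sl = fit_slices[phase]
        fit = force_impact(
            ForceModulusSeries(
                mod.timestamps[sl], mod.modulus[sl], baseline_removed=True
            )
        )
        n_pk = count_force_peaks(win, peak_threshold_N)
        values = {
            "mean_force": mean,
            "median_force": median,
            "max_force": mx,
            "fit": fit,
            "stdev_force": sd,
            "n_peaks": float(n_pk),
        }
        for metric, unit in DISTAL_METRICS.items():
            records.append(
                MetricRecord(trial.trial_id, phase, metric, float(values[metric]), unit)
            )
    return records
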