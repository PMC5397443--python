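"""Trial data model for catheter manipulation recordings.

A *trial* is one cannulation run: multi-rate sensor channels (proximal
axial force and torque at 25 Hz, electromagnetic tip positions at 40 Hz,
or 3-axis distal contact forces at 25 Hz) plus metadata and the two phase
boundaries that split the run into the anatomical phases A (approach),
B (navigation / vessel selection) and C (cannulation).

On-disk format is one CSV per channel (header ``t,value`` or ``t,x,y,z``)
plus a JSON manifest; floats are written with 17 significant digits so a
write/read round trip is bit exact.

Sign conventions, fixed at ingest: axial force push > 0, pull < 0;
torque clockwise > 0, counterclockwise < 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "TimeSeriesChannel",
    "Trial",
    "PivotPose",
    "PhaseSegmentation",
    "TASKS",
    "SKILLS",
    "SETUPS",
    "REQUIRED_CHANNELS",
    "read_trial",
    "write_trial",
    "synchronize",
    "pivot_calibrate",
    "apply_tip_offset",
    "segment",
]

TASKS = ("LRA", "RRA", "LSA", "LCCA", "RCCA")
SKILLS = ("expert", "novice")
SETUPS = ("proximal", "distal")
UNITS = ("N", "N·mm", "mm", "s")

#: channels a trial must carry for each sensing setup
REQUIRED_CHANNELS = {
    "proximal": ("axial_force", "torque", "tip_position"),
    "distal": ("contact_force_xyz",),
}

PHASES = ("A", "B", "C")


class ValidationError(ValueError):
    """A trial, channel or segmentation violates a structural invariant."""


@dataclass
class TimeSeriesChannel:
    """One sensor stream: strictly increasing timestamps plus per-sample
    scalar or 3-vector values."""

    name: str
    unit: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in UNITS:
            raise ValidationError(
                f"channel {self.name!r}: unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        if self.timestamps.ndim != 1:
            raise ValidationError(f"channel {self.name!r}: timestamps must be 1-D")
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValidationError(
                f"channel {self.name!r}: {self.values.shape[0]} samples for "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.values.ndim not in (1, 2) or (
            self.values.ndim == 2 and self.values.shape[1] != 3
        ):
            raise ValidationError(
                f"channel {self.name!r}: values must be scalar or 3-vector per sample"
            )
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"channel {self.name!r}: timestamps not strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 2

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])


@dataclass
class Trial:
    """One cannulation run: metadata, channels, and phase boundaries."""

    trial_id: str
    operator_id: str
    skill: str
    task: str
    setup: str
    channels: dict[str, TimeSeriesChannel]
    phase_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.skill not in SKILLS:
            raise ValidationError(f"skill must be one of {SKILLS}, got {self.skill!r}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.setup not in SETUPS:
            raise ValidationError(f"setup must be one of {SETUPS}, got {self.setup!r}")
        if not self.channels:
            raise ValidationError("trial has no channels")
        missing = [
            name for name in REQUIRED_CHANNELS[self.setup] if name not in self.channels
        ]
        if missing:
            raise ValidationError(
                f"{self.setup} trial {self.trial_id!r} missing channels: {missing}"
            )
        b1, b2 = self.phase_bounds = (
            float(self.phase_bounds[0]),
            float(self.phase_bounds[1]),
        )
        t0, t1 = self.common_span
        if not (t0 < b1 < b2 < t1):
            raise ValidationError(
                f"phase bounds {self.phase_bounds} not ordered strictly inside "
                f"common channel span ({t0:g}, {t1:g})"
            )

    @property
    def common_span(self) -> tuple[float, float]:
        """Time interval covered by every channel."""
        t0 = max(ch.span[0] for ch in self.channels.values())
        t1 = min(ch.span[1] for ch in self.channels.values())
        return t0, t1

    @property
    def duration(self) -> float:
        t0, t1 = self.common_span
        return t1 - t0


@dataclass(frozen=True)
class PivotPose:
    """One tracked pose of the tip sensor while its physical tip is held
    on a fixed pivot point."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if t.shape != (3,):
            raise ValidationError("translation must be a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("rotation not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation must be proper (det +1)")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Three contiguous half-open intervals [start, end) labelled A, B, C.

    The final phase is closed at the trial's end so that the three phases
    cover the whole span.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        iv = {p: (float(a), float(b)) for p, (a, b) in self.intervals.items()}
        object.__setattr__(self, "intervals", iv)
        if tuple(iv) != PHASES:
            raise ValidationError(f"phases must be exactly {PHASES}")
        for p, (a, b) in iv.items():
            if not a < b:
                raise ValidationError(f"phase {p} interval [{a:g}, {b:g}) is empty")
        for prev, nxt in zip(PHASES[:-1], PHASES[1:]):
            if not math.isclose(iv[prev][1], iv[nxt][0], abs_tol=1e-12):
                raise ValidationError(f"phases {prev} and {nxt} are not contiguous")

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals["A"][0], self.intervals["C"][1]

    def mask(self, timestamps: np.ndarray, phase: str) -> np.ndarray:
        """Boolean sample mask for a phase; last phase includes its right edge."""
        a, b = self.intervals[phase]
        ts = np.asarray(timestamps)
        if phase == PHASES[-1]:
            return (ts >= a) & (ts <= b)
        return (ts >= a) & (ts < b)

    def boundary_indices(self, timestamps: np.ndarray) -> tuple[int, int]:
        """Indices of the first samples of phases B and C."""
        ts = np.asarray(timestamps)
        return (
            int(np.searchsorted(ts, self.intervals["B"][0], side="left")),
            int(np.searchsorted(ts, self.intervals["C"][0], side="left")),
        )


def segment(trial: Trial) -> PhaseSegmentation:
    """Phase segmentation of a trial from its stored phase boundaries."""
    t0, t1 = trial.common_span
    b1, b2 = trial.phase_bounds
    if not (t0 < b1 < b2 < t1):
        raise ValidationError(
            f"phase bounds {trial.phase_bounds} outside trial span ({t0:g}, {t1:g})"
        )
    return PhaseSegmentation({"A": (t0, b1), "B": (b1, b2), "C": (b2, t1)})


# ---------------------------------------------------------------------------
# I/O

_FLOAT_FMT = "%.17g"


def write_trial(trial: Trial, out_dir: str | Path) -> Path:
    """Write one CSV per channel plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "trial_id": trial.trial_id,
        "operator_id": trial.operator_id,
        "skill": trial.skill,
        "task": trial.task,
        "setup": trial.setup,
        "phase_bounds": list(trial.phase_bounds),
        "channels": [],
    }
    for name in sorted(trial.channels):
        ch = trial.channels[name]
        fname = f"{trial.trial_id}_{name}.csv"
        cols = ["x", "y", "z"] if ch.is_vector else ["value"]
        header = ",".join(["t"] + cols)
        data = np.column_stack(
            [ch.timestamps, ch.values if ch.is_vector else ch.values[:, None]]
        )
        np.savetxt(out / fname, data, fmt=_FLOAT_FMT, delimiter=",",
                   header=header, comments="")
        manifest["channels"].append(
            {
                "name": name,
                "file": fname,
                "unit": ch.unit,
                "nominal_rate_hz": ch.nominal_rate_hz,
            }
        )
    mpath = out / f"{trial.trial_id}.json"
    mpath.write_text(json.dumps(manifest, indent=2, ensure_ascii=False) + "\n",
                     encoding="utf-8")
    return mpath


def read_trial(manifest_path: str | Path) -> Trial:
    """Read a trial from its JSON manifest and referenced channel CSVs."""
    mpath = Path(manifest_path)
    meta = json.loads(mpath.read_text(encoding="utf-8"))
    channels: dict[str, TimeSeriesChannel] = {}
    for entry in meta["channels"]:
        fpath = mpath.parent / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"channel file {fpath} referenced by manifest")
        raw = np.genfromtxt(fpath, delimiter=",", names=True)
        names = raw.dtype.names
        ts = np.asarray(raw["t"], dtype=float)
        if "value" in names:
            values = np.asarray(raw["value"], dtype=float)
        else:
            values = np.column_stack([raw["x"], raw["y"], raw["z"]]).astype(float)
        channels[entry["name"]] = TimeSeriesChannel(
            name=entry["name"],
            unit=entry["unit"],
            timestamps=ts,
            values=values,
            nominal_rate_hz=entry.get("nominal_rate_hz"),
        )
    return Trial(
        trial_id=meta["trial_id"],
        operator_id=meta["operator_id"],
        skill=meta["skill"],
        task=meta["task"],
        setup=meta["setup"],
        channels=channels,
        phase_bounds=tuple(meta["phase_bounds"]),
    )


# ---------------------------------------------------------------------------
# Multi-rate synchronization

def synchronize(trial: Trial, target_rate_hz: float = 25.0) -> Trial:
    """Resample every channel onto one uniform clock by linear interpolation.

    The common clock runs at ``target_rate_hz`` over the time span shared by
    all channels (at least 1 s of overlap is required).  The force
    acquisition rate (25 Hz) is the default: metrics mix force and position
    and the slowest stream bounds the information content, so the 40 Hz EM
    positions are downsampled onto the force clock.
    """
    t0, t1 = trial.common_span
    if t1 - t0 < 1.0:
        raise ValidationError(
            f"channels overlap for only {t1 - t0:g} s; need at least 1 s"
        )
    n = int(math.floor((t1 - t0) * target_rate_hz + 1e-9)) + 1
    clock = t0 + np.arange(n) / target_rate_hz
    out: dict[str, TimeSeriesChannel] = {}
    for name, ch in trial.channels.items():
        if ch.is_vector:
            vals = np.column_stack(
                [np.interp(clock, ch.timestamps, ch.values[:, k]) for k in range(3)]
            )
        else:
            vals = np.interp(clock, ch.timestamps, ch.values)
        out[name] = TimeSeriesChannel(
            name=name, unit=ch.unit, timestamps=clock.copy(), values=vals,
            nominal_rate_hz=target_rate_hz,
        )
    return replace(trial, channels=out)


# ---------------------------------------------------------------------------
# Pivot calibration

def pivot_calibrate(
    poses: Sequence[PivotPose],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares tip offset from poses collected about a fixed pivot.

    While the physical tip rests on a pivot point ``c``, every tracked pose
    (R_i, p_i) of the sensor satisfies ``R_i t + p_i = c`` where ``t`` is the
    fixed offset from the sensor origin to the tip, expressed in the sensor
    frame.  Stacking all poses gives the linear system
    ``[R_i  -I] [t; c] = -p_i`` solved in the least-squares sense.

    Returns ``(tip_offset_mm, pivot_point_mm, rms_residual_mm)``.
    """
    if len(poses) < 3:
        raise ValidationError("pivot calibration needs at least 3 poses")
    A = np.zeros((3 * len(poses), 6))
    b = np.zeros(3 * len(poses))
    for i, pose in enumerate(poses):
        A[3 * i : 3 * i + 3, :3] = pose.rotation
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -pose.translation
    x, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6 or sv[-1] < 1e-10 * sv[0]:
        raise ValidationError(
            "pivot geometry is rank deficient: poses must include at least "
            "two distinct sensor orientations"
        )
    t, c = x[:3], x[3:]
    resid = np.array([p.rotation @ t + p.translation - c for p in poses])
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t, c, rms


def apply_tip_offset(
    trial: Trial,
    tip_offset: float | np.ndarray,
    orientations: np.ndarray | None = None,
    smooth_window: int = 5,
) -> Trial:
    """Correct the tip_position channel for the sensor-origin-to-tip offset.

    With full per-sample orientation matrices available (``orientations``,
    shape (n, 3, 3)), ``tip_offset`` is a 3-vector in the sensor frame and
    each position is shifted by ``R_i @ tip_offset``.  A 5-DoF EM coil has no
    roll, so the usual case is a scalar offset applied along the unit tangent
    of the (moving-average smoothed) trajectory.
    """
    ch = trial.channels.get("tip_position")
    if ch is None:
        raise ValidationError("trial has no tip_position channel")
    pos = ch.values
    if orientations is not None:
        off = np.asarray(tip_offset, dtype=float)
        if off.shape != (3,):
            raise ValidationError("with orientations, tip_offset must be a 3-vector")
        shift = np.einsum("nij,j->ni", np.asarray(orientations, dtype=float), off)
        new = pos + shift
    else:
        d = float(tip_offset)
        if d == 0.0:
            return trial
        new = pos + d * _trajectory_tangent(pos, smooth_window)
    new_ch = TimeSeriesChannel(
        name=ch.name, unit=ch.unit, timestamps=ch.timestamps.copy(), values=new,
        nominal_rate_hz=ch.nominal_rate_hz,
    )
    channels = dict(trial.channels)
    channels["tip_position"] = new_ch
    return replace(trial, channels=channels)


def _trajectory_tangent(pos: np.ndarray, window: int) -> np.ndarray:
    """Unit tangent of a smoothed 3-D trajectory; stationary stretches reuse
    the last moving direction."""
    if window > 1:
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(pos[:, k], kernel, mode="same") for k in range(3)]
        )
        # moving average shrinks toward interior values at the edges; use the
        # raw endpoints there to avoid bending straight trajectories
        h = window // 2
        sm[:h] = pos[:h]
        sm[-h:] = pos[-h:]
    else:
        sm = pos
    tang = np.gradient(sm, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    unit = np.zeros_like(tang)
    moving = norms > 1e-12
    unit[moving] = tang[moving] / norms[moving, None]
    if moving.any():
        # forward/backward fill for stationary samples
        idx = np.where(moving, np.arange(len(pos)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first + int(np.argmax(moving[first:]))
        unit = unit[idx]
    return unit
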