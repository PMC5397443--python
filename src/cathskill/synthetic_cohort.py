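"""Seeded synthetic expert/novice trial generator.

No operator recordings are bundled with this package, so every downstream
stage (metrics, repeatability, group statistics, classification) is
exercised on synthetic cohorts that emulate the structure of the real
study: three-phase cannulation runs on five target vessels, proximal
force/torque at 25 Hz with electromagnetic tip positions at 40 Hz, or
3-axis distal contact forces at 25 Hz quantized to the sensor's 4 mN
resolution.

The generative model, per trial:

* The tip advances along a fixed task-specific 3-D centerline at a
  phase-dependent base speed modulated by a smooth lognormal process
  (median multiplier 1, so the per-phase *median* tip speed tracks the
  profile's ``advance_speed_mm_s``).  Poisson-distributed reversal events
  superimpose triangular retract/re-advance excursions, which
  simultaneously create displacement peaks, speed spikes and pull-force
  episodes — the coupled signature that separates novices from experts.
* Proximal axial force follows the signed tip speed through a force gain,
  with an extra pull bias during retractions (pull < 0 by convention);
  torque consists of sparse bidirectional half-sine twist events,
  concentrated in the cannulation phase.
* Distal contact force is a slow baseline wander plus half-sine contact
  bursts with random 3-D direction, amplitude and duration drawn around
  the profile's contact parameters, denser in the cannulation phase.

Operator identity enters as lognormal random-effect multipliers (sd 0.15)
on the main profile parameters, drawn once per operator, so repetitions
within an operator correlate — which the DTW repeatability analysis needs.
All randomness flows through ``numpy.random.default_rng`` seeded from the
cohort design seed, so a cohort is a pure function of (design, profiles).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .trial_model import (
    SETUPS,
    TASKS,
    TimeSeriesChannel,
    Trial,
    ValidationError,
)

__all__ = [
    "SkillProfile",
    "CohortDesign",
    "default_profiles",
    "generate_trial",
    "generate_cohort",
    "task_centerline",
    "design_from_yaml",
    "profile_from_yaml",
]

POSITION_RATE_HZ = 40.0
FORCE_RATE_HZ = 25.0
#: distal force sensor resolution, N
FORCE_RESOLUTION_N = 0.004

#: relative contact/torque event density per phase A, B, C — events cluster
#: in the cannulation phase
_PHASE_EVENT_WEIGHT = {"torque": (0.4, 1.0, 3.0), "contact": (0.3, 1.0, 3.0)}

#: profile parameters that receive per-operator lognormal random effects
_OPERATOR_EFFECT_FIELDS = (
    "advance_speed_mm_s",
    "reversal_rate_per_s",
    "reversal_depth_mm",
    "pull_bias_N",
    "torque_amp_Nmm",
    "contact_rate_per_s",
    "contact_amp_N",
)


@dataclass(frozen=True)
class SkillProfile:
    """Generative parameters of one skill group.

    Rates are events per second, amplitudes in the channel's physical unit.
    ``advance_speed_mm_s`` and ``phase_durations_s`` are per phase (A, B, C).
    """

    advance_speed_mm_s: tuple[float, float, float]
    speed_log_sd: float
    reversal_rate_per_s: float
    reversal_depth_mm: float
    reversal_speed_mm_s: float
    force_gain_N_per_mm_s: float
    pull_bias_N: float
    torque_event_rate_per_s: float
    torque_amp_Nmm: float
    torque_event_dur_s: float
    contact_rate_per_s: float
    contact_amp_N: float
    contact_dur_s: float
    phase_durations_s: tuple[float, float, float]
    position_noise_sd_mm: float
    force_noise_sd_N: float
    torque_noise_sd_Nmm: float
    contact_noise_sd_N: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x < 0 for x in vals):
                raise ValidationError(f"profile parameter {f.name} must be >= 0")

    def scaled(self, multipliers: dict[str, float]) -> "SkillProfile":
        """New profile with named parameters multiplied (operator effects)."""
        changes: dict[str, object] = {}
        for name, m in multipliers.items():
            v = getattr(self, name)
            changes[name] = (
                tuple(x * m for x in v) if isinstance(v, tuple) else v * m
            )
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CohortDesign:
    """Study design: operator counts per group, tasks, repetitions, setup."""

    n_expert_operators: int
    n_novice_operators: int
    tasks: tuple[str, ...]
    repetitions_per_task: int
    setup: str
    seed: int

    def __post_init__(self) -> None:
        if self.n_expert_operators < 1 or self.n_novice_operators < 1:
            raise ValidationError("operator counts must be >= 1")
        if self.repetitions_per_task < 1:
            raise ValidationError("repetitions_per_task must be >= 1")
        object.__setattr__(self, "tasks", tuple(self.tasks))
        if not self.tasks:
            raise ValidationError("task list must be non-empty")
        for t in self.tasks:
            if t not in TASKS:
                raise ValidationError(f"unknown task {t!r}; expected one of {TASKS}")
        if self.setup not in SETUPS:
            raise ValidationError(f"setup must be one of {SETUPS}")

    @property
    def n_trials(self) -> int:
        return (
            (self.n_expert_operators + self.n_novice_operators)
            * len(self.tasks)
            * self.repetitions_per_task
        )


def default_profiles() -> tuple[SkillProfile, SkillProfile]:
    """Default (expert, novice) profiles.

    Calibrated so that on seeded cohorts the group contrasts point the way
    the study found them: experts advance at roughly half the novice median
    tip speed (≈2 vs ≈4 mm/s in the approach phase), retract less often and
    less deeply, apply smaller pull forces and twists, and touch the vessel
    wall more rarely and more gently (cannulation-phase peak contact forces
    of order 0.5 N vs 1.8 N), with novices also taking longer.
    """
    expert = SkillProfile(
        advance_speed_mm_s=(2.0, 2.0, 1.5),
        speed_log_sd=0.55,
        reversal_rate_per_s=0.05,
        reversal_depth_mm=4.0,
        reversal_speed_mm_s=6.0,
        force_gain_N_per_mm_s=0.05,
        pull_bias_N=0.02,
        torque_event_rate_per_s=0.05,
        torque_amp_Nmm=0.3,
        torque_event_dur_s=0.8,
        contact_rate_per_s=0.06,
        contact_amp_N=0.32,
        contact_dur_s=0.8,
        phase_durations_s=(55.0, 35.0, 35.0),
        position_noise_sd_mm=0.01,
        force_noise_sd_N=0.01,
        torque_noise_sd_Nmm=0.02,
        contact_noise_sd_N=0.008,
    )
    novice = SkillProfile(
        advance_speed_mm_s=(3.0, 3.0, 2.4),
        speed_log_sd=0.7,
        reversal_rate_per_s=0.25,
        reversal_depth_mm=5.0,
        reversal_speed_mm_s=9.0,
        force_gain_N_per_mm_s=0.08,
        pull_bias_N=0.10,
        torque_event_rate_per_s=0.15,
        torque_amp_Nmm=0.8,
        torque_event_dur_s=0.8,
        contact_rate_per_s=0.14,
        contact_amp_N=0.8,
        contact_dur_s=1.2,
        phase_durations_s=(70.0, 50.0, 55.0),
        position_noise_sd_mm=0.02,
        force_noise_sd_N=0.02,
        torque_noise_sd_Nmm=0.04,
        contact_noise_sd_N=0.015,
    )
    return expert, novice


# ---------------------------------------------------------------------------
# Task centerlines

_TASK_CURVE_SEED = {task: 7000 + i for i, task in enumerate(TASKS)}


def task_centerline(task: str) -> np.ndarray:
    """Fixed piecewise-linear 3-D centerline for a task, ≈600 mm long.

    The anatomy gives only qualitative shape, so each task gets a
    deterministic gently wandering polyline of realistic total length.
    """
    rng = np.random.default_rng(_TASK_CURVE_SEED[task])
    n_seg, seg_len = 12, 50.0
    direction = np.array([0.0, 0.0, 1.0])
    points = [np.zeros(3)]
    for _ in range(n_seg):
        turn = rng.normal(0.0, 0.25, size=3)
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        points.append(points[-1] + seg_len * direction)
    return np.asarray(points)


def _curve_point(points: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arclengths ``s`` on a polyline, linearly extrapolated."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.asarray(s, dtype=float)
    out = np.column_stack([np.interp(s, cum, points[:, k]) for k in range(3)])
    over = s > total
    if over.any():
        last_dir = seg[-1] / seg_len[-1]
        out[over] = points[-1] + (s[over] - total)[:, None] * last_dir
    return out


# ---------------------------------------------------------------------------
# Single-trial generation

def _phase_of(t: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Phase index (0, 1, 2) per timestamp."""
    return np.searchsorted(np.asarray(bounds), t, side="right")


def _event_times(
    rng: np.random.Generator,
    durations: Sequence[float],
    base_rate: float,
    weights: tuple[float, float, float],
) -> np.ndarray:
    """Poisson event times over the trial, phase-weighted rates."""
    times = []
    start = 0.0
    for dur, w in zip(durations, weights):
        lam = base_rate * w * dur
        k = rng.poisson(lam)
        times.append(start + rng.uniform(0.0, dur, size=k))
        start += dur
    return np.sort(np.concatenate(times))


def _half_sine_bursts(
    t: np.ndarray,
    times: np.ndarray,
    amps: np.ndarray,
    durs: np.ndarray,
) -> np.ndarray:
    """Sum of half-sine pulses amp*sin(pi*(t-t0)/dur) on [t0, t0+dur]."""
    out = np.zeros_like(t)
    for t0, a, d in zip(times, amps, durs):
        m = (t >= t0) & (t <= t0 + d)
        out[m] += a * np.sin(np.pi * (t[m] - t0) / d)
    return out


def generate_trial(
    task: str,
    skill_profile: SkillProfile,
    phase_durations: Sequence[float],
    setup: str,
    seed,
    trial_id: str = "T000",
    operator_id: str = "OP00",
    skill: str = "novice",
) -> Trial:
    """Generate one synthetic cannulation trial.

    ``seed`` may be an int or a sequence of ints; the same seed always
    yields a bit-identical trial.
    """
    durations = tuple(float(d) for d in phase_durations)
    if len(durations) != 3 or any(d <= 0 for d in durations):
        raise ValidationError("phase_durations must be three positive values (s)")
    if setup not in SETUPS:
        raise ValidationError(f"setup must be one of {SETUPS}")
    p = skill_profile
    rng = np.random.default_rng(seed)
    total = sum(durations)
    bounds = (durations[0], durations[0] + durations[1])

    # --- kinematics on the fine 40 Hz clock -------------------------------
    n40 = int(np.floor(total * POSITION_RATE_HZ + 1e-9)) + 1
    t40 = np.arange(n40) / POSITION_RATE_HZ
    phase_idx = _phase_of(t40, bounds)
    base = np.asarray(p.advance_speed_mm_s)[phase_idx]
    if p.speed_log_sd > 0:
        z = rng.standard_normal(n40)
        z = gaussian_filter1d(z, sigma=POSITION_RATE_HZ)  # ~1 s correlation
        sd = z.std()
        if sd > 0:
            z = z / sd
        speed = base * np.exp(p.speed_log_sd * z)
    else:
        speed = base.astype(float)
    velocity = speed.copy()

    # reversal events: triangular retract / re-advance excursions
    if p.reversal_rate_per_s > 0:
        ev = _event_times(rng, durations, p.reversal_rate_per_s, (1.0, 1.0, 1.0))
        depths = p.reversal_depth_mm * rng.lognormal(0.0, 0.35, size=ev.size)
        for t0, depth in zip(ev, depths):
            if p.reversal_speed_mm_s <= 0:
                continue
            half = depth / p.reversal_speed_mm_s
            retract = (t40 >= t0) & (t40 < t0 + half)
            readv = (t40 >= t0 + half) & (t40 < t0 + 2 * half)
            velocity[retract] = -p.reversal_speed_mm_s
            velocity[readv] = p.reversal_speed_mm_s

    arclength = np.concatenate([[0.0], np.cumsum(velocity[:-1] + velocity[1:])]) / (
        2 * POSITION_RATE_HZ
    )
    arclength = np.clip(arclength, 0.0, None)

    # --- 25 Hz clock ------------------------------------------------------
    n25 = int(np.floor(total * FORCE_RATE_HZ + 1e-9)) + 1
    t25 = np.arange(n25) / FORCE_RATE_HZ

    channels: dict[str, TimeSeriesChannel] = {}
    if setup == "proximal":
        positions = _curve_point(task_centerline(task), arclength)
        if p.position_noise_sd_mm > 0:
            positions = positions + rng.normal(
                0.0, p.position_noise_sd_mm, size=positions.shape
            )
        channels["tip_position"] = TimeSeriesChannel(
            "tip_position", "mm", t40, positions, POSITION_RATE_HZ
        )

        v25 = np.interp(t25, t40, velocity)
        force = np.where(
            v25 >= 0,
            p.force_gain_N_per_mm_s * v25,
            -p.pull_bias_N - 0.2 * p.force_gain_N_per_mm_s * np.abs(v25),
        )
        if p.force_noise_sd_N > 0:
            force = force + rng.normal(0.0, p.force_noise_sd_N, size=n25)
        channels["axial_force"] = TimeSeriesChannel(
            "axial_force", "N", t25, force, FORCE_RATE_HZ
        )

        torque = np.zeros(n25)
        if p.torque_event_rate_per_s > 0 and p.torque_event_dur_s > 0:
            ev = _event_times(
                rng, durations, p.torque_event_rate_per_s,
                _PHASE_EVENT_WEIGHT["torque"],
            )
            amps = p.torque_amp_Nmm * rng.lognormal(0.0, 0.3, size=ev.size)
            amps *= rng.choice([-1.0, 1.0], size=ev.size)  # CW / CCW
            durs = np.full(ev.size, p.torque_event_dur_s)
            torque = _half_sine_bursts(t25, ev, amps, durs)
        if p.torque_noise_sd_Nmm > 0:
            torque = torque + rng.normal(0.0, p.torque_noise_sd_Nmm, size=n25)
        channels["torque"] = TimeSeriesChannel(
            "torque", "N·mm", t25, torque, FORCE_RATE_HZ
        )
    else:
        contact = np.zeros((n25, 3))
        if p.contact_rate_per_s > 0 and p.contact_dur_s > 0:
            ev = _event_times(
                rng, durations, p.contact_rate_per_s,
                _PHASE_EVENT_WEIGHT["contact"],
            )
            amps = p.contact_amp_N * rng.lognormal(0.0, 0.35, size=ev.size)
            durs = p.contact_dur_s * rng.lognormal(0.0, 0.2, size=ev.size)
            dirs = rng.standard_normal((ev.size, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            for k in range(3):
                contact[:, k] = _half_sine_bursts(t25, ev, amps * dirs[:, k], durs)
        # slow baseline wander (incomplete zeroing / thermal drift)
        drift = gaussian_filter1d(
            rng.normal(0.0, 1.0, size=(n25, 3)), sigma=5 * FORCE_RATE_HZ, axis=0
        )
        dsd = drift.std(axis=0)
        dsd[dsd == 0] = 1.0
        contact = contact + 0.01 * drift / dsd
        if p.contact_noise_sd_N > 0:
            contact = contact + rng.normal(0.0, p.contact_noise_sd_N, size=(n25, 3))
        contact = np.round(contact / FORCE_RESOLUTION_N) * FORCE_RESOLUTION_N
        channels["contact_force_xyz"] = TimeSeriesChannel(
            "contact_force_xyz", "N", t25, contact, FORCE_RATE_HZ
        )

    return Trial(
        trial_id=trial_id,
        operator_id=operator_id,
        skill=skill,
        task=task,
        setup=setup,
        channels=channels,
        phase_bounds=bounds,
    )


# ---------------------------------------------------------------------------
# Cohorts

def generate_cohort(
    design: CohortDesign,
    expert_profile: SkillProfile | None = None,
    novice_profile: SkillProfile | None = None,
) -> list[Trial]:
    """Generate one trial per (operator, task, repetition).

    Operator random effects (lognormal multipliers, sd 0.15, on the main
    profile parameters) are drawn once per operator, so an operator's
    repetitions share a signature.  The returned trial order is randomized
    with the design seed.  Every trial is an independent observation in the
    downstream statistics, mirroring the study design.
    """
    if expert_profile is None or novice_profile is None:
        dexp, dnov = default_profiles()
        expert_profile = expert_profile or dexp
        novice_profile = novice_profile or dnov

    operators: list[tuple[str, str, SkillProfile]] = []
    for i in range(design.n_expert_operators):
        operators.append((f"E{i + 1:02d}", "expert", expert_profile))
    for i in range(design.n_novice_operators):
        operators.append((f"N{i + 1:02d}", "novice", novice_profile))

    trials: list[Trial] = []
    for op_idx, (op_id, skill, profile) in enumerate(operators):
        op_rng = np.random.default_rng([design.seed, 1, op_idx])
        mult = {
            name: float(op_rng.lognormal(0.0, 0.15))
            for name in _OPERATOR_EFFECT_FIELDS
        }
        op_profile = profile.scaled(mult)
        dur_mult = float(op_rng.lognormal(0.0, 0.10))
        for t_idx, task in enumerate(design.tasks):
            for rep in range(design.repetitions_per_task):
                trial_rng = np.random.default_rng(
                    [design.seed, 2, op_idx, t_idx, rep]
                )
                durations = tuple(
                    d * dur_mult * float(trial_rng.lognormal(0.0, 0.08))
                    for d in op_profile.phase_durations_s
                )
                trials.append(
                    generate_trial(
                        task,
                        op_profile,
                        durations,
                        design.setup,
                        seed=[design.seed, 3, op_idx, t_idx, rep],
                        trial_id=f"{op_id}-{task}-r{rep + 1}",
                        operator_id=op_id,
                        skill=skill,
                    )
                )
    order = np.random.default_rng([design.seed, 99]).permutation(len(trials))
    return [trials[i] for i in order]


def design_from_yaml(path) -> CohortDesign:
    """CohortDesign from a YAML mapping of its fields."""
    import yaml

    raw = yaml.safe_load(open(path))
    raw["tasks"] = tuple(raw["tasks"])
    return CohortDesign(**raw)


def profile_from_yaml(path) -> SkillProfile:
    """SkillProfile from a YAML mapping of its fields."""
    import yaml

    raw = yaml.safe_load(open(path))
    for key in ("advance_speed_mm_s", "phase_durations_s"):
        raw[key] = tuple(raw[key])
    return SkillProfile(**raw)
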