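"""Synthetic Kinect-style gait generator with exact ground truth.

Emulates the statistical structure the segmentation method assumes for
walking children: trials of a few strides at ~30 Hz with stride
lengths around 25 frames, subject-level timing differences (uniform
temporal scaling), stride-level timing jitter (non-uniform scaling),
additive joint-position noise, and an arbitrary rigid placement of the
sensor.

The kinematic model is deliberately simple rather than biomechanical:
the hip center advances at the subject's average speed with a small
vertical bob; each foot alternates stance (ankle anchored at a fixed
ground point) and swing (C1-smooth forward translation with a
sinusoidal lift, zero velocity at both stance boundaries); upper-body
joints ride at fixed offsets from the hip center.  Heel strike is the
first stance instant, toe-off the last.  Every event time, heel center
and per-trial gait parameter is known exactly, with sub-frame truth
stored alongside the frame-quantized annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import SENSOR, FootEvents, StrideAnnotation, TrialWalk
from .layout import DEFAULT_LAYOUT, N_JOINTS
from .parameters import GaitParameters, compute_gait_parameters
from .segmentation import FootSegmentation
from .templates import round_half_up

# body geometry (meters): a small child, hip ~0.45 m, head ~0.85 m
HIP_HEIGHT = 0.45
ANKLE_HEIGHT = 0.05
FOOT_DROP = np.array([0.07, 0.0, -0.04])   # foot joint relative to ankle
HIP_HALF_WIDTH = 0.08
FOOT_HALF_WIDTH = 0.10
SWING_LIFT = 0.05
BOB_AMP = 0.015
SWAY_AMP = 0.01

UPPER_OFFSETS = {
    "hip_center": (0.0, 0.0, 0.0),
    "spine": (0.0, 0.0, 0.15),
    "shoulder_center": (0.0, 0.0, 0.30),
    "head": (0.0, 0.0, 0.40),
    "shoulder_left": (0.0, 0.15, 0.28),
    "elbow_left": (0.0, 0.18, 0.16),
    "wrist_left": (0.0, 0.20, 0.04),
    "hand_left": (0.02, 0.21, -0.02),
    "shoulder_right": (0.0, -0.15, 0.28),
    "elbow_right": (0.0, -0.18, 0.16),
    "wrist_right": (0.0, -0.20, 0.04),
    "hand_right": (0.02, -0.21, -0.02),
}


@dataclass
class SynthConfig:
    """Cohort-level generator settings (defaults are the study conditions)."""

    n_subjects: int = 10
    trials_per_subject: int = 3
    strides_per_trial: int = 4
    frame_rate: float = 30.0
    stride_period_mean: float = 0.8        # s, across subjects
    stride_period_sd: float = 0.08         # s, across subjects
    within_subject_period_cv: float = 0.05  # per-stride fractional SD
    stance_fraction: float = 0.6
    stride_length_mean: float = 0.72       # m, across subjects
    stride_length_sd: float = 0.07         # m, across subjects
    joint_noise_sd: float = 0.01           # m, i.i.d. per coordinate
    jitter_sd_ms: float = 0.0              # sampling-period jitter
    rigid_placement: bool = True
    lead_time: float = 0.1                 # s of walk before the first heel strike
    #: snap subject stride periods to whole frames.  The ideal-condition
    #: control: off the frame grid, sub-frame phase drift makes event
    #: rounding inconsistent between strides — a sampling artifact that
    #: would mask whether the pipeline itself is exact.
    snap_period_to_frames: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("stride_period_sd", "stride_length_sd",
                     "within_subject_period_cv", "joint_noise_sd",
                     "jitter_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_subjects < 1 or self.trials_per_subject < 1 \
                or self.strides_per_trial < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SubjectParams:
    """Per-subject gait parameters (uniform scaling across subjects)."""

    subject_id: str
    stride_period: float   # s
    stride_length: float   # m


@dataclass
class GroundTruth:
    """Exact events, heel centers and parameters for one synthetic trial."""

    annotation: StrideAnnotation
    heel_strike_times: dict[str, list[float]]   # sub-frame truth, seconds
    toe_off_times: dict[str, list[float]]
    heel_centers: dict[str, np.ndarray]         # sensor frame, meters
    parameters: GaitParameters
    stride_period: float
    stride_length: float

    def foot_segmentation(self, side: str) -> FootSegmentation:
        """Ground truth wrapped as a FootSegmentation."""
        hs = self.annotation.foot(side).heel_strikes
        return FootSegmentation(
            side=side,
            n_strides=len(hs) - 1,
            spans=[(a, b - 1) for a, b in zip(hs, hs[1:])],
            heel_strike_frames=list(hs),
            toe_off_frames=list(self.annotation.foot(side).toe_offs),
            heel_centers=self.heel_centers[side],
        )


def _swing_profile(phase: np.ndarray) -> np.ndarray:
    """C1 monotone 0->1 profile with zero velocity at both ends."""
    return phase - np.sin(2 * np.pi * phase) / (2 * np.pi)


def _interp_extrap(t: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Piecewise-linear interpolation with linear edge extrapolation."""
    if t <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (t - xs[0]))
    if t >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (t - xs[-1]))
    return float(np.interp(t, xs, ys))


class _FootTrack:
    """Piecewise stance/swing ankle trajectory for one foot.

    Built from extended heel-strike times ``h[-1..S]`` and ground
    anchors ``a[-1..S]`` (one virtual stride before the first recorded
    heel strike and a trailing stance after the last).
    """

    def __init__(self, heel_strikes: np.ndarray, anchors: np.ndarray,
                 stance_fraction: float, lateral: float) -> None:
        self.h = heel_strikes        # (S+2,) times, h[0] is the virtual stride
        self.a = anchors             # (S+2,) forward anchor coordinates
        self.stance = stance_fraction
        self.lateral = lateral

    def toe_off_times(self) -> np.ndarray:
        return self.h[:-1] + self.stance * np.diff(self.h)

    def ankle_at(self, t: float) -> np.ndarray:
        h, a = self.h, self.a
        if t <= h[0]:
            x, z = a[0], ANKLE_HEIGHT
        elif t >= h[-1]:
            x, z = a[-1], ANKLE_HEIGHT
        else:
            i = int(np.searchsorted(h, t, side="right") - 1)
            t0, t1 = h[i], h[i + 1]
            toe = t0 + self.stance * (t1 - t0)
            if t <= toe:
                x, z = a[i], ANKLE_HEIGHT
            else:
                phase = (t - toe) / (t1 - toe)
                x = a[i] + (a[i + 1] - a[i]) * float(_swing_profile(np.array(phase)))
                z = ANKLE_HEIGHT + SWING_LIFT * float(np.sin(np.pi * phase))
        return np.array([x, self.lateral, z])


def generate_trial_walk(
    config: SynthConfig,
    subject: SubjectParams,
    trial_seed,
    trial_id: str = "t0",
) -> tuple[TrialWalk, GroundTruth]:
    """Generate one sensor-frame trial walk plus its ground truth.

    ``trial_seed`` feeds a dedicated random stream (per-stride timing,
    joint noise, sampling jitter, rigid placement).
    """
    rng = np.random.default_rng(trial_seed)
    fs = config.frame_rate
    T, L = subject.stride_period, subject.stride_length
    S = config.strides_per_trial

    # One alternating footfall sequence (R, L, R, L, ...): per-step times
    # of 0.5 T with multiplicative jitter.  Coupling the feet through a
    # single step stream keeps their relative phase bounded — real feet
    # cannot drift into each other.  A stride is two consecutive steps,
    # so the per-step CV is sqrt(2) times the stride-period CV.
    step_cv = config.within_subject_period_cv * np.sqrt(2.0)
    n_steps = 2 * S + 3          # two virtual events before the first HS
    half = 0.5 * T
    if config.snap_period_to_frames:
        # keep every event on the frame grid (no half-frame rounding ties)
        half = round(half * fs) / fs
    base = np.where(np.arange(n_steps) % 2 == 0, half, T - half)
    steps = base * (1.0 + step_cv * rng.standard_normal(n_steps))
    steps = np.clip(steps, 0.25 * T, 0.75 * T)
    events = config.lead_time + np.concatenate(
        [[-steps[0] - steps[1]], np.cumsum(steps) - steps[0] - steps[1]]
    )
    # events[0], events[2], ... are right heel strikes (events[0] virtual);
    # events[1], events[3], ... left (events[1] virtual)
    right_hs = events[0::2][:S + 2]
    left_hs = events[1::2][:S + 2]

    right = _FootTrack(right_hs, L * np.arange(-1, S + 1),
                       config.stance_fraction, -FOOT_HALF_WIDTH)
    left = _FootTrack(left_hs, 0.5 * L + L * np.arange(-1, S + 1),
                      config.stance_fraction, FOOT_HALF_WIDTH)
    tracks = {"right": right, "left": left}

    def step_phase(t: float) -> float:
        """Continuous footfall phase: +1 per step, integer at heel strikes."""
        if t <= events[0]:
            return (t - events[0]) / (events[1] - events[0])
        if t >= events[-1]:
            k = len(events) - 2
            return k + 1 + (t - events[-1]) / (events[-1] - events[-2])
        k = int(np.searchsorted(events, t, side="right") - 1)
        return k + (t - events[k]) / (events[k + 1] - events[k])

    end_time = max(right.h[-1], left.h[-1]) + config.lead_time
    n = int(np.floor(end_time * fs)) + 1
    times = np.arange(n) / fs
    if config.jitter_sd_ms > 0:
        periods = 1.0 / fs + rng.normal(0.0, config.jitter_sd_ms / 1000.0, n)
        times = np.concatenate([[0.0], np.cumsum(periods[1:])])

    frames = np.empty((n, N_JOINTS, 3))
    idx = DEFAULT_LAYOUT.index
    for k, t in enumerate(times):
        # the hip tracks the feet: mean of both feet's piecewise-linear
        # anchor progressions, so per-stride timing jitter cannot make
        # the trunk drift away from the legs over the walk
        hip_x = 0.5 * (_interp_extrap(t, right.h, right.a)
                       + _interp_extrap(t, left.h, left.a))
        # bob (one cycle per step) and sway (one per stride) are locked
        # to the footfall phase, not to nominal time
        phi = step_phase(t)
        hip = np.array([
            hip_x,
            SWAY_AMP * np.sin(np.pi * phi),
            HIP_HEIGHT + BOB_AMP * np.sin(2 * np.pi * phi),
        ])
        for name, off in UPPER_OFFSETS.items():
            frames[k, idx[name]] = hip + np.asarray(off)
        for side, sign in (("left", 1.0), ("right", -1.0)):
            hip_side = hip + np.array([0.0, sign * HIP_HALF_WIDTH, -0.03])
            ankle = tracks[side].ankle_at(t)
            frames[k, idx[f"hip_{side}"]] = hip_side
            frames[k, idx[f"ankle_{side}"]] = ankle
            frames[k, idx[f"knee_{side}"]] = (
                0.5 * (hip_side + ankle) + np.array([0.03, 0.0, 0.0])
            )
            frames[k, idx[f"foot_{side}"]] = ankle + FOOT_DROP

    # ground truth in world coordinates before noise / placement
    ground_z = (ANKLE_HEIGHT + FOOT_DROP[2])
    events_hs = {s: tracks[s].h[1:].tolist() for s in ("left", "right")}
    events_to = {s: tracks[s].toe_off_times()[1:].tolist()
                 for s in ("left", "right")}
    centers_world = {
        s: np.column_stack([
            tracks[s].a[1:],
            np.full(S + 1, tracks[s].lateral),
            np.full(S + 1, ground_z),
        ])
        for s in ("left", "right")
    }

    if config.joint_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.joint_noise_sd, frames.shape)

    if config.rigid_placement:
        R = Rotation.random(rng=rng).as_matrix()
        tr = rng.uniform(-2.0, 2.0, 3)
    else:
        R, tr = np.eye(3), np.zeros(3)
    frames = frames @ R.T + tr
    centers = {s: c @ R.T + tr for s, c in centers_world.items()}

    ann = StrideAnnotation(
        left=FootEvents(
            heel_strikes=[round_half_up(t * fs) for t in events_hs["left"]],
            toe_offs=[round_half_up(t * fs) for t in events_to["left"]],
        ),
        right=FootEvents(
            heel_strikes=[round_half_up(t * fs) for t in events_hs["right"]],
            toe_offs=[round_half_up(t * fs) for t in events_to["right"]],
        ),
    )
    walk = TrialWalk(frames, frame_rate=fs, subject_id=subject.subject_id,
                     trial_id=trial_id, frame_tag=SENSOR)
    gt = GroundTruth(
        annotation=ann,
        heel_strike_times=events_hs,
        toe_off_times=events_to,
        heel_centers=centers,
        parameters=GaitParameters(),  # filled below
        stride_period=T,
        stride_length=L,
    )
    gt.parameters = compute_gait_parameters(
        gt.foot_segmentation("left"), gt.foot_segmentation("right"), fs
    )
    return walk, gt


@dataclass
class SubjectRecord:
    params: SubjectParams
    trials: list[tuple[TrialWalk, GroundTruth]] = field(default_factory=list)


def draw_subject(config: SynthConfig, index: int) -> SubjectParams:
    """Draw one subject's gait parameters (dedicated stream)."""
    rng = np.random.default_rng([config.seed, index])
    period = float(np.clip(
        rng.normal(config.stride_period_mean, config.stride_period_sd),
        0.4, 1.6))
    if config.snap_period_to_frames:
        period = round(period * config.frame_rate) / config.frame_rate
    length = rng.normal(config.stride_length_mean, config.stride_length_sd)
    return SubjectParams(
        subject_id=f"s{index:02d}",
        stride_period=period,
        stride_length=float(np.clip(length, 0.35, 1.2)),
    )


def generate_cohort(config: SynthConfig) -> list[SubjectRecord]:
    """Generate the full cohort: subjects x trials with ground truth.

    Subject-level parameters are drawn once per subject; per-stride
    perturbations are drawn per trial from a stream seeded by
    (cohort seed, subject index, trial index).
    """
    cohort = []
    for s in range(config.n_subjects):
        subject = draw_subject(config, s)
        rec = SubjectRecord(params=subject)
        for t in range(config.trials_per_subject):
            walk, gt = generate_trial_walk(
                config, subject, trial_seed=[config.seed, s, 1000 + t],
                trial_id=f"t{t}",
            )
            rec.trials.append((walk, gt))
        cohort.append(rec)
    return cohort
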