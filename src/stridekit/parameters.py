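"""Spatiotemporal gait parameters from per-foot segmentations.

Nine parameters are reported, matching standard instrumented-walkway
output: left/right step time (s), cadence (strides/min), mean swing
time (s), left/right stride length (cm), left/right step length (cm),
and velocity (cm/s).  Definitions:

* step time  S^r = mean over cycles of (next right heel strike - left
  heel strike); S^l symmetric;
* stride time R = mean interval between consecutive same-foot heel
  strikes;
* cadence    C = 60/R^r + 60/R^l;
* swing time W = mean (next same-foot heel strike - toe-off);
* stride length L = mean distance between consecutive same-foot heel
  centers;
* step length D^r = mean scalar projection of (right heel center -
  previous left heel center) onto the line of progression joining the
  two flanking left heel centers; D^l symmetric;
* velocity   V = (L^r + L^l) / (R^r + R^l).

Times are averaged over the available cycles; feet are paired by
temporal adjacency after merging the two heel-strike streams, so
boundary events without a partner are dropped rather than force-paired.
Lengths are internally meters and converted to centimeters exactly at
the reporting boundary.  Parameters whose inputs are missing are
reported as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import FootSegmentation

M_TO_CM = 100.0


@dataclass
class GaitParameters:
    """The nine spatiotemporal parameters (NaN where undefined)."""

    step_time_left: float = math.nan       # s
    step_time_right: float = math.nan      # s
    stride_time_left: float = math.nan     # s
    stride_time_right: float = math.nan    # s
    cadence: float = math.nan              # strides/min
    swing_time_left: float = math.nan      # s
    swing_time_right: float = math.nan     # s
    swing_time: float = math.nan           # s, across-feet mean
    stride_length_left: float = math.nan   # cm
    stride_length_right: float = math.nan  # cm
    step_length_left: float = math.nan     # cm
    step_length_right: float = math.nan    # cm
    velocity: float = math.nan             # cm/s
    k_used: dict[str, int] = field(default_factory=dict)

    #: the nine headline parameters, in reporting order
    REPORTED = (
        "step_time_left", "step_time_right", "cadence", "swing_time",
        "stride_length_left", "stride_length_right",
        "step_length_left", "step_length_right", "velocity",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.REPORTED}


def _mean(values) -> float:
    return float(np.mean(values)) if len(values) else math.nan


def step_time_cycles(
    own_heel_strikes, other_heel_strikes
) -> list[float]:
    """Per-cycle step times for one foot (seconds).

    Each opposite-foot heel strike is paired with the next own-foot
    heel strike; pairs broken by a missing or non-alternating event are
    dropped.
    """
    out = []
    for t_other in other_heel_strikes:
        nxt = [t for t in own_heel_strikes if t > t_other]
        if not nxt:
            continue
        t_own = min(nxt)
        # drop the pair if another opposite-foot strike intervenes
        if any(t_other < u < t_own for u in other_heel_strikes):
            continue
        out.append(t_own - t_other)
    return out


def temporal_parameters(
    seg_left: FootSegmentation,
    seg_right: FootSegmentation,
    frame_rate: float,
) -> GaitParameters:
    """Temporal parameters (times in seconds) from both feet's events."""
    p = GaitParameters()
    hs = {side: [t / frame_rate for t in seg.heel_strike_frames]
          for side, seg in (("left", seg_left), ("right", seg_right))}
    to = {side: [t / frame_rate for t in seg.toe_off_frames]
          for side, seg in (("left", seg_left), ("right", seg_right))}

    for side in ("left", "right"):
        strides = [b - a for a, b in zip(hs[side], hs[side][1:])]
        setattr(p, f"stride_time_{side}", _mean(strides))
        p.k_used[f"stride_time_{side}"] = len(strides)

        other = "right" if side == "left" else "left"
        steps = step_time_cycles(hs[side], hs[other])
        setattr(p, f"step_time_{side}", _mean(steps))
        p.k_used[f"step_time_{side}"] = len(steps)

        swings = []
        for t_toe in to[side]:
            nxt = [t for t in hs[side] if t > t_toe]
            if nxt:
                swings.append(min(nxt) - t_toe)
        setattr(p, f"swing_time_{side}", _mean(swings))
        p.k_used[f"swing_time_{side}"] = len(swings)

    if not math.isnan(p.stride_time_right) and not math.isnan(p.stride_time_left):
        p.cadence = 60.0 / p.stride_time_right + 60.0 / p.stride_time_left
        p.k_used["cadence"] = (p.k_used["stride_time_right"]
                               + p.k_used["stride_time_left"])
    swing_feet = [w for w in (p.swing_time_left, p.swing_time_right)
                  if not math.isnan(w)]
    p.swing_time = _mean(swing_feet)
    p.k_used["swing_time"] = (p.k_used.get("swing_time_left", 0)
                              + p.k_used.get("swing_time_right", 0))
    return p


def step_length_cycles(
    own_centers: np.ndarray,
    own_times,
    other_centers: np.ndarray,
    other_times,
) -> list[float]:
    """Per-cycle step lengths for one foot (meters).

    For each own-foot heel center falling between two consecutive
    opposite-foot heel strikes, the step length is the scalar
    projection of (own center - earlier opposite center) onto the line
    of progression joining the two opposite-foot centers.
    """
    out = []
    for j in range(len(other_times) - 1):
        t0, t1 = other_times[j], other_times[j + 1]
        inside = [i for i, t in enumerate(own_times) if t0 < t < t1]
        if len(inside) != 1:
            continue
        i = inside[0]
        line = other_centers[j + 1] - other_centers[j]
        norm = float(np.linalg.norm(line))
        if norm <= 0:
            continue
        out.append(float((own_centers[i] - other_centers[j]) @ line) / norm)
    return out


def spatial_parameters(
    seg_left: FootSegmentation,
    seg_right: FootSegmentation,
    params: GaitParameters | None = None,
) -> GaitParameters:
    """Spatial parameters (cm) from heel centers; fills velocity.

    Updates ``params`` in place when given (so temporal and spatial
    halves share one record).
    """
    p = params if params is not None else GaitParameters()
    segs = {"left": seg_left, "right": seg_right}
    for side in ("left", "right"):
        seg = segs[side]
        if seg.heel_centers is None or len(seg.heel_centers) < 2:
            p.k_used[f"stride_length_{side}"] = 0
            continue
        c = np.asarray(seg.heel_centers, dtype=float)
        lengths = np.linalg.norm(np.diff(c, axis=0), axis=1)
        setattr(p, f"stride_length_{side}", float(lengths.mean()) * M_TO_CM)
        p.k_used[f"stride_length_{side}"] = len(lengths)

    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        seg, oth = segs[side], segs[other]
        if (seg.heel_centers is None or oth.heel_centers is None
                or len(oth.heel_centers) < 2):
            p.k_used[f"step_length_{side}"] = 0
            continue
        steps = step_length_cycles(
            np.asarray(seg.heel_centers), seg.heel_strike_frames,
            np.asarray(oth.heel_centers), oth.heel_strike_frames,
        )
        if steps:
            setattr(p, f"step_length_{side}", _mean(steps) * M_TO_CM)
        p.k_used[f"step_length_{side}"] = len(steps)

    if not any(math.isnan(x) for x in (
            p.stride_length_left, p.stride_length_right,
            p.stride_time_left, p.stride_time_right)):
        p.velocity = ((p.stride_length_left + p.stride_length_right)
                      / (p.stride_time_left + p.stride_time_right))
        p.k_used["velocity"] = (p.k_used["stride_length_left"]
                                + p.k_used["stride_length_right"])
    return p


def compute_gait_parameters(
    seg_left: FootSegmentation,
    seg_right: FootSegmentation,
    frame_rate: float,
) -> GaitParameters:
    """All nine parameters from a per-foot segmentation pair."""
    p = temporal_parameters(seg_left, seg_right, frame_rate)
    return spatial_parameters(seg_left, seg_right, p)


def subject_aggregate(trials: list[GaitParameters]) -> GaitParameters:
    """Cycle-count-weighted mean of each parameter across trials."""
    if not trials:
        raise ValueError("no trials to aggregate")
    agg = GaitParameters()
    names = [f.name for f in agg.__dataclass_fields__.values()
             if f.name != "k_used"]
    for name in names:
        num = den = 0.0
        for t in trials:
            v = getattr(t, name)
            k = t.k_used.get(name, 1)
            if not math.isnan(v) and k > 0:
                num += k * v
                den += k
        if den > 0:
            setattr(agg, name, num / den)
        agg.k_used[name] = int(sum(t.k_used.get(name, 0) for t in trials))
    return agg
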