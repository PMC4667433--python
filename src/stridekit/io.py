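"""Plain-text I/O for trial walks, gait-event annotations, and template banks.

Formats
-------
Trial walk
    Wide CSV, one row per frame: a ``frame`` column followed by
    ``<joint>_<axis>`` columns for the 20 joints and axes x, y, z
    (meters).  A JSON sidecar with the same basename and suffix
    ``.meta.json`` holds ``frame_rate``, ``subject_id``, ``trial_id``
    and ``frame_tag``.
Annotations
    JSON: ``{"left": {"heel_strikes": [...], "toe_offs": [...]},
    "right": {...}}`` with 0-based frame indices.
Template bank
    JSON with nested arrays (means, covariances, toe-off index per
    scale m and side); see :mod:`stridekit.templates`.

All frame indices in files and interfaces are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import DEFAULT_LAYOUT, N_JOINTS, SkeletonLayout

AXES = ("x", "y", "z")

SENSOR = "sensor"
CANONICAL = "canonical"


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class TrialWalk:
    """A skeleton-tracking time series for one walking trial.

    Parameters
    ----------
    frames
        Array of shape (n, 20, 3): per-frame 3D joint positions in
        meters, in the :data:`stridekit.layout.JOINT_NAMES` order.
    frame_rate
        Nominal sampling rate in Hz.
    frame_tag
        ``"sensor"`` for raw device coordinates, ``"canonical"`` after
        mapping into the subject-attached reference frame.
    """

    frames: np.ndarray
    frame_rate: float = 30.0
    subject_id: str = ""
    trial_id: str = ""
    frame_tag: str = SENSOR
    layout: SkeletonLayout = field(default=DEFAULT_LAYOUT, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2 and self.frames.shape[1] == 3 * N_JOINTS:
            self.frames = self.frames.reshape(-1, N_JOINTS, 3)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (N_JOINTS, 3):
            raise FormatError(
                f"trial walk frames must have shape (n, {N_JOINTS}, 3), "
                f"got {self.frames.shape}"
            )
        if self.n < 2:
            raise FormatError(f"trial walk needs at least 2 frames, got {self.n}")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("trial walk contains non-finite coordinates")
        if not self.frame_rate > 0:
            raise FormatError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.frame_tag not in (SENSOR, CANONICAL):
            raise FormatError(f"unknown frame_tag {self.frame_tag!r}")

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    def as_vectors(self) -> np.ndarray:
        """Frames flattened to shape (n, 60) skeleton vectors."""
        return self.frames.reshape(self.n, 3 * N_JOINTS)

    def joint(self, name: str) -> np.ndarray:
        """Per-frame (n, 3) trajectory of one named joint."""
        return self.frames[:, self.layout.index[name], :]

    def matching_coordinates(self, joints) -> np.ndarray:
        """(n, 3*len(joints)) matrix restricted to the given joints."""
        idx = self.layout.indices(joints)
        return self.frames[:, idx, :].reshape(self.n, 3 * len(idx))

    def replace(self, **kwargs) -> "TrialWalk":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FootEvents:
    """Heel-strike and toe-off frame indices for one foot (0-based)."""

    heel_strikes: list[int] = field(default_factory=list)
    toe_offs: list[int] = field(default_factory=list)


@dataclass
class StrideAnnotation:
    """Manually (or synthetically) annotated gait events for both feet.

    Invariants: event lists strictly increasing; between consecutive
    heel strikes of a foot lies exactly one toe-off of that foot.
    """

    left: FootEvents = field(default_factory=FootEvents)
    right: FootEvents = field(default_factory=FootEvents)

    def __post_init__(self) -> None:
        for side in ("left", "right"):
            ev = self.foot(side)
            ev.heel_strikes = [int(t) for t in ev.heel_strikes]
            ev.toe_offs = [int(t) for t in ev.toe_offs]
            for name, lst in (("heel_strikes", ev.heel_strikes),
                              ("toe_offs", ev.toe_offs)):
                if any(b <= a for a, b in zip(lst, lst[1:])):
                    raise ValueError(
                        f"{side} {name} must be strictly increasing: {lst}"
                    )
            for a, b in zip(ev.heel_strikes, ev.heel_strikes[1:]):
                k = sum(1 for t in ev.toe_offs if a < t < b)
                if k != 1:
                    raise ValueError(
                        f"{side} foot: expected exactly one toe-off in "
                        f"({a}, {b}), found {k}"
                    )

    def foot(self, side: str) -> FootEvents:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def validate_range(self, n: int) -> None:
        for side in ("left", "right"):
            ev = self.foot(side)
            for t in ev.heel_strikes + ev.toe_offs:
                if not 0 <= t < n:
                    raise ValueError(
                        f"{side} event frame {t} outside [0, {n})"
                    )


# ---------------------------------------------------------------------------
# trial walk CSV + sidecar
# ---------------------------------------------------------------------------

def _walk_columns(layout: SkeletonLayout) -> list[str]:
    return [f"{j}_{a}" for j in layout.joint_names for a in AXES]


def _meta_path(path: Path) -> Path:
    stem = path.stem if path.suffix else path.name
    return path.with_name(stem + ".meta.json")


def write_trial_walk(walk: TrialWalk, path) -> None:
    """Write a trial walk as wide CSV plus a ``.meta.json`` sidecar.

    Floating values are serialized with 17 significant digits, so a
    round trip reproduces coordinates bit-for-bit.
    """
    path = Path(path)
    cols = _walk_columns(walk.layout)
    df = pd.DataFrame(walk.as_vectors(), columns=cols)
    df.insert(0, "frame", np.arange(walk.n))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "frame_rate": walk.frame_rate,
        "subject_id": walk.subject_id,
        "trial_id": walk.trial_id,
        "frame_tag": walk.frame_tag,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_trial_walk(path) -> TrialWalk:
    """Read a trial walk written by :func:`write_trial_walk`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    expected = ["frame"] + _walk_columns(DEFAULT_LAYOUT)
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: header mismatch; expected {len(expected)} columns "
            f"(frame + {3 * N_JOINTS} coordinates), got {len(df.columns)}"
        )
    coords = df[expected[1:]]
    values = coords.to_numpy()
    if values.dtype.kind not in "fi" or not np.all(np.isfinite(values)):
        # locate the first offending cell for the error message
        arr = coords.apply(pd.to_numeric, errors="coerce").to_numpy()
        rows, cols = np.nonzero(~np.isfinite(arr))
        if rows.size:
            raise FormatError(
                f"{path}: non-numeric cell at data row {rows[0]}, "
                f"column {expected[1:][cols[0]]!r}"
            )
        raise FormatError(f"{path}: non-numeric coordinate data")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return TrialWalk(
        values.astype(float),
        frame_rate=float(meta.get("frame_rate", 30.0)),
        subject_id=str(meta.get("subject_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        frame_tag=str(meta.get("frame_tag", SENSOR)),
    )


# ---------------------------------------------------------------------------
# annotations JSON
# ---------------------------------------------------------------------------

def write_annotations(ann: StrideAnnotation, path, overwrite: bool = True) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    payload = {
        side: {
            "heel_strikes": ann.foot(side).heel_strikes,
            "toe_offs": ann.foot(side).toe_offs,
        }
        for side in ("left", "right")
    }
    path.write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> StrideAnnotation:
    path = Path(path)
    data = json.loads(path.read_text())
    feet = {}
    for side in ("left", "right"):
        if side not in data:
            raise FormatError(f"{path}: missing foot key {side!r}")
        entry = data[side]
        for key in ("heel_strikes", "toe_offs"):
            if key not in entry:
                raise FormatError(f"{path}: {side} is missing {key!r}")
        feet[side] = FootEvents(
            heel_strikes=list(entry["heel_strikes"]),
            toe_offs=list(entry["toe_offs"]),
        )
    return StrideAnnotation(left=feet["left"], right=feet["right"])


# ---------------------------------------------------------------------------
# template bank JSON (serialization half; construction in templates.py)
# ---------------------------------------------------------------------------

def write_template_bank(bank, path) -> None:
    from .templates import TemplateBank  # local import avoids a cycle

    assert isinstance(bank, TemplateBank)
    payload = {
        "m_mean": bank.m_mean,
        "m_sd": bank.m_sd,
        "gamma": bank.gamma,
        "matching_joints": list(bank.matching_joints),
        "scales": sorted(bank.scales),
        "templates": {
            str(m): {
                side: {
                    "means": bank.template(m, side).means.tolist(),
                    "covariances": bank.template(m, side).covariances.tolist(),
                    "toe_off_index": int(bank.template(m, side).toe_off_index),
                }
                for side in ("left", "right")
            }
            for m in sorted(bank.scales)
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_template_bank(path):
    from .templates import StrideTemplate, TemplateBank

    data = json.loads(Path(path).read_text())
    templates = {}
    for m_str, sides in data["templates"].items():
        m = int(m_str)
        for side, tpl in sides.items():
            templates[(m, side)] = StrideTemplate(
                side=side,
                means=np.asarray(tpl["means"], dtype=float),
                covariances=np.asarray(tpl["covariances"], dtype=float),
                toe_off_index=int(tpl["toe_off_index"]),
            )
    return TemplateBank(
        templates=templates,
        m_mean=int(data["m_mean"]),
        m_sd=int(data["m_sd"]),
        matching_joints=tuple(data["matching_joints"]),
        gamma=data.get("gamma"),
    )
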