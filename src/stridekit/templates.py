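"""Probabilistic stride template models.

A stride template of length m is a sequence of (mean, covariance) pairs,
one per template time index, describing the distribution of the
matching-joint coordinates (all leg joints plus the hip center, d = 27)
at each instant of a stride cycle.  Separate right and left templates
are learned, at every integer scale m in a set M covering about 95 % of
observed stride lengths (mean +/- 2 SD).

Learning: annotated strides (heel strike to next same-foot heel strike)
are extracted from canonical-frame training walks, resampled to each
length m with cubic splines, and averaged per time index.  Sample
covariances are shrunk toward a scaled identity and floored to stay
positive definite with any training-set size >= 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .io import CANONICAL, StrideAnnotation, TrialWalk
from .layout import MATCHING_JOINTS

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few annotated strides to learn templates."""


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5))


@dataclass
class StrideTemplate:
    """One stride template: per-time means and covariances.

    ``toe_off_index`` is the 0-based template time index of the toe-off
    within the stride cycle.
    """

    side: str
    means: np.ndarray            # (m, d)
    covariances: np.ndarray      # (m, d, d)
    toe_off_index: int
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        m, d = self.means.shape
        if self.covariances.shape != (m, d, d):
            raise ValueError("covariance stack does not match means")
        if not 0 <= self.toe_off_index < m:
            raise ValueError(
                f"toe_off_index {self.toe_off_index} outside [0, {m})"
            )

    @property
    def m(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factors of the covariances, cached."""
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.covariances)
        return self._chol


@dataclass
class TemplateBank:
    """Right and left stride templates at every scale m in M."""

    templates: dict[tuple[int, str], StrideTemplate]
    m_mean: int
    m_sd: int
    matching_joints: tuple[str, ...] = MATCHING_JOINTS
    #: acceptance threshold calibrated on the training walks (optional)
    gamma: float | None = None

    def __post_init__(self) -> None:
        scales = self.scales
        if not scales:
            raise ValueError("template bank is empty")
        if scales != list(range(min(scales), max(scales) + 1)):
            raise ValueError("scale set must be consecutive integers")
        for m in scales:
            for side in ("left", "right"):
                if (m, side) not in self.templates:
                    raise ValueError(f"missing {side} template at scale {m}")

    @property
    def scales(self) -> list[int]:
        return sorted({m for m, _ in self.templates})

    def template(self, m: int, side: str) -> StrideTemplate:
        return self.templates[(m, side)]

    def side(self, side: str) -> list[StrideTemplate]:
        return [self.template(m, side) for m in self.scales]


def extract_strides(
    walk: TrialWalk,
    ann: StrideAnnotation,
    side: str,
    joints: tuple[str, ...] = MATCHING_JOINTS,
) -> list[tuple[np.ndarray, int]]:
    """Extract single stride-cycle subsequences for one foot.

    Each stride spans ``[H_i, H_{i+1})`` (half-open) between consecutive
    same-foot heel strikes; the toe-off offset is ``T_i - H_i``.  A
    stride with no toe-off annotated inside it is skipped with a logged
    warning.  Returns a list of ``(subsequence, toe_off_offset)`` where
    the subsequence is restricted to the matching joints.
    """
    if walk.frame_tag != CANONICAL:
        raise ValueError("strides must be extracted from canonical-frame walks")
    ann.validate_range(walk.n)
    ev = ann.foot(side)
    data = walk.matching_coordinates(joints)
    strides: list[tuple[np.ndarray, int]] = []
    for a, b in zip(ev.heel_strikes, ev.heel_strikes[1:]):
        toes = [t for t in ev.toe_offs if a < t < b]
        if len(toes) != 1:
            log.warning(
                "%s stride [%d, %d): expected one toe-off, found %d; skipped",
                side, a, b, len(toes),
            )
            continue
        strides.append((data[a:b].copy(), toes[0] - a))
    return strides


def build_scale_set(stride_lengths) -> tuple[int, int, range]:
    """Rounded mean / SD of stride lengths and the scale set M.

    M = {m_mean - 2*sd, ..., m_mean + 2*sd} (clipped below at 2), so
    about 95 % of stride lengths fall inside the covered range.  The SD
    is the sample (n-1) standard deviation.
    """
    lengths = np.asarray(list(stride_lengths), dtype=float)
    if lengths.size < 2:
        raise InsufficientDataError(
            f"need at least 2 stride lengths, got {lengths.size}"
        )
    m_mean = round_half_up(float(lengths.mean()))
    m_sd = round_half_up(float(lengths.std(ddof=1)))
    lo = max(m_mean - 2 * m_sd, 2)
    hi = m_mean + 2 * m_sd
    return m_mean, m_sd, range(lo, hi + 1)


def resample_stride(subseq: np.ndarray, m: int) -> np.ndarray:
    """Resample a stride to length m with natural cubic splines.

    Each coordinate channel is interpolated over a uniform grid of m
    points spanning the original support; endpoints are preserved
    exactly.
    """
    subseq = np.asarray(subseq, dtype=float)
    if m < 2:
        raise ValueError(f"target length must be >= 2, got {m}")
    v = subseq.shape[0]
    if v < 2:
        raise ValueError(f"stride subsequence must have >= 2 frames, got {v}")
    if v == m:
        return subseq.copy()
    grid = np.linspace(0.0, v - 1.0, m)
    spline = CubicSpline(np.arange(v), subseq, axis=0, bc_type="natural")
    out = spline(grid)
    out[0], out[-1] = subseq[0], subseq[-1]
    return out


def regularize_covariance(
    cov: np.ndarray, shrinkage: float = 0.1, floor: float = 1e-6
) -> np.ndarray:
    """Shrink a covariance toward a scaled identity and floor eigenvalues.

    ``(1 - lam) * cov + lam * tr(cov)/d * I``, then any eigenvalue below
    ``floor`` (m^2) is raised to it, guaranteeing positive definiteness
    for any training-set size.
    """
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    shrunk = (1.0 - shrinkage) * cov + shrinkage * (np.trace(cov) / d) * np.eye(d)
    shrunk = 0.5 * (shrunk + shrunk.T)
    w, v = np.linalg.eigh(shrunk)
    if w.min() < floor:
        w = np.maximum(w, floor)
        shrunk = (v * w) @ v.T
        shrunk = 0.5 * (shrunk + shrunk.T)
    return shrunk


def learn_templates_for_side(
    strides: list[tuple[np.ndarray, int]],
    m: int,
    side: str,
    shrinkage: float = 0.1,
    floor: float = 1e-6,
) -> StrideTemplate:
    """Learn one template of length m from extracted strides."""
    if len(strides) < 2:
        raise InsufficientDataError(
            f"{side}: need >= 2 strides to learn a template, got {len(strides)}"
        )
    resampled = np.stack([resample_stride(s, m) for s, _ in strides])
    # toe-off offsets mapped onto the resampled uniform grid
    toe = [off * (m - 1) / (s.shape[0] - 1) for s, off in strides]
    toe_index = round_half_up(float(np.mean(toe)))
    toe_index = min(max(toe_index, 0), m - 1)
    means = resampled.mean(axis=0)
    covs = np.empty((m, means.shape[1], means.shape[1]))
    for i in range(m):
        x = resampled[:, i, :]
        diff = x - x.mean(axis=0)
        cov = diff.T @ diff / (x.shape[0] - 1)
        covs[i] = regularize_covariance(cov, shrinkage=shrinkage, floor=floor)
    return StrideTemplate(
        side=side, means=means, covariances=covs, toe_off_index=toe_index
    )


def learn_template_bank(
    training: list[tuple[TrialWalk, StrideAnnotation]],
    joints: tuple[str, ...] = MATCHING_JOINTS,
    shrinkage: float = 0.1,
    floor: float = 1e-6,
) -> TemplateBank:
    """Learn the full right/left template bank from annotated walks.

    Stride lengths from both feet are pooled to fix the scale set M;
    for every m in M and each side, strides are spline-resampled to m
    and averaged per time index (mean and regularized covariance).
    """
    strides = {"left": [], "right": []}
    for walk, ann in training:
        for side in ("left", "right"):
            strides[side].extend(extract_strides(walk, ann, side, joints=joints))
    counts = {s: len(v) for s, v in strides.items()}
    if min(counts.values()) < 2:
        raise InsufficientDataError(
            f"need >= 2 strides per side, got {counts}"
        )
    lengths = [s.shape[0] for side in ("left", "right")
               for s, _ in strides[side]]
    m_mean, m_sd, scale_set = build_scale_set(lengths)
    templates: dict[tuple[int, str], StrideTemplate] = {}
    for m in scale_set:
        for side in ("left", "right"):
            templates[(m, side)] = learn_templates_for_side(
                strides[side], m, side, shrinkage=shrinkage, floor=floor
            )
    return TemplateBank(
        templates=templates, m_mean=m_mean, m_sd=m_sd, matching_joints=joints
    )
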