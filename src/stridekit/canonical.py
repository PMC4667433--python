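"""Subject-attached canonical reference frame.

Skeleton trackers report joint positions in the sensor's own frame,
which depends on where the device happens to stand.  Stride templates,
however, must be sensor-placement independent.  This module estimates a
*canonical reference frame* from the data itself:

* ``u1`` — the vertical axis, constant over a walk: the second principal
  component of the pooled joint point cloud (the first component is the
  progression direction, along which the cloud is most elongated),
  sign-oriented so the head lies above the ankles.  Hands, wrists and
  elbows are excluded for robustness to arm swings.
* ``u2_t`` — the per-frame direction of progression: first principal
  direction of a short window of skeleton center points (mean of the two
  hip joints and the hip center), projected onto the ground plane and
  oriented along the displacement of the window.
* ``u3_t = u1 x u2_t`` — the lateral axis.

Mapping a skeleton vector into the frame subtracts, per frame, the
ground height (so the lowest joint sits at vertical coordinate 0) and
the horizontal position of the body center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CANONICAL, TrialWalk
from .layout import ARM_JOINTS, CENTER_JOINTS, JOINT_NAMES


class DegenerateGeometryError(ValueError):
    """The joint cloud does not span enough dimensions to define axes."""


@dataclass
class CanonicalFrameSeries:
    """Per-frame canonical axes and anchor points of one trial walk.

    Attributes
    ----------
    u1 : (3,) vertical axis (constant).
    u2 : (n, 3) per-frame progression axes.
    u3 : (n, 3) per-frame lateral axes, ``u1 x u2_t``.
    center : (n, 3) skeleton center points ``y_c,t`` (sensor frame).
    ground : (n, 3) per-frame ground-contact joints ``y_0,t``
        (the joint with minimal u1-coordinate).
    tau : half-window (frames) used for the progression estimate.
    """

    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray
    center: np.ndarray
    ground: np.ndarray
    tau: int

    def basis(self, t: int) -> np.ndarray:
        """Column-orthonormal 3x3 matrix U_t = [u1, u2_t, u3_t]."""
        return np.column_stack([self.u1, self.u2[t], self.u3[t]])


def estimate_vertical_axis(walk: TrialWalk) -> np.ndarray:
    """Estimate the unit vertical axis from the pooled joint cloud.

    Returns the second principal component of the mean-removed cloud of
    all joints over all frames (arms excluded), oriented so that the
    head's mean coordinate exceeds the ankles' mean coordinate.
    """
    keep = [j for j in JOINT_NAMES if j not in ARM_JOINTS]
    idx = walk.layout.indices(keep)
    cloud = walk.frames[:, idx, :].reshape(-1, 3)
    centered = cloud - cloud.mean(axis=0)
    # principal directions via SVD of the mean-removed coordinate matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "joint cloud is (near-)collinear; cannot estimate a vertical axis"
        )
    u1 = vt[1]
    head = walk.joint("head").mean(axis=0)
    ankles = 0.5 * (walk.joint("ankle_left").mean(axis=0)
                    + walk.joint("ankle_right").mean(axis=0))
    if float(u1 @ (head - ankles)) < 0:
        u1 = -u1
    return u1 / np.linalg.norm(u1)


def skeleton_centers(walk: TrialWalk) -> np.ndarray:
    """Per-frame skeleton center point: mean of the hip joints."""
    return np.mean(
        [walk.joint(j) for j in CENTER_JOINTS], axis=0
    )


def estimate_progression_axes(
    walk: TrialWalk, u1: np.ndarray, tau: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame progression (u2_t) and lateral (u3_t) unit axes.

    For every frame t, the window of skeleton centers
    ``[y_c,max(t-tau,0) .. y_c,min(t+tau,n-1)]`` (truncated at the walk
    ends) is mean-removed; its first principal direction, projected on
    the plane orthogonal to ``u1`` and normalized, gives ``u2_t``, with
    the sign chosen so it points along the window's displacement.
    """
    n = walk.n
    centers = skeleton_centers(walk)
    u2 = np.empty((n, 3))
    for t in range(n):
        lo, hi = max(t - tau, 0), min(t + tau, n - 1)
        win = centers[lo:hi + 1]
        centered = win - win.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        disp = centers[hi] - centers[lo]
        if s[0] <= 1e-12 and np.linalg.norm(disp) <= 1e-12:
            raise DegenerateGeometryError(
                f"stationary window around frame {t}: no direction of progression"
            )
        v = vt[0]
        v = v - (v @ u1) * u1  # project onto the ground plane
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            raise DegenerateGeometryError(
                f"progression direction at frame {t} is vertical/undefined"
            )
        v = v / nv
        if float(v @ disp) < 0:
            v = -v
        u2[t] = v
    u3 = np.cross(np.broadcast_to(u1, u2.shape), u2)
    return u2, u3


def to_canonical(
    walk: TrialWalk, tau: int = 3
) -> tuple[TrialWalk, CanonicalFrameSeries]:
    """Map a sensor-frame trial walk into the canonical reference frame.

    Every joint position becomes ``U_t^T y_{i,t}`` minus the offset
    ``[u1.y_0,t ; u2_t.y_c,t ; u3_t.y_c,t]``: coordinate 0 is height
    above the lowest joint, coordinates 1 and 2 are positions along the
    progression and lateral axes relative to the body center.
    """
    if walk.frame_tag == CANONICAL:
        raise ValueError("walk is already in the canonical frame")
    u1 = estimate_vertical_axis(walk)
    u2, u3 = estimate_progression_axes(walk, u1, tau=tau)
    centers = skeleton_centers(walk)

    heights = walk.frames @ u1                       # (n, 20) u1-coordinates
    ground_idx = np.argmin(heights, axis=1)          # lowest joint per frame
    ground = walk.frames[np.arange(walk.n), ground_idx]

    out = np.empty_like(walk.frames)
    for t in range(walk.n):
        U = np.column_stack([u1, u2[t], u3[t]])
        offset = np.array([
            u1 @ ground[t],
            u2[t] @ centers[t],
            u3[t] @ centers[t],
        ])
        out[t] = walk.frames[t] @ U - offset
    series = CanonicalFrameSeries(
        u1=u1, u2=u2, u3=u3, center=centers, ground=ground, tau=tau
    )
    return walk.replace(frames=out, frame_tag=CANONICAL), series
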