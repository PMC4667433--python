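"""Trial-walk segmentation into stride cycles.

The pipeline for one foot:

1. SSWM against the template bank gives the best-matching stride, the
   optimal scale m*, and the accumulated-cost matrix D_S.
2. Additional stride endings are read off the local minima of
   ``D_S(., m*)``: starting from the global minimum, the search expands
   alternately toward earlier and later times; a local minimum is
   accepted if it lies at least 2m*/3 from every accepted ending and
   its normalized cost is below a threshold gamma, and a direction is
   closed when the nearest candidate lies more than 4m*/3 beyond the
   boundary ending.  The count of accepted endings is the stride count N.
3. Contiguous refinement (CSDTW_L): a template built by concatenating N
   copies of the scale-m* template is matched with subsequence DTW; the
   warping path maps each copy's first index to a heel strike and its
   toe-off index to a toe-off, making consecutive strides exactly
   contiguous.
4. Heel centers: the ankle joint at each heel strike, projected onto
   the ground plane in the canonical frame and expressed back in sensor
   coordinates.

Run once per foot with that foot's templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .canonical import CanonicalFrameSeries, to_canonical
from .io import CANONICAL, SENSOR, TrialWalk
from .matching import MatchResult, NoMatchError, sdtw_ml, sswm
from .templates import StrideTemplate, TemplateBank

log = logging.getLogger(__name__)


@dataclass
class FootSegmentation:
    """Per-foot segmentation of a trial walk into N contiguous strides.

    ``heel_strike_frames`` has N+1 entries delimiting N strides;
    ``spans`` are inclusive (start, end) frame pairs tiling the walk
    between the first and last heel strike.  ``heel_centers`` holds one
    sensor-frame 3D point (meters) per heel strike.
    """

    side: str
    n_strides: int
    spans: list[tuple[int, int]] = field(default_factory=list)
    heel_strike_frames: list[int] = field(default_factory=list)
    toe_off_frames: list[int] = field(default_factory=list)
    heel_centers: np.ndarray | None = None
    m_star: int | None = None
    gamma: float | None = None
    match: MatchResult | None = field(default=None, repr=False)


def segmentation_to_dict(
    segs: dict[str, FootSegmentation], frame_rate: float
) -> dict:
    """JSON-ready payload for a two-foot segmentation."""
    out: dict = {"frame_rate": frame_rate}
    for side, seg in segs.items():
        out[side] = {
            "n_strides": seg.n_strides,
            "m_star": seg.m_star,
            "gamma": seg.gamma,
            "spans": [list(s) for s in seg.spans],
            "heel_strike_frames": list(seg.heel_strike_frames),
            "heel_strike_seconds": [t / frame_rate
                                    for t in seg.heel_strike_frames],
            "toe_off_frames": list(seg.toe_off_frames),
            "toe_off_seconds": [t / frame_rate for t in seg.toe_off_frames],
            "heel_centers_m": (seg.heel_centers.tolist()
                               if seg.heel_centers is not None else None),
        }
    return out


def segmentation_from_dict(payload: dict) -> tuple[dict[str, FootSegmentation], float]:
    """Inverse of :func:`segmentation_to_dict`."""
    frame_rate = float(payload["frame_rate"])
    segs = {}
    for side in ("left", "right"):
        d = payload[side]
        segs[side] = FootSegmentation(
            side=side,
            n_strides=int(d["n_strides"]),
            spans=[tuple(s) for s in d["spans"]],
            heel_strike_frames=[int(t) for t in d["heel_strike_frames"]],
            toe_off_frames=[int(t) for t in d["toe_off_frames"]],
            heel_centers=(np.asarray(d["heel_centers_m"], dtype=float)
                          if d.get("heel_centers_m") is not None else None),
            m_star=d.get("m_star"),
            gamma=d.get("gamma"),
        )
    return segs, frame_rate


def find_local_minima(row: np.ndarray, window: int) -> list[int]:
    """Indices strictly smaller than all neighbours within +/- window."""
    row = np.asarray(row, dtype=float)
    n = row.size
    minima = []
    for t in range(n):
        lo, hi = max(t - window, 0), min(t + window, n - 1)
        neighbours = np.r_[row[lo:t], row[t + 1:hi + 1]]
        if neighbours.size and np.all(row[t] < neighbours):
            minima.append(t)
    return minima


def find_stride_endings(
    row: np.ndarray, m_star: int, gamma: float,
    spacing: int | None = None,
) -> list[int]:
    """Accepted stride ending times from the last row of D_S.

    Local minima (strictly minimal within +/- floor(s/4)) whose
    normalized cost ``row[t]/m*`` is below gamma are candidates.  The
    search starts at the global minimum and expands alternately in the
    decreasing- and increasing-time directions; within a direction the
    next accepted ending must lie between 2s/3 and 4s/3 from the
    boundary ending (and at least 2s/3 from every accepted ending),
    otherwise the direction is closed.

    ``s`` is the stride-duration proxy used by the spacing rules; it
    defaults to the template scale m*, but the caller may pass the
    observed best-match span length, which tracks the walker's true
    stride duration even when the selected scale is biased long.
    """
    row = np.asarray(row, dtype=float)
    s = m_star if spacing is None else spacing
    window = max(s // 4, 1)
    candidates = [t for t in find_local_minima(row, window)
                  if row[t] / m_star < gamma]
    if not candidates:
        return []
    start = min(candidates, key=lambda t: (row[t], t))
    accepted = [start]
    near, far = 2.0 * s / 3.0, 4.0 * s / 3.0

    def admissible(t: int, boundary: int) -> bool:
        if not near <= abs(t - boundary) <= far:
            return False
        return all(abs(t - a) >= near for a in accepted)

    lo = hi = start
    open_dirs = {"dec": True, "inc": True}
    while open_dirs["dec"] or open_dirs["inc"]:
        for direction in ("dec", "inc"):
            if not open_dirs[direction]:
                continue
            boundary = lo if direction == "dec" else hi
            pool = [t for t in candidates
                    if (t < boundary if direction == "dec" else t > boundary)
                    and admissible(t, boundary)]
            if not pool:
                open_dirs[direction] = False
                continue
            # lowest cost in the admissible band; ties to the nearest
            chosen = min(pool, key=lambda t: (row[t], abs(t - boundary)))
            accepted.append(chosen)
            if direction == "dec":
                lo = chosen
            else:
                hi = chosen
    return sorted(accepted)


def concatenate_templates(template: StrideTemplate, n: int) -> StrideTemplate:
    """Template formed by concatenating n copies of a stride template.

    The result has length n*m; its per-copy toe-off indices are
    ``i*m + toe_off_index`` for i = 0..n-1 (exposed via
    :func:`concatenated_toe_offs`).
    """
    if n < 1:
        raise ValueError(f"need at least one copy, got {n}")
    return StrideTemplate(
        side=template.side,
        means=np.tile(template.means, (n, 1)),
        covariances=np.tile(template.covariances, (n, 1, 1)),
        toe_off_index=template.toe_off_index,
    )


def concatenated_toe_offs(template: StrideTemplate, n: int) -> list[int]:
    """Toe-off template indices of the n-fold concatenated template."""
    return [i * template.m + template.toe_off_index for i in range(n)]


def _run_midpoint(frames: list[int]) -> int:
    """Midpoint (rounded down) of a contiguous run of walk frames."""
    return (frames[0] + frames[-1]) // 2


def contiguous_refine(
    X: np.ndarray, template: StrideTemplate, n_strides: int
) -> tuple[list[int], list[int], list[tuple[int, int]]]:
    """Contiguous SDTW (CSDTW_L): refine N strides to exact contiguity.

    Matches the N-fold concatenated template against the walk with
    subsequence DTW and maps, through the warping path, each copy's
    first template index to a heel strike and its toe-off index to a
    toe-off.  A template index aligned to a run of walk frames maps to
    the run's midpoint (rounded down).  Returns (heel_strikes [N+1],
    toe_offs [N], inclusive spans [N]).
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    concat = concatenate_templates(template, n_strides)
    res = sdtw_ml(X, concat)
    m = template.m
    heel_strikes = []
    for k in range(n_strides):
        run = res.path.frames_for_template_index(k * m)
        heel_strikes.append(_run_midpoint(run))
    heel_strikes.append(res.t_e + 1)      # final ending delimits the last stride
    toe_offs = []
    for j in concatenated_toe_offs(template, n_strides):
        run = res.path.frames_for_template_index(j)
        toe_offs.append(_run_midpoint(run))
    spans = [(heel_strikes[i], heel_strikes[i + 1] - 1)
             for i in range(n_strides)]
    return heel_strikes, toe_offs, spans


def estimate_heel_centers(
    walk: TrialWalk,
    heel_strike_frames: list[int],
    series: CanonicalFrameSeries,
    side: str,
) -> np.ndarray:
    """Heel centers: ankle positions projected onto the ground plane.

    At each heel strike t the ankle's canonical horizontal coordinates
    are combined with the ground height and mapped back to the sensor
    frame: ``y_H = U_t [u1.y_0,t ; u2_t.y_a,t ; u3_t.y_a,t]``.
    Returns an (len(frames), 3) array in sensor coordinates (meters).
    """
    if walk.frame_tag != SENSOR:
        raise ValueError("heel centers are computed from the sensor-frame walk")
    ankle = walk.joint(f"ankle_{side}")
    centers = np.empty((len(heel_strike_frames), 3))
    for k, t in enumerate(heel_strike_frames):
        if not 0 <= t < walk.n:
            raise ValueError(f"heel-strike frame {t} outside [0, {walk.n})")
        U = series.basis(t)
        comp = np.array([
            series.u1 @ series.ground[t],
            series.u2[t] @ ankle[t],
            series.u3[t] @ ankle[t],
        ])
        centers[k] = U @ comp
    return centers


def calibrate_gamma(
    bank: TemplateBank,
    calibration,
    factor: float = 2.5,
    window: int = 3,
) -> float:
    """Choose the acceptance threshold gamma from annotated walks.

    With shrinkage-regularized covariances the scale of the normalized
    Mahalanobis matching cost depends on the data regime (noise level,
    within- vs across-subject variability), so a fixed threshold cannot
    be universal.  The threshold is therefore tied to the observed cost
    of *genuine* stride endings: for every calibration walk and side,
    the D_S row of the best scale is probed within ``window`` frames of
    each annotated stride ending, and gamma is ``factor`` times the
    largest normalized cost found.  Spurious endings (partial or
    non-gait segments) sit far above genuine ones, so a modest safety
    factor separates the two.

    ``calibration`` is a list of (walk, annotation) pairs — typically
    the same walks the templates were learned from.
    """
    values = []
    for walk, ann in calibration:
        if walk.frame_tag != CANONICAL:
            walk, _ = to_canonical(walk)
        X = walk.matching_coordinates(bank.matching_joints)
        for side in ("left", "right"):
            hs = ann.foot(side).heel_strikes
            if len(hs) < 2:
                continue
            res = sswm(X, bank.side(side))
            row = res.d_s[:, res.m_star - 1]
            for h in hs[1:]:
                t = min(max(h - 1, 0), walk.n - 1)   # stride ends at H_{i+1}-1
                lo, hi = max(t - window, 0), min(t + window, walk.n - 1)
                values.append(float(np.min(row[lo:hi + 1])) / res.m_star)
    if not values:
        raise ValueError("no annotated strides in the calibration set")
    # floor guards the fully deterministic regime where genuine ending
    # costs vanish to numerical noise
    return max(factor * float(np.max(values)), 1e-6)


def segment_foot(
    X: np.ndarray, bank: TemplateBank, side: str, gamma: float
) -> FootSegmentation:
    """Segment one foot's strides from canonical matching coordinates."""
    try:
        match = sswm(X, bank.side(side))
    except NoMatchError:
        log.warning("%s foot: walk shorter than every template scale", side)
        return FootSegmentation(side=side, n_strides=0, gamma=gamma)
    m_star = match.m_star
    span_len = match.t_e - match.t_s + 1
    endings = find_stride_endings(match.d_s[:, m_star - 1], m_star, gamma,
                                  spacing=span_len)
    if not endings:
        log.warning("%s foot: no stride endings below gamma=%.3g", side, gamma)
        return FootSegmentation(side=side, n_strides=0, m_star=m_star,
                                gamma=gamma, match=match)
    n_strides = len(endings)
    tpl = bank.template(m_star, side)
    heel_strikes, toe_offs, spans = contiguous_refine(X, tpl, n_strides)
    return FootSegmentation(
        side=side,
        n_strides=n_strides,
        spans=spans,
        heel_strike_frames=heel_strikes,
        toe_off_frames=toe_offs,
        m_star=m_star,
        gamma=gamma,
        match=match,
    )


def segment_trial_walk(
    walk: TrialWalk,
    bank: TemplateBank,
    gamma: float = 1.0,
    tau: int = 3,
) -> dict[str, FootSegmentation]:
    """Segment a sensor-frame trial walk into strides for both feet.

    Maps the walk into the canonical frame, runs the per-foot
    segmentation twice (right and left templates), and attaches heel
    centers in sensor coordinates.  Returns ``{"left": ..., "right":
    ...}``.
    """
    if walk.frame_tag == CANONICAL:
        raise ValueError(
            "segment_trial_walk needs the sensor-frame walk "
            "(heel centers are expressed in sensor coordinates)"
        )
    canonical_walk, series = to_canonical(walk, tau=tau)
    X = canonical_walk.matching_coordinates(bank.matching_joints)
    out: dict[str, FootSegmentation] = {}
    for side in ("left", "right"):
        seg = segment_foot(X, bank, side, gamma)
        if seg.n_strides > 0:
            frames = [min(t, walk.n - 1) for t in seg.heel_strike_frames]
            seg.heel_centers = estimate_heel_centers(walk, frames, series, side)
        out[side] = seg
    return out
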