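"""Segmentation accuracy, method agreement, and the LOSO harness.

Segmentation accuracy
    * overlap percentage between a predicted and a ground-truth stride
      support (inclusive spans): intersection length over union span
      length, 0 when disjoint;
    * AoD (accuracy on detection): mean overlap after pairing predicted
      to ground-truth strides by maximal overlap (one-to-one greedy);
      unmatched strides on either side contribute 0;
    * Rand index: pair-counting agreement of the two segmentations seen
      as frame clusterings (stride id or background) over the annotated
      span;
    * instant error SD: sample SD (seconds) of matched event-time
      errors — a constant offset yields SD 0.

Method agreement (two instruments measuring the same subjects)
    Pearson's rho, Lin's concordance correlation coefficient with a
    Fisher-z 95 % CI, ICC(2,k) with absolute agreement (two-way random
    effects, F-based CI, via pingouin), Bland-Altman bias and limits of
    agreement (bias +/- 1.96 SD), and the percentage error
    100 * 4 SD / (mean_a + mean_b).

Repeatability: 2 x SD of within-subject trial differences, absolute
and as a percentage of the grand mean.

The LOSO harness learns templates from all subjects but one, segments
the held-out subject's trials, and pools the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .canonical import to_canonical
from .io import StrideAnnotation, TrialWalk
from .segmentation import FootSegmentation, calibrate_gamma, segment_trial_walk
from .templates import learn_template_bank

Span = tuple[int, int]


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# segmentation accuracy
# ---------------------------------------------------------------------------

def overlap_percentage(t: Span, g: Span) -> float:
    """Overlap between two inclusive spans, in [0, 1]."""
    for s in (t, g):
        if s[0] > s[1]:
            raise ValueError(f"invalid span {s}")
    inter = min(t[1], g[1]) - max(t[0], g[0]) + 1
    if inter <= 0:
        return 0.0
    union = max(t[1], g[1]) - min(t[0], g[0]) + 1
    return inter / union


def pair_spans_by_overlap(
    pred: list[Span], gt: list[Span]
) -> list[tuple[int, int, float]]:
    """One-to-one greedy pairing by descending overlap percentage."""
    scored = sorted(
        ((overlap_percentage(p, g), i, j)
         for i, p in enumerate(pred) for j, g in enumerate(gt)),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for s, i, j in scored:
        if s <= 0 or i in used_p or j in used_g:
            continue
        pairs.append((i, j, s))
        used_p.add(i)
        used_g.add(j)
    return pairs


def _pair_events(pred: list[int], gt: list[int]) -> list[tuple[int, int]]:
    """One-to-one event pairing by ascending absolute time difference."""
    scored = sorted(
        ((abs(p - g), i, j) for i, p in enumerate(pred)
         for j, g in enumerate(gt)),
        key=lambda x: (x[0], x[1], x[2]),
    )
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for _, i, j in scored:
        if i in used_p or j in used_g:
            continue
        pairs.append((pred[i], gt[j]))
        used_p.add(i)
        used_g.add(j)
    return pairs


@dataclass
class SegmentationScore:
    aod: float
    rand_index: float
    instant_error_sd: float               # s, pooled heel strikes + toe-offs
    per_stride_overlaps: list[float] = field(default_factory=list)
    heel_strike_errors: list[float] = field(default_factory=list)  # frames
    toe_off_errors: list[float] = field(default_factory=list)      # frames


def _frame_labels(spans: list[Span], lo: int, hi: int) -> np.ndarray:
    """Frame labels over [lo, hi]: stride id (1-based) or 0 background."""
    labels = np.zeros(hi - lo + 1, dtype=int)
    for sid, (a, b) in enumerate(spans, start=1):
        a, b = max(a, lo), min(b, hi)
        if a <= b:
            labels[a - lo:b - lo + 1] = sid
    return labels


def segmentation_score(
    pred: FootSegmentation,
    gt: StrideAnnotation,
    frame_rate: float,
    side: str | None = None,
) -> SegmentationScore:
    """Score a predicted foot segmentation against annotated events."""
    side = side or pred.side
    ev = gt.foot(side)
    if len(ev.heel_strikes) < 2:
        raise ValueError(f"no ground-truth strides for {side} foot")
    gt_spans = [(a, b - 1) for a, b in zip(ev.heel_strikes,
                                           ev.heel_strikes[1:])]
    pred_spans = list(pred.spans)

    pairs = pair_spans_by_overlap(pred_spans, gt_spans)
    overlaps = [s for _, _, s in pairs]
    overlaps += [0.0] * (len(gt_spans) - len(pairs))
    overlaps += [0.0] * (len(pred_spans) - len(pairs))
    aod = float(np.mean(overlaps)) if overlaps else 0.0

    lo, hi = ev.heel_strikes[0], ev.heel_strikes[-1] - 1
    from sklearn.metrics import rand_score
    rand = float(rand_score(_frame_labels(gt_spans, lo, hi),
                            _frame_labels(pred_spans, lo, hi)))

    hs_pairs = _pair_events(pred.heel_strike_frames, ev.heel_strikes)
    to_pairs = _pair_events(pred.toe_off_frames, ev.toe_offs)
    hs_err = [p - g for p, g in hs_pairs]
    to_err = [p - g for p, g in to_pairs]
    pooled = np.asarray(hs_err + to_err, dtype=float) / frame_rate
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return SegmentationScore(
        aod=aod,
        rand_index=rand,
        instant_error_sd=sd,
        per_stride_overlaps=overlaps,
        heel_strike_errors=[float(e) for e in hs_err],
        toe_off_errors=[float(e) for e in to_err],
    )


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    pearson: float
    ccc: float
    ccc_ci: tuple[float, float]
    icc_2k: float
    icc_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    pe: float                     # percentage error
    n: int


def concordance_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Lin's CCC: 2 rho sa sb / (sa^2 + sb^2 + (ma - mb)^2)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    cov = np.cov(a, b, ddof=1)[0, 1]
    return float(2 * cov / (va + vb + (a.mean() - b.mean()) ** 2))


def _ccc_fisher_ci(ccc: float, rho: float, a, b, alpha=0.05):
    """Fisher-z 95 % CI for the CCC (Lin's asymptotic variance)."""
    n = len(a)
    u = (np.mean(a) - np.mean(b)) / math.sqrt(
        np.std(a, ddof=1) * np.std(b, ddof=1))
    c2 = ccc ** 2
    r2 = rho ** 2
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (rho * (1 - c2) ** 2)
        - c2 ** 2 * u ** 4 / (2 * r2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(ccc)
    half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(max(var_z, 0.0))
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def agreement(a, b) -> AgreementReport:
    """Agreement between two per-subject measurement vectors.

    ``a`` is the criterion instrument, ``b`` the method under test;
    bias is ``mean(b - a)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise InsufficientDataError("need paired vectors of length >= 3")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("zero variance: correlation undefined")
    rho = float(stats.pearsonr(a, b).statistic)
    ccc = concordance_correlation(a, b)
    if abs(ccc) < 1.0 and abs(rho) < 1.0 and rho != 0:
        ccc_ci = _ccc_fisher_ci(ccc, rho, a, b)
    else:
        ccc_ci = (ccc, ccc)

    import pandas as pd
    import pingouin as pg
    n = a.size
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "value": np.concatenate([a, b]),
    })
    icc_table = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="value"
    ).set_index("Type")
    # absolute-agreement average-raters ICC; label differs across versions
    for label in ("ICC2k", "ICC(A,k)"):
        if label in icc_table.index:
            row = icc_table.loc[label]
            break
    else:
        raise RuntimeError("ICC(2,k) row not found in pingouin output")
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in row.index else "CI95"
    icc_ci = (float(row[ci_col][0]), float(row[ci_col][1]))

    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pe = 100.0 * 4.0 * sd / (float(a.mean()) + float(b.mean()))
    return AgreementReport(
        pearson=rho,
        ccc=ccc,
        ccc_ci=ccc_ci,
        icc_2k=icc,
        icc_ci=icc_ci,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pe=pe,
        n=n,
    )


def repeatability(pairs) -> tuple[float, float]:
    """Repeatability from per-subject (trial1, trial2) value pairs.

    Returns ``(2 x SD of within-subject differences, the same as a
    percentage of the grand mean)``.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3 or pairs.shape[1] != 2:
        raise InsufficientDataError("need >= 3 (trial1, trial2) pairs")
    diff = pairs[:, 1] - pairs[:, 0]
    absolute = 2.0 * float(diff.std(ddof=1))
    grand = float(pairs.mean())
    return absolute, 100.0 * absolute / grand


def jitter_cv(
    mean_period_ms: float,
    sd_period_ms: float,
    samples_per_stride: float,
    n_trials: int,
    strides_per_trial: int,
) -> float:
    """Coefficient of variation (%) of the mean stride time under
    i.i.d. Gaussian sampling-period jitter.

    A stride sampled q times has time mean q*mu and SD sqrt(q)*sigma;
    averaging over n_trials x strides_per_trial strides divides the SD
    by the square root of that count.
    """
    if (mean_period_ms <= 0 or samples_per_stride <= 0 or n_trials <= 0
            or strides_per_trial <= 0 or sd_period_ms < 0):
        raise ValueError("all arguments must be positive (sd may be 0)")
    sd = math.sqrt(samples_per_stride) * sd_period_ms \
        / math.sqrt(n_trials * strides_per_trial)
    return 100.0 * sd / (samples_per_stride * mean_period_ms)


# ---------------------------------------------------------------------------
# leave-one-subject-out harness
# ---------------------------------------------------------------------------

@dataclass
class LosoResult:
    per_subject: dict[str, list[SegmentationScore]]
    pooled_aod: float
    pooled_rand: float
    pooled_error_sd: float                  # s
    heel_strike_mae: float                  # frames
    gamma_used: dict[str, float]


def loso_evaluate(
    cohort: list[tuple[str, list[tuple[TrialWalk, StrideAnnotation]]]],
    gamma: float | None = None,
    gamma_factor: float = 2.5,
    tau: int = 3,
) -> LosoResult:
    """Leave-one-subject-out segmentation evaluation.

    ``cohort`` maps subject ids to (sensor-frame walk, annotation)
    trials.  For each held-out subject, templates are learned from all
    other subjects' annotated walks (converted to the canonical frame),
    gamma is calibrated on those training walks unless given, and the
    held-out trials are segmented and scored per side.
    """
    if len(cohort) < 2:
        raise InsufficientDataError("leave-one-subject-out needs >= 2 subjects")
    canonical_cache = {}
    for sid, trials in cohort:
        for k, (walk, ann) in enumerate(trials):
            canonical_cache[(sid, k)], _ = to_canonical(walk, tau=tau)

    per_subject: dict[str, list[SegmentationScore]] = {}
    gamma_used: dict[str, float] = {}
    all_errs: list[float] = []
    hs_errs: list[float] = []
    aods: list[float] = []
    rands: list[float] = []
    for held_idx, (sid, trials) in enumerate(cohort):
        training = [
            (canonical_cache[(osid, k)], ann)
            for osid, otrials in cohort if osid != sid
            for k, (_, ann) in enumerate(otrials)
        ]
        bank = learn_template_bank(training)
        g = gamma if gamma is not None else calibrate_gamma(
            bank, training, factor=gamma_factor
        )
        gamma_used[sid] = g
        scores: list[SegmentationScore] = []
        for walk, ann in trials:
            segs = segment_trial_walk(walk, bank, gamma=g, tau=tau)
            for side in ("left", "right"):
                score = segmentation_score(segs[side], ann, walk.frame_rate,
                                           side=side)
                scores.append(score)
                aods.append(score.aod)
                rands.append(score.rand_index)
                all_errs.extend(
                    (np.asarray(score.heel_strike_errors
                                + score.toe_off_errors) / walk.frame_rate)
                )
                hs_errs.extend(abs(e) for e in score.heel_strike_errors)
        per_subject[sid] = scores
    errs = np.asarray(all_errs, dtype=float)
    return LosoResult(
        per_subject=per_subject,
        pooled_aod=float(np.mean(aods)),
        pooled_rand=float(np.mean(rands)),
        pooled_error_sd=float(errs.std(ddof=1)) if errs.size > 1 else 0.0,
        heel_strike_mae=float(np.mean(hs_errs)) if hs_errs else math.nan,
        gamma_used=gamma_used,
    )
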