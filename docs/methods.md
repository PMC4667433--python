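# Methods

## Data model

A *trial walk* is a sequence `x_1..x_n` of skeleton vectors: 3D
positions (meters) of 20 joints tracked by a Kinect-style sensor at a
nominal 30 Hz. Indices are 0-based everywhere in files and APIs;
match spans are inclusive. The matching stages use only the leg
joints plus the hip center (9 joints, d = 27 coordinates): arm and
trunk tracking adds variance without carrying stride-phase
information.

## Canonical reference frame

All modeling happens in a subject-attached frame so that the sensor
can stand anywhere:

* **u1 (vertical, constant per walk)** — second principal component
  (SVD) of the mean-removed cloud of all joints over all frames.  The
  first component is the progression direction (the cloud stretches
  ~3 m along the walk); the second is vertical because a standing
  body is taller than it is wide.  Hands, wrists and elbows are
  excluded (robustness to arm swings); the sign is set so the head's
  mean coordinate exceeds the ankles' (the source material leaves the
  orientation rule open; anatomy decides it here).
* **u2_t (progression, per frame)** — first principal direction of
  the skeleton-center points (mean of hip-center and both hip joints)
  in a window of ±τ frames (τ = 3 by default), projected onto the
  plane ⊥ u1, normalized, and oriented along the window displacement.
  Windows are truncated at the walk ends, preserving length n.
* **u3_t = u1 × u2_t.**

A joint y becomes `x = U_tᵀ y − [u1·y_0,t ; u2_t·y_c,t ; u3_t·y_c,t]`
with `y_0,t` the lowest joint (per-frame ground contact, argmin of the
u1-coordinate over all 20 joints) and `y_c,t` the skeleton center.
Vertical coordinates are heights above ground; horizontal coordinates
are body-centered.  On noiseless data the mapping is invariant to any
rigid placement of the sensor to ~1e-15 m (tested to 1e-6).  Strongly
curved walking paths are out of scope: the frame assumes a roughly
straight trajectory.

## Stride templates

A stride template of length m is `(μ_1, Λ_1)..(μ_m, Λ_m)` — per-instant
mean and covariance of the matching coordinates over training strides,
plus a toe-off index. Training strides are the annotated half-open
intervals [heel strike, next same-foot heel strike), spline-resampled
(natural cubic, endpoints exact) to each m in the scale set
M = {m̄ − 2σ … m̄ + 2σ} of rounded mean/SD of the pooled stride lengths
(≈95 % Gaussian coverage; sample SD; half-up rounding so e.g.
σ = 3.536 → 4). Right and left banks are learned separately; on
symmetric gait the left template is essentially the right one
circularly shifted by the step time.

**Covariance regularization.** With tens of strides in d = 27 the
sample covariances are ill-conditioned or singular, so
`Λ ← (1−λ)·Λ̂ + λ·(tr Λ̂/d)·I` with λ = 0.1, plus an absolute
eigenvalue floor of 1e-6 m² (≈1 mm SD). This guarantees positive
definiteness for any training size ≥ 2 while keeping the Mahalanobis
geometry of the well-measured directions.

## Matching

Frame cost against template instant i is the squared Mahalanobis
distance `d_i(x) = (x−μ_i)ᵀ Λ_i⁻¹ (x−μ_i)` (via cached Cholesky
factors; exact to 1e-9 against a direct solve). On top of it:

* fixed-scale matching (Euclidean `D_E` / maximum-likelihood `D_L`);
* uniform scaling `US_L = min_m D_L/m` — the 1/m factor makes every
  scale a priori equally likely;
* non-uniform scaling `DTW_L`: dynamic time warping with the standard
  step set {(1,0),(0,1),(1,1)}, both ends anchored;
* joint search `SWM_L = min_m min_span DTW_L/m`, implemented literally
  as a fresh DTW table per (start, end) pair — the cubic brute-force
  oracle, kept as the correctness reference;
* subsequence DTW `SDTW_L`: one accumulated-cost matrix D_S with a
  free start (row 0 costs nothing to enter), best ending
  `t_e = argmin_t D_S(t, m)`, start recovered by traceback — O(n·m);
* `SSWM_L = min_m SDTW_L/m` — the production matcher, O(n·m·|M|).

Tie-breaking is fixed for determinism: smallest m, then earliest span;
the traceback prefers the diagonal step, then the template-consuming
step. Every DP counts its cell updates, so the complexity gap
(≈2× vs ≈8× work when n doubles) is measurable, mirroring the ~10³
speedup the efficient matcher delivers at realistic n. On randomly
drawn instances the efficient matcher reproduces the oracle's
(distance, span, scale) exactly; with continuous-valued data ties have
probability zero, so the fixed tie order never actually diverges.

## Segmentation

Per foot: SSWM gives the best stride, its scale m\* and D_S. Further
stride endings are local minima of `D_S(·, m*)` (strictly minimal
within ±⌊s/4⌋) with normalized cost below γ, accepted while expanding
alternately to earlier and later times with stride-like spacing
(between 2s/3 and 4s/3 of the boundary ending). The count N of
accepted endings is the stride count. A template of N concatenated
copies is then re-matched with subsequence DTW; template indices
k·m\* map through the warping path to heel strikes (run midpoints,
rounded down), toe-off indices likewise, and the final ending closes
the last stride — consecutive strides tile the walk exactly. Heel
centers are the ankle positions at heel strikes projected onto the
ground plane and expressed in sensor coordinates.

Two deliberate departures from the obvious implementation:

* **Spacing proxy s.** The ending-spacing rules use the *observed
  span length* of the initial best match rather than m\*. Under
  shrinkage regularization the 1/m normalization is mildly biased
  toward larger scales (a finer template lets each frame match a
  closer phase), so m\* can overshoot the true stride duration by
  ~30 %; the matched span measures it directly. When m\* is unbiased
  the two coincide.
* **Calibrated γ.** The classical choice γ = 1 presupposes a
  particular covariance conditioning: for data drawn from the model
  itself the expected per-frame Mahalanobis cost is ≈ d = 27, so a
  fixed unit threshold is meaningless under shrinkage. γ is instead
  calibrated on the (annotated) template-training walks: 2.5 × the
  largest normalized D_S cost found within ±3 frames of a known
  stride ending, floored at 1e-6 for the fully deterministic regime.
  Genuine endings on held-out subjects stay within ~1.7× of the
  training maximum while spurious minima (partial strides, non-gait
  data) sit ≥4× higher, so the factor separates the two. γ = 1
  remains the documented default of `segment_trial_walk` for callers
  who manage their own scale.

## Gait parameters

Nine parameters, averaged over the available cycles k (reported per
parameter, since e.g. one fewer swing than strides may be usable):
step times S^l/S^r (opposite-foot heel strike to next own heel
strike; feet paired by temporal adjacency after merging the event
streams, unpaired boundary events dropped), stride times R, cadence
C = 60/R^r + 60/R^l, swing time W (toe-off to next own heel strike;
reported per foot and as the across-feet mean), stride lengths L
(consecutive same-foot heel-center distances), step lengths D (scalar
projection onto the line of progression joining the flanking
opposite-foot heel centers), velocity V = (L^r+L^l)/(R^r+R^l).
Internally meters and seconds; centimeters exactly (×100) at the
reporting boundary. Missing inputs yield NaN, never zero. Subject
aggregation is the cycle-count-weighted mean across trials.

## Evaluation

* **AoD** — strides paired one-to-one greedily by overlap percentage
  (inclusive-span intersection over union); unmatched strides on
  either side score 0; AoD is the mean.
* **Rand index** — frames of the annotated span labeled by stride id
  (or background), compared as clusterings by pair counting
  (scikit-learn's `rand_score`).
* **Instant error SD** — sample SD of matched event-time errors in
  seconds, pooled over heel strikes and toe-offs (per-type lists also
  reported); a constant offset gives SD 0.
* **Agreement** — Pearson ρ (scipy); Lin's CCC
  `2ρσ_aσ_b/(σ_a²+σ_b²+(μ_a−μ_b)²)` with a Fisher-z 95 % CI (Lin's
  asymptotic variance); ICC(2,k), absolute agreement, with F-based CI
  (pingouin); Bland–Altman bias ± 1.96 SD; percentage error
  100·4 SD/(mean_a+mean_b). Repeatability is 2 SD of within-subject
  trial differences, absolute and as % of the grand mean. All SDs are
  sample (n−1).
* **Jitter CV** — closed-form propagation of i.i.d. Gaussian
  sampling-period jitter into the averaged stride time:
  CV = 100·(√q·σ/√(trials·strides))/(q·μ) for q samples per stride;
  0.65 % at the published sensor figures (33.4 ± 3.7 ms, q = 24,
  3 × 4 strides), verified against Monte-Carlo simulation.
* **LOSO harness** — templates learned from all subjects but one
  (γ calibrated on the same training walks), held-out trials
  segmented and scored, results pooled.

## Synthetic gait generator

The generator emulates the statistical structure the method assumes,
not anatomy. Default conditions: 3 trials × 4 strides per subject at
30 Hz; stride period 0.8 ± 0.08 s and stride length 0.72 ± 0.07 m
across subjects (a 2–4-year-old's scale, ~25 frames per stride);
per-stride timing jitter 5 % CV; stance fraction 0.6; joint noise SD
0.01 m; a random rigid sensor placement.

Kinematics: footfalls form one alternating step sequence (per-step
multiplicative jitter, step CV = √2 × stride CV) — coupling the feet
keeps their relative phase bounded, as real gait does. Each foot
alternates stance (ankle anchored at a fixed ground point) and swing
(C¹ sinusoidal-lift profile with zero velocity at both boundaries);
heel strike is the first stance instant, toe-off the last. The hip
center tracks the mean of the feet's piecewise-linear anchor
progressions (so timing jitter cannot make the trunk drift away from
the legs), with bob and sway phase-locked to the footfalls.
Upper-body joints ride at fixed offsets. Events are recorded both
exactly (sub-frame seconds) and rounded to frames; ground-truth heel
centers are the stance anchors; ground-truth parameters are computed
from the quantized events by the same parameter module the pipeline
uses, so truth and prediction share one definition.

**The ideal condition.** "Noise-free" checks use joint noise 0,
timing jitter 0, *and* stride periods snapped to the frame grid
(`snap_period_to_frames`). Off the grid, true events fall on
half-frame rounding ties and the ground-truth quantization itself
becomes inconsistent at the ±1-frame level — a sampling artifact
(temporal resolution is the known accuracy floor of 30 Hz tracking,
hitting swing time hardest), not a pipeline property. In the ideal
condition the pipeline recovers all nine parameters exactly;
at 0.01 m noise the mean stride-time error is ≈0.01 s (≪ 2 frames)
and the mean stride-length error ≈0.4 %.

What passing synthetic tests does *not* show: robustness to real
tracker failure modes (joint swaps, occlusion dropouts, distance- and
pose-dependent noise), to gait asymmetries or pathologies, or to
curved walking paths. The generator's noise is i.i.d. Gaussian and
its gait is symmetric by construction.

## Numerical choices

Half-up rounding wherever the math says "rounded" (deterministic,
matches the worked examples; banker's rounding would make σ = 2.5
round down). Degenerate inputs raise typed errors: collinear joint
clouds and stationary windows (frame estimation), fewer than two
strides (learning), zero-variance vectors (correlation). Warping-path
invariants (boundary, monotonicity, step set, length bounds) are
validated in tests on every recovered path. The D_S matrices are kept
in memory (n·m ≤ ~10⁴ at this scale) because the endings search and
debugging exports need them.

## Known limitations

Template banks are learned from the whole cohort; no stratification
by age or leg length. Segmentation is whole-trial batch, not
streaming. The scale-selection bias under shrinkage (see above) is
compensated rather than removed; with large training cohorts and
well-conditioned covariances it shrinks. Step-length pairing assumes
alternating footfalls and drops cycles broken by missed strides
rather than interpolating them.
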