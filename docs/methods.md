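# Methods

This note documents the models, conventions and numerical choices behind
`padrom`, in the order the pipeline runs.

## Orientation model and joint angles

Segment orientations are unit quaternions, scalar-first `(w, x, y, z)`,
Hamilton convention, canonical sign `w >= 0`. The source never states a
storage convention, so this one is fixed package-wide. The joint rotation is
`q_joint = q_proximal^-1 ⊗ q_distal`, i.e. the rotation carrying the
proximal segment frame onto the distal one; both operands must live in the
same global frame, which cannot be verified from the data and is therefore a
documented contract. The operand naming follows the equation's conventional
reading (the inverse on the proximal side) even though the surrounding prose
can be read as labelling the operands the other way; the choice is fixed
here rather than configurable so results cannot silently flip.

Joint angles come from the intrinsic Y–X′–Z″ factorisation
`R = Ry(θy) · Rx(θx) · Rz(θz)`, in degrees, with the channel-to-plane map
(one configurable table, not per-joint code): Y = flexion/extension,
X = adduction(+)/abduction(−), Z = internal(+)/external(−) rotation at the
shoulder and pronation(+)/supination(−) at the forearm. Ranges are
`θy, θz ∈ (−180, 180]`, `θx ∈ [−90, 90]`. At the gimbal singularity
(`|θx|` within 0.01° of 90°) the Y–Z coupling is folded entirely into θy and
θz is set to zero; affected samples can be flagged.

**Mid-axis reflection unwrap.** A physical rotation about the X axis beyond
±90° (shoulder abduction reaches ~170°) decomposes as a reflected θx with
both outer channels jumping to 180°. Before static-ROM extraction on an X
channel the package restores the anatomical angle via
`θx → sign(θx)·180 − θx` on frames where `|θy| > 90` and `|θz| > 90`. This
is exact for the single-axis movements the static tasks prescribe and is not
applied to dynamic channels, whose X excursions stay well below 90°.

## Filtering

A 4th-order Butterworth low-pass at 6 Hz is applied to the four quaternion
components independently, then the quaternions are renormalised — the filter
acts on the orientation data, not on derived angles. Filtering is zero-phase
(forward–backward `filtfilt`), the biomechanics norm; the effective
attenuation order is therefore 8 and the DC gain exactly 1. Antipodal sign
flips (q vs −q) are removed before filtering. Preconditions: cutoff below
Nyquist, at least `3 × order` samples.

## ROM extraction

* **Static ROM** = |extremum in the task's movement direction − initial
  anatomical angle|, the latter being the mean over the first 0.25 s
  (24 frames at 96 Hz; configurable — the source does not define the
  baseline window). Left and right sides are averaged; a missing side
  propagates the present one with a logged warning. ROM is reported as
  non-negative degrees; direction lives in the task definition, not the
  sign.
* **Shot events.** SR = frame of peak hand angular speed (the faster hand is
  taken as the lead); SI = first frame after the last pre-release dip below
  10 % of that peak; ST (slap shot) = extremal backswing of the lead-shoulder
  flexion channel between SI and SR. The thresholds are configurable; the
  original event criteria are cited but not restated by the source, so this
  detector is the package's own design, validated against the generator's
  ground truth. A trial whose peak hand speed stays below 30 °/s raises a
  "no shot detected" error naming the criterion.
* **Phase ROM** = max − min of the joint-angle channel within the closed
  event window (SI–SR for the wrist shot; SI–ST and ST–SR for the slap
  shot). The endpoint-difference alternative was rejected: the reported
  dynamic tables list plane-pair ROMs (e.g. flexion/extension) that only a
  windowed max − min can produce.
* **Handedness.** Right-handed shooters are mirrored before dynamic
  analysis: left/right segment labels swap and quaternions map
  `(w, x, y, z) → (w, −x, y, −z)`, preserving the sagittal (Y) channel and
  negating the lateral (X) and axial (Z) channels. The operation is an
  involution.
* **Averaging.** Repetitions are averaged into a typical trial per
  participant × condition; missing repetitions average over what is present,
  with a warning.

## Statistics

One-way repeated-measures ANOVA per joint plane across the six conditions:
`F = (SS_cond/(k−1)) / (SS_err/((n−1)(k−1)))` from the within-subject
decomposition, partial η² = `SS_cond/(SS_cond+SS_err)`, Greenhouse–Geisser
epsilon from the double-centred sample covariance,
`ε = tr(S*)²/((k−1)tr(S*²))`, clipped to `[1/(k−1), 1]`. The GG-corrected p
is reported unconditionally (no Mauchly gate), matching the named method.

**A calibration caveat, documented deliberately:** when sphericity truly
holds, the GG epsilon estimate is biased below 1 at this design size
(n = 9, k = 6), so the corrected test is conservative — its empirical
type-I error under a spherical Gaussian null is ≈ 0.02 at α = 0.05, while
the uncorrected F from the same decomposition is exactly calibrated
(≈ 0.05). Both rates are exposed (`p_value` vs `p_uncorrected`, and both
appear in the acceptance report). Power at the published shoulder-flexion
effect profile is ≈ 1.0.

LSD post-hoc = uncorrected pairwise paired t-tests, gated by a significant
omnibus test (the gate is the caller's α; setting α = 1 opens it
everywhere). An identical pair returns t = 0, p = 1 rather than 0/0.
Shapiro–Wilk delegates to the standard algorithm (scipy), with an explicit
error on constant samples.

Survey tests treat Likert scores as ordinal: Friedman across pads with
average-rank tie correction (a fully tied matrix returns statistic 0,
p = 1), Wilcoxon signed-rank pairwise with zero differences dropped and
average ranks for ties. Null distributions are exact where feasible: the
classical tie-free Wilcoxon distribution up to n = 25, full 2ⁿ sign
enumeration of the observed (possibly tied) ranks up to n = 14, normal
approximation beyond; Spearman p is an exact n! permutation for n ≤ 8 and a
t approximation above. Effect-size bands: η² at 0.01/0.06/0.14
(below-small/small/medium/large), |r| at 0.1/0.3/0.5
(negligible/low/moderate/high).

"Comfort level" for the comfort–ROM correlation is the mean Q1 score pooled
over shoulder and elbow protectors (optionally pooling reverse-coded Q3);
"total ROM" sums condition-mean ROM over the nine static tasks plus the
significant dynamic planes. Both aggregations are stated choices — the
source does not specify the ones behind its reported coefficients, which is
why those coefficients are reproduced structurally, not numerically.

## Synthetic data generator

The generator defines the study conditions: 9 participants (7 left-, 2
right-handed), 11 tasks, 6 conditions, 5 repetitions, 96 Hz. Defaults:

| parameter | default | meaning |
|---|---|---|
| restriction factors f | published pad/control ratios, clipped to (0, 1] | per condition × task/plane ROM scaling; f(no pads) = 1 exactly |
| orientation noise SD | 0.5° | white Gaussian per relative-joint Euler channel, added before quaternion conversion |
| participant ROM SD | 8° at a 160° movement | multiplicative between-participant mobility (constant CV, so small planes scale down) |
| repetition ROM SD | 3° at a 160° movement | trial-to-trial execution variability, same CV scaling |
| comfort coupling | 0.9 | latent-variable correlation between survey scores and injected restriction |

Static trials hold a zero baseline for 0.5 s, rise along a minimum-jerk
profile for 1.2 s to `participant ROM × f`, and hold 0.5 s — the hold
guarantees the filtered peak equals the designed peak. Shot trials place
piecewise-linear excursions on every analysed joint plane: wrist-shot planes
rise by the phase ROM inside SI–SR; slap-shot planes rise by the SI–ST ROM
to a kinked maximum at ST and fall by the ST–SR ROM, so each window's
max − min equals the design exactly and the kink keeps the swing-top
detectable under noise. The lead wrist carries an angular-speed profile with
a steep onset ramp at SI, a floor above the SI threshold through the
backswing, and its global peak at SR. Ground-truth events are obtained by
applying the event definitions to the noise-free motion after the standard
6 Hz smoothing (events are features of the smoothed movement); the designed
template frames are stored alongside. Survey scores discretise a latent
normal `c·(−z) + sqrt(1−c²)·ε` (sign flipped for Q3, pure noise for Q2),
where z is the standardised per-protector restriction; scores are clipped
to 1–5, so ordering among pads with nearly equal restriction can tie after
rounding.

Per-trial counter-based substreams derive from one global seed, making every
trial independently reproducible and the full study byte-deterministic.
Composition runs through `scipy.spatial.transform.Rotation`, a route
independent of the analysis code's own quaternion algebra.

What the generator does **not** emulate: soft-tissue artefact, sensor
drift, cross-talk between anatomical planes, fatigue or learning across
repetitions, and any pad-specific movement *strategy* changes — it restricts
amplitude, not coordination. Passing tests therefore demonstrate that the
pipeline recovers what was injected under realistic noise, not that the
published numbers would be reproduced from the original recordings.

## Problem sizes and tolerances

Calibration uses 2000 null simulations (9 × 6) and 500 power simulations.
Parameter recovery runs 20 seeds of a 9-participant, 2-repetition static
study (the tighter repetition budget is conservative: less averaging than
the full design) and 20 survey seeds for the comfort coupling. Euler
round-trips are exact to 1e−6°; sums-of-squares match brute-force oracles to
1e−8; enumerated p-values match exactly. Quaternion unit norm is enforced to
1e−9 after every operation.

## Known limitations

* Reference-frame consistency between proximal and distal segments cannot be
  validated from the data.
* The YXZ sequence is fixed; joints better served by other sequences (e.g.
  Y–X–Y for humeral elevation) are still decomposed as YXZ, relying on the
  mid-axis unwrap for large abductions.
* The GG-corrected test is conservative under true sphericity at this design
  size (see above).
* BVH support covers rotation channels and hierarchy composition only
  (positions ignored, Y-up right-handed files assumed).
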