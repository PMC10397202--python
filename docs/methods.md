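# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `podscape`, and what the synthetic generator does
and does not emulate.

## Data model

The kinematic input is a skeleton trajectory: T × 16 × 3 coordinates in mm
at a fixed frame rate (default 30 frames/s), over a canonical keypoint
order (nose, ears, neck, limbs, claws, back, tail segments). Validation
rejects non-finite coordinates rather than imputing them: gap-filling of
dropped tracking is an upstream concern and any policy chosen here would
silently shape the speed features. Movement labels are per-frame integers
over a 40-class vocabulary, interconvertible with a 1-based inclusive
segment table; both file forms are plain CSV.

The animal's planar position is the **back** keypoint throughout (centre
time, arena containment). It is the most stable torso point; the nose is
used only where the measure is explicitly about the snout (investigation
geometry), and the neck only to define the facing direction.

## Pose features

Thirteen per-frame features with units:

| feature | definition | units |
|---|---|---|
| length | 3-D nose ↔ tail-root distance | mm |
| neck_height, back_height | z of the named keypoint | mm |
| front_width, hind_width | 3-D left ↔ right fore/hind-limb distance | mm |
| back/nose/claw speeds | per-frame 3-D displacement of the keypoint | mm/frame |
| body_speed | per-frame 3-D displacement of the 16-keypoint centroid | mm/frame |
| acceleration | first difference of back speed | mm/frame² |
| angular_velocity | frame-to-frame deflection of the tail-root→neck axis | rad/frame |
| spine_angle | angle at the back between back→neck and back→tail-root | rad |

Two deliberate design choices sit here. First, the torso "height" is split
into two features (neck and back), and the centroid speed completes the
13-feature default; an 11-feature reduced configuration (single height, no
centroid speed) is provided because both 91- and 77-dimensional summaries
are legitimate configurations of the same machinery, and the feature list
is a plain argument everywhere. Second, speeds are reported in mm/frame
(the native sampling units); a frame-rate-aware mm/s view exists for
reporting only, so that changing the nominal frame rate can never silently
change a statistic.

Distance, speed and angle features are invariant to rotation about the
vertical axis and to translation; heights are invariant to horizontal
translation only. The test suite asserts both.

## PMF summaries ("eigenvalues")

Each feature series is histogrammed into 50 uniform bins spanning its
observed [min, max]; probabilities are counts/total. A constant series is
given a widened unit range so exactly one bin carries probability 1 —
degenerate sessions summarize cleanly instead of erroring.

Seven descriptor statistics are taken per curve, in fixed order: mean,
median, SD, 25% quantile, 75% quantile, min, max. The default treats the
50 probabilities themselves as a discrete signal (`on="probabilities"`);
the alternative (`on="values"`) describes the underlying distribution via
probability-weighted bin centres. The two modes answer different
questions. Probability-signal statistics capture the *shape* of a
distribution and are invariant to shifts and rescalings of the feature
(each animal's PMF spans its own range); value-level statistics capture
location and scale. Subtype clustering therefore uses `on="values"`
(`eigenvalue_matrix` defaults to it): hyperactive and hypoactive animals
differ precisely in how fast and how high, which shape-only descriptors
cannot see, and with shape-only summaries the subtype recovery simulations
sit at chance.

## Resampling Kolmogorov–Smirnov test

Group-level PMF curves are compared by drawing n = 500 values from each
curve's implied distribution (inverse-CDF with uniform placement within a
bin) and scanning the pooled sorted sample for
D = max |F₀(x) − G₀(x)|. The rejection rule is selectable:

* `exact` (default): the two-sample p-value at the actual sample sizes
  (scipy), rejected below α = 0.05. Measured null rejection rate over
  1,000 independent-draw repetitions: within [0.03, 0.07].
* `asymptotic`: the closed form c(α)·√((n₁+n₂)/(n₁n₂)).
* `pooled-table`: a one-sample table lookup at the pooled size 2n — a
  compatibility mode; it is anticonservative for two-sample use and not
  recommended.

Seeding is per draw: the draw from the second curve defaults to the same
seed as the first (common random numbers, so identical curves give D = 0
exactly), and null calibration passes an independent second seed.

## Investigation geometry and the DSP

Thresholds (all configurable, defaults in mm): approach distance 60, climb
distance 30, orientation cone half-angle π/2 (the literal acute-angle
test). Distances are measured to the object centre; the footprint radius
is available for a surface-distance correction. Investigating runs
separated by fewer than 5 frames (~167 ms at 30 frames/s) merge into one
bout, preventing detector flicker from inflating bout counts; the gap is
configurable. A bout is deep when climb-triggered or when it carries a
label from the deep-interaction classes — by default {6, 20, 35}, the
vocabulary entries annotated as climbing, stretched-attend/touch and
sniffing; the set is a config entry because vocabulary annotations are a
property of the upstream segmentation, not of this package.

DSP = arcsin((T_deep − T_shallow)/(T_deep + T_shallow)), undefined (error)
when no investigation occurred rather than silently 0 — a session with no
object contact carries no preference information.

## Diagnosis

Fractions are z-scored per movement across all model + control samples
(zero-variance movements contribute 0), then cut into two clusters by Ward
linkage on Euclidean distance — standard clustergram defaults. The cluster
holding the larger share of control samples anchors "normal". A model
cluster is labelled POD only if it is also *depleted* of controls: its
within-cluster control share must fall below half the overall control
share (ratio configurable). Without the depletion condition, a two-cluster
cut of a homogeneous cohort necessarily splits it and would label roughly
half of an unaffected model group POD; with it, homogeneous model groups
stay non-POD (measured: ≥ 99% of model animals across 100 null
simulations) while a genuinely shifted subgroup forms a control-free
cluster and is labelled POD with ARI ≈ 1 at the generator's default effect
size.

## Embedding, boundary and projection

t-SNE to 3-D with perplexity = 6 (the "neighbourhood" parameter; exposed
as `neighbor_param`), PCA initialization, exact gradients, learning rate
10, early exaggeration 6, 2,000 iterations, seeded. The small fixed
learning rate matters: at the few-dozen-sample scale of these cohorts the
adaptive learning-rate heuristic takes steps large enough to shatter
well-separated clusters, and embeddings of 10-SD-separated blobs were not
reliably linearly separable until it was pinned down. Embedding requires
more samples than the perplexity and at least 3 input columns.

The decision boundary is a soft-margin linear SVM (C = 1) in the embedded
space. Projection values are signed Euclidean distances
(w·y + b)/‖w‖, sign-flipped if needed so the POD centroid is positive;
the raw unnormalized scores w·y + b are also reported since both
conventions are in circulation. For treated cohorts the boundary is fitted
once on the diagnosed POD/non-POD animals and new samples are projected
post hoc — they never refit the space.

## Subtype clustering

Eigenvalue columns are standardized, embedded with the same t-SNE
machinery, and split by k-means (k = 2, 10 restarts, seeded). Naming is a
function of the data, not the cluster indices: the cluster with the larger
mean of the speed features' "mean" descriptors is Hyper. Relabelling or
reordering samples therefore never flips the semantics.

## Classifier and incidence

Logistic regression; inverse-regularization C selected from 30 log-spaced
candidates in [1e-4, 1e4] by stratified 5-fold CV error (fold shuffling
seeded); the running minimum over candidates is the reported
minimum-classification-error curve. Ties in CV error resolve to the
smallest (most regularized) candidate. Incidence is 100 · n_POD / n_total
over the predicted labels.

## Synthetic generator

The generator defines the study conditions the tests run under.

* **Labels**: semi-Markov bouts — class entered with probability
  proportional to its target fraction, geometric bout length (mean 9
  frames ≈ 0.3 s), so empirical fractions converge to the profile.
  Sessions default to 18,000 frames (10 min at 30 frames/s). The
  delirium-like profile raises 8 designated classes to 0.040 and lowers 6
  to 0.010 against a uniform 0.025 baseline; at the default session length
  those ±0.015 shifts are ≥ 3 across-animal SDs, the intended
  detectable-effect regime. Control-like and non-POD-like profiles are
  uniform.
* **Kinematics**: heading-diffusion random walk with gamma step lengths
  (located at `speed_scale`), folded back into the arena inset by the body
  reach so all keypoints stay inside; a rigid body plan rotated by the
  heading, plus 1 mm isotropic keypoint noise. Hyper defaults: 4 mm/frame,
  32 mm torso height; Hypo: 2 mm/frame, 24 mm — a speed ratio of 2.
* **Investigation sessions**: scheduled bouts are realized exactly — the
  nose holds ~42 mm from the object facing it (approach) and deep bouts
  climb (nose ~18 mm, back above the object top) in their second half;
  between bouts the animal idles at a rest point chosen on a grid to keep
  the nose > 80 mm from every object. Transitions are instantaneous by
  construction; scheduled bouts must be ≥ 10 frames apart so detector
  merging cannot fuse them.

What the generator does **not** emulate: realistic gait or posture
dynamics, inter-animal variability beyond sampling noise (all animals of a
group share one profile), label–kinematics coupling (label streams and
skeletons are generated independently), arena-wall thigmotaxis, and
session-to-session drift. Passing recovery tests therefore demonstrates
that the pipeline's inference is correct when its assumptions hold, not
that real cohorts separate this cleanly; on real data the effect sizes,
not the machinery, are the question.

## Problem sizes

The simulation suites use cohorts of 20 animals per group at 18,000-frame
sessions for label-level analyses, 3,000-frame sessions for pose-level
analyses, and 50–100 seeded repetitions per property; these sizes give the
recovery statistics comfortable margins over their thresholds while
keeping the default test run in the minutes range.

## Known limitations

* The recognition index is implemented as the normalized difference
  (novel − familiar)/(novel + familiar); the novel-time share
  novel/(novel + familiar) is provided as `novel_time_ratio` since both
  definitions circulate.
* The composite Z score is the literal sum of the three standardized
  metrics; no sign convention is imposed on its components.
* Welch's t per movement with Sidak adjustment reproduces per-movement
  post-hoc contrasts; a full two-factor omnibus analysis is out of scope
  because it adds nothing to movement selection.
* `diagnose_pod` accepts a seed for interface uniformity, but the Ward cut
  is deterministic.
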