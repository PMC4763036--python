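# Methods

## The task and its geometry

A point-to-origin trial carries the observer along a two-segment outbound
path: a straight approach, one yaw turn of signed angle θ (positive =
rightward), and a second straight segment. The observer then reports the
egocentric quadrant containing the origin. All geometry lives in a
bird's-eye right-handed frame: the start pose faces +z, +x points right,
headings are degrees clockwise from +z, bearings are normalised to
(−180°, 180°].

The default kinematics are a 1 s linear acceleration at 10 m/s² to a
10 m/s cruise, 2 s of cruise, the turn, 3 s of cruise and 1 s of linear
deceleration; with θ = 0 the endpoint is exactly 60 m ahead
(5 + 20 + 0 + 30 + 5 m). The turn uses a triangular angular-velocity
profile — constant angular acceleration α = 15 deg/s² for half the turn,
constant deceleration for the other half — so its duration is
T = 2·√(|θ|/α): exactly 4 s for 60°, 4.899 s for 90°. The default trial
plan is 60° left, 90° right, 90° right, 60° left.

Design choices where the kinematics are underdetermined:

* **Translation during the turn** is at constant cruise speed along the
  instantaneous heading (continuity with both straight phases). The
  resulting turn phase is a clothoid pair, evaluated in closed form with
  Fresnel integrals; `simulate_trajectory` cross-checks it on a fixed time
  grid (default dt = 1 ms, trapezoid-integrated positions, analytic speed
  and heading at every sample).
* **Quadrant boundaries**: a predicted bearing on {0°, ±90°, 180°} raises
  a degenerate-geometry error rather than tie-breaking. The experimental
  angles never produce boundary bearings; for |θ| < 135° with the default
  kinematics all four strategies land strictly inside distinct quadrants.

Strategy predictions, per trial: a *turner* reports the homing bearing in
the frame of the final heading; a *non-turner* in the never-rotated
initial frame; a *non-mover* points along the outbound displacement (as if
indicating origin → endpoint); a *spinner* answers in the final frame
rotated by 180°. For a left 60° turn these give back-left, back-right,
front-left, front-right respectively, and the map mirrors left/right under
θ → −θ. Because the map is a bijection per turn direction, each answer
inverts to exactly one per-trial strategy label.

## Classification

A participant is classified as a user of the strategy whose label appears
in at least ⌈0.75 · n_trials⌉ trials — 3 of 4 — and otherwise carries *no
preference*. With other trial counts, two labels reaching the threshold
resolve conservatively to no preference. Preprocessing removes rows with
missing gender, ethnicity or answers first, classifies the survivors, and
then removes spinner-classified participants (too sparse to model);
surviving rows keep their order and the operation is idempotent. Ethnicity
is pooled to Caucasian / Chinese / Other.

## The classification model

The analysis outcome is the four-level classification (baseline: no
preference) regressed on ethnicity (reference Caucasian), response mode
(reference pictorial) and gender (reference female) with all interactions,
12 dummy-coded terms per non-baseline outcome under the softmax link

    p_k(x) = exp(x·β_k) / Σ_j exp(x·β_j),   β_no-preference ≡ 0.

Fitting is maximum likelihood (statsmodels, Newton iterations from a zero
start, convergence tolerance 1e-10, max 200 iterations), so estimates are
deterministic given the data. When Newton fails or returns non-finite
estimates — which happens under complete or quasi-separation — the fit
falls back to L-BFGS, which keeps estimates finite and the predicted
classes correct. Fitted standard errors above 10 trigger a
quasi-separation warning rather than penalised refitting; the published
coefficient table itself contains such artifact rows (±12-scale estimates
with implausibly small SEs).

Likelihood-ratio term tests refit the model with one term's columns
removed while all other terms — including interactions containing the
tested factor — stay in the model (`scheme="drop-one"`, the default; a
`"hierarchical"` scheme that also removes containing interactions is
provided because the convention behind a term-per-row ANOVA table is
genuinely ambiguous). Degrees of freedom per row are (columns removed) ×
(non-baseline outcome contrasts): 6/3/3 for the main effects, 6/6/3 for
the two-ways, 6 for the three-way. Training accuracy is the share of
participants whose highest fitted probability matches their observed
classification. The binary variant restricts to turner/non-turner rows
and fits the same design as a logit on turner.

## Odds ratios

For a factor contrast c = x(level a) − x(level b) at a fixed profile of
the remaining factors, OR = exp(c·β_target − c·β_baseline); for the
no-preference baseline outcome the second term is zero. Enumerating all
dummy-coding reference-level combinations ("baseline rotation", 3 × 2 × 2
= 12) only re-parametrises the model, so the OR engine computes every
pairwise contrast directly from one coefficient matrix; a test confirms
rotation invariance by refitting under relabelled levels.

Wald intervals are built on the log scale. With a fitted model the
delta-method variance uses the full coefficient covariance. In
printed-coefficient mode (a typed-in published table with per-coefficient
SEs only) the variance falls back to the sum of squared weighted SEs and
is flagged approximate — ignoring the (typically positive) coefficient
covariances makes these intervals conservative, wide enough that
significance decisions should not be read off them. Reporting keeps ORs
whose interval excludes 1, drops values outside [0.001, 100] as
sparse-data artifacts, and shows only the >1 orientation of each mirror
pair (the mirrored record has the reciprocal value). Recomputing the
published worked examples from the printed table reproduces them to their
printed precision; two contrasts (printed 9.58 and 3.93) disagree by ≲1%
because the published coefficients are themselves rounded.

## Bootstrap null accuracy

Observed classifications are held fixed; each of B replicates (default
10,000) assigns every participant a random label — uniform over the four
analysis classes (naive) or drawn from the observed class frequencies
(weighted) — and scores agreement. Naive accuracy converges on 1/4, the
four-class chance level; weighted accuracy on Σ p². The 2.5th–97.5th
percentile band is the null interval; a model accuracy strictly above the
upper bound counts as beating chance (bounds count as within). Percentile
rather than BCa intervals: the construction being emulated is a plain
percentile one. The published naive interval (23.5–28.7%) is narrower
than the analytic four-class uniform band at n = 498 (≈21.2–28.8%) and its
exact construction is underdetermined, so it is not asserted; the weighted
band is checked as a consistency property (Σ p² ≈ 31.3% for the observed
class shares falls inside the published 29.7–35%).

## Synthetic cohorts: what they emulate and what they do not

`GeneratorConfig` defaults encode the published study conditions: 12
covariate cells (ethnicity × gender × response mode) with fixed sizes
summing to 501 participants, latent classifications drawn from the softmax
model with the published coefficients capped at |β| ≤ 5, a per-trial lapse
probability of 0.05, and the four-trial turn plan. Cell sizes are
deterministic, so cohorts are exactly sized and cell-level demographics
carry no sampling noise. Capping replaces the ±12-scale separation
artifacts; uncapped values would empty cells at any realistic n. The
default lapse rate is a modest attention-slip level chosen once — the
source reports no lapse model — and the lapse is uniform over the three
non-target quadrants as the simplest exchangeable noise.

Strategy-class participants emit their strategy's predicted quadrant per
trial, lapses aside. No-preference participants emit a forced 2–2 split
over two distinct randomly chosen strategies, which guarantees the 75%
criterion fails; the class is defined only negatively, so any generative
story is a package choice. Consequences worth knowing:

* at lapse 0 the classifier recovers every latent class exactly;
* at lapse 0.05 a strategy participant is misclassified only when ≥ 2 of
  4 answers lapse appropriately (probability ≈ 0.014, checked against
  exact enumeration of the 4⁴ answer patterns);
* the generator does not model trial-order learning (the drift toward
  turner answers in real no-preference participants), answer-sheet
  randomisation effects, or within-cell demographic correlation. Passing
  tests therefore validate the analysis machinery, not behavioural realism.

A 507-row fixture variant appends six incomplete rows and forces exactly
three spinner-consistent participants so preprocessing reproduces the
published flow 507 → −6 missing → −3 spinners → 498 analysed.

## Calibration checks and their problem sizes

Two simulation checks guard the estimation machinery, sized to run in a
few minutes on one CPU:

* **Recovery**: 100 cohorts at 50× the default cell sizes (n = 25,050)
  are refit on the latent classification; the generating coefficients lie
  inside the joint 95% Wald region (quadratic form against χ²₀.₉₅,₃₆) in
  94 of 100 seeds. Refitting on the latent class rather than the observed
  classification isolates parameter recovery from the lapse process,
  whose misclassification bias is bounded and tested separately. Joint
  Wald regions are mildly anti-conservative here because one non-mover
  cell has expected count ≈ 0.5 even at 50× sizes.
* **Type-I error**: in 1,000 default-size cohorts with gender permuted
  (hence independent of outcome), the LR test for gender rejects at the
  5% level in 5.2% of replicates.

## Known limitations

* Printed-coefficient Wald intervals are approximate (no covariances) and
  materially wider than fitted-model intervals.
* The model and generator treat trials as exchangeable given the latent
  class; order effects are tabulated (transition counts) but not modelled.
* Quasi-separated fits are flagged, not penalised; users wanting finite
  interval estimates under separation should reduce the design or pool
  cells.
* The no-preference emission model is one of many consistent with the
  class's negative definition; quantities that depend on its fine
  structure (e.g. the share of no-preference participants with ≥1 turner
  answer) are fixture constructions, not predictions.
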