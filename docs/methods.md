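# Methods

This note documents the generative model, the estimation procedures, the
numerical choices, and what the synthetic-data tests do and do not show.

## Task design generator

The design is a three-phase, four-key Stroop task.  Colors (and matching
words) form two fixed sets, red/blue and yellow/green; words combine with
colors within a set only, giving 8 stimuli; crossing stimuli with the
set-level ISPC assignment (MC/MI) gives the 16 conditions used throughout.
Defaults follow the task this package models: phases of 8/50/48 mini-blocks
of 16 trials, one set 75% congruent (MC) and the other 25% (MI), phase 2
flipping the phase-1 assignment and phase 3 restoring it, set→MC assignment
in phase 1 alternating across subject index.

Within a mini-block the stimulus counts follow the unique template
compatible with 16 trials, 75/25 per-set congruency, and 50% overall
congruency: the MC set contributes its two congruent stimuli 3× each and
its two incongruent stimuli 1× each; the MI set the reverse.  Consequences
asserted by tests: exactly 50% congruent per mini-block, frequent
(MC-congruent, MI-incongruent) vs infrequent types at 3:1 in every phase,
and all 16 conditions populated once phases flip.  ISPC is assigned at the
set level; per-color assignment within a set would make every word 50%
congruent and abolish the word-level (SR) contingency.

Mini-block sizes other than 16 are supported only as integer multiples of
the template.  Randomness flows from one master seed through per-subject
`SeedSequence` substreams, so any subject can be regenerated independently.

## Neural encoding model

Each trial's epoch (64 channels, 50 samples/s, −200..1500 ms by default) is

    x(t) = Σ_f  a_f · e_f(t) · u_f(level) · g_f  +  ε(t),   ε ~ N(0, σ²I)

with factors f ∈ {color, word, set, congruency, ISPC, SC, SR}.  Spatial
patterns `u` are unit-norm and mutually orthogonal across the
non-association factors; the SC and SR families (8 patterns each) share
exactly `round(overlap_fraction · 8)` basis directions and are rotated
within their spans so individual patterns never coincide.  Envelopes `e`
are Hann windows over factor-specific latency ranges (e.g. color 80–1200
ms, SC/SR 150–900 ms), zero before stimulus onset — pre-stimulus samples
are pure noise.

The trial gain `g` is log-normal with mean 1.  With `coupling=True`
(default) one gain multiplies both the SC and SR amplitudes, implementing
the integrated-representation regime; `coupling=False` draws two
independent gains for null testing.

Defaults were calibrated once, while building the generator, so that the
structure it is designed to express is actually expressed at desk scale:
stimulus-factor amplitudes ≈ 1, SC/SR amplitudes 1.5, sensor noise SD 1,
gain σ = 1 (coefficient of variation ≈ 1.3, i.e. large single-trial
amplitude variability).  At these settings 16-way decoding peaks near 0.33
(chance 1/16), pre-stimulus decoding is at chance, and the shared gain
produces a post-stimulus SC–SR coupling ≈ +0.1 Fisher-z above the
pre-stimulus baseline that vanishes when the gains are decoupled.

What the generator does **not** emulate: volume conduction from realistic
sources, temporally autocorrelated or non-stationary noise, ocular/muscle
artifacts, learning dynamics within a phase, and sequential (trial n−1)
effects.  Passing tests therefore certify the *analysis chain* (that each
stage recovers the structure it targets, with calibrated nulls), not that
real EEG contains that structure.

## Behavior model

RT = exp(log(base + conflict) + η) + slope·g, with η Gaussian on the log
scale (σ = 0.15), base 720 ms, conflict cost 80 ms shrunk by the factor
0.4 on MI trials (the ISPC effect), and slope −60 ms per unit gain linking
strong task representations to fast responses.  RTs beyond the 1500 ms
deadline become missing responses.  Errors are Bernoulli per
congruency × ISPC cell (2/4/10/6%).  The resulting grand-mean RT is
≈ 700 ms.

## Behavioral statistics

RT analyses keep correct trials within ±3 SD of each subject's mean,
computed in a single pass over the whole session before any removal
(configurable per phase).  Each phase is tested with a 2 (Congruency) × 2
(ISPC) within-subject ANOVA on per-subject cell means (statsmodels
`AnovaRM`); partial η² = F·df₁/(F·df₁+df₂).  The ISPC contrast is a paired
t on the per-subject difference between MC and MI conflict effects with
Cohen's d = mean/SD of the paired differences.  For a 2×2 within design
the interaction F equals that t squared — asserted to machine precision as
a cross-check between the two routes.  Error rates use raw per-cell
proportions.

## Decoding

The decoder is Gaussian LDA with a shared within-class covariance shrunk
toward a scaled identity, `(1−λ)S + λ·tr(S)/p·I`, with λ from the
analytic Ledoit–Wolf rule per timepoint (64 features vs a few hundred
trials make the raw pooled covariance ill-conditioned).  Posteriors come
from equal-prior softmax over the linear discriminant scores; prediction
ties break to the lowest class index.  The implementation is vectorized
across timepoints for tractability and is verified in tests against
scikit-learn's `lsqr` LDA at fixed shrinkage (agreement ~1e−10) and
against the closed-form Gaussian discriminant oracle.

Cross-validation follows the frequency-balanced scheme: per random
partition (10 by default) the frequent trials of each condition are split
into three parts; each part joined with the infrequent trials forms one
subset (30 repetitions), and every class within a subset is down-sampled
to the exact common minimum.  Exact balance matters: with merely
approximate balance, per-class training-count differences bias the class
posteriors, and the trial-wise RSA then shows spurious *pre-stimulus*
group effects at realistic subject counts.  Each subset runs a stratified
4-fold CV per timepoint; accuracy averages over folds, parts and
partitions.  Trial-wise posteriors are clipped to [1e−12, 1−1e−12],
logit-transformed, and averaged over a trial's test occurrences.  The
clip is deliberately loose: sharp posteriors keep condition structure in
their tails, and a harsh bound flattens exactly the most informative
trials.  Error trials are excluded by default (configurable).  Group
inference is a one-sample t vs chance per timepoint, Bonferroni-corrected
(α = 0.001 by default).

## Subspaces and the overlap simulation

A decoder subspace is the orthonormalized span of the centered 8-way LDA
weight vectors `Σ⁻¹(μ_c − μ̄)` (rank ≤ 7).  Per CV fold, both subspaces are
fit on training data only; train and test data are projected into each
basis and 8-way SC and SR decoders are trained and tested in both, with
byte-identical fold assignments across the four decoders and a hard
leakage guard.  On the task design the SC and SR label sets share the
ISPC factor and color confines word to its set, so cross-subspace
decoding is structurally above chance even with disjoint pattern
families; tests therefore assert the qualitative pattern (chance < cross
< within) on task data and the exact regimes on constructed data with
independent labels.

The shared-dimension simulation makes the regimes exact: two 8-dim
layouts of 8 equidistant Gaussian class centers (scaled coordinate
vectors; distance 2.0, within-class SD 1.0 by default, putting the own
decoder near 50% accuracy — both config-exposed, as a real dataset would
supply them).  Own decoders see all 8 dims; a cross decoder sees
`n_shared` randomly re-drawn informative dims, the rest filled with
label-independent coordinates.  At 0 shared dims cross accuracy is at
1/8; at 8 it matches the own decoder; in between it is strictly
intermediate and monotone.

Classical (Torgerson) MDS embeds the 16×16 (or 8×8) mean-posterior
confusion matrix: symmetrize to s = (P+Pᵀ)/2, convert to dissimilarity
d_ij = s_ii/2 + s_jj/2 − s_ij (floored at 0, zero diagonal), then
eigendecompose the double-centered squared distances (scikit-bio `pcoa`;
verified against a direct double-centering oracle).  Cumulative explained
variance is the running share of positive eigenvalues.

## Regression RSA

For a trial of condition c the dependent variable at each timepoint is the
16-vector of logit posteriors; the design matrix holds an intercept and
eight binary 16-cell regressors (color, word, congruency, ISPC, SC, SR,
identity, frequency), cell j = 1 iff condition j shares that factor's
level with c.  SC sharing means same color *and* same ISPC (each SC class
contains exactly 2 of the 16 conditions), SR likewise via word × ISPC.
Identity is the own-condition one-hot; frequency marks conditions sharing
the trial's frequent/infrequent status.  OLS per trial × timepoint yields
t = b/SE with df = 16 − 9 = 7.

The VIF screen regresses each column on the others (intercept included);
on the enumerated design the identity regressor sits exactly at VIF = 5
and every other column below it, so the screen flags at ≥ 5 (with a 1e−6
float guard) to reproduce the intended outcome "only identity removed".
`trialwise_rsa(vif_threshold=5)` reruns with flagged columns dropped.

Group inference submits per-subject mean t values to one-sample t tests
(Bonferroni α = 0.001 over timepoints).

**SC–SR coupling.**  Per subject and timepoint the SC and SR strengths are
correlated across trials, by Spearman rank correlation by default: the
trial-wise t values are heavy-tailed (near-exact fits yield huge t) and a
few such trials dominate a Pearson r; ranks are outlier-robust while
preserving the monotone gain-driven covariation (Pearson remains a
config option).  Two guards isolate genuine trial-wise coupling:
strengths are centered within subject × condition (condition-level
decodability differences otherwise masquerade as coupling), and the mean
pre-stimulus Fisher-z correlation serves as each subject's baseline,
absorbing the structural correlation that coefficients from one shared
regression carry even for pure noise.  Post-stimulus points are tested on
z(r) − z(baseline), Bonferroni α = 0.05, flagged only when positive.  Under
decoupled generation this statistic is null (the independent gain variance
in fact dilutes the structural baseline correlation slightly).

## Brain–behavior mixed model

At each analysis timepoint, log RT is regressed on the trial-wise
strengths (z-scored within subject) with fixed dummy intercepts for the 8
SC (or SR) trial types and a random intercept per subject, by REML
(statsmodels `MixedLM`).  An alternative interpretation — per-class
strength slopes instead of a shared slope — is exposed via
`per_class_slopes=True`; neither is asserted to be the canonical reading.
Stimulus-locked, only trials that have not yet responded at that timepoint
enter (RT > t); response-locked, only trials whose stimulus is already on
screen (RT ≥ −t).  The stimulus-locked timecourse runs over timepoints
from 0 up to (excluding) the grand-mean RT.  With a single subject the
model reduces to OLS with the same fixed design (verified to 1e−6).
Natural log for the RT transform.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down studies chosen as the package's
working sizes: typically 4–20 subjects, phases of (2, 12, 10) mini-blocks
(384 trials/subject; near-equal set-A/set-B condition counts), epochs to
800 ms (51 timepoints), and the full 30-repetition CV scheme.  The
permuted-label chance check uses the full 8/50/48 design for 8 subjects at
20 timepoints.  The overlap simulation uses its defaults (8 dims, 8
classes × 100 points, 40 repetitions).  Degenerate inputs are handled
explicitly: singular covariance without shrinkage raises with advice;
zero-variance group tests fall back to an exact tie rule; an all-equal
confusion matrix yields an empty MDS embedding with a warning; trials
never drawn into any balanced subset are dropped from trial-wise outputs.

## Known limitations

- The generator's linear-Gaussian patterns make LDA exactly the right
  model family; real EEG violates this, so absolute accuracies here do not
  forecast empirical ones.
- Cross-subspace decoding on the task design cannot reach chance even with
  disjoint SC/SR pattern families (label sets share ISPC); only the
  independent-label construction and the Gaussian simulation realize the
  chance regime.
- The coupling statistic's baseline correction assumes the structural
  (noise-driven) correlation is stationary across the epoch; strong
  time-varying misfit could bias it, which is why the rank transform and
  condition centering are defaults.
- Response-locked epochs are re-sampled from stimulus-locked ones by
  nearest-sample lookup, not re-epoched from continuous data.
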