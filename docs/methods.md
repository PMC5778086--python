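# Methods

`ruleflux` re-implements, as a tested pipeline, a population-level analysis
of prefrontal activity recorded while rats switch between navigation rules
many times within one session.  Because no public recording of this task
exists, the package ships a synthetic-session generator whose defaults are
the study conditions every stage is validated against.  This note documents
the models, the generator, the numerical choices, and the limits of what
the synthetic validation shows.

## Task and data model

A plus maze has two start arms (North, South) and two goal arms (East,
West).  Four rules are possible: two allocentric (`go_east`, `go_west` — go
to a fixed goal arm) and two egocentric (`go_right`, `go_left` — turn to
the animal's own side).  Maze geometry fixes the egocentric mapping: an
animal heading from the North arm toward the centre faces South, so East is
on its left; from the South arm East is on its right.  Whenever 13 of the
last 15 trials of the current rule are correct, the rule changes without
warning; a change within a strategy class (e.g. `go_east` → `go_west`) is a
*reversal*, across classes a *switch*.  The criterion window is evaluated
over the last `min(15, t)` trials and can fire from the 13th block trial —
the most permissive reading consistent with "13 of 15", checked exhaustively
against a brute-force scan for every sequence up to length 18.

A session is three CSV files (trials, spikes, trajectories; columns in the
`session_io` docstring).  Times are seconds from session start; positions
cm in the maze frame (origin at the centre, North along +y).  A repeated
rule's two blocks carry distinct block ids throughout, since the analyses
ask precisely whether the second presentation re-uses the first state.
Rule blocks, including each block's change type, are reconstructed from the
trial table on read, and the `correct` column is validated against the
recoding of (start, choice) under the active rule.

## Behavioural state-space model

Per-trial performance is the latent state of a Bernoulli random walk:

    x_t = x_{t-1} + eps_t,  eps_t ~ N(0, sigma_eps^2)
    P(correct_t) = logistic(x_t + logit(background_p)),  background_p = 0.5

**Estimation.** The random-walk variance is estimated by direct bounded
maximisation (Brent on log sigma^2) of the Gaussian-filter approximate
marginal likelihood, with the initial state profiled out by a fixed-point
iteration.  An EM M-step was deliberately not used: its updates crawl
(increments ~1e-4 per iteration near the optimum because the likelihood is
very flat in sigma^2), so any practical stopping rule freezes it far below
the maximiser, which over-smooths the curve and collapses interval
coverage.

**Prior bounds on sigma^2.**  The search is bounded to [0.01, 1.0], acting
as a weakly informative prior.  The lower bound matters: for unremarkable
outcome sequences the unbounded maximiser collapses to 0 and the resulting
near-constant curve badly under-covers a truly drifting performance
(measured coverage 0.47 without the bound vs ~0.88 with it, on
model-drawn curves).  The upper bound says a latent drift above one logit
unit per trial — learning within a single trial — is not identifiable
between observations.

**Smoothing.**  Given (sigma^2, x0), per-trial posteriors come from
expectation propagation on the chain: one Gaussian site per trial,
moment-matched against the Bernoulli likelihood by 31-point Gauss-Hermite
quadrature, with Kalman re-smoothing after each sweep (damping 0.7).  For
this log-concave model EP marginal means agree with dense-grid integration
to ~4e-3 on the probability scale; a one-pass Laplace smoother was ~0.1
off and was replaced.  Credible intervals are equal-tailed Gaussian
quantiles of the latent, mapped through the logistic; the default level is
90% (the lower bound is the 5th percentile), configurable.  A single-site
Metropolis sampler over the latent path is included as an independent
cross-check of the smoother (agreement within 0.01 at long chains).

**Phases.**  Each rule has its own curve: all session outcomes are recoded
under that rule and fitted over the whole session.  A trial's phase uses
the ongoing rule's curve and the block's entry type: naive when the lower
credible bound is below 0.1 (reversal) or 0.3 (switch; the session's first
block uses the switch cutoff), learnt above 0.6, learning in between.
Boundary values fall into `learning` (naive is strictly below, learnt
strictly above).

## Synthetic sessions

The generator emits behaviour, spikes, and trajectories with known ground
truth.  Defaults emulate the task's descriptive scale: four blocks (three
rule changes, the median), ~100 trials per session, 20 simultaneous
neurons, ~30% of neurons performance-coupled.

* **Behaviour.**  Within a block the true p(correct) rises logistically
  from chance toward `asymptote_p` (default 0.9) with slope
  `learning_rate` (default 0.35) and half-rise at 4/`learning_rate`
  trials, so the curve starts within ~2% of chance for any slope.  The
  13-of-15 criterion ends blocks; a cap (`max_block_trials`, default 60)
  ends a block that never reaches criterion so low-asymptote
  configurations terminate.  Start arms are drawn with the constraint that
  the same arm never repeats five times; the chosen arm is whichever makes
  the drawn outcome correct under the active rule, so the emitted
  `correct` column always equals the recoding.
* **Segment timing.**  Run and inter-trial durations are log-normal,
  matched to the printed quartiles (run 2.28 / 2.86 / 4.34 s); the reward
  window is fixed at 2 s.  The inter-trial upper quartile as printed in
  the source material (18.42 s) lies below its median (19.16 s), which is
  arithmetically impossible, so the spread is derived from the lower
  quartile alone and the upper quartile is its log-symmetric counterpart
  (23.72 s).
* **Population states.**  Each block occupies a centre in a latent z-space;
  trials scatter around it isotropically (`within_state_sd`, default 1).
  Centres follow a random walk with momentum: each rule change adds a step
  of length `state_separation` (default 4) composed of a fresh orthogonal
  direction (weight sqrt(1-g^2)) and one session-wide direction (weight
  g = 0.5).  Consequences: adjacent states are exactly one separation
  apart; centre distance grows with the number of intervening rule
  changes; and a repeated rule under `new_state` steps *beyond* the pool
  of intervening states.  The momentum term is load-bearing for the
  decoder protocol: with a fully orthogonal walk the repetition lies in a
  direction the training data never samples, where a near-unpenalised
  linear classifier's output is overfitting noise rather than a
  rejection.  `same_state` re-uses the first centre exactly;
  `drift_only` replaces all block structure with a linear drift of the
  whole population along one direction (`state_separation`/100 z-units
  per trial by default).
* **Performance coupling.**  A coupled neuron loads on the Gaussian scores
  of the *latent* p(correct) — the integrated learning state, not the
  single-trial outcome — with Pearson loading 2·sin(pi·rho/6) so the
  emitted rates hit a target Spearman `coupling_strength`; the loading is
  computed against the total non-state noise budget including the
  per-segment jitter, making the target exact for segment rates (checked
  at 2000 trials within 0.05).  A separate fraction
  (`frac_instantaneous`) responds to the same-trial outcome only.
* **Rates and spikes.**  Latent z maps to Hz through
  rate = baseline · exp(0.3·z), with log-normal baselines (median ~3 Hz,
  ~14% above 10 Hz, standing in for putative fast-spiking cells) and an
  independent 0.3-z jitter per behavioural segment, so segments agree
  without being identical.  Spike trains are emitted as evenly spaced
  trains whose counts encode the segment rate — a rate-faithful encoding,
  deliberately *not* a Poisson process, so that rate-level ground truth
  survives the spikes-to-rates round trip up to duration quantisation.
  The entire-trial rate is the duration-weighted mix of the three
  segments.
* **Trajectories.**  A run is a parabola in the path's canonical frame
  (longitudinal axis from start-arm end to goal-arm end, transverse axis
  pointing away from the centre): base curvature bulges ~35 cm toward the
  centre, with per-trial coefficient jitter, optional linear drift of the
  approach angle (`trajectory_drift`), additive sampling noise
  (`trajectory_noise_sd`, default 1 cm) at 25 Hz, and speed = arc length /
  run duration.  `movement_coupling` optionally loads rates on the
  standardised (a, b, c, speed) features — the movement-confound scenario.

Three fields (`frac_instantaneous`, `movement_coupling`,
`trajectory_drift`, defaults 0) exist solely to build the control
scenarios: the shuffled-performance contrast, the movement-driven
re-analysis, and the drift-vs-rules disambiguation.

## Firing-rate correlates

Rates are spike counts over segment durations (run, fixed 2-s reward,
inter-trial up to the next run start, entire trial up to the next trial
start).  Per neuron and segment, Spearman rho against the estimated
performance curve, with Bonferroni-Holm step-down over the neuron family
within one segment (not neurons x segments).  Constant-rate neurons are
flagged and excluded from the family.  The shuffled-performance null
permutes trial order jointly for rates and outcomes, re-fits the
performance curve on the shuffled outcomes, re-correlates (1000 shuffles by
default, per-neuron 2.5/97.5 bands, pooled KS comparison across neurons).
The 10-Hz enrichment test is an uncorrected 2x2 chi-square of rate group x
significance, plus a sign-enrichment chi-square among significant neurons.

**A caution discovered during validation.**  The shuffle control's premise
— that a neuron responding only to the same-trial outcome keeps its
correlation under the null — is approximate.  The observed outcome
sequence is temporally structured, so its fitted curve correlates more
with the same-trial outcome than shuffled-order curves do; an
outcome-locked neuron inherits a one-sided margin (~+0.05–0.08 in rho) and
escapes above the 97.5% bound in ~15% of simulated sessions (far above
the nominal 2.5%).  Integrator neurons separate cleanly (outside the band
in ~96% of runs), and the distribution-level KS comparison is unaffected,
but inside-the-band should not be read as proof of outcome-locked coding.

## Population vectors, clustering, distances

Population vectors are per-neuron z-scored rates over the learning+learnt
trials only (naive trials mostly reflect perseveration); zero-variance
neurons are dropped with a warning.  Note that z-scoring bounds any single
bimodal coordinate at ~2 SD of separation, which is why the generator
spreads state separation across many coordinates.

K-means with k = number of rule blocks (sklearn, Lloyd; 100 random
restarts by default, or centre-of-mass initialisation from the labelled
blocks), each cluster mapped to its majority block (many-to-one allowed),
accuracy = correctly grouped / total.  Significance: the block labels are
permuted against the rate rows and the identical clustering re-run;
p = (1 + #{null >= observed}) / (1 + n_perm).  This p-value is valid
(super-uniform; measured type-I 0.04 at nominal 0.05) but discrete and
tie-conservative: when every cluster maps to the majority block the
accuracy sits on a plateau atom, so the null p-distribution has visible
atoms (notably at 1.0) and is *not* exactly uniform.

The Mahalanobis distance to a rule cluster uses a diagonally shrunk
covariance S' = (1-lambda)S + lambda·diag(S), with the smallest lambda in
{0.1, 0.5, 1.0} giving condition number below 1e6 (trials-per-rule below
the neuron count is common).  The Mahalanobis *clustering* variant
(iterative assignment to regularised rule clusters, collapsed clusters
re-seeded from the farthest trial) is only meaningful when trials comfortably
exceed neurons: with as many neurons as member trials each cluster's
fitted metric absorbs its own members and assignments freeze at their
initialisation.

## Rule-distance geometry

For every block pair: Euclidean centre distance, symmetrised
centre-to-cluster Mahalanobis distance, `trials_between` (absolute
difference of median included-trial indices), `rules_between` (blocks
strictly in between).  Pooled regression: distance on trials_between,
rules_between and their interaction.  Numerical choices, each fixing a
measured defect:

* distances *and* trial gaps are standardised within session before
  pooling (sessions differ in neuron and trial counts; with raw gaps,
  session-heterogeneous slopes leak shared variance into rules_between
  and the drift scenario mis-attributes);
* p-values use a residual-df correction — each session's standardisation
  consumes two degrees of freedom that naive OLS ignores, which otherwise
  roughly doubles the false-positive rate on the null regressor;
* Breusch-Pagan homoscedasticity is reported alongside.

Partial Spearman correlations (first-order, from pairwise rank
correlations, t approximation on n-3 df) accompany the regression.  The
repeated-rule test normalises each pair's distance by the pooled mean of
its rules_between stratum (mean normalised distance is exactly 1 per
stratum); same-rule vs different-rule normalised distances are compared by
Wilcoxon rank-sum.  A regression-residual normalisation is available as an
alternative.  A same-rule pair whose stratum has no different-rule
reference is dropped with a warning — this happens in any single 4-block
session, so the repeat test is meant to be run pooled across sessions.

A residual limitation: the plug-in centre distance has a noise floor that
inflates short gaps (E[d] = sqrt(signal^2 + noise^2)), bending the
distance-vs-time relation.  In short-block sessions this leaks into
rules_between as a ~10-20% false-positive rate under pure drift; with
long blocks (>= 50-80 trials) the floor is negligible and attribution is
clean.  The validation suite therefore runs the drift scenario with long
blocks, and real-data users should expect reduced specificity when rule
blocks are short.

## Repetition decoder

Per repetition (1000 by default): a fresh random 70% of rule A's included
trials (labelled 1) plus all trials of other rules except the repetition
A-deg (labelled 0) train a linear classifier — logistic regression with a
weak ridge (C = 1e4) or a linear SVM (C = 1) — with class weights inverse
to class size (the '0' pool is much larger; unweighted fits predict '0'
trivially).  Reported accuracies are the fraction of held-out A trials and
of A-deg trials classified as A, plus a rank-sum comparison of the two
distributions.  Identical-vector input is flagged degenerate and returns
the constant prediction.

## Movement controls

Trajectories are fitted per trial as transverse = a·s^2 + b·s + c in the
path's canonical frame.  The similarity index between two trials is the
range-normalised Euclidean distance of coefficient triples with weights
1/(max - min) per coefficient over the comparison population; a degenerate
(zero-range) coefficient contributes nothing.  The trajectory-matched test
takes, on a shared path type (>= 5 trials in each block; the best-covered
path by default), A x A-deg cross pairs below the 5th percentile of
cross-pair similarity and within-A pairs above the 95th percentile of
within-pair similarity (selection counts floor(0.05·n), at least 1), and
compares their population-vector distances by rank-sum.  Percentile
selections of a few pairs have essentially no rank-sum power; the test
needs long blocks (tens of trials per path) to be informative.

The movement GLM regresses each neuron's rate, per path type, on
(a, b, c, speed) with an intercept — five distinct coefficients.  Path
subsets with fewer trials than regressors fall back to mean-centring with
a logged warning.  Residuals (reassembled in trial order) feed the
re-analysis: performance correlations, overall clustering, and clustering
within each path type separately (so trajectory differences cannot
distinguish rules inside a subset), reported side by side with the
originals including the rank agreement of per-neuron correlation values.
Because the GLM removes a per-path intercept, the *overall* residual
clustering mixes path-specific offsets and can lose accuracy even for
movement-free rates; the per-path comparison is the meaningful one, which
is how the validation checks preservation.

## Validation scale and scenarios

The acceptance suite (`tests/test_acceptance.py`) runs every stage at a
fixed, seeded scale chosen to finish in minutes on one CPU: 200 step
sequences for the estimator; exhaustive criterion scan to length 18; 100
sessions of 300 neurons for detection/family-wise error (a single gradual
learning episode, where the estimated curve tracks the latent performance
at rho ~0.95 — with mid-session rule changes the maximum-likelihood curve
under-tracks sawtooth learning and attenuates all correlations); 200 null
sessions for clustering calibration; 100 pooled-session runs per geometry
direction; 100 seeds per repetition-test direction; and a full CLI
round-trip checked byte for byte.  Scenario parameters (separations, block
lengths, session counts) are stated in the test bodies; they are study
conditions, not tunables.

What passing does *not* show about real data: the generator's rates are
rate-faithful (no Poisson spiking variability), states are isotropic
Gaussian with exactly known geometry, trajectories are ideal parabolas,
and drift is linear.  Real sessions will sit between the clean scenarios
and the documented failure regimes (short blocks for the geometry, strong
outcome locking for the shuffle null, trials ~ neurons for Mahalanobis
clustering).
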