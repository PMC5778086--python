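# ruleflux

Analysis pipeline for prefrontal population recordings during **multiple
within-session rule switches** on a plus maze, plus a synthetic-session
generator that makes every stage testable without any recording.

Rats start from the North or South arm and choose the East or West goal
arm under one of four rules — allocentric (`go_east`, `go_west`) or
egocentric (`go_right`, `go_left`).  After 13 correct choices within the
last 15 trials the rule changes unannounced, several times per session,
sometimes repeating an earlier rule.  Given per-trial behaviour, sorted
spike times and run trajectories, the package asks:

1. **How well is the animal doing, trial by trial?**  A Bernoulli
   state-space model — latent random walk `x_t = x_{t-1} + eps_t`,
   `P(correct_t) = logistic(x_t + logit(0.5))` — estimated by marginal
   maximum likelihood with expectation-propagation smoothing, giving a
   per-trial probability with credible bounds.  Thresholding the lower
   bound of the ongoing rule's curve labels each trial naive, learning or
   learnt.
2. **Which neurons track performance?**  Per-segment firing rates (run,
   2-s reward, inter-trial, entire trial) correlated with the performance
   curve (Spearman, Bonferroni-Holm over the neuron family), with a
   shuffled-performance null that distinguishes integration of past
   outcomes from same-trial reward responses, and a chi-square enrichment
   of high-rate (>= 10 Hz) neurons.
3. **Do population vectors cluster by rule?**  Trials as z-scored
   population vectors (learning + learnt only), K-means with k = number of
   rule blocks, accuracy = correctly grouped trials, permutation p-value
   from label shuffles; Euclidean and regularised-Mahalanobis variants.
4. **Rules or mere drift?**  Centre-of-mass distances of all block pairs
   regressed on the number of trials vs the number of rules in between
   (pooled across sessions, with partial rank correlations).
5. **Does a repeated rule re-enter its old state?**  A linear decoder
   trained on rule A vs all others — the repetition A-deg never in
   training — is tested on held-out A and on A-deg; plus a rank-sum test
   on rules-between-normalised centre distances of repeated vs
   non-repeated rule pairs.
6. **Is it all just movement?**  Run paths fitted as parabolas
   (`a s^2 + b s + c` in each path's canonical frame), a range-normalised
   similarity index between trajectories, trajectory-matched distance
   comparisons, and a per-path GLM of rate on (a, b, c, speed) whose
   residuals are pushed back through the whole pipeline.

The synthetic generator (`ruleflux.synthetic_data`) emits sessions with
criterion-driven rule changes, logistic learning, rule-specific population
states (a random walk of states with momentum; repeats can form a new
state, re-use the old one, or be replaced by pure temporal drift),
performance-coupled neurons with exact target Spearman correlations, and
parabolic trajectories — all with ground truth attached.

## Worked example

```python
import numpy as np
from ruleflux import behavior, firing_correlates as fc
from ruleflux.population_states import build_population_vectors, cluster_by_rule
from ruleflux.repetition_decoder import decode_rule_repetition
from ruleflux.synthetic_data import GeneratorConfig, generate_session

session, truth = generate_session(GeneratorConfig(seed=7), seed=7)
print(session.n_trials, [(b.rule_name, b.n_trials) for b in session.rule_schedule])
# 103 [('go_east', 24), ('go_right', 31), ('go_west', 22), ('go_east', 26)]

curve = behavior.estimate_performance(session.outcomes())
print(round(float(np.sqrt(np.mean((curve.p_mode - truth.p_true) ** 2))), 3))
# 0.139          <- RMSE of the estimated curve against the latent truth

phases = behavior.session_phases(session)
frm = fc.compute_segment_rates(session, "entire_trial")
print(fc.performance_correlations(frm, curve).n_significant)
# 13             <- of 20 neurons significantly performance-correlated (Holm)

pm = build_population_vectors(frm, phases, session.rule_schedule)
ev = cluster_by_rule(pm, n_perm=499, seed=0, n_restarts=20)
print(round(ev.accuracy, 3), round(ev.p_perm, 4))
# 0.845 0.002    <- trials cluster by rule far above the permutation null

blocks = session.rule_schedule   # go_east appears twice: blocks 0 and 3
res = decode_rule_repetition(pm, blocks[0], blocks[3], n_reps=1000, seed=0)
print(round(res.median_A, 2), round(res.median_Arep, 2))
# 0.86 0.04      <- held-out A decodes as A; its repetition does not
```

The last line is the core finding the pipeline is built around: when the
same rule returns later in the session, the population does not return to
its original firing state — the repetition is classified with the *other*
rules, and its centre distance is indistinguishable from that of any two
different rules at the same separation.

## Command line

```
ruleflux simulate --seed 7 --out sess/           # emit a synthetic session
ruleflux report --session sess/ --seed 7 --out out/   # run every stage
```

`simulate` writes `trials.csv`, `spikes.csv`, `trajectories.csv` and
`ground_truth.json`; `report` writes per-stage tables
(`performance.csv`, `correlations.csv`, `clusters.csv`,
`distance_table.csv`, `decoder.csv`, `trajectory_fits.csv`, ...), JSON
summaries and a log naming config, seed and package version.  Individual
stages (`behavior`, `correlate`, `cluster`, `geometry`, `decode`,
`movement`) run the same computations separately; options live in a plain
`key = value` config file.  Outputs are byte-identical across reruns with
the same seed.

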