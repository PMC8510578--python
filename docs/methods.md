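# Methods

## Data model

One observation unit is a single animal's ordered sequence of binary
choices (APPROACH = entered the odorized channel, AVOID = entered the clean
channel) within an experimental phase: PRE (naive hour-long test), POST
(hour-long test after training), NEXT_DAY (retest after overnight rest).
Backing up before the junction is not a choice and is unrepresentable in the
types.  Animals that made no decisions in a phase are retained with empty
sequences: they stay in the animal-resampling pool of the bootstraps but
carry zero decision weight, and they are excluded from likelihood fits
(their preference is undefined).  Extinction/habituation blocks are protocol
metadata, not phases, because no choices are scored during training.

## Preference and uncertainty

The population preference is decision-weighted: total approaches over total
choices, so animals that made more decisions contribute more.  Because one
animal's successive choices anti-correlate, decisions are not independent
and a binomial error bar would be wrong.  Uncertainty instead comes from
resampling:

* **Hierarchical bootstrap** — sample animals with replacement, then within
  each sampled animal sample its decisions with replacement (independently
  per condition); recompute the decision-weighted preference.  10,000
  replicates by default; the error bar is the replicate standard deviation.
* **Animal-only bootstrap** — same, but decision sequences are kept intact,
  preserving within-animal correlation.

In paired comparisons (the same animals pre and post) the same resampled
animals enter both conditions of each replicate.  The comparison p-value is
a *ranking-consistency score*: the fraction of replicates whose condition
ranking disagrees with the reference ranking, with exactly tied replicates
counted half.  (Half-weighting makes a fully degenerate comparison — e.g.
a condition against itself under animal-only resampling, where every
replicate ties — score p = 0.5 rather than 0 or 1.)  When the point
estimates tie exactly, the reference ranking is the replicate-majority
ranking.  Zero disagreements are reported as "< 1/B".  This score is not a
calibrated type-I test; a simulation in the test suite checks only that its
null rate is loosely near nominal.

Classical tests are delegated to scipy: Fisher's exact test on the pooled
2×2 pre/post count table (two-sided by the point-probability rule, p = 1 for
degenerate margins by convention) and the two-sided Mann–Whitney U on
per-animal preferences (exact enumeration when min(n, m) ≤ 8 without ties,
tie-corrected normal approximation with continuity correction otherwise —
the conventions of the standard implementations the printed values being
reproduced were computed with).

## Generative model

The simulator produces data with the nested structure the analysis assumes.

* **Choice sequences.**  A two-state Markov chain on the previous choice:
  P(approach | previous approach) = m − δ_a, P(approach | previous avoid) =
  m + δ_b, with δ_b = m·δ_a/(1 − m) so the stationary mean is exactly the
  target m.  The first choice of a phase is drawn at the marginal mean.
  Default δ_a = 0.08 produces a modest negative lag-1 autocorrelation and an
  effective σ̃ < 1; the true magnitude in real data is not published, so this
  is a calibration choice, not a measured value.
* **Learning.**  All-or-none mode: each training cycle independently
  converts an untrained animal with probability ρ (default 0.4, i.e.
  λ = 1 − ρ = 0.6), so the expected untrained fraction after i cycles is
  (1 − ρ)^i; a trained animal's mean jumps from μ_u = 0.27 to μ_t = 0.52
  (the two observed population centers).  Graded mode: the latent mean
  increases linearly by `graded_step` per cycle (clipped to [0, 1]) — the
  simplest monotone parameterization of a drifting-mean alternative.
* **Extinction.**  Unrewarded CS cycles revert a trained animal with a
  per-cycle probability (default 0.15), all-or-none, mirroring the
  observation that extinguished animals return to the untrained state rather
  than an intermediate one.
* **Decision counts.**  Per phase, negative binomial (mean 30, dispersion 8,
  floor 1), matching the wide per-animal spread (~15–40 choices/hour) of the
  reference counts.
* **Dose design.**  Default doses (0, 1, 2, 3, 4, 5, 10, 20) cycles with the
  reference group sizes (50, 35, 87, 31, 32, 63, 14, 64 animals).
* **Reproducibility.**  Per-animal streams are split from the master seed by
  `SeedSequence(seed, spawn_key=(dose_index, animal_index))`, so changing
  one group's size never perturbs another animal's draws.

What the simulator does **not** emulate: spatial kinematics, real-time CO₂
concentration dependence, animal-to-animal heterogeneity in μ_u or in ρ,
drift of preference within a phase, and inactivity (zero-decision animals)
beyond the configurable count floor.  Passing recovery tests therefore show
the estimators work when the model's assumptions hold; they do not validate
those assumptions against real larvae.

## Likelihoods and fitting

Each animal contributes one (p, n) pair; the Gaussian observation model has
variance σ̃²·p̄(1 − p̄)/n, floored at 10⁻⁶ so degenerate but legal proposals
(means at 0 or 1) keep finite densities.  No truncation of the Gaussians to
[0, 1] — the parameter counts admit no truncation terms.  The five variants
and their parameter counts at D dose levels:

| model          | free parameters                          | k (D = 8) |
|----------------|------------------------------------------|-----------|
| shifting_mean  | μ(n_c) per dose + global σ̃               | 9         |
| graded         | μ(n_c), σ(n_c) per dose                  | 16        |
| quantized      | μ_u, μ_t, σ̃, f_u(n_c) per dose           | 11        |
| three_cluster  | μ₁ ≤ μ₂ ≤ μ₃, σ̃, (f₁, f₂)(n_c) per dose  | 20        |
| all_or_none    | μ_u, μ_t, σ̃, λ                           | 4         |

Observations for BIC are animals with n ≥ 1 (one likelihood term each).

Optimization is multi-start L-BFGS-B on an unconstrained scale (logit for
probabilities and fractions, log for scales; three-cluster means ordered by
stick-breaking, simplex weights by two logits per dose).  Each fit uses one
heuristic start (method-of-moments means; f_u from a 0.4-threshold split of
per-animal preferences; the graded start is its closed-form per-dose MLE)
plus `n_starts` Gaussian perturbations of it (default 20; recovery
experiments in the tests use 2–5, which the strong heuristic starts make
sufficient).  `compare_models` additionally warm-starts each richer model
from the embedded optimum of its nested neighbor (all_or_none → quantized →
three_cluster), which guarantees the nesting inequalities of the maximized
log-likelihoods up to optimizer tolerance.  Ties between optima break toward
the lexicographically smallest parameter dictionary.  Convergence tolerance
is 10⁻⁸ on the objective.

## Trained-fraction profile intervals

For one dose group, with μ_u, μ_t, σ̃ frozen at the global quantized fit,
the profile log-likelihood g(f) in the trained fraction f is a sum of logs
of linear functions of f, hence concave.  f₀ maximizes g on [0, 1] (bounded
scalar minimization plus explicit endpoint checks); the interval is the
connected set where g(f) ≥ g(f₀) − 1/2, with endpoints found by Brent root
finding at tolerance 10⁻⁴ (10⁻⁵ in the accuracy tests) and clipped to
[0, 1].  When μ_u = μ_t the profile is flat and the interval is [0, 1].

## Problem sizes used in the automated checks

Chosen to keep the full suite around seven minutes on one CPU: nesting
inequalities on 20 datasets of 15 animals/dose; all-or-none parameter
recovery on 20 datasets of 300 animals/dose (λ within ±0.05, means within
±0.02 in ≥ 18/20); BIC model-selection recovery on 50 switch-like and 12
graded datasets at the reference group sizes; decay-law consistency at
2,000 animals/dose; profile-interval accuracy against a 4001-point grid
scan on 20 groups of 40 animals.  `scripts/acceptance.py` repeats the same
computations at slightly smaller replicate counts (12 selection datasets,
10 profile groups) under a user-supplied seed.

## Known limitations

* The Gaussian observation model is a poor approximation for very small n
  (a handful of decisions); such animals still enter fits with large
  variance but the normal tails are not those of a binomial.
* σ̃ is global; any dose dependence of the serial correlation is absorbed
  into misfit.
* The ranking-consistency p-value is descriptive, not a calibrated test,
  and no multiple-comparison correction is applied across conditions.
* Exact reproduction of the published model-comparison deltas requires the
  deposited per-animal source data; `scripts/fit_source_data.py` performs
  that fit when such a spreadsheet is supplied.
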