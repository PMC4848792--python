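# Methods

## The problem

Official cause-of-death statistics tabulate a single *underlying* cause per
death, selected from the full death certificate (in the US by the ACME
software). A substantial share of deaths — roughly one in ten in the ICD10
era — ends up coded to causes that are unusable for public-health analysis:
ill-defined conditions ("R" codes), intermediate causes such as heart
failure or septicemia, modes of death, and injuries of undetermined intent.
These *garbage codes* must be redistributed onto valid causes before
cause-specific mortality can be compared across time, place or ICD revision.

`gcredist` redistributes garbage-coded deaths using the rest of the
certificate. The key observation is that when a garbage code appears as a
*contributing* cause on certificates that carry a valid underlying cause,
those certificates reveal which valid causes tend to sit behind the garbage
code, conditional on everything else written on the certificate.

## Cause list, garbage taxonomy, target matrices

Deaths are condensed onto 25 mutually exclusive, collectively exhaustive
causes (communicable `A.*`, non-communicable `B.*`, injuries `C.*`), and
garbage codes are grouped into nine categories (septicemia, heart failure,
ill-defined cancer, volume depletion, wholly ill-defined, ill-defined
cardiovascular, ill-defined injury — ICD9 only —, undetermined intent,
ill-defined infectious).

For each garbage category a *target matrix* lists the valid causes that
could plausibly have produced the death. Three rules are fixed by the
method's design: heart failure redistributes only to the eight
non-communicable causes excluding cancers and the mental/neurological
group (so its reference category is diabetes, `B.2`); ill-defined cancers
redistribute only to the six cancer groups; wholly ill-defined deaths may go
to any valid cause. The remaining six columns of the default matrix are a
documented best reading and are deliberately **configuration, not code**
(`taxonomy.DEFAULT_TARGETS`, YAML-loadable): plausible alternative readings
should be expressed by editing the config. The default additionally routes
intestinal infections (`A.5`) and mental/neurological (`B.8`) through the
any-cause column only.

The ICD9/ICD10 code maps shipped in `cause_map` are built from ICD
chapter/block ranges (about 1,300 ICD9 and 2,300 ICD10 three-character
codes). They are block-level approximations intended as replaceable
defaults: any production analysis should load its own
`code,revision,category` file. Lookup of a 4-character code falls back to
its 3-character parent; in strict mode (default) unmapped codes are errors,
in lenient mode they map to `B.7` (other NCDs) with a logged warning.
Block choices worth noting: ICD10 S/T nature-of-injury codes used as
underlying cause map to `garbage:ill_defined` (the ill-defined-injury
category exists only under ICD9, where codes 800–999 carry it), and ICD9
V codes map to `B.7`.

## The stratum model

Strata are (ICD revision × sex × 19 age groups × garbage category); each is
fitted independently. Within a stratum with target causes u = 1..U:

- **training set** — certificates listing the garbage code as a contributing
  cause on certificate lines 1–5 with a valid underlying cause among the
  targets; the outcome y_i is which target was assigned;
- **prediction set** — certificates whose underlying cause *is* the garbage
  code.

Line 6 stands for Part II of the certificate ("other significant conditions
contributing to death but not resulting in death") and is excluded from all
covariates in both sets.

The model is a mixed-effects multinomial logistic regression. With the
first target (in canonical cause order) as the reference category,

    theta_i[1] = 0
    theta_i[u] = alpha[u] + beta[u] * year_i + sum_j gamma[u][j] * M_ij
                 + pi_state[u][s_i] + pi_place[u][p_i] + pi_race[u][r_i]
    y_i ~ Categorical(softmax(theta_i))

where M is the vector of binary indicators marking which of the 25 valid
causes appear anywhere on lines 1–5 (garbage categories never enter M; the
modeled garbage code's own presence is constant in training by construction
and is therefore not a covariate). `exp(gamma[u][j])` is the relative risk
ratio (RRR) of target u versus the reference when cause j is on the
certificate; RRR tables are emitted with the reference column fixed at 1.00
and display clipping at ≤0.1x / ≥10x (raw values are preserved).

Numerical conventions:

- **Year** is centred at the revision era midpoint (1988.5 for ICD9
  1979–1998, 2005 for ICD10 1999–2011) and scaled to decades; the slope is
  per-target.
- **Priors** are weakly informative: Normal(0, 2.5) on alpha, beta, gamma;
  Normal(0, sigma_f) on each random effect; HalfNormal(1) on each factor
  scale sigma_f (shared across targets within a factor). All scales are
  configurable (`PriorConfig`).
- **Targets never observed in training** are dropped from the stratum before
  outcome indexing and receive predicted probability 0; they are listed in
  the stratum manifest.
- **Unseen factor levels at prediction time** contribute 0 (the population
  mean), the standard partial-pooling prediction for a new level.
- **Small strata** (default: fewer than 50 training deaths, or fewer than
  two surviving targets) are not fitted; their garbage deaths are
  redistributed by pooled empirical target shares (±1 adjacent age bin,
  then the sex × revision margin), flagged `fallback` in all outputs. Every
  garbage death is always reassigned so the cause list stays exhaustive.

## Inference

Both engines share one log-posterior implementation with analytic
gradients.

**MAP (default).** L-BFGS from a zero start, so the fit is fully
deterministic. The joint posterior of a hierarchical model is unbounded as
sigma_f → 0 (the usual funnel degeneracy), so the MAP engine holds the
random-effect scales fixed (default 1.0, configurable via
`PriorConfig.map_sigma`) and optimizes the fixed and random effects — a
ridge-penalized estimate. Convergence is checked on the gradient
sup-norm.

**NUTS MCMC (opt-in).** Full-Bayes fitting uses the package's No-U-Turn
sampler over a non-centred parameterization (pi = sigma_f · z, sigma_f
estimated hierarchically, sampled as log sigma with the Jacobian term). The
sampler implements multinomial (progressive, biased) trajectory sampling,
the momentum-sum U-turn criterion, dual-averaging step-size adaptation
(target acceptance 0.9), and a diagonal metric adapted over Stan-style
expanding warmup windows, initialized at the prior marginal variances. A
dense-metric option exists but is off by default: with the short windows
used here its covariance estimate is too noisy and measurably hurt
effective sample size. Divergences are flagged at an energy error of 1000.
Diagnostics (computed with arviz over every sampled dimension) report
split-R̂ as the primary convergence statistic alongside the stricter
rank-normalized R̂ and bulk ESS; a warning flag is set when split-R̂
exceeds 1.01. Per-death probabilities from an MCMC fit are posterior means
of the per-draw softmax (a proper posterior predictive), not the softmax at
the posterior mean.

## Redistribution

Each garbage death receives a probability vector over its stratum's
targets. *Proportional* redistribution (default) adds that vector as
fractional counts — the population-level convention; *hard* redistribution
assigns the death wholly to the argmax target, ties broken toward the lower
canonical cause index and logged. Fractional counts are kept as reals
end-to-end; largest-remainder integerization is available at report time.
Every run embeds a conservation ledger: total deaths are identical before
and after (tolerance 1e-6) and garbage categories end at exactly zero. With
an intercept-only model, proportional redistribution reproduces the
training set's empirical target shares — the strictly-proportional baseline
this method generalizes.

## Synthetic data

The generator (`synthetic`) emits full micro-data records from a known
instance of the stratum model so that every stage is testable without the
restricted vital-registration data it emulates. Demographics are drawn
uniformly over configured levels; contributing-cause indicators are drawn
independently per cause given demographics; the true underlying cause is
drawn from the model's softmax; a configured fraction of certificates is
emitted garbage-coded (truth recorded separately); on the rest, the garbage
code is listed as a contributing cause on a random line 1–5. Decoy codes
are placed on line 6 (10% of records by default) to exercise the Part II
exclusion. ICD codes are synthesized from the default map's first code per
category.

Default conditions (the package's standard recovery harness): 20,000
certificates in one ICD10 stratum (men 70–74, heart failure), U = 4 targets
(B.2, B.3.1, B.3.2, B.3.3), five active contributing-cause indicators with
coefficients in [−1.5, 1.5] including one of exactly log 3 (RRR 3.0),
occurrence probability 0.30 per active cause, 4 states × 6 places × 3 races
with random-effect scale 0.3, 30% garbage-coded. A smaller U = 3, n = 500
variant serves as the MCMC diagnostic case. The
`reveal_true_cause_prob` knob (default 0) can additionally list the true
cause on garbage-coded certificates to emulate causal-chain misordering; it
is off by default because indicators are drawn before the outcome, so any
drawn indicator already appears on the certificate, and post-hoc insertion
would distort the prediction set's covariate distribution.

What the generator does **not** emulate: realistic US cause-of-death
frequencies, within-certificate correlation between contributing causes
beyond the outcome link, ACME coding behaviour, multi-stratum demographic
structure (unless configured). Passing recovery tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
real-data validity of those assumptions.

## Measured behaviour at the standard conditions

`scripts/acceptance.py` recomputes, from scratch at a caller-supplied seed:
maximum absolute error of the MAP gamma estimates and the RRR estimate for
the log 3 coefficient (n = 20,000); the maximum per-target gap, in
percentage points, between proportional-redistribution shares and the truth
table; the conservation residual and remaining garbage deaths; NUTS
split-R̂, divergence count, and posterior calibration (max |z| of active
coefficients) on the n = 500 stratum; and the exact likelihood-enumeration
and intercept-only oracles. The test suite asserts the corresponding
bounds (gamma within ±0.15, RRR in [2.4, 3.75], shares within 2 pp,
conservation to 1e-6, split-R̂ ≤ 1.01 with zero divergences, oracles to
1e-10/1e-3).

## Known limitations

- The default cause maps and six of nine target-matrix columns are
  replaceable approximations; analyses of real micro-data should supply
  their own mapping configuration.
- MAP with fixed random-effect scales under-propagates uncertainty relative
  to the full posterior; the MCMC engine is the reference when uncertainty
  in the RRRs matters.
- Redistributed counts carry no uncertainty intervals (posterior draws are
  retained in `FitResult` for future use).
- Strata are fitted independently; there is no partial pooling across age
  groups or sexes beyond the small-stratum fallback.
- The method presumes garbage coding arises from misattribution within the
  causal chain, not misdiagnosis; where a garbage code rarely co-occurs
  with valid underlying causes (wholly ill-defined deaths), training data
  are thin and the fallback/proportional behaviour dominates.
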