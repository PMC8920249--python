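# Methods

This note documents the statistical models behind `preysel`, the
parameter choices that matter, and the limits of what the synthetic-data
tests demonstrate.

## Electivity model

Daily electivity uses the Manly-Chesson index in its constant-prey
(no-depletion) form: α_j ∝ r_j / p_j normalised to sum to 1, where r is
the day's consumed proportions and p the *nominal daily starting*
offered proportions. Because prey are replaced every 24 h at the same
starting relative abundances, within-day depletion is not corrected
for; the depletion bookkeeping (below) quantifies how often it matters.
A species never consumed on a feeding day has r_j = 0 and hence
α_j = 0 with no special-casing; a day with zero total consumption has
no α (non-feeding days are excluded from averaging, never imputed as
uniform).

Per individual, daily α vectors are averaged unweighted over feeding
days (`method="daily_mean"`). A pooled variant (`method="pooled"`:
counts summed over all days, then one α) is provided; the two agree
closely in practice, and they answer subtly different questions — with
single-prey days the daily-mean α converges to the *pick distribution*
normalize(π ⊙ p), while the pooled α divides by availability once and
converges to the preference π itself. Both identities are exploited by
the recovery tests.

### Treatment-level inference

Individuals are the independent replicates (days within an individual
are not). The per-species CI on the across-individual mean α is a
two-sided Student-t interval by default (`ci_method = t`), chosen for
the small per-treatment sample sizes typical of such trials (10–31
individuals); a seeded nonparametric bootstrap (`ci_method =
bootstrap`, percentile interval) is available since the appropriate
interval construction for mean electivity is not settled in the
literature. Selection calls compare the interval with the random-feeding
line 1/m: wholly above → positive selection, wholly below → negative
selection (avoidance), otherwise none. A single individual yields no
interval; the call is `none` and flagged as CI-undefined.

## Petraitis' W

The niche-breadth index is the standardised multinomial likelihood
ratio of the individual diet x_i (total n_i, observed proportions
p_i = x_i/n_i) against the population diet proportions q:

    log L_i = Σ_j x_ij (ln q_j − ln p_ij)      (0 · ln(·) ≡ 0, i.e. 0⁰ = 1)
    λ_i     = −2 log L_i   (the multinomial G statistic)
    W_i     = L_i^(1/n_i) = exp(−λ_i / (2 n_i)) ∈ (0, 1]

W_i = 1 exactly when p_ij = q_j on the individual's support. The
implementation is validated against an independent brute-force oracle
(scipy's multinomial log-pmf evaluated under both hypotheses) on every
diet with n_i ≤ 6 and m ≤ 3 — this likelihood-ratio form is the
package's own reconstruction of the index from first principles, and
the exhaustive cross-check is the guard on it.

The population diet q is the pooled consumption of all *included*
individuals within the same treatment, focal individual included (an
exclude-self option exists but is off by default, matching the
convention of comparing each member against the whole).

### Significance

- `chi2`: upper tail of λ at df = (species in the population diet) − 1,
  the free parameters of the population multinomial. df is configurable
  because conventions differ.
- `monte_carlo` (default in the pipeline): draw multinomial(n_i, q)
  diets and report the fraction with W ≤ observed. Small W means a
  narrow diet, so this is a left-tail test; an observed W of 1 has
  p = 1 by construction.

The asymptotic χ² is anticonservative at the per-individual totals seen
in daily feeding trials (a handful of prey per individual over two
weeks), which is why the resampling null is the default; every output
row records which method produced its p-value. Calibration is verified
empirically: at n_i = 100 with no heterogeneity the χ² test rejects at
≈ the nominal 5% (within binomial error over 2000 simulated
individuals), and Monte-Carlo and χ² p-values agree within 0.02 at
n_i = 200.

## Bookkeeping rules

- **Inclusion filter**: predators consuming fewer than 3 prey over the
  trial are excluded (boundary inclusive). "Fed at least 3 times" is
  read as total prey consumed — each feeding event is one prey, since
  daily intake rarely exceeds one — with a feeding-days variant
  (`min_feedings_mode = days`) for the alternative reading.
- **Mortality/predation rate**: deaths (or predations) divided by trial
  days, reported exactly and rounded to 2 decimals.
- **Depletion**: a case is a predator-day on which some species' count
  equals its offer; spillover is a case on which any *non-depleted*
  species was also eaten. Percent spillover uses integer counts before
  the single division and is flagged undefined (not zero) when there
  are no cases.
- **Fidelity**: the most-consumed species' share of an individual's
  total diet; ties for the top species are broken uniformly at random
  under the run seed and flagged.
- **Weekly stability** (28-day trials): weeks are consecutive 7-day
  blocks from day 1. α is computed per individual-week (individual-weeks
  without feeding are omitted) and the week × species interaction is
  tested by permuting week labels within individuals (2000 permutations,
  seeded, add-one p-value). This is a deliberately assumption-light
  substitute for a mixed-model interaction test and is labelled as such
  in every output; it tests exchangeability of weeks within individuals,
  not the full mixed-model hypothesis.

## Synthetic-data model

The simulator reproduces the trial geometry it is meant to exercise:
m = 4 prey species, 8 prey per compartment replaced daily, 14-day
trials (28 for stability checks), one predator per compartment, 8
compartments per tank.

- **Individual preferences**: π_i ~ Dirichlet(κ Π). Π defaults to
  (0.50, 0.08, 0.24, 0.18) — a strong first-species preference and
  near-avoidance of the second, the qualitative ordering the four-prey
  design is built to detect. κ (default 2.0) sets between-individual
  heterogeneity: κ → ∞ approaches identical individuals,
  `concentration="none"` makes them exactly identical (the null for
  calibration), small κ produces strong specialists. κ = 2 was chosen
  as a mid-range default producing clearly detectable specialisation at
  the default geometry.
- **Daily intake**: i.i.d. across days over {0, 1, 2, 3} prey, default
  (0.55, 0.38, 0.06, 0.01), i.e. mean ≈ 0.53 prey/day with a hard
  maximum of 3 — matching a regime where predators eat roughly every
  other day and multi-prey days are rare. No hunger carry-over is
  modelled.
- **Prey choice**: sequential without replacement within the day, each
  pick with probability ∝ π_j × (individuals of j still available).
  This abundance weighting gives α the interpretation Chesson intended
  and yields the closed forms used in testing: with intake ≡ 1 the
  single-pick distribution is exactly normalize(π ⊙ offered
  proportions). A pure-preference rule (∝ π_j over non-depleted
  species) exists for contrast experiments. If every species the
  predator prefers is depleted mid-day and intake remains, the
  remaining picks are uniform over still-available prey — forced
  consumption of non-preferred prey, the same phenomenon the depletion
  spillover statistic counts in real data.
- Ground truth (π_i, κ, seed) is written to a separate ledger file and
  never mixed into analysis inputs.

### What the simulator does and does not show

Passing recovery and calibration tests on simulated data shows the
estimators are internally consistent under the stated model:
Dirichlet-distributed preferences, i.i.d. daily intake, and
abundance-weighted multinomial choice. Real feeding data can violate
all three — prey behaviour (burying, movement) modulates encounter
rates, hunger and experience induce day-to-day dependence, and prey
re-use across days may select for less palatable individuals. The
simulator also omits compartment geometry, predator interference and
prey-size variation. Results on simulated data therefore validate the
*pipeline*, not any biological claim about a particular predator.

## Numerical choices

- α and W are computed in double precision; α vectors are checked to
  sum to 1 within 1e-9, offered proportions within 1e-12.
- Monte-Carlo p-values compare with a 1e-12 slack (W ≤ observed + ε) so
  exact ties count as non-rejections.
- The permutation p uses the add-one convention (1+hits)/(1+B), so it is
  never exactly zero and equals 1 under perfectly week-stable data.
- Tie-breaking (fidelity) and all resampling draw from
  `numpy.random.default_rng` seeded from the run configuration; a fixed
  seed makes every pipeline output byte-stable.
- Problem sizes in the test suite (e.g. 2000 simulated individuals for
  calibration, 50 predators × 200 days for recovery, 20 paired seeds
  for the κ ordering) are the smallest at which the binomial/Monte-Carlo
  error bands quoted in the tests are comfortably discriminating.

## Known limitations

- The no-depletion form of α is biased when within-day depletion is
  common; the depletion summary quantifies exposure to this bias but no
  depletion-corrected estimator is provided.
- The χ² significance route for W should not be trusted below roughly
  n_i = 30; use the Monte-Carlo route (the default).
- The weekly permutation test has less power than a well-specified
  mixed model when individual baselines differ strongly.
- Control (predator-free) rows share the record table under
  `predator_id = "CONTROL"` and are excluded from analysis
  automatically; they carry no compartment-level metadata beyond
  tank/compartment labels.
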