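# Methods

## Force-of-infection model

The focal host's force of infection (FOI) is the sum of an intraspecific and
an interspecific term,

    FOI_F = β_FF · N_F^k_FF · (I_F/N_F) + β_FA · N_A^k_FA · (I_A/N_A),

with densities in snails per 0.1 m² throughout (converters `per_m2` /
`per_01m2` are provided; a single unit convention avoids silent 10× errors in
the power law, whose β scale depends on it). Each exponent `k` interpolates
between frequency dependence (`k = 0`, the term is β·I/N) and density
dependence (`k = 1`, the term is β·I). A species with zero density
contributes zero by definition — this avoids 0⁰ and 0/0 and is consistent
because I = 0 whenever N = 0.

Sentinel enclosure counts are modelled as trial-level binomials:
`n_infested ~ Binomial(n_exposed, 1 − exp(−FOI_F · t))` with `t` the trial
duration in days. The binomial form is the natural error model for caged
sentinel counts; nothing in the data identifies extra-binomial dispersion at
the trial level. Covariates for a trial are the same-week survey densities
averaged across sites, so the FOI is constant within a trial; a trial whose
week lacks focal or alternative observations raises a pairing error rather
than silently dropping data. Inside the likelihood the infestation
probability is clamped to [1e−12, 1 − 1e−12] so that boundary parameter
values (e.g. both β = 0 against nonzero counts) yield a very negative but
finite log-likelihood, keeping the sampler stable.

Priors are independent uniforms: β ∈ [0, 2] (2 is an extreme transmission
rate at these density scales) and k ∈ [0, 1]. The nested single-host model
fixes β_FA = 0 and is compared to the multi-host model by DIC.

## Contact-rate model

Expected contacts per focal snail over `T` observed minutes at partner
density `N` follow a Holling Type II functional response,

    μ(N) = e·T·N / (1 + e·H·(N − 1)),

where `e` is the encounter rate (min⁻¹ per unit density) and `H` the contact
handling time (minutes per contact), giving the saturation ceiling `T/H`.
The `(N − 1)` denominator term is kept from the intraspecific formulation
(the focal individual's single partner at N = 1 incurs no handling
competition, so μ(1) = e·T exactly); a `minus_one=False` flag switches to the
plain-`N` variant for sensitivity analysis. Container mean counts are
normal about μ with constant SD σ — the container mean is the unit of
analysis because snails within a container are not independent, and the
number of focal snails per container is carried but not used as a weight.
Priors: e ~ U(0, 1), H ~ U(0, 44) min, and σ ~ U(0, 20) (the response is a
mean of a handful of small counts over 45 min; 20 far exceeds any plausible
residual SD).

## Transmission-success analysis

Each replicate pairs one symbiont-loaded donor snail with one clean receiver
for 18 h. The dispersal response is replicate-level binomial: `on_receiver`
successes out of `on_donor + on_receiver` attached worms. Worms recovered
loose in cups, or missing entirely, never faced the donor-vs-receiver choice
and are excluded from that denominator; replicates with no attached worms
are excluded from fits and reported as such. The eight early 1 h replicates
are retained in the data model (flagged by `duration_hours`) but excluded
from model fits, which use only full-length trials.

The binomial GLM (logit link) has treatment, source, and their interaction;
the Poisson GLM (log link) models total recovered worms by treatment. Both
are fitted by IRLS (statsmodels.GLM) with Wald z-tests; coefficients
exceeding 15 in magnitude on the link scale are flagged as separation.
Reference levels default to treatment = intraspecific, source =
alternative_sourced; because the scientific contrast of interest (the
interspecific effect among focal-sourced worms, and the sign of the
interaction) reads most naturally against a focal-sourced baseline, a
`source_reference` switch re-parameterizes the same fit, and the pipeline
writes both. The fate-accounting table sums worms per treatment × source
cell by final location, floors per-replicate `missing` at zero and reports
reproduction surplus separately, since asexual reproduction during the trial
can push recoveries above additions.

Descriptive intervals are exact: Clopper–Pearson (beta quantiles) for
proportions and the chi-square/gamma construction for Poisson means — the
standard asymmetric exact choices.

## Bayesian engine

The sampler is a component-wise Gaussian random-walk Metropolis with
independent bounded-uniform priors, chosen for robustness on these 2–4
parameter posteriors rather than sophistication. Per-parameter step sizes
start at 10% of the prior range and adapt every 50 iterations during burn-in
toward a ~30% acceptance rate, then freeze, so retained draws form a valid
Markov chain. Parameters are sampled on their natural scale; proposals
outside the prior box are rejected. Chain `c` derives all its randomness
from one generator seeded with `seed + c`, making runs bit-reproducible.
Defaults are three chains × 30 000 iterations with 15 000 burn-in, and
convergence requires split-R̂ < 1.01 for every parameter (each chain is
halved before computing the between/within variance ratio; an all-constant
parameter returns 1 with a degeneracy flag).

DIC uses the classic posterior-mean plug-in: `D(θ) = −2 log L(θ)`,
`pD = mean(D) − D(θ̄)`, `DIC = D(θ̄) + 2·pD`, falling back to the posterior
median with a warning when the mean lies outside the likelihood's support.
DIC variants differ across tools, and the plug-in form can even yield small
negative pD for strongly skewed bounded posteriors; only DIC *orderings*
between nested models should be interpreted, not absolute values. Credible
intervals are equal-tailed quantile intervals with the posterior median as
the point estimate.

## Synthetic data

The generators draw data with exactly the structure the fits assume, with
one deliberate exception noted below.

- **Field season.** Weekly mean densities follow Gaussian bumps: the
  alternative host peaks early (18 snails/0.1 m² around week 5) and then
  persists at a 1.5 snails/0.1 m² baseline, the focal host peaks late (20
  around week 14), and infestation prevalence (shared by both species) peaks
  at 0.75 around week 16. Site-level counts are Poisson around the weekly
  mean and infested counts Binomial(N, prevalence). Sentinel infestations
  are Binomial draws with the FOI evaluated at the same site-averaged
  simulated densities the fit later uses. The late-season combination of
  *low* alternative density and *high* prevalence matters: exposure at
  N_A ≈ 1–2 identifies β_FA (N^k ≈ 1 regardless of k) while leaving k_FA
  essentially at its prior — the weak-identifiability structure the field
  system exhibits. Default FOI truth is β_FF = 0.10, k_FF = 1.0,
  β_FA = 0.01, k_FA = 0.5: dominant density-dependent intraspecific
  transmission with an order-of-magnitude weaker interspecific rate.
- **Contact experiment.** Densities 1–14, 16, 18 with three replicates
  each, 45 min observations, three focal snails per container; truth
  e = 0.012 min⁻¹, H = 3.25 min, σ = 1. Observations are normal about the
  Holling curve *truncated at zero*, since a mean contact count cannot be
  negative — a deliberate, slight deviation from the untruncated normal
  likelihood used in fitting, negligible at this signal-to-noise.
- **Transmission experiment.** Replicate counts (20, 21, 40, 49) across the
  four treatment × source cells, 10 worms per donor, 18 h. Each worm fails
  to attach (→ donor cup) with a per-cell probability — 0.24 where the donor
  species differs from the worms' source species, 0.01 where it matches,
  reflecting the host-preference attachment barrier — otherwise dies
  unobserved with probability 0.4, otherwise disperses with the cell's
  probability (0.32, 0.83, 0.08, 0.03). Optional reproduction adds Poisson
  offspring per attached worm (default off).

What the generators do **not** emulate: spatial heterogeneity among sites
beyond Poisson noise, week-to-week autocorrelation in prevalence, contact
overdispersion between containers (σ is the single noise knob), worm-level
dependence within a replicate beyond the binomial, and within-trial FOI
dynamics. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the assumed data-generating structure, not
robustness to real-field misspecification.

## Simulation-study problem sizes

Repeated-fit studies balance Monte Carlo fidelity against wall time, as a
package design choice: the contact-recovery study runs 25 experiments at the
full design with 3 × 4 000 (2 000 burn-in) chains; the FOI-recovery study
runs 25 seasons with 19 weekly trials of 40 sentinels and 3-day exposures at
3 × 8 000 (4 000) chains. Short exposures keep infestation probabilities off
the ceiling — week-long exposures under the default truth saturate
(p ≈ 1), which carries no information about how FOI scales with density and,
with the generating k_FF sitting on its prior boundary at 1, biases β_FF
upward along the β·N^k ridge. Single showcase fits (examples, pipeline
defaults, convergence checks) use the full 3 × 30 000 (15 000) settings.
Interval-coverage assertions use the ≥ 80%-of-25 criterion appropriate to
this replication level; the GLM interaction-sign study uses 100 simulations.

## Known limitations

- The FOI model is static per trial; no within-season SIR dynamics, no
  spatial structure among enclosure sites.
- k parameters near their generating boundary (0 or 1) are estimated with
  the one-sided bias inherent to bounded uniform priors; credible intervals
  for β remain approximately calibrated under informative designs but
  degrade when most trials saturate.
- DIC's plug-in pD is unreliable for the weakly identified 4-parameter
  model; use the comparison qualitatively.
- The binomial GLM treats attached worms within a replicate as independent
  given the replicate totals; overdispersion from worm clustering is not
  modelled.
- The CSV schemas are this package's canonical dialect; externally deposited
  data of the same shape need a one-off column-mapping step.
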