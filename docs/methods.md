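# Methods

## The problem

Hospital quality profiling in the United States compares 30-day
mortality rates against a national benchmark. Rates, however, carry a
geographic component: hospitals sit in climates that differ in disease
pressure (respiratory infection in cold dry winters, heat stress in hot
ones), and a hospital cannot choose its climate. `hospclimate`
implements a pipeline that (i) links hospitals to the dominant
Köppen-Geiger climate of their county, (ii) asks how much of the
between-hospital variation in 30-day mortality is attributable to
climate after adjusting for county socioeconomics, and (iii) re-scores
hospitals against climate peers instead of the nation.

## Geographic linkage

Hospitals carry ZIP codes; climates and socioeconomic covariates are
county-level. ZIPs resolve to 5-digit county FIPS codes through a
crosswalk table; a ZIP straddling county lines takes its designated
primary county (largest weight, else first row), with the ambiguity
counted. Counties that straddle a climate boundary carry several
Köppen-Geiger codes with proportions; the dominant (largest-share)
code is kept, ties broken lexicographically so the choice is
reproducible. Records that cannot be linked — unmapped ZIP, county
absent from the climate or ACS table — are excluded and counted, never
imputed: the provenance log satisfies `input = output + Σ removals` at
every stage, and tests enforce it.

The Köppen-Geiger classifier (used by the synthetic generator to keep
county climates internally consistent) implements the standard
threshold cascade on 12-month mean temperature (°C) and precipitation
(mm): polar E when the warmest month is below 10 °C (ET/EF split at
0 °C); otherwise arid B when annual precipitation falls below 10× the
dryness threshold (2·T̄ann, +28 when ≥ ⅔ of precipitation falls in
summer, +14 when neither season dominates; desert/steppe split at 5×;
h/k at 18 °C annual mean); otherwise A/C/D by the coldest month
(≥ 18 °C, above −3 °C, at or below −3 °C), with the usual s/w/f
dry-season letters and a/b/c/d temperature letters. Summer is Apr–Sep
in the northern hemisphere, Oct–Mar in the southern. The rare
equatorial summer-dry class (As) is folded into Aw by default, the
common convention in US county tables. Property tests check the
cascade is total and single-valued and that main-group guards evaluated
independently agree with the emitted class.

## Cohort filters

From the Hospital Compare-style flat file, only the six 30-day
mortality measures are kept (measure-ID prefix filter, configurable;
defaults are the `MORT_30_*` IDs of the 2015 annual release). Scores
are percentages; death counts are reconstructed as
`round(score × denominator / 100)`. For denominators under 1,000 and a
one-decimal printed score this inversion is exact; the observation
validator allows the half-count slack `max(0.05, 50/denominator)`
percentage points. Cells printed 'Not Available' are dropped (CMS
suppresses small or protected cells); hospitals with no available cell
are dropped; hospitals alone in their climate are dropped, because a
single hospital cannot inform a climate-level contrast. Each rule logs
its count.

## The hierarchical model

Each available hospital × measure cell is a binomial draw:

    deaths[hm] ~ Binomial(denominator[hm], p[hm])
    logit(p[hm]) = α_m + u_h + γ_{c(h)} + x_h·β

with measure intercepts α_m (baseline 30-day mortality differs by
condition), hospital effects u_h ~ Normal(0, σ_u), partially pooled
climate effects γ_c ~ Normal(0, σ_γ), and β on the six column-wise
z-scored county covariates (income log-transformed first — county
income is heavily right-skewed; the flag is exposed). Modelling counts
rather than published rates makes hospital size part of the likelihood:
a 60-patient denominator carries far more sampling noise than a
600-patient one, and the hierarchical prior shrinks its estimate
accordingly — small-climate effects shrink harder toward the grand
mean, which a test verifies on matched synthetic data.

Priors are weakly informative: Normal(0, 2.5) on α and β, half-Normal(1)
on σ_u and σ_γ. A fixed-effects climate option (γ_c ~ Normal(0, 2.5),
no σ_γ) and a Gaussian likelihood on the logit of the
continuity-corrected observed rate (`normal-on-logit-rate`) are exposed
for sensitivity analysis; the Gaussian variant deliberately lacks the
size-dependent sampling variance and exists to show what that
assumption buys.

**Identification.** Adding a constant to every γ_c (or every u_h) and
subtracting it from every α_m leaves the likelihood unchanged, as does
shifting u along any covariate column against β. Only contrasts are
likelihood-identified; the Gaussian priors pin the remainder. Climate
effects are therefore reported and tested on the recentred sum-to-zero
scale γ̃_c = γ_c − mean(γ). For the same reason the covariate estimand
in simulations is `beta_effective` — the generating coefficient times
the realized sample sd of the covariate — since the model fits
z-scores computed from the realized sample.

## Posterior computation

No general-purpose MCMC engine is part of the package's dependency
set; the sampler is purpose-built for this model's structure
(`_sampler.py`) and runs 4 chains of 2000 iterations (half warm-up) by
default, the convention of the standard Bayesian engines:

- **Partition blocks.** u, α and γ each partition the observation
  cells, so every component of a block is updated simultaneously with
  an independent random-walk Metropolis step (per-component scales
  adapted toward 0.44 acceptance during warm-up only, Robbins–Monro
  with gain t^−0.6).
- **β block.** Coordinate walks early in warm-up, then joint adaptive
  Metropolis using the running posterior covariance (2.38/√P scaling,
  global factor adapted toward 0.23).
- **Translation moves.** The likelihood-invariant (aliased) directions
  above are resolved by exact Gibbs draws of the shift under the
  Gaussian priors: α↔u, α↔γ, per-climate γ↔u, and the P-dimensional
  β↔u shift (u → u − Xδ, β → β + δ). These cost no likelihood
  evaluations and are what make the weakly identified blocks mix.
- **Scales.** σ_u, σ_γ (and σ_e for the Gaussian variant) use
  univariate slice sampling on the log scale, interleaved with joint
  rescaling moves that multiply a scale and its whole effect block by
  a common factor (the Gaussian prior and the Jacobian cancel, leaving
  the likelihood ratio times the half-Normal ratio) — these traverse
  the narrow-σ funnel that per-component walks cannot.

Chains are seeded `default_rng([seed, chain])`; identical seed, config
and library versions reproduce summaries exactly (tested). Convergence
is declared at max R-hat ≤ 1.05 and min bulk ESS ≥ 100 across all
blocks (arviz diagnostics); operations that require a converged fit
(effect tables, model comparison) refuse otherwise rather than
returning silently.

## Climate significance

The original analysis reports a p < 0.001 climate dependence without
stating the procedure, so the package operationalizes the question as
predictive model comparison: the model is fitted with and without the
climate block, expected log predictive density is estimated by WAIC
from pointwise log-likelihood draws, and the difference's standard
error comes from the pointwise contributions. "Climate matters" when
the no-climate model loses by more than two standard errors, or when
the 95% interval of σ_γ excludes values below 0.01 on the logit scale.
Operating characteristics are measured by simulation: with γ ≡ 0 the
climate model should rarely be preferred; with sd(γ) = 0.3 it should
usually be.

The one-way F-test (between/within mean-square ratio, p from
F(k−1, N−k)) is kept as the descriptive pre-model screen, computed from
explicit sums of squares with an optional denominator-weighted
variant; it operates on hospital-level observed rates, unweighted by
default, matching its descriptive role.

## Within-climate adjustment

The benchmark rate of a climate is the denominator-weighted pooled rate
`100·Σdeaths/Σdenominators` per measure (an unweighted mean-of-rates
option exists; the weighted default keeps small hospitals from
dominating the benchmark). A hospital's excess is its observed rate
(re-derived from counts, so the identity below is exact) minus its
climate benchmark; the denominator-weighted mean excess within every
climate is zero by construction, tested to 1e-10. Percentiles among
climate peers use the midrank convention and are suppressed below 5
peers. The national benchmark is carried alongside for contrast. When
only one climate is present the two benchmarks coincide exactly.

## Synthetic data: what it emulates, and what it does not

The generator draws counties nested in climates (one climate a forced
singleton by default, so the singleton filter always has work to do;
~30% of counties carry a secondary climate share to exercise the
dominant-climate rule), hospitals nested in counties, county confounder
z-scores with a climate-level component (association 0.5 by default,
so confounder adjustment demonstrably moves climate estimates),
log-normal denominators, binomial deaths from the logit model above,
and threshold suppression (denominator < 25 → 'Not Available').

Default study conditions: 600 hospitals, 150 counties, 8 climates, six
measures with per-condition baseline mortality (AMI 14%, CABG 3.3%,
COPD 8%, HF 12%, PN 16%, STK 15% — the scale of the published
condition-specific national rates), σ_u = 0.15, γ drawn Normal(0, 0.3)
then centred, β = (0.2, 0, 0, 0, 0, 0) on the z scale (income active,
the rest null, so both signal detection and null coverage are
exercised), denominators log-normal with median 200 (the scale implied
by per-hospital percentages over hundreds of patients), dispersion 0.7
split into a per-hospital size factor and per-measure jitter.

Deliberate departures from real data: no spatial geometry (counties are
exchangeable labels); printed scores are exactly count-consistent,
whereas CMS publishes model-based risk-standardized rates; suppression
is purely a denominator threshold, whereas CMS also suppresses for
reporting elections; denominators are top-coded at 999 so the
one-decimal printed score inverts to counts exactly; confounders are
independent across columns given climate. Passing tests therefore
demonstrate the pipeline's correctness and the estimator's calibration
under the stated generative model — not that real Hospital Compare
scores are count-consistent or that real confounding is this tame.

## Problem sizes in the harnesses

Parameter recovery runs 8 replicates at the full default conditions
(600 hospitals); per replicate the posterior-mean RMSE of γ̃ and β and
joint 95% interval coverage are recorded. Null/power operating
characteristics use 10 + 10 replicates at 400 hospitals and 120
counties, two fits each. These sizes are the package's chosen
simulation budget; the thresholds they are checked against (RMSE ≤ 0.1,
null preference ≤ 20%, power ≥ 80%, coverage at the nominal rate
within binomial tolerance) are fixed properties of the method, not of
the budget.

## Known limitations

- The per-component Metropolis scheme is efficient for this model
  family but model-specific: adding cross-classified effects (e.g.
  measure × climate interactions) would need new blocks and new
  translation moves.
- WAIC can be optimistic when pointwise contributions are heavy-tailed;
  the comparison reports its standard error and the σ_γ rule as a
  second line of evidence rather than a single p-value.
- Real-data reproduction of the published cohort (4,524 hospitals, 15
  climates, 2,373 counties) requires the archived 2015 release, a
  ZIP→FIPS crosswalk and an ACS extract; the pipeline accepts those
  files directly, but no external data ships with the package.
- County-level covariates and climates ignore within-county
  heterogeneity; hospitals inherit their county wholesale.
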