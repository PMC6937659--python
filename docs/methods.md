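# Methods

`fpsae` estimates subnational levels and trends of family-planning
indicators — modern contraceptive prevalence (mCPR), traditional-method
prevalence, unmet need, and the derived demand satisfied — from
individual-level records of complex household surveys. It follows the
two-stage small-area-estimation strategy used for subnational health
indicators: design-based direct estimation per area and survey, then
Bayesian hierarchical space-time smoothing of the logit-scale estimates.

## Stage 1 — design-based direct estimation

For each cell (area `a`, survey `c`, demographic subgroup, outcome) with
records `(y_i, w_i)`:

- Prevalence: Hájek ratio `p̂ = Σ w_i y_i / Σ w_i`. The ratio is invariant
  to the scale of the weights, so normalized release weights work unchanged.
- Variance: with-replacement between-PSU Taylor linearization. With score
  contributions `z_i = w_i (y_i − p̂)/Σw`, PSU totals are contrasted within
  strata: `V̂ = Σ_h n_h/(n_h−1) Σ_j (Z_hj − Z̄_h)²`. Single-PSU strata are
  collapsed with the adjacent stratum in sort order (configurable:
  `certainty` or `fail`).
- Logit scale: `y = logit(p̂)`, `V_y = V̂ / (p̂(1−p̂))²` (delta method).
  Estimates at 0 or 1 are first pulled in by half a pseudo-observation per
  effective sample, `p̃ = (p̂·n_eff + 0.5)/(n_eff + 1)` with
  `n_eff = p̂(1−p̂)/V̂`, and the variance floored at `p̃(1−p̃)/n_eff`; the
  row is flagged `adjusted`. Cells with fewer than `n_min = 10` records are
  dropped and logged — logit-scale asymptotics are meaningless there, not
  merely noisy.

Subgroups are all-women (default) or the four age-parity groups
(nulliparous/parous × 15–24/25+), each analyzed in its own full pipeline.

Stage 1 is approximately calibrated at realistic PSU counts: the test
suite checks that Wald intervals `p̂ ± 1.96√V̂` cover the frame truth for
90–98% of replicate surveys, and that the estimator is design-unbiased
under the PPS design. The residual few percent of z-score inflation comes
from treating the χ²-distributed `V̂` as known — inherent to the
pseudo-likelihood approach and worse the fewer PSUs per area.

## Stage 2 — latent Gaussian space-time model

The logit estimates are treated as Gaussian observations with known
variances (the stage-1 pseudo-likelihood):

    y_i ~ N(η_{a,t} + φ_{k} + ψ_{k,t} + ξ_{k,a}, V_{y,i})
    η_{a,t} = μ + α_t + e_t + s_a + v_a + δ_{a,t}

with, per block: `α` an intrinsic RW2 over calendar years (national trend),
`e` iid yearly shocks, `s` an intrinsic CAR (ICAR) over the area adjacency
graph, `v` iid area effects, `δ` a Knorr–Held type II interaction (an
independent RW2 per area; type IV, RW2 × ICAR, behind a flag), and
instrument effects: type `φ`, type-year `ψ`, type-area `ξ`. Each block has
precision `τ_b`; ICAR structures are scaled to unit generalized variance so
one prior on σ means the same thing on any graph.

Identifiability conventions (exact linear constraints `Cx = 0`):

- Sums: `α` and `e` sum to zero over the observed years, `s` per graph
  component, `v` over areas, `δ` per area over the observed years.
  Supporting the time constraints on *observed* years only removes the same
  flat directions but leaves forecast years free, so forecast variance
  grows with the horizon instead of being tied back by a grid-wide
  contrast.
- Trends: linear time trends are flat (unpenalized) directions of the RW2
  structure and must stay *representable*, not be pinned to zero. With the
  type II interaction on, each area's linear trend is a free flat direction
  of `δ` (these span the common trend too, so `α`'s trend direction is then
  constrained away to avoid a doubly flat, singular pair); without the
  interaction `α` keeps its trend free. Pinning the trends — a tempting
  reading of "remove the RW2 null space" — makes subnational trends
  unrepresentable and demonstrably destroys calibration.
- Instrument effects: `φ` is mean-zero across types, so `η` is the
  instrument-averaged truth. `ψ` (type-year) and `ξ` (type-area) exist only
  on cells the instrument actually fielded — a never-fielded cell is pinned
  to zero — and are centered within instrument over the observed cells.
  Without the support restriction a year shock can hide in `ψ` by
  compensating on data-free cells, collapsing the estimated year-shock
  variance and, with it, the uncertainty of unobserved years.

Because instrument effects are identified only as contrasts, a world in
which instruments carry absolute biases is fit up to the across-instrument
mean of those biases; the estimand of `η` is the instrument-averaged
population rate. Even restricted, `ψ` is genuinely non-separable from `e`
in years covered by a single instrument; fits that include `ψ` should read
its posterior as convention-resolved, and the calibration experiments use
the identified model without it.

Hyperpriors: penalized-complexity priors on each σ_b with
`P(σ_b > 1) = 0.01` (default), or Gamma(0.5, 5·10⁻⁴) on precisions.

### Inference

Blocked Gibbs MCMC:

1. `x | τ, y` — the full latent vector is jointly Gaussian; one exact draw
   via dense Cholesky of the sparse-assembled precision
   `P = Σ_b τ_b Q_b + AᵀV⁻¹A` (latent dimension ≤ ~900 at the default
   scenario, well inside dense range). Constraints are enforced by
   conditioning-by-kriging; the factorized matrix is `P + κCᵀC`, which on
   the constraint manifold equals `P` identically, so the constrained law
   is exact. This closed-form conditional doubles as the oracle the sampler
   is tested against.
2. `τ_b | x` — conjugate Gamma draw (Gamma family) or random-walk
   Metropolis on `log τ_b` (PC family) with per-block proposal sd
   `∝ √(2/rank_b)`; a global step size would freeze the high-rank blocks.
3. Interweaving (ASIS): a non-centered rescaling move per block — propose
   `σ'_b`, scale the block by `σ'_b/σ_b` with its whitened coordinates
   fixed, accept on the likelihood × prior ratio. The centered updates
   alone mix with autocorrelation times in the hundreds for
   high-dimensional blocks; interweaving brings hyperparameter effective
   sample sizes up by an order of magnitude at negligible cost.

Precisions are capped at `τ ≤ 10⁶` (σ ≥ 10⁻³): the PC prior's polynomial
tail in `τ` otherwise allows excursions to `τ ~ 10⁸` that numerically swamp
the flat trend directions in the joint factorization.

Forecast years (default horizon: one year past the last survey) carry
prior structure but no likelihood rows; their posterior variance grows
with the horizon.

Defaults: 4 chains × 5000 iterations, 2500 burn-in — appropriate for final
analyses; the validation experiments use reduced draw counts and note it.

## Model comparison

DIC, WAIC and the sum of log conditional predictive ordinates (LCPO), all
from the same draws × observations matrix of pointwise Gaussian
log-likelihoods (one observation = one direct-estimate row). The DIC
plug-in is evaluated at the posterior mean of the latent linear predictor
(the observation law is Gaussian in it). CPO uses the harmonic-mean
identity in log space, with a count of observations whose importance
weights are dominated by a single draw (max share > 0.5) reported as a
stability warning. No composite ranking is invented: models are ranked per
criterion (DIC/WAIC ascending, LCPO descending).

## Indicator summaries

Every summary transforms draws first and summarizes afterwards: inverse
logit per draw, then medians and central 95% intervals.

- Demand satisfied: `DS = m/(m + t + u)` per draw and cell, combining the
  three outcome fits by draw index. Draw-matching propagates uncertainty
  without asserting any cross-outcome posterior correlation (the outcomes
  are fitted separately).
- Annual rate of change between two years: `(p_to − p_from)/Δyears × 100`
  percentage points per year per draw and area, summarized with the
  posterior probability of a positive change. An area counts as a
  "significant increase" when the 95% interval lies above zero.
- National aggregates: population-weighted combinations of area draws,
  requiring an external table of women aged 15–49 per area.

## The synthetic world

Real inputs (DHS/MICS-style microdata) are access-gated, so validation
runs against simulated worlds with known truth:

- Latent surfaces are drawn from the model's own component priors
  (intrinsic draws sampled in the orthogonal complement of each null
  space), one surface per outcome.
- The sampling frame gives each area 2 strata × 40 clusters of 100–300
  women, with iid Normal(0, 0.3²) logit offsets per cluster — so design
  effects exceed 1 and design-based variance is genuinely different from
  binomial variance.
- Surveys sample 15 clusters per stratum by PPS with replacement (each hit
  an independent PSU) and take 25 women per hit; weights are inverse
  inclusion probabilities. The scale (30 PSUs, 750 women per area-survey)
  matches the order of real DHS/MICS state samples; far fewer PSUs would
  make the χ²-noise of `V̂` material and is *not* the regime the real
  instruments operate in.
- Outcomes are drawn as one 4-way categorical per woman (modern beats
  traditional beats unmet), guaranteeing the exclusivity invariants.
- The default multi-survey scenario mimics the Nigeria data landscape:
  37 areas, 15 years, ten rounds of four instrument types, with the
  PMA-like rounds covering six areas.

What a green calibration test establishes — and what it does not: the
calibration experiment draws each replicate's component sds from the
model's PC hyperprior and the latent field and instrument effects from the
model's own constrained priors, then pushes that truth through the full
two-stage survey machinery. That is the regime in which 95% credible
intervals have exact 95% frequentist coverage if every stage (simulator,
direct estimation, assembly, sampler, summaries) is correct, so the
experiment validates the machinery end-to-end; residual deviation reflects
the stage-1 idealization (a few percent of sd from treating `V̂` as known)
and finite chains. It does not certify 95% coverage at any *fixed*
parameter value (shrinkage priors trade coverage at fixed points for
precision; with truth at fixed sds, coverage of η sits measurably below
nominal, driven by unobserved years), and it cannot
certify behavior under real-data pathologies the generator omits:
nonresponse, frame undercoverage, respondent-reporting effects, or
instrument biases that are not additive on the logit scale.

The coverage estimand is the logit of the population-frame prevalence (the
size-weighted cluster average of inverse-logit rates — what design-unbiased
estimators converge to), not the latent `η_true`: with cluster
heterogeneity the two differ by a Jensen shift (~+0.04 logit at p ≈ 0.1).

## Numerical choices

- Boundary rule `(p̂·n_eff + 0.5)/(n_eff + 1)` ties the correction to the
  design effect through `n_eff`; with `V̂ = 0` the unweighted `n` is used.
- Structure-matrix null spaces are detected at eigenvalue tolerance 1e-9
  relative to the largest eigenvalue.
- The constraint system keeps full row rank by construction (one redundant
  two-way-centering row dropped per interaction block; type IV interaction
  constraints come from an orthonormal numerical null-space basis).
- τ updates use the constrained degrees of freedom (block size minus its
  constraint count) as the Gamma shape increment / density exponent.
- Draw medians and percentiles use the linear-interpolation convention of
  numpy; with degenerate draws all three summary points coincide.

## Known limitations

- The pseudo-likelihood treats design-based variances as known; with few
  PSUs per area this under-states uncertainty (a ~3% z-sd inflation at 30
  PSUs/area, worse below).
- `ψ` margins are only partially separable from `e` when a year is covered
  by a single instrument; the constraints resolve the aliasing by
  convention, not by information.
- No covariates, no spatially continuous model, no replicate-weight
  variance, no poststratification, and no derivation of the unmet-need
  flag from raw questionnaires (it enters as a given binary).
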