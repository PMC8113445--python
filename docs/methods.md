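# Methods

## The model

`traitlv` calibrates a temperature-dependent variant of the Lotka–Volterra
competition model for species-rich plant communities. The biomass `B_ij` of
species `i` in plot `j` with standardized mean temperature `θ_j` follows

    (1/B_ij) dB_ij/dt = g_i (θ_j − θmin_i) − c_i B_ij − l_i Σ_k B_kj

with four demographic parameters per species:

| parameter | meaning | units | sign |
|---|---|---|---|
| `θmin_i` | minimum temperature for positive intrinsic growth | standardized-temperature z-score | any |
| `g_i` | growth slope per unit standardized temperature | 1/time | > 0 |
| `c_i` | intraspecific competition rate | 1/(biomass·time) | > 0 |
| `l_i` | sensitivity to total surrounding biomass | 1/(biomass·time) | > 0 |

Interspecific competition acts only through the community total `Σ_k B_kj`
(which includes species `i` itself, so a species self-limits at total rate
`c_i + l_i`). This structure makes the system globally stable: there is a
unique feasible equilibrium for every parameter set, reached from any
positive initial condition. Observed communities are assumed to be at that
equilibrium, which is what lets static abundance data calibrate a dynamic
model.

### Equilibrium computation

Setting the growth rates to zero for a surviving set gives
`B_i = (r_i − l_i T)/c_i` with `r_i = g_i(θ − θmin_i)` and the community
total `T` solving `T = Σ_i (r_i − l_i T)/c_i`. A species survives iff its
invasion rate `r_i − l_i T` is positive, i.e. iff `r_i/l_i > T`. Sorting
species by `r_i/l_i` and growing the survivor set greedily (T increases
monotonically while added species can still invade) identifies the unique
consistent set in `O(S log S)` (`analytic_equilibrium`).

`integrate_to_equilibrium` is the dynamical route: adaptive LSODA
integration (rtol 1e-8, atol 1e-12) over a base span of `500 / median(g)`
time units. Near-marginal survivors relax at rate `≈ c_i B*_i`, which is
unbounded as `B*_i → 0`, so no fixed horizon is adequate for every
parameter draw; the solver therefore continues in doubling chunks until the
relative change of the composition vector over a chunk falls below 1e-6
(at most 12 doublings). Both routes are cross-checked against each other in
the test suite (worst observed relative biomass deviation ~1e-9, asserted
at 1e-4 over 100 random communities). The reported `residual` is the
largest per-capita rate among species above the extinction threshold
(relative abundance 1e-10); species being excluded keep a constant negative
per-capita rate forever and are instead assessed through their vanishing
abundance.

The likelihood uses the fixed-point route by default
(`LikelihoodConfig(equilibrium_method="analytic")`): it is exact, removes
any dependence on initial biomass, and is two orders of magnitude faster,
which keeps full calibrations on a single CPU in minutes. The ODE route
(`"ode"`, random initial biomass uniform on (0.1, 1) times the
single-species biomass scale, seed-controlled) remains available and is the
reference implementation in the dual-route tests.

## The transfer function

Rather than estimating `3S` demographic parameters directly, each of
`θmin`, `l`, `c` is a generalized linear function of `N = 3` orthogonal,
unit-variance trait axes. The regression coefficients are constrained to
the unit hypersphere and parameterized by `N−1` polar angles (`[0, π]` for
the first `N−2`, `[0, 2π]` for the last), giving the link scale

    E_im = Σ_n coef_n(φ_m) · t_in ,   ||coef|| = 1 .

With standardized orthogonal axes, `E_m` is again standard normal across
species, so the scale `a_m ≥ 0` and offset `b_m` control the across-species
mean and spread of the demographic parameter directly:

* `θmin_i = a·E_i + b` (linear — can be negative),
* `l_i, c_i = exp(a·E_i + b)` (log-linear — strictly positive).

This is mathematically equivalent to an ordinary linear regression on the
axes (the inverse polar transform `unit_vector_to_angles` reproduces any
unit coefficient vector with in-range angles, tested by round-trip), but it
decouples *direction* (angles, uninformative priors) from *magnitude*
(`a_m`, `b_m`, regularizing priors).

Two quantities are not identifiable from relative-abundance data and are
fixed: the shared growth slope `g = 10^−3.43` (it only rescales biomass and
time) and the competition offset `b_c = 10^−3.8` (shifting `b_c` and `b_l`
together rescales `c` and `l` jointly, which rescales absolute biomass but
leaves composition unchanged). The test suite verifies both invariances
explicitly. With `N = 3` this leaves 11 free parameters:
3 × 2 angles + `a_θmin`, `b_θmin`, `a_l`, `b_l`, `a_c`.

The exponent of the log-linear map is clipped at ±50 before
exponentiation: the regularizing priors make that region negligible, but
early sampler exploration visits it and would otherwise overflow.

## Trait preprocessing

Individual measurements are averaged per species; skewed traits are
log-transformed (isotopic ratios such as δ13C/δ15N, which can be negative,
are exempt); the species × trait matrix is summarized by a
correlation-matrix PCA (traits carry mixed units, so unit-scaling is the
only defensible default). The first `k = 3` score vectors are rescaled to
unit sample variance — required for the standard-normal link-scale property
— and given a deterministic sign (largest-magnitude loading positive) so
repeated runs are identical.

## Inference

Counts of a fixed number of individuals per plot (101 by default, a
typical transect effort) are modeled as multinomial draws with cell
probabilities equal to equilibrium relative biomass. The log-pmf is exact
(including the multinomial coefficient, so deviances and DIC are absolute);
probabilities are floored at 1e-300 inside the logarithm, and a species
observed at exactly zero probability yields −∞ (the proposal is rejected).

Priors: uniform on every angle over its geometric range; half-normal
(scale 1) on each `a_m`; normal on the free offsets, `b_θmin ~ N(0, 2)` (the
temperature covariate is a z-score) and `b_l ~ N(−5, 2)` (interspecific
sensitivity centered about an order of magnitude below the intraspecific
rate scale, keeping equilibria bounded at realistic richness). All
hyperparameters are exposed in `PriorSpec` and the YAML config.

The posterior is explored with a differential-evolution MCMC with
past-state archive and snooker updates (DEzs). Each independent chain group
holds three walkers and an archive `Z` (initialized with `max(30, 10 d)`
prior draws, appended with the walker states every 10 steps). Proposals are
`x + γ(1+e)(z1−z2)` with `γ = 2.38/√(2d)` (γ = 1 with probability 0.1 for
mode jumps, `e ~ U(−0.05, 0.05)`); with probability 0.1 a snooker move
proposes along the line through `x` and an archive point with the
`(|x*−z|/|x−z|)^{d−1}` Metropolis correction. Out-of-bounds
differential-evolution proposals are reflected at the parameter bounds
(symmetric, so detailed balance is preserved); out-of-bounds snooker
proposals are simply rejected by the prior. Runs are bit-reproducible from
the seed. The default run design for field-scale analyses is 8 independent
groups × 50 000 steps with the last 30% retained; the desk-scale recovery
harness uses 3 groups × 20 000 steps. Convergence is assessed with per-parameter and
multivariate (Brooks–Gelman) potential scale reduction factors, written by
`gelman_rubin` and cross-checked against `arviz.rhat` in the tests.

## Validation metrics

* **Nagelkerke pseudo-R²** against the hypothesis that all `S` modeled
  species have equal relative abundance in every plot;
  `n` is the number of sampled individuals in scope (all plots globally,
  one plot's effort per plot). Negative values flag plots where the model
  fits worse than the uniform null.
* **DIC** = `D(median) + 2 pD`, `pD = mean(D) − D(median)`, evaluated at the
  componentwise posterior median.
* **Null models**: the whole calibration re-run after shuffling the
  trait-axis rows jointly among species (preserves the inter-axis
  covariance, breaks the trait–abundance link; identity permutations are
  excluded, per-axis shuffling is available behind a flag).
* **AUC** of predicted equilibrium relative abundance against observed
  presence/absence, every plot × species cell scored separately.
* **Posterior trait–demography correlations**: Pearson correlations among
  `{θmin, l, c}` and against raw traits, rebuilt per posterior draw and
  summarized as median with a 95% credible interval; zero-variance vectors
  (e.g. a scale parameter of exactly 0) are reported as undefined.

## The synthetic study

`SyntheticScenario` defaults describe a desk-scale version of the field
design: `S = 40` species, `J = 12` plots, `N = 3` axes, 101 individuals per
plot, raw temperatures evenly spaced over 4.55–8.26 °C and standardized.
Axes are column-centered QR-orthogonalized standard normals rescaled to
unit variance (the preprocessing contract, exactly). The true transfer
function encodes a stress-dominance pattern: `θmin` and `l` load on trait
directions correlated at about −0.5, so cold-adapted species are
stress-tolerant but competition-sensitive, and species turn over along the
gradient (per-plot richness rises from ~5 at the cold end to ~35 at the
warm end). The directions are deliberately *not* antipodal: with effort 101
per plot, near-antipodal directions make `θmin`-threshold exclusion and
`l`-driven exclusion nearly confounded (likelihood profiling shows a long
flat ridge), whereas at −0.5 the two mechanisms remain separable and the
full transfer function is recovered.

What the generator does *not* emulate: intraspecific trait variability,
measurement error in traits, non-equilibrium communities, spatial coupling
between plots, and transect-sampling bias toward dominant species. Passing
recovery tests therefore show the estimator is correct *under the model's
own assumptions*, not that those assumptions hold for any particular field
system.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: recovery uses 3 chain
groups × 20 000 steps (≈ 4 minutes), null-discrimination replicates 1 group
× 4 000 steps (≈ 30 s per real/null pair). The 8 × 50 000 design remains
the default of the `calibrate` CLI for real analyses. Angle wraparound in
the last (2π-periodic) angle is avoided in the default truth by placing it
mid-range. Ties in the survivor search are resolved by the greedy prefix
rule; a community where no species is viable is returned as a flagged
degenerate state (and is a structured error in the data generator).

## Known limitations

* `g` is shared across species by construction (only its product with time
  is observable from static data); temporal data would be needed to free it.
* The multinomial likelihood ignores overdispersion and spatial
  autocorrelation within transects.
* The fixed-point solver assumes the single-total-biomass interaction
  structure; a general interaction matrix would need the ODE route (and
  would not be globally stable in general).
* DIC point evaluation at the componentwise posterior median can sit off
  the ridge for strongly curved posteriors; the deviance trace is stored so
  alternative point estimates can be computed from the posterior CSV.
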