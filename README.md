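# traitlv

Calibrating process-based community models in species-rich ecosystems is
normally blocked by a parameter explosion: a Lotka–Volterra model of `S`
species needs `O(S)`–`O(S²)` demographic rates that nobody can measure for a
hundred-species grassland. `traitlv` implements an inverse-modeling solution:
species' demographic parameters are not estimated one by one but predicted
from a few functional-trait axes through a low-dimensional **transfer
function**, whose handful of parameters are calibrated against static
community abundance data by MCMC. The package is aimed at community
ecologists who have (i) a species × trait table, (ii) plot × species
individual counts at fixed sampling effort along an environmental gradient,
and optionally (iii) presence/absence surveys for validation.

## The model

Biomass dynamics of species `i` in plot `j` with standardized temperature
`θ_j`:

    (1/B_ij) dB_ij/dt = g_i (θ_j − θmin_i) − c_i B_ij − l_i Σ_k B_kj

Interspecific competition acts through the community total, which makes the
system globally stable; observed communities are treated as its equilibrium.
Each of `θmin`, `l`, `c` is a generalized linear function of `N = 3`
orthogonal trait axes with unit-norm coefficients parameterized by polar
angles, plus a scale `a_m ≥ 0` and offset `b_m`:

    E_im = coef(φ_m) · t_i ,   θmin_i = a E_i + b ,   l_i, c_i = exp(a E_i + b)

`g` (shared) and `b_c` are fixed (`10^−3.43`, `10^−3.8`): they are not
identifiable from relative abundances. That leaves **11 free parameters**
for `3S` demographic rates. The likelihood is multinomial — each sampled
individual belongs to species `i` with probability equal to its equilibrium
relative biomass — and the posterior is explored with a
differential-evolution MCMC with past-state archive and snooker updates
(DEzs). Fit quality is judged by Nagelkerke pseudo-R² and DIC against
trait-shuffled null calibrations, and by presence/absence AUC. See
`docs/methods.md` for the full account.

## Worked example

Simulate a synthetic study (40 species, 12 plots, 101 individuals/plot,
known transfer function), calibrate it, and compare against the truth:

```sh
traitlv recover -S 40 -J 12 --chains 3 --steps 20000 --seed 1 -o out/recover
```

which prints (about four minutes on one CPU):

```json
{
  "demography_correlations": {
    "theta_min": 0.9999229686579714,
    "l": 0.9893949201496879,
    "c": 0.9818676006826367
  },
  "coverage_count": 11,
  "mpsrf": 1.074642217160825,
  "dic_real": 1056.1877129667705,
  "dic_null": 2736.284729842241
}
```

Reading: the posterior-median demographic parameter vectors correlate with
the generating truth at r ≈ 0.98–1.00 across the 40 species; all 11 true
transfer-function parameters fall inside their 95% credible intervals; the
multivariate Gelman–Rubin factor is close to 1 (chains converged); and the
calibration using the real trait axes fits the counts far better
(DIC 1056) than the same machinery given trait axes shuffled among species
(DIC 2736) — the trait signal, not model flexibility, carries the fit.

The same pipeline runs on real CSV inputs through a YAML config:

```sh
traitlv calibrate -c run.yaml        # posterior.csv + demography_median.csv
traitlv validate -c run.yaml --posterior out/posterior.csv   # R², DIC, AUC
traitlv nullmodels -c run.yaml -n 200                        # null ensemble
```

`run.yaml` names the traits/sites/counts (and optional occurrences) CSVs and
may override priors, solver tolerances, and MCMC settings; every command
writes a JSON manifest so a run is reconstructible from its outputs.

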