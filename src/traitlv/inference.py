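"""Bayesian calibration of the transfer function from community counts.

The data are multinomial samples of a fixed number of individuals per plot
(101 by default, a typical transect effort); each species' sampling
probability is its relative biomass at the model equilibrium for that
plot's temperature.
The posterior over the free transfer-function parameters (uniform priors on
the angles, regularizing priors on the scales and offsets) is explored with
a differential-evolution MCMC sampler that proposes jumps from a thinned
archive of past states (DEzs: ter Braak & Vrugt 2008), including snooker
updates.  The growth slope ``g`` and the competition offset ``b_c`` are not
identifiable from relative abundances (rescaling ``c`` and ``l`` jointly
rescales biomass but not composition, and ``g`` only sets the time unit), so
both are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import halfnorm, norm

from .errors import DimensionError, InvalidValueError, TraitLVError
from .model_core import (
    DemographicParams,
    SiteTable,
    SolverConfig,
    analytic_equilibrium,
    integrate_to_equilibrium,
)
from .transfer import (
    B_C_FIXED_DEFAULT,
    G_FIXED_DEFAULT,
    TraitAxes,
    TransferParams,
    build_demography,
)

# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySample:
    """Plot-by-species individual counts with fixed per-plot effort."""

    plot_id: np.ndarray
    species_id: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "plot_id", np.asarray(self.plot_id))
        object.__setattr__(self, "species_id", np.asarray(self.species_id))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.plot_id), len(self.species_id)):
            raise DimensionError("counts must be a plot x species matrix")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
                raise InvalidValueError("counts must be nonnegative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def effort(self) -> np.ndarray:
        """Total individuals sampled per plot."""
        return self.counts.sum(axis=1)

    @property
    def n_plots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=self.species_id)
        df.insert(0, "plot_id", self.plot_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CommunitySample":
        df = pd.read_csv(path)
        species = [c for c in df.columns if c != "plot_id"]
        return cls(
            plot_id=df["plot_id"].to_numpy(),
            species_id=np.asarray(species),
            counts=df[species].to_numpy(),
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_P_FLOOR = 1e-300


def multinomial_loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Exact log multinomial pmf, including the multinomial coefficient.

    Probabilities are floored at 1e-300 inside the logarithm only; a species
    observed (count > 0) at exactly zero probability yields ``-inf`` (the
    data are impossible under the parameterization).
    """
    counts = np.asarray(counts)
    p = np.asarray(p, dtype=float)
    if counts.shape != p.shape:
        raise DimensionError("counts and p must have the same length")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise InvalidValueError("counts must be nonnegative integers")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise InvalidValueError("p must be nonnegative and sum to 1 within 1e-9")
    counts = counts.astype(np.int64)
    if np.any((counts > 0) & (p == 0.0)):
        return -np.inf
    n = counts.sum()
    coeff = gammaln(n + 1) - gammaln(counts + 1).sum()
    return float(coeff + (counts * np.log(np.maximum(p, _P_FLOOR))).sum())


def uniform_null_loglik(sample: CommunitySample) -> float:
    """Log-likelihood of equal relative abundance over the modeled pool."""
    p = np.full(sample.n_species, 1.0 / sample.n_species)
    return sum(multinomial_loglik(row, p) for row in sample.counts)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors on the free transfer-function parameters.

    Angles get uniform priors over their geometric ranges.  The scales
    ``a_m`` get half-normal priors and the free offsets ``b_m`` normal
    priors; these regularize the across-species mean and spread of the
    demographic parameters (which ``a_m``/``b_m`` control directly), keeping
    equilibria bounded without informing the trait-demography directions.
    """

    n_axes: int = 3
    a_scale: dict = field(default_factory=lambda: {
        "a_theta_min": 1.0, "a_l": 1.0, "a_c": 1.0,
    })
    b_loc: dict = field(default_factory=lambda: {"b_theta_min": 0.0, "b_l": -5.0})
    b_scale: dict = field(default_factory=lambda: {"b_theta_min": 2.0, "b_l": 2.0})

    @property
    def n_free(self) -> int:
        return 3 * (self.n_axes - 1) + 5

    @property
    def param_names(self) -> list[str]:
        return TransferParams.param_names(self.n_axes)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) support bounds per free parameter."""
        k = self.n_axes - 1
        lo, hi = [], []
        for _m in range(3):
            lo += [0.0] * k
            hi += [np.pi] * (k - 1) + [2 * np.pi]
        lo += [0.0, -np.inf, 0.0, -np.inf, 0.0]
        hi += [np.inf] * 5
        return np.array(lo), np.array(hi)

    def log_density(self, vec: np.ndarray) -> float:
        vec = np.asarray(vec, dtype=float)
        if vec.shape[0] != self.n_free:
            raise DimensionError("parameter vector length does not match prior")
        lo, hi = self.bounds()
        if np.any(vec < lo) or np.any(vec > hi) or not np.all(np.isfinite(vec)):
            return -np.inf
        k = self.n_axes - 1
        # uniform angles: first k-1 over [0, pi], last over [0, 2 pi], x3
        lp = -3.0 * ((k - 1) * np.log(np.pi) + np.log(2 * np.pi))
        a_tm, b_tm, a_l, b_l, a_c = vec[3 * k:]
        lp += halfnorm.logpdf(a_tm, scale=self.a_scale["a_theta_min"])
        lp += halfnorm.logpdf(a_l, scale=self.a_scale["a_l"])
        lp += halfnorm.logpdf(a_c, scale=self.a_scale["a_c"])
        lp += norm.logpdf(b_tm, self.b_loc["b_theta_min"], self.b_scale["b_theta_min"])
        lp += norm.logpdf(b_l, self.b_loc["b_l"], self.b_scale["b_l"])
        return float(lp)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        k = self.n_axes - 1
        out = np.empty((size, self.n_free))
        col = 0
        for _m in range(3):
            for j in range(k):
                width = np.pi if j < k - 1 else 2 * np.pi
                out[:, col] = rng.uniform(0, width, size)
                col += 1
        out[:, col] = np.abs(rng.normal(0, self.a_scale["a_theta_min"], size))
        out[:, col + 1] = rng.normal(self.b_loc["b_theta_min"],
                                     self.b_scale["b_theta_min"], size)
        out[:, col + 2] = np.abs(rng.normal(0, self.a_scale["a_l"], size))
        out[:, col + 3] = rng.normal(self.b_loc["b_l"], self.b_scale["b_l"], size)
        out[:, col + 4] = np.abs(rng.normal(0, self.a_scale["a_c"], size))
        return out


# ---------------------------------------------------------------------------
# posterior target
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LikelihoodConfig:
    """How equilibria are computed inside the likelihood.

    ``equilibrium_method="analytic"`` (default) evaluates the fixed point
    directly; ``"ode"`` integrates the ODE from random positive biomass with
    a per-run seed (global stability makes the start immaterial).
    """

    equilibrium_method: str = "analytic"
    solver_cfg: SolverConfig = field(default_factory=SolverConfig)
    b0_seed: int = 0
    g_value: float = G_FIXED_DEFAULT
    b_c_value: float = B_C_FIXED_DEFAULT


@dataclass(frozen=True)
class LogPosteriorResult:
    log_posterior: float
    log_likelihood: float
    log_prior: float
    equilibria: tuple  # per-plot EquilibriumState


def _plot_equilibria(params: DemographicParams, thetas: np.ndarray,
                     cfg: LikelihoodConfig) -> list:
    states = []
    for j, th in enumerate(thetas):
        if cfg.equilibrium_method == "analytic":
            states.append(analytic_equilibrium(params, th))
        elif cfg.equilibrium_method == "ode":
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=cfg.b0_seed, spawn_key=(j,)))
            states.append(integrate_to_equilibrium(
                params, th, solver_cfg=cfg.solver_cfg, rng=rng))
        else:
            raise InvalidValueError(
                f"unknown equilibrium method {cfg.equilibrium_method!r}")
    return states


def log_posterior(
    tp: TransferParams,
    axes: TraitAxes,
    sites: SiteTable,
    sample: CommunitySample,
    prior: PriorSpec,
    cfg: LikelihoodConfig | None = None,
) -> LogPosteriorResult:
    """Log posterior of one transfer parameterization, with cached equilibria."""
    cfg = cfg or LikelihoodConfig()
    if sample.n_species != axes.n_species:
        raise DimensionError("community sample and trait axes species counts differ")
    if sample.n_plots != sites.n_plots:
        raise DimensionError("community sample and site table plot counts differ")
    lp_prior = prior.log_density(tp.to_vector())
    if not np.isfinite(lp_prior):
        return LogPosteriorResult(-np.inf, np.nan, -np.inf, ())
    params = build_demography(tp, axes)
    try:
        states = _plot_equilibria(params, sites.theta, cfg)
    except TraitLVError:
        return LogPosteriorResult(-np.inf, np.nan, lp_prior, ())
    ll = 0.0
    for state, row in zip(states, sample.counts):
        ll += multinomial_loglik(row, state.rel_abundance) if not state.degenerate \
            else (-np.inf if row.sum() > 0 else 0.0)
        if not np.isfinite(ll):
            ll = -np.inf
            break
    return LogPosteriorResult(ll + lp_prior, ll, lp_prior, tuple(states))


def make_target(
    axes: TraitAxes,
    sites: SiteTable,
    sample: CommunitySample,
    prior: PriorSpec,
    cfg: LikelihoodConfig | None = None,
) -> Callable[[np.ndarray], tuple[float, float]]:
    """Fast flat-vector posterior target for the sampler.

    Returns a callable mapping the 11-vector of free parameters to
    ``(log_posterior, log_likelihood)``.
    """
    cfg = cfg or LikelihoodConfig()

    def target(vec: np.ndarray) -> tuple[float, float]:
        lp_prior = prior.log_density(vec)
        if not np.isfinite(lp_prior):
            return -np.inf, np.nan
        tp = TransferParams.from_vector(vec, prior.n_axes,
                                        g_value=cfg.g_value, b_c_value=cfg.b_c_value)
        res = log_posterior(tp, axes, sites, sample, prior, cfg)
        return res.log_posterior, res.log_likelihood

    return target


# ---------------------------------------------------------------------------
# DEzs sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZConfig:
    """Archive settings of the DEzs sampler."""

    m0: int | None = None          # initial archive rows (default max(30, 10 d))
    update_every: int = 10         # append walkers to Z every this many steps
    snooker_prob: float = 0.1
    gamma_jump_prob: float = 0.1   # probability of a gamma = 1 mode-jumping move
    jitter: float = 0.05           # multiplicative jitter on the DE step
    boundary: str = "reflect"      # "reflect" or "reject" for out-of-bounds DE moves


@dataclass
class PosteriorSample:
    """MCMC output: all iterations of every walker, plus traces and metadata.

    ``draws`` has shape (iterations, walkers, d) where walkers pools the 3
    internal walkers of each independent DEzs group.  Post-burn-in draws are
    obtained with :meth:`retained`.
    """

    draws: np.ndarray
    log_posterior: np.ndarray
    log_likelihood: np.ndarray
    param_names: list[str]
    seed: int | None
    n_groups: int
    burn_fraction: float = 0.7
    meta: dict = field(default_factory=dict)

    @property
    def deviance(self) -> np.ndarray:
        return -2.0 * self.log_likelihood

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[0]

    def _burn_index(self, burn_fraction: float | None) -> int:
        frac = self.burn_fraction if burn_fraction is None else burn_fraction
        return int(np.floor(frac * self.n_iterations))

    def retained(self, burn_fraction: float | None = None) -> np.ndarray:
        """Post-burn-in draws flattened to (samples, d)."""
        i0 = self._burn_index(burn_fraction)
        return self.draws[i0:].reshape(-1, self.draws.shape[2])

    def retained_chains(self, burn_fraction: float | None = None) -> np.ndarray:
        i0 = self._burn_index(burn_fraction)
        return self.draws[i0:]

    def retained_deviance(self, burn_fraction: float | None = None) -> np.ndarray:
        i0 = self._burn_index(burn_fraction)
        return self.deviance[i0:].ravel()

    def median_vector(self, burn_fraction: float | None = None) -> np.ndarray:
        """Componentwise posterior median of the free parameters."""
        return np.median(self.retained(burn_fraction), axis=0)

    def credible_intervals(self, level: float = 0.95,
                           burn_fraction: float | None = None) -> np.ndarray:
        q = np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        return np.quantile(self.retained(burn_fraction), q, axis=0).T

    def to_frame(self, burn_fraction: float | None = None) -> pd.DataFrame:
        i0 = self._burn_index(burn_fraction)
        it, ch, d = self.draws.shape
        rows = []
        for c in range(ch):
            df = pd.DataFrame(self.draws[i0:, c, :], columns=self.param_names)
            df.insert(0, "iteration", np.arange(i0, it))
            df.insert(0, "chain", c)
            df["log_posterior"] = self.log_posterior[i0:, c]
            df["deviance"] = self.deviance[i0:, c]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path, burn_fraction: float | None = None) -> None:
        self.to_frame(burn_fraction).to_csv(path, index=False)


_N_WALKERS = 3  # internal walkers per DEzs group


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold a proposal back into [lo, hi] (preserves proposal symmetry)."""
    x = x.copy()
    for _ in range(100):
        below, above = x < lo, x > hi
        if not (below.any() or above.any()):
            return x
        x[below] = 2 * lo[below] - x[below]
        x[above] = 2 * hi[above] - x[above]
    return np.clip(x, lo, hi)  # pathological proposal far outside the box


def _normalize_target(target) -> Callable[[np.ndarray], tuple[float, float]]:
    def wrapped(x):
        out = target(x)
        if isinstance(out, tuple):
            return float(out[0]), float(out[1])
        return float(out), float(out)
    return wrapped


def run_dezs(
    target: Callable,
    n_chains: int = 3,
    steps: int = 10000,
    z_config: ZConfig | None = None,
    seed: int | None = None,
    init_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    initial: np.ndarray | None = None,
    d: int | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    param_names: Sequence[str] | None = None,
    burn_fraction: float = 0.7,
) -> PosteriorSample:
    """Differential-evolution MCMC with past-state archive and snooker moves.

    ``n_chains`` independent DEzs groups are run sequentially, each holding
    three internal walkers and its own archive Z.  Proposals are
    ``x + gamma (1+e) (z1 - z2)`` with ``gamma = 2.38 / sqrt(2 d)`` (gamma = 1
    with a small probability, enabling mode jumps) and ``z1, z2`` drawn from
    the archive; with probability ``snooker_prob`` a snooker move proposes
    along the line through ``x`` and an archive point, with the
    ``|x*-z|^(d-1)/|x-z|^(d-1)`` Metropolis correction.  Walkers are appended
    to the archive every ``update_every`` steps.  Out-of-bounds DE proposals
    are reflected at the bounds (symmetric); out-of-bounds snooker proposals
    are left for the prior to reject.

    ``target`` maps a parameter vector to either a log-density or a
    ``(log_posterior, log_likelihood)`` pair.  Runs are bit-reproducible for
    a given seed.
    """
    zc = z_config or ZConfig()
    tgt = _normalize_target(target)

    if initial is None and init_sampler is None:
        raise InvalidValueError("provide `initial` walkers or an `init_sampler`")
    if initial is not None:
        initial = np.asarray(initial, dtype=float)
        d = initial.shape[-1]
    if d is None:
        raise InvalidValueError("dimension d could not be inferred")
    m0 = zc.m0 if zc.m0 is not None else max(30, 10 * d)
    if bounds is not None:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    gamma_de = 2.38 / np.sqrt(2.0 * d)

    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(n_chains)

    all_draws = np.empty((steps, n_chains * _N_WALKERS, d))
    all_lp = np.empty((steps, n_chains * _N_WALKERS))
    all_ll = np.empty((steps, n_chains * _N_WALKERS))
    n_accept = 0

    for gi in range(n_chains):
        rng = np.random.default_rng(group_seeds[gi])

        def draw_start(n):
            if init_sampler is not None:
                return np.asarray(init_sampler(rng, n), dtype=float).reshape(n, d)
            idx = rng.integers(0, initial.shape[0], size=n)
            return initial[idx] + 1e-6 * rng.standard_normal((n, d))

        # archive and walkers
        Z = list(draw_start(m0))
        X = np.empty((_N_WALKERS, d))
        lp = np.full(_N_WALKERS, -np.inf)
        ll = np.full(_N_WALKERS, np.nan)
        for w in range(_N_WALKERS):
            for _try in range(200):
                x0 = draw_start(1)[0]
                lp0, ll0 = tgt(x0)
                if np.isfinite(lp0):
                    X[w], lp[w], ll[w] = x0, lp0, ll0
                    break
            else:
                raise TraitLVError(
                    "could not find a finite-posterior start after 200 draws; "
                    "check the prior support and the equilibrium solver"
                )

        for it in range(steps):
            for w in range(_N_WALKERS):
                x = X[w]
                use_snooker = rng.random() < zc.snooker_prob
                log_corr = 0.0
                if use_snooker:
                    idx = rng.choice(len(Z), size=3, replace=False)
                    z, z1, z2 = Z[idx[0]], Z[idx[1]], Z[idx[2]]
                    dvec = x - z
                    nrm = np.linalg.norm(dvec)
                    if nrm < 1e-300:
                        continue  # degenerate direction; stay put this move
                    dhat = dvec / nrm
                    gamma_s = rng.uniform(1.2, 2.2)
                    xprop = x + gamma_s * ((z1 - z2) @ dhat) * dhat
                    nrm_new = np.linalg.norm(xprop - z)
                    if nrm_new < 1e-300:
                        continue
                    log_corr = (d - 1) * (np.log(nrm_new) - np.log(nrm))
                else:
                    idx = rng.choice(len(Z), size=2, replace=False)
                    z1, z2 = Z[idx[0]], Z[idx[1]]
                    gamma = 1.0 if rng.random() < zc.gamma_jump_prob else gamma_de
                    e = rng.uniform(-zc.jitter, zc.jitter)
                    xprop = x + gamma * (1.0 + e) * (z1 - z2)
                    if bounds is not None and zc.boundary == "reflect":
                        xprop = _reflect(xprop, lo, hi)
                lp_new, ll_new = tgt(xprop)
                if np.isfinite(lp_new):
                    log_alpha = lp_new - lp[w] + log_corr
                    if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
                        X[w], lp[w], ll[w] = xprop, lp_new, ll_new
                        n_accept += 1
            if (it + 1) % zc.update_every == 0:
                Z.extend(X.copy())
            cols = slice(gi * _N_WALKERS, (gi + 1) * _N_WALKERS)
            all_draws[it, cols] = X
            all_lp[it, cols] = lp
            all_ll[it, cols] = ll

    return PosteriorSample(
        draws=all_draws, log_posterior=all_lp, log_likelihood=all_ll,
        param_names=list(param_names) if param_names is not None
        else [f"p{i}" for i in range(d)],
        seed=seed, n_groups=n_chains, burn_fraction=burn_fraction,
        meta={
            "steps": steps,
            "acceptance_rate": n_accept / (steps * n_chains * _N_WALKERS),
            "z_config": zc.__dict__.copy(),
        },
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> tuple[np.ndarray, float]:
    """Potential scale reduction factors from (iterations, chains, d) draws.

    Returns per-parameter psrf and the multivariate psrf of Brooks & Gelman.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    n, m, d = chains.shape
    if m < 2 or n < 10:
        raise InvalidValueError("need >= 2 chains and >= 10 retained draws")
    means = chains.mean(axis=0)                      # (m, d)
    W = chains.var(axis=0, ddof=1).mean(axis=0)      # (d,)
    B = n * means.var(axis=0, ddof=1)                # (d,)
    if np.any(W <= 0):
        raise InvalidValueError("zero within-chain variance; psrf undefined")
    var_hat = (n - 1) / n * W + B / n
    psrf = np.sqrt(var_hat / W)

    # multivariate: largest eigenvalue of W_mat^{-1} B_mat / n
    centered = chains - means[None, :, :]
    W_mat = np.einsum("nmi,nmj->ij", centered, centered) / (m * (n - 1))
    gmean = means.mean(axis=0)
    dm = means - gmean
    B_mat = n * np.einsum("mi,mj->ij", dm, dm) / (m - 1)
    try:
        lam = np.linalg.eigvals(np.linalg.solve(W_mat, B_mat / n))
        lam1 = float(np.max(lam.real))
    except np.linalg.LinAlgError as exc:
        raise InvalidValueError("singular within-chain covariance") from exc
    mpsrf = float(np.sqrt((n - 1) / n + (m + 1) / m * lam1))
    return psrf, mpsrf


# ---------------------------------------------------------------------------
# full calibration convenience wrapper
# ---------------------------------------------------------------------------

def calibrate(
    axes: TraitAxes,
    sites: SiteTable,
    sample: CommunitySample,
    prior: PriorSpec | None = None,
    cfg: LikelihoodConfig | None = None,
    n_chains: int = 8,
    steps: int = 50000,
    burn_fraction: float = 0.7,
    seed: int | None = None,
    z_config: ZConfig | None = None,
) -> PosteriorSample:
    """Run the full calibration: target construction + DEzs sampling.

    Defaults target a field-scale analysis (8 independent chains of
    50000 steps, the last 30% retained).
    """
    prior = prior or PriorSpec()
    cfg = cfg or LikelihoodConfig()
    target = make_target(axes, sites, sample, prior, cfg)
    return run_dezs(
        target, n_chains=n_chains, steps=steps, z_config=z_config, seed=seed,
        init_sampler=lambda rng, n: prior.sample(rng, n),
        d=prior.n_free, bounds=prior.bounds(),
        param_names=prior.param_names, burn_fraction=burn_fraction,
    )
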