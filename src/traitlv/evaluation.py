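"""Model validation: pseudo-R2, DIC, trait-shuffling null models, AUC,
posterior trait-demography correlations.

Fit quality is judged against the hypothesis that every species in the
modeled pool has equal relative abundance in every plot.  Nagelkerke's
pseudo-R2 normalizes the likelihood ratio by the sampling effort; the DIC
penalizes posterior mean deviance by the effective parameter count.  Null
models re-run the whole calibration after shuffling the trait-axis rows
among species, which preserves the trait covariance structure while breaking
the trait-abundance link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DataError, DimensionError, InvalidValueError
from .inference import (
    CommunitySample,
    LikelihoodConfig,
    PosteriorSample,
    PriorSpec,
    log_posterior,
    multinomial_loglik,
)
from .model_core import EXTINCTION_TOL, SiteTable
from .traits import TraitTable
from .transfer import TraitAxes, TransferParams, build_demography


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R2 of a model against a null log-likelihood.

    ``n`` is the number of sampled individuals in scope (all plots for the
    global value, one plot's effort for a per-plot value).  Values are <= 1;
    negative values flag a model fitting worse than the equal-abundance
    null.
    """
    if n <= 0:
        raise InvalidValueError("n must be positive")
    if loglik_null >= 0:
        raise InvalidValueError("degenerate null likelihood (loglik_null >= 0)")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_model))
    max_r2 = 1.0 - np.exp((2.0 / n) * loglik_null)
    return float(cox_snell / max_r2)


def dic(deviance_draws: np.ndarray, deviance_at_point: float) -> float:
    """Deviance information criterion with pD = mean(D) - D(point).

    The point estimate is evaluated at the posterior median parameter
    vector by the callers in this package.
    """
    draws = np.asarray(deviance_draws, dtype=float)
    if draws.size < 2:
        raise InvalidValueError("need at least two deviance draws")
    if not (np.all(np.isfinite(draws)) and np.isfinite(deviance_at_point)):
        raise InvalidValueError("non-finite deviance values")
    p_d = draws.mean() - deviance_at_point
    return float(deviance_at_point + 2.0 * p_d)


@dataclass(frozen=True)
class FitMetrics:
    pseudo_r2_global: float
    pseudo_r2_per_plot: np.ndarray
    dic: float
    deviance_at_median: float
    p_d: float
    mean_deviance: float


def fit_metrics(
    post: PosteriorSample,
    axes: TraitAxes,
    sites: SiteTable,
    sample: CommunitySample,
    prior: PriorSpec,
    cfg: LikelihoodConfig | None = None,
) -> FitMetrics:
    """Pseudo-R2 (global and per plot, at the posterior median) and DIC."""
    cfg = cfg or LikelihoodConfig()
    med = post.median_vector()
    tp = TransferParams.from_vector(med, prior.n_axes,
                                    g_value=cfg.g_value, b_c_value=cfg.b_c_value)
    res = log_posterior(tp, axes, sites, sample, prior, cfg)
    S = sample.n_species
    p_null = np.full(S, 1.0 / S)
    ll_null_plots = np.array([
        multinomial_loglik(row, p_null) for row in sample.counts
    ])
    ll_model_plots = np.array([
        multinomial_loglik(row, st.rel_abundance)
        for row, st in zip(sample.counts, res.equilibria)
    ])
    efforts = sample.effort
    r2_global = nagelkerke_r2(float(ll_model_plots.sum()),
                              float(ll_null_plots.sum()), int(efforts.sum()))
    r2_plots = np.array([
        nagelkerke_r2(lm, ln, int(n))
        for lm, ln, n in zip(ll_model_plots, ll_null_plots, efforts)
    ])
    dev_draws = post.retained_deviance()
    dev_point = -2.0 * res.log_likelihood
    return FitMetrics(
        pseudo_r2_global=r2_global, pseudo_r2_per_plot=r2_plots,
        dic=dic(dev_draws, dev_point), deviance_at_median=float(dev_point),
        p_d=float(dev_draws.mean() - dev_point),
        mean_deviance=float(dev_draws.mean()),
    )


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def null_trait_randomization(
    axes: TraitAxes,
    seed: int | None = None,
    per_axis: bool = False,
) -> TraitAxes:
    """Shuffle trait-axis values among species (identity permutation excluded).

    By default one permutation is applied jointly to all axis columns,
    preserving the inter-axis structure; ``per_axis=True`` shuffles each
    column independently.
    """
    if axes.n_species < 2:
        raise InvalidValueError("need at least two species to shuffle")
    rng = np.random.default_rng(seed)
    if per_axis:
        shuffled = np.column_stack([
            axes.axes[_nonidentity_perm(rng, axes.n_species), j]
            for j in range(axes.n_axes)
        ])
    else:
        shuffled = axes.axes[_nonidentity_perm(rng, axes.n_species)]
    return TraitAxes(
        species_id=axes.species_id, axes=shuffled,
        axis_variance_explained=axes.axis_variance_explained,
    )


def _nonidentity_perm(rng: np.random.Generator, n: int) -> np.ndarray:
    for _ in range(1000):
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            return perm
    raise RuntimeError("failed to draw a non-identity permutation")  # pragma: no cover


# ---------------------------------------------------------------------------
# presence/absence prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceTable:
    """Plot-by-species presence/absence from independent surveys."""

    plot_id: np.ndarray
    species_id: np.ndarray
    present: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "plot_id", np.asarray(self.plot_id))
        object.__setattr__(self, "species_id", np.asarray(self.species_id))
        pres = np.asarray(self.present)
        if pres.shape != (len(self.plot_id), len(self.species_id)):
            raise DimensionError("present must be a plot x species matrix")
        if not np.all(np.isin(pres, [0, 1])):
            raise InvalidValueError("present must be 0/1")
        object.__setattr__(self, "present", pres.astype(bool))

    @classmethod
    def from_csv(cls, path) -> "OccurrenceTable":
        df = pd.read_csv(path)
        species = [c for c in df.columns if c != "plot_id"]
        return cls(plot_id=df["plot_id"].to_numpy(),
                   species_id=np.asarray(species),
                   present=df[species].to_numpy())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.present.astype(int), columns=self.species_id)
        df.insert(0, "plot_id", self.plot_id)
        df.to_csv(path, index=False)


def auc_presence(rel_abundance: np.ndarray, occ: OccurrenceTable):
    """ROC AUC of predicted relative abundance against observed occurrence.

    ``rel_abundance`` is the plot-by-species equilibrium relative-abundance
    matrix; every plot x species cell is one classification instance scored
    by its predicted abundance (a rank statistic, so any monotone transform
    of the scores gives the same AUC).
    Returns (auc, (fpr, tpr, thresholds)).
    """
    scores = np.asarray(rel_abundance, dtype=float)
    if scores.shape != occ.present.shape:
        raise DimensionError("relative-abundance and occurrence shapes differ")
    y = occ.present.ravel().astype(int)
    s = scores.ravel()
    if y.min() == y.max():
        raise DataError("occurrence data contain a single class; AUC undefined")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, (fpr, tpr, thr)


def predicted_presence(rel_abundance: np.ndarray,
                       threshold: float = EXTINCTION_TOL) -> np.ndarray:
    """Binary presence predictions from equilibrium relative abundances."""
    return np.asarray(rel_abundance) > threshold


# ---------------------------------------------------------------------------
# posterior trait-demography correlations
# ---------------------------------------------------------------------------

def posterior_demography_summary(
    post: PosteriorSample,
    axes: TraitAxes,
    traits: TraitTable | None = None,
    cfg: LikelihoodConfig | None = None,
    n_axes: int = 3,
    max_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations among demographic parameters (and with raw
    traits) across the posterior.

    For each retained draw the demographic parameters are rebuilt and the
    correlations computed; the table reports the median and 2.5/97.5
    percentiles across draws.  Zero-variance parameter vectors (e.g. a
    transfer scale of exactly 0) make a correlation undefined and are
    reported as NaN with ``n_defined`` telling how many draws supported it.
    """
    cfg = cfg or LikelihoodConfig()
    draws = post.retained()
    if draws.shape[0] < 100:
        raise InvalidValueError("need at least 100 retained draws")
    if draws.shape[0] > max_draws:
        idx = np.random.default_rng(seed).choice(draws.shape[0], max_draws,
                                                 replace=False)
        draws = draws[idx]
    demo_names = ["theta_min", "l", "c"]
    pairs = [("theta_min", "l"), ("theta_min", "c"), ("l", "c")]
    trait_cols = list(traits.trait_names) if traits is not None else []
    records = {f"r({a},{b})": [] for a, b in pairs}
    for dn in demo_names:
        for t in trait_cols:
            records[f"r({dn},{t})"] = []
    for vec in draws:
        tp = TransferParams.from_vector(vec, n_axes, g_value=cfg.g_value,
                                        b_c_value=cfg.b_c_value)
        demo = build_demography(tp, axes)
        vals = {"theta_min": demo.theta_min, "l": demo.l, "c": demo.c}
        for a, b in pairs:
            records[f"r({a},{b})"].append(_safe_pearson(vals[a], vals[b]))
        for dn in demo_names:
            for j, t in enumerate(trait_cols):
                records[f"r({dn},{t})"].append(
                    _safe_pearson(vals[dn], traits.values[:, j]))
    rows = []
    for name, rs in records.items():
        arr = np.asarray(rs, dtype=float)
        ok = arr[np.isfinite(arr)]
        rows.append({
            "correlation": name,
            "median": np.median(ok) if ok.size else np.nan,
            "ci_low": np.quantile(ok, 0.025) if ok.size else np.nan,
            "ci_high": np.quantile(ok, 0.975) if ok.size else np.nan,
            "n_defined": int(ok.size),
            "n_draws": int(arr.size),
        })
    return pd.DataFrame(rows)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(pearsonr(x, y)[0])
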