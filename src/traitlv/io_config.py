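"""Run configuration, table alignment, and output manifests.

A run is fully described by a YAML config (paths + preprocessing, prior,
solver, and MCMC settings + seeds); every CLI command serializes the
resolved config, seeds, and package version into a JSON manifest next to
its outputs so the run can be reconstructed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DataError
from .evaluation import OccurrenceTable
from .inference import CommunitySample, LikelihoodConfig, PriorSpec
from .model_core import SiteTable, SolverConfig
from .traits import TraitTable, log_transform, pca_axes
from .transfer import B_C_FIXED_DEFAULT, G_FIXED_DEFAULT, TraitAxes

DEFAULTS = {
    "preprocessing": {
        "n_axes": 3,
        "log_exempt": ["d13C", "d15N"],
        "traits_are_axes": False,  # set True if the traits CSV already holds scaled axes
    },
    "fixed": {"g_value": G_FIXED_DEFAULT, "b_c_value": B_C_FIXED_DEFAULT},
    "prior": {
        "a_scale": {"a_theta_min": 1.0, "a_l": 1.0, "a_c": 1.0},
        "b_loc": {"b_theta_min": 0.0, "b_l": -5.0},
        "b_scale": {"b_theta_min": 2.0, "b_l": 2.0},
    },
    "solver": {"rtol": 1e-8, "atol": 1e-12, "horizon": None,
               "horizon_rates": 500.0, "residual_tol": 1e-8},
    "likelihood": {"equilibrium_method": "analytic"},
    "mcmc": {"n_chains": 8, "steps": 50000, "burn_fraction": 0.7,
             "snooker_prob": 0.1},
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated, fully-resolved run configuration."""

    traits_csv: str | None = None
    sites_csv: str | None = None
    counts_csv: str | None = None
    occurrences_csv: str | None = None
    output_dir: str = "traitlv_out"
    options: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"traits_csv", "sites_csv", "counts_csv", "occurrences_csv",
                 "output_dir"}
        cfg = cls(**{k: raw.pop(k) for k in list(raw) if k in known})
        for section, values in raw.items():
            if section not in cfg.options:
                raise DataError(f"unknown config section {section!r}")
            if isinstance(values, dict):
                unknown = set(values) - set(cfg.options[section])
                if unknown:
                    raise DataError(
                        f"unknown keys in config section {section!r}: {sorted(unknown)}")
                cfg.options[section].update(values)
            else:
                cfg.options[section] = values
        return cfg

    def prior(self) -> PriorSpec:
        p = self.options["prior"]
        return PriorSpec(
            n_axes=self.options["preprocessing"]["n_axes"],
            a_scale=dict(p["a_scale"]), b_loc=dict(p["b_loc"]),
            b_scale=dict(p["b_scale"]),
        )

    def likelihood_config(self) -> LikelihoodConfig:
        s = self.options["solver"]
        return LikelihoodConfig(
            equilibrium_method=self.options["likelihood"]["equilibrium_method"],
            solver_cfg=SolverConfig(
                rtol=s["rtol"], atol=s["atol"], horizon=s["horizon"],
                horizon_rates=s["horizon_rates"], residual_tol=s["residual_tol"],
            ),
            g_value=self.options["fixed"]["g_value"],
            b_c_value=self.options["fixed"]["b_c_value"],
        )

    def to_manifest(self, extra: dict | None = None) -> dict:
        from . import __version__

        manifest = {
            "package": "traitlv",
            "version": __version__,
            "config": {
                "traits_csv": self.traits_csv, "sites_csv": self.sites_csv,
                "counts_csv": self.counts_csv,
                "occurrences_csv": self.occurrences_csv,
                "output_dir": self.output_dir,
                **self.options,
            },
        }
        if extra:
            manifest.update(extra)
        return manifest


def write_manifest(cfg: RunConfig, out_dir: Path, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(cfg.to_manifest(extra), fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_tables(cfg: RunConfig):
    """Load and align all input tables on shared species/plot identifiers.

    Returns ``(axes, sites, sample, occurrences_or_None, report)`` where
    ``report`` lists identifiers dropped from each table during alignment.
    Species present in the counts but missing from the traits are an error:
    the method needs traits for every modeled species.
    """
    if not (cfg.traits_csv and cfg.sites_csv and cfg.counts_csv):
        raise DataError("traits_csv, sites_csv and counts_csv are all required")
    pre = cfg.options["preprocessing"]
    sample = CommunitySample.from_csv(cfg.counts_csv)
    sites = SiteTable.from_csv(cfg.sites_csv)

    if pre["traits_are_axes"]:
        axes = TraitAxes.from_csv(cfg.traits_csv)
    else:
        table = TraitTable.from_csv(cfg.traits_csv)
        table = log_transform(table, exempt=set(pre["log_exempt"]))
        axes = pca_axes(table, k=pre["n_axes"])

    trait_sp = set(map(str, axes.species_id))
    count_sp = set(map(str, sample.species_id))
    missing = sorted(count_sp - trait_sp)
    if missing:
        raise DataError(
            "species present in counts but missing from traits: "
            + ", ".join(missing[:10])
        )
    report = {"dropped_trait_species": sorted(trait_sp - count_sp),
              "dropped_plots": []}

    # order axes rows to match the counts' species order
    order = {str(s): i for i, s in enumerate(axes.species_id)}
    idx = np.array([order[str(s)] for s in sample.species_id])
    axes = TraitAxes(species_id=sample.species_id, axes=axes.axes[idx],
                     axis_variance_explained=axes.axis_variance_explained)

    plot_order = {str(p): i for i, p in enumerate(sites.plot_id)}
    missing_plots = [str(p) for p in sample.plot_id if str(p) not in plot_order]
    if missing_plots:
        raise DataError("plots in counts missing from sites: "
                        + ", ".join(missing_plots[:10]))
    pidx = np.array([plot_order[str(p)] for p in sample.plot_id])
    report["dropped_plots"] = sorted(
        set(map(str, sites.plot_id)) - set(map(str, sample.plot_id)))
    sites = SiteTable(plot_id=sample.plot_id, theta=sites.theta[pidx])

    occ = None
    if cfg.occurrences_csv:
        occ = OccurrenceTable.from_csv(cfg.occurrences_csv)
        osp = {str(s): i for i, s in enumerate(occ.species_id)}
        bad = sorted(set(map(str, occ.species_id)) - count_sp)
        if bad:
            raise DataError("occurrence species outside the modeled pool: "
                            + ", ".join(bad[:10]))
        oidx_sp = np.array([osp[str(s)] for s in sample.species_id
                            if str(s) in osp])
        # restrict occurrences to modeled species/plots, in matching order
        keep_sp = [str(s) in osp for s in sample.species_id]
        opl = {str(p): i for i, p in enumerate(occ.plot_id)}
        oidx_pl = np.array([opl[str(p)] for p in sample.plot_id
                            if str(p) in opl])
        keep_pl = [str(p) in opl for p in sample.plot_id]
        occ = OccurrenceTable(
            plot_id=sample.plot_id[keep_pl],
            species_id=sample.species_id[keep_sp],
            present=occ.present[np.ix_(oidx_pl, oidx_sp)].astype(int),
        )
    return axes, sites, sample, occ, report
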