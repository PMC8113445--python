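"""Raw functional-trait preprocessing: species averaging, log transforms, PCA.

The community-level workflow measures traits on individuals, averages them by
species, log-transforms the skewed ones (isotopic ratios such as d13C and
d15N, which can be negative, stay on their original scale), and summarizes
the species-by-trait matrix with a correlation-matrix PCA.  The first ``k``
component scores, rescaled to unit variance, form the orthogonal trait axes
consumed by the transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataError, DimensionError, InvalidValueError
from .transfer import TraitAxes


@dataclass(frozen=True)
class TraitTable:
    """Species-by-trait value matrix with log-transform bookkeeping."""

    species_id: np.ndarray
    values: np.ndarray
    trait_names: list[str]
    log_transformed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "species_id", np.asarray(self.species_id))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise DimensionError("values must be a 2-d species x trait matrix")
        if self.values.shape != (self.species_id.shape[0], len(self.trait_names)):
            raise DimensionError("values shape does not match species_id/trait_names")
        if len(set(self.species_id.tolist())) != self.species_id.shape[0]:
            raise DataError("duplicate species_id rows")
        if not self.log_transformed:
            object.__setattr__(
                self, "log_transformed", {t: False for t in self.trait_names}
            )

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "species_id", self.species_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        traits = [c for c in df.columns if c != "species_id"]
        return cls(
            species_id=df["species_id"].to_numpy(),
            values=df[traits].to_numpy(dtype=float),
            trait_names=traits,
        )

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls.from_frame(pd.read_csv(path))


def average_by_species(individual_measurements: pd.DataFrame) -> TraitTable:
    """Arithmetic species means from a long (species_id, trait, value) table."""
    df = individual_measurements
    required = {"species_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"long table needs columns {sorted(required)}")
    wide = df.pivot_table(index="species_id", columns="trait", values="value",
                          aggfunc="mean")
    if wide.isna().any().any():
        gaps = [
            f"{sp}:{tr}"
            for sp, row in wide.iterrows()
            for tr in wide.columns[row.isna()]
        ]
        raise DataError(f"missing species x trait combinations: {', '.join(gaps)}")
    wide = wide.sort_index()
    return TraitTable(
        species_id=wide.index.to_numpy(),
        values=wide.to_numpy(dtype=float),
        trait_names=list(wide.columns),
    )


def log_transform(table: TraitTable, exempt: set[str] = frozenset()) -> TraitTable:
    """Natural-log transform all traits except those named in ``exempt``."""
    exempt = set(exempt)
    unknown = exempt - set(table.trait_names)
    if unknown:
        raise DataError(f"exempt traits not in table: {sorted(unknown)}")
    values = table.values.copy()
    flags = dict(table.log_transformed)
    for j, name in enumerate(table.trait_names):
        if name in exempt:
            continue
        col = values[:, j]
        if np.any(col <= 0):
            bad = table.species_id[col <= 0]
            raise InvalidValueError(
                f"trait {name!r} has nonpositive values for species "
                f"{', '.join(map(str, bad[:5]))}; cannot log-transform"
            )
        values[:, j] = np.log(col)
        flags[name] = True
    return TraitTable(
        species_id=table.species_id, values=values,
        trait_names=list(table.trait_names), log_transformed=flags,
    )


def pca_axes(table: TraitTable, k: int = 3) -> TraitAxes:
    """First ``k`` correlation-matrix PCA axes, rescaled to unit variance.

    Traits are centered and scaled to unit variance before projection (the
    traits carry mixed units), component scores are rescaled to unit sample
    variance, and each axis gets a deterministic sign (its largest-magnitude
    trait loading is positive) so repeated runs agree exactly.
    """
    S, P = table.values.shape
    if k > min(S - 1, P):
        raise InvalidValueError(f"k={k} exceeds min(S-1, P)={min(S - 1, P)}")
    if not np.all(np.isfinite(table.values)):
        raise InvalidValueError("trait table contains non-finite values")
    sd = table.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [table.trait_names[j] for j in np.flatnonzero(sd == 0)]
        raise DataError(f"constant traits cannot be scaled: {const}")
    z = (table.values - table.values.mean(axis=0)) / sd
    pca = PCA(n_components=min(S - 1, P), svd_solver="full")
    scores = pca.fit_transform(z)
    ratios = pca.explained_variance_ratio_
    score_sd = scores[:, :k].std(axis=0, ddof=1)
    if np.any(score_sd < 1e-12 * max(1.0, score_sd.max(initial=0.0))) or np.any(
        score_sd == 0
    ):
        raise DataError(f"trait matrix rank below k={k}")
    axes = scores[:, :k] / score_sd
    # deterministic sign: largest-|loading| trait loads positively
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            axes[:, j] = -axes[:, j]
    return TraitAxes(
        species_id=table.species_id, axes=axes,
        axis_variance_explained=ratios[:k],
    )
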