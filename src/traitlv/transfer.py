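"""Hyperspherical trait-to-demography transfer function.

Each demographic parameter ``m`` (theta_min, l, c) is a generalized linear
function of ``N`` orthogonal trait axes.  The regression coefficients are
constrained to the unit hypersphere and parameterized by ``N-1`` angles
(first ``N-2`` in [0, pi], the last in [0, 2*pi]), so that with standardized
orthogonal axes the link scale ``E_m = coef . t`` is again standard normal
across species.  A scale ``a_m >= 0`` and offset ``b_m`` then set the mean
and spread of the demographic parameter:

    theta_min_i = a * E_i + b          (linear; can be negative)
    l_i, c_i    = exp(a * E_i + b)     (log-linear; strictly positive)

The growth slope ``g`` (shared across species) and the offset ``b_c`` of the
intraspecific competition rate are not identifiable from relative-abundance
data and are fixed constants (defaults 10**-3.43 and 10**-3.8).  With N = 3
axes this leaves eleven free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidValueError
from .model_core import DemographicParams

G_FIXED_DEFAULT = 10.0 ** -3.43
B_C_FIXED_DEFAULT = 10.0 ** -3.8

#: clip |a*E + b| at this bound before exponentiating (overflow guard for
#: early sampler exploration; the regularizing priors make the region
#: negligible but proposals visit it)
EXP_CLIP = 50.0


@dataclass(frozen=True)
class TraitAxes:
    """Species-by-axis matrix of orthogonal, scaled trait axes."""

    species_id: np.ndarray
    axes: np.ndarray
    axis_variance_explained: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "species_id", np.asarray(self.species_id))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.axes.ndim != 2:
            raise DimensionError("axes must be a 2-d species x axis matrix")
        if self.axes.shape[0] != self.species_id.shape[0]:
            raise DimensionError("species_id length does not match axes rows")
        if self.n_axes < 1:
            raise InvalidValueError("need at least one trait axis")
        if not np.all(np.isfinite(self.axes)):
            raise InvalidValueError("axes must be finite")
        if self.axis_variance_explained is not None:
            object.__setattr__(
                self, "axis_variance_explained",
                np.asarray(self.axis_variance_explained, dtype=float),
            )

    @property
    def n_species(self) -> int:
        return self.axes.shape[0]

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.axes, columns=[f"axis{k + 1}" for k in range(self.n_axes)]
        )
        df.insert(0, "species_id", self.species_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraitAxes":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("axis")]
        return cls(species_id=df["species_id"].to_numpy(), axes=df[cols].to_numpy())


def _check_angles(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1 or phi.shape[0] < 1:
        raise DimensionError("phi must be a 1-d vector of N-1 angles")
    if not np.all(np.isfinite(phi)):
        raise InvalidValueError("angles must be finite")
    if phi.shape[0] > 1 and (np.any(phi[:-1] < 0) or np.any(phi[:-1] > np.pi)):
        raise InvalidValueError("inner angles must lie in [0, pi]")
    if phi[-1] < 0 or phi[-1] > 2 * np.pi:
        raise InvalidValueError("last angle must lie in [0, 2*pi]")
    return phi


def angles_to_unit_vector(phi: np.ndarray) -> np.ndarray:
    """Polar angles -> unit-norm coefficient vector of length N = len(phi)+1.

    coef = (cos p1, sin p1 cos p2, ..., sin p1 ... sin p_{N-1}).
    """
    phi = _check_angles(phi)
    n = phi.shape[0] + 1
    coef = np.empty(n)
    sin_prod = 1.0
    for k in range(n - 1):
        coef[k] = sin_prod * np.cos(phi[k])
        sin_prod *= np.sin(phi[k])
    coef[n - 1] = sin_prod
    return coef


def unit_vector_to_angles(coef: np.ndarray) -> np.ndarray:
    """Inverse polar transform: unit vector -> in-range angle vector.

    Right inverse of :func:`angles_to_unit_vector` up to the standard polar
    degeneracies (angles after a zero sine product are unconstrained).
    """
    u = np.asarray(coef, dtype=float)
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
        raise InvalidValueError("coefficient vector must have unit norm")
    n = u.shape[0]
    phi = np.empty(n - 1)
    for k in range(n - 2):
        tail = np.linalg.norm(u[k + 1:])
        phi[k] = np.arctan2(tail, u[k])  # in [0, pi] since tail >= 0
    phi[n - 2] = np.arctan2(u[n - 1], u[n - 2]) % (2 * np.pi)
    return phi


def link_scale(axes: TraitAxes, phi_m: np.ndarray) -> np.ndarray:
    """Per-species link scale E = axes @ coef(phi_m)."""
    coef = angles_to_unit_vector(phi_m)
    if coef.shape[0] != axes.n_axes:
        raise DimensionError(
            f"phi implies {coef.shape[0]} axes but TraitAxes has {axes.n_axes}"
        )
    return axes.axes @ coef


def to_positive_param(E: np.ndarray, a: float, b: float) -> np.ndarray:
    """Log-linear transform d = exp(a*E + b) (strictly positive parameters)."""
    if a < 0:
        raise InvalidValueError("scale a must be nonnegative")
    z = a * np.asarray(E, dtype=float) + b
    return np.exp(np.clip(z, -EXP_CLIP, EXP_CLIP))


def to_real_param(E: np.ndarray, a: float, b: float) -> np.ndarray:
    """Linear transform d = a*E + b (sign-unrestricted parameters)."""
    if a < 0:
        raise InvalidValueError("scale a must be nonnegative")
    return a * np.asarray(E, dtype=float) + b


@dataclass(frozen=True)
class TransferParams:
    """Free transfer-function parameters plus the fixed constants.

    With N axes the free parameters are, in flat-vector order:
    ``phi_theta_min (N-1), phi_l (N-1), phi_c (N-1), a_theta_min,
    b_theta_min, a_l, b_l, a_c`` — eleven in total for N = 3.
    """

    phi_theta_min: np.ndarray
    phi_l: np.ndarray
    phi_c: np.ndarray
    a_theta_min: float
    b_theta_min: float
    a_l: float
    b_l: float
    a_c: float
    g_value: float = G_FIXED_DEFAULT
    b_c_value: float = B_C_FIXED_DEFAULT

    def __post_init__(self):
        for name in ("phi_theta_min", "phi_l", "phi_c"):
            object.__setattr__(self, name, _check_angles(getattr(self, name)))
        n_ang = self.phi_theta_min.shape[0]
        if self.phi_l.shape[0] != n_ang or self.phi_c.shape[0] != n_ang:
            raise DimensionError("angle vectors must all have length N-1")
        for name in ("a_theta_min", "a_l", "a_c"):
            if getattr(self, name) < 0:
                raise InvalidValueError(f"{name} must be nonnegative")
        if self.g_value <= 0:
            raise InvalidValueError("g_value must be positive")

    @property
    def n_axes(self) -> int:
        return self.phi_theta_min.shape[0] + 1

    @property
    def n_free(self) -> int:
        return 3 * (self.n_axes - 1) + 5

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.phi_theta_min, self.phi_l, self.phi_c,
            [self.a_theta_min, self.b_theta_min, self.a_l, self.b_l, self.a_c],
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_axes: int = 3,
                    g_value: float = G_FIXED_DEFAULT,
                    b_c_value: float = B_C_FIXED_DEFAULT) -> "TransferParams":
        vec = np.asarray(vec, dtype=float)
        k = n_axes - 1
        if vec.shape[0] != 3 * k + 5:
            raise DimensionError(
                f"expected {3 * k + 5} free parameters for N={n_axes}, got {vec.shape[0]}"
            )
        return cls(
            phi_theta_min=vec[:k], phi_l=vec[k:2 * k], phi_c=vec[2 * k:3 * k],
            a_theta_min=float(vec[3 * k]), b_theta_min=float(vec[3 * k + 1]),
            a_l=float(vec[3 * k + 2]), b_l=float(vec[3 * k + 3]),
            a_c=float(vec[3 * k + 4]),
            g_value=g_value, b_c_value=b_c_value,
        )

    @staticmethod
    def param_names(n_axes: int = 3) -> list[str]:
        k = n_axes - 1
        names = [f"phi_theta_min_{i + 1}" for i in range(k)]
        names += [f"phi_l_{i + 1}" for i in range(k)]
        names += [f"phi_c_{i + 1}" for i in range(k)]
        names += ["a_theta_min", "b_theta_min", "a_l", "b_l", "a_c"]
        return names


def build_demography(tp: TransferParams, axes: TraitAxes) -> DemographicParams:
    """Map trait axes through the transfer function to per-species rates."""
    if tp.n_axes != axes.n_axes:
        raise DimensionError(
            f"TransferParams expects N={tp.n_axes} axes, TraitAxes has {axes.n_axes}"
        )
    e_tm = link_scale(axes, tp.phi_theta_min)
    e_l = link_scale(axes, tp.phi_l)
    e_c = link_scale(axes, tp.phi_c)
    S = axes.n_species
    return DemographicParams(
        theta_min=to_real_param(e_tm, tp.a_theta_min, tp.b_theta_min),
        g=np.full(S, tp.g_value),
        c=to_positive_param(e_c, tp.a_c, tp.b_c_value),
        l=to_positive_param(e_l, tp.a_l, tp.b_l),
        species_id=axes.species_id,
    )
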