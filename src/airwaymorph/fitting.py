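"""Passive-parameter estimation from pressure--radius inflation data.

Quasi-static inflation of the passive (agonist-free, ungrown) airway yields
a pressure--radius curve whose shape is set by the passive hyperelastic
coefficients.  ``fit_passive_params`` estimates a chosen subset of those
coefficients by trust-region nonlinear least squares on the inner radius;
``generate_synthetic_pr`` produces seeded synthetic inflation tables
(forward curve plus additive Gaussian radius noise) standing in for
published quasi-static inflation measurements, for parameter-recovery
testing.

Identifiability dictates the default free subset: at homeostatic volume
fractions the proliferative stiffness c_neo multiplies a tiny fraction
(0.02) of the same invariant as c_ground (0.28), the muscle-fibre amplitude
k1_c rises from the same zero-strain origin as the ground matrix, and each
exponent k2 is strongly correlated with its amplitude k1 along a single
inflation path.  A single passive inflation curve therefore determines two
well-conditioned quantities: the pre-recruitment stiffness scale and the
collagen recruitment amplitude.  The default frees (c_ground, k1_e), with
c_neo and k1_c tied proportionally to the fitted ground-matrix scale (their
default ratios preserved), and the exponents, recruitment stretch and fibre
angle held fixed; any other subset can be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constitutive import MaterialParams
from .growth import ConstituentFields, RateParams
from .mechanics import GrownGeometry, pressure_radius_curve

__all__ = [
    "PressureRadiusData",
    "FitResult",
    "fit_passive_params",
    "generate_synthetic_pr",
    "DEFAULT_FREE_PARAMS",
]

DEFAULT_FREE_PARAMS = ("c_ground", "k1_e")

#: parameters scaled with c_ground's fitted/guess ratio when not themselves free
_TIED_TO_GROUND = ("c_neo", "k1_c")


@dataclass
class PressureRadiusData:
    """Rows of (transmural pressure kPa, inner radius mm) with provenance."""

    pressure_kPa: np.ndarray
    radius_mm: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pressure_kPa = np.asarray(self.pressure_kPa, dtype=float)
        self.radius_mm = np.asarray(self.radius_mm, dtype=float)
        if self.pressure_kPa.shape != self.radius_mm.shape:
            raise ValueError("pressure and radius columns must have equal length")
        if not np.all(np.isfinite(self.pressure_kPa)):
            raise ValueError("pressures must be finite")
        if np.any(self.radius_mm <= 0):
            raise ValueError("radii must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"transmural_pressure_kPa": self.pressure_kPa,
                             "inner_radius_mm": self.radius_mm})

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "PressureRadiusData":
        df = pd.read_csv(path)
        return cls(df["transmural_pressure_kPa"].to_numpy(),
                   df["inner_radius_mm"].to_numpy(), provenance=provenance)


@dataclass
class FitResult:
    """Fitted passive coefficients plus regression diagnostics."""

    params: MaterialParams
    free_names: tuple
    fitted_values: np.ndarray
    residuals: np.ndarray
    r_squared: float
    cost: float
    success: bool
    message: str


def _forward_radius(mat: MaterialParams, pressures, geometry, fields) -> np.ndarray:
    rows = pressure_radius_curve(geometry, fields, 0.0, mat, pressures)
    return np.array([r for (_, r, _) in rows])


def _passive_setup(rates: RateParams, R1: float, Rint: float, R2: float,
                   nodes_per_layer: int):
    geom = GrownGeometry.reference(R1, Rint, R2, nodes_per_layer)
    fields = ConstituentFields.homeostatic(rates, geom)
    return geom, fields


def generate_synthetic_pr(true_params: MaterialParams, pressure_grid, noise_sd: float,
                          seed: int, rates: RateParams | None = None,
                          R1: float = 1.8, Rint: float = 1.9, R2: float = 2.3,
                          nodes_per_layer: int = 51) -> PressureRadiusData:
    """Synthetic quasi-static inflation table: forward passive curve plus
    additive Gaussian noise on the radii (seeded, reproducible)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rates = rates or RateParams()
    geom, fields = _passive_setup(rates, R1, Rint, R2, nodes_per_layer)
    radii = _forward_radius(true_params, pressure_grid, geom, fields)
    rng = np.random.default_rng(seed)
    noisy = radii + rng.normal(0.0, noise_sd, size=radii.shape)
    return PressureRadiusData(np.asarray(pressure_grid, dtype=float), noisy,
                              provenance=f"synthetic(seed={seed}, sd={noise_sd})")


def fit_passive_params(data: PressureRadiusData,
                       initial_guess: MaterialParams | None = None,
                       free: tuple = DEFAULT_FREE_PARAMS,
                       bounds_scale: tuple = (1e-3, 1e3),
                       rates: RateParams | None = None,
                       R1: float = 1.8, Rint: float = 1.9, R2: float = 2.3,
                       nodes_per_layer: int = 51) -> FitResult:
    """Estimate passive hyperelastic coefficients from inflation data.

    Trust-region-reflective least squares on the inner radius, fitting the
    passive model (agonist-free, ungrown reference geometry, homeostatic
    volume fractions).  The active parameter T_c is never fitted.  Bounds
    for each free coefficient are its initial guess scaled by
    ``bounds_scale``.  Deterministic given data and guess.

    Raises
    ------
    ValueError
        For degenerate data (fewer points than free parameters, or constant
        radius) or an unknown free-parameter name.
    RuntimeError
        If the optimizer fails to converge.
    """
    guess = initial_guess or MaterialParams()
    rates = rates or RateParams()
    if data.pressure_kPa.size < len(free):
        raise ValueError("need at least as many data points as free parameters")
    if np.ptp(data.radius_mm) < 1e-12:
        raise ValueError("degenerate data: radius column is constant (ill-posed fit)")
    for name in free:
        if not hasattr(guess, name):
            raise ValueError(f"unknown free parameter {name!r}")
        if name == "T_c":
            raise ValueError("T_c is active tone and is excluded from passive fits")
    geom, fields = _passive_setup(rates, R1, Rint, R2, nodes_per_layer)

    x0 = np.array([getattr(guess, name) for name in free], dtype=float)
    lo = x0 * bounds_scale[0]
    hi = x0 * bounds_scale[1]

    def make_params(x) -> MaterialParams:
        updates = dict(zip(free, x))
        if "c_ground" in updates and guess.c_ground > 0:
            scale = updates["c_ground"] / guess.c_ground
            for tied in _TIED_TO_GROUND:
                if tied not in updates:
                    updates[tied] = getattr(guess, tied) * scale
        return replace(guess, **updates)

    def residual(x):
        return _forward_radius(make_params(x), data.pressure_kPa, geom, fields) \
            - data.radius_mm

    sol = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    if not sol.success:
        raise RuntimeError(f"passive fit failed to converge: {sol.message}")
    res = sol.fun
    ss_res = float(res @ res)
    ss_tot = float(np.sum((data.radius_mm - data.radius_mm.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return FitResult(
        params=make_params(sol.x), free_names=tuple(free), fitted_values=sol.x,
        residuals=res, r_squared=r2, cost=float(sol.cost),
        success=bool(sol.success), message=str(sol.message),
    )
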