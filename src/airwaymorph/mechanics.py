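"""Quasi-static elastic equilibrium of the grown two-layer airway.

The airway is a thick-walled incompressible cylinder in plane strain.  The
grown (stress-free) configuration is described by a material grid of grown
radii ``xi`` per layer; the elastic deformation ``r = r(xi)`` then follows in
closed form from incompressibility,

    r(xi)^2 = r1^2 + xi^2 - xi1^2,

so the only unknown is the deformed inner radius ``r1``.  Radial momentum
balance

    dT_rr/dr + (T_rr - T_thth)/r = 0

is integrated across the wall layer by layer (the Lagrange multiplier cancels
in the stress difference; radial stress is continuous at the interface), and
``r1`` is found by a safeguarded 1-D root find on the outer pressure residual
``T_rr(r2) + P2``.  This is the classical shooting formulation for tube
inflation, collapsed to a single quadrature per trial ``r1`` because the
radial map is explicit.

Transmural profiles are reported on the concatenated grid with the interface
node appearing twice (once per layer): volume fractions, and hence the hoop
stress, jump across the interface, while ``r`` and ``T_rr`` are continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, quad
from scipy.optimize import brentq

from .constitutive import MaterialParams, active_force_density, fibre_invariant

__all__ = [
    "GrownGeometry",
    "LoadCase",
    "MechanicalState",
    "EquilibriumError",
    "map_radii",
    "solve_equilibrium",
    "pressure_radius_curve",
    "quadrature_pressure_oracle",
    "CLOSURE_RADIUS_MM",
]

#: deformed inner radius (mm) below which the airway is considered closed
CLOSURE_RADIUS_MM = 0.01


class EquilibriumError(RuntimeError):
    """No equilibrium found within the r1 bracket; carries both residuals."""

    def __init__(self, msg: str, residual_lo: float, residual_hi: float):
        super().__init__(msg)
        self.residual_lo = residual_lo
        self.residual_hi = residual_hi


@dataclass
class GrownGeometry:
    """Material grid of grown radii per layer, plus fixed reference radii.

    The inner layer (subepithelial basement membrane, pure ECM) occupies
    ``[xi1, xi_int]``, the outer (smooth-muscle) layer ``[xi_int, xi2]``.
    The outer wall is pinned, ``xi2 == R2`` at all times; growth is inward.
    """

    xi_inner_layer: np.ndarray
    xi_outer_layer: np.ndarray
    R1: float
    Rint: float
    R2: float

    def __post_init__(self) -> None:
        self.xi_inner_layer = np.asarray(self.xi_inner_layer, dtype=float)
        self.xi_outer_layer = np.asarray(self.xi_outer_layer, dtype=float)
        if np.any(np.diff(self.xi_inner_layer) <= 0) or np.any(np.diff(self.xi_outer_layer) <= 0):
            raise ValueError("grown-radius grids must be strictly increasing")
        if not np.isclose(self.xi_inner_layer[-1], self.xi_outer_layer[0], rtol=0, atol=1e-12):
            raise ValueError("layer grids must conform at the interface")
        if not (self.xi1 < self.xi_int < self.xi2):
            raise ValueError("need xi1 < xi_int < xi2")

    @classmethod
    def reference(cls, R1: float, Rint: float, R2: float,
                  nodes_per_layer: int = 101) -> "GrownGeometry":
        """Ungrown geometry: xi == R on uniform per-layer grids."""
        return cls(
            xi_inner_layer=np.linspace(R1, Rint, nodes_per_layer),
            xi_outer_layer=np.linspace(Rint, R2, nodes_per_layer),
            R1=R1, Rint=Rint, R2=R2,
        )

    @property
    def xi1(self) -> float:
        return float(self.xi_inner_layer[0])

    @property
    def xi_int(self) -> float:
        return float(self.xi_inner_layer[-1])

    @property
    def xi2(self) -> float:
        return float(self.xi_outer_layer[-1])

    @property
    def n_inner(self) -> int:
        return self.xi_inner_layer.size

    @property
    def xi_all(self) -> np.ndarray:
        """Concatenated per-layer grid (interface node appears twice)."""
        return np.concatenate([self.xi_inner_layer, self.xi_outer_layer])


@dataclass(frozen=True)
class LoadCase:
    """Pressure boundary conditions: luminal P1 and external P2 (kPa)."""

    P1: float = 0.0
    P2: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.P1) and np.isfinite(self.P2)):
            raise ValueError("pressures must be finite")


@dataclass
class MechanicalState:
    """Equilibrium solution on the concatenated material grid.

    Arrays have the interface node duplicated (end of inner layer, start of
    outer layer); ``r`` and ``Trr`` coincide there while ``Tth``, ``Tzz``,
    ``p_lagrange`` and ``tau`` may jump.
    """

    xi: np.ndarray
    r: np.ndarray
    Trr: np.ndarray
    Tth: np.ndarray
    Tzz: np.ndarray
    p_lagrange: np.ndarray
    tau: np.ndarray
    r1: float
    r_int: float
    r2: float
    closed: bool


def map_radii(r1_guess: float, geom: GrownGeometry) -> np.ndarray:
    """Deformed radii r(xi) on the concatenated grid for a trial inner radius.

    Incompressibility gives ``r^2 = r1^2 + xi^2 - xi1^2`` across both layers
    (radial continuity at the interface is automatic).
    """
    if r1_guess <= 0:
        raise ValueError("r1_guess must be > 0")
    xi = geom.xi_all
    return np.sqrt(r1_guess**2 + xi**2 - geom.xi1**2)


def _stress_differences(xi, r, phi_c, phi_p, phi_e, k, mat: MaterialParams):
    """(Tth - Trr, Tzz - Trr) from passive + active parts; p cancels."""
    lam_th = r / xi
    lam_r = 1.0 / lam_th  # plane strain, lam_z = 1
    W1 = 0.5 * (phi_c * mat.c_ground + phi_p * mat.c_neo + phi_e * mat.c_ground)
    I4 = fibre_invariant(lam_th, 1.0, mat.alpha)
    xc = np.maximum(I4 - 1.0, 0.0)  # tension-only fibre response
    dWc = mat.k1_c * xc * np.exp(mat.k2_c * xc**2)
    xe = np.maximum(I4 - mat.lambda_u**2, 0.0)  # crimped below recruitment
    dWe = mat.k1_e * xe * np.exp(mat.k2_e * xe**2)
    W4 = phi_c * dWc + phi_e * dWe
    c2, s2 = np.cos(mat.alpha) ** 2, np.sin(mat.alpha) ** 2
    A = active_force_density(k, mat)
    dth = 2.0 * W1 * (lam_th**2 - lam_r**2) + 2.0 * W4 * lam_th**2 * c2 + phi_c * A * c2
    dzz = 2.0 * W1 * (1.0 - lam_r**2) + 2.0 * W4 * s2 + phi_c * A * s2
    return dth, dzz


def _gather_fields(geom: GrownGeometry, fields, k_field):
    """Per-node (phi_c, phi_p, phi_e, k) on the concatenated grid."""
    n_in = geom.n_inner
    phi_c = np.concatenate([np.zeros(n_in), np.asarray(fields.phi_c, dtype=float)])
    phi_p = np.concatenate([np.zeros(n_in), np.asarray(fields.phi_p, dtype=float)])
    phi_e = np.concatenate([np.asarray(fields.phi_e_inner, dtype=float),
                            np.asarray(fields.phi_e, dtype=float)])
    k = np.asarray(k_field, dtype=float)
    if k.ndim == 0:
        k = np.full(n_in + geom.xi_outer_layer.size, float(k))
    if phi_c.size != geom.xi_all.size or k.size != geom.xi_all.size:
        raise ValueError("field arrays do not conform to the geometry grids")
    return phi_c, phi_p, phi_e, k


def solve_equilibrium(geom: GrownGeometry, fields, k_field, loads: LoadCase,
                      mat: MaterialParams, r1_bracket=(None, None),
                      xtol: float = 1e-12, r1_init: float | None = None) -> MechanicalState:
    """Solve radial momentum balance for the deformed configuration.

    Parameters
    ----------
    geom : GrownGeometry
    fields : ConstituentFields
        Volume fractions on the material grids (see :mod:`airwaymorph.growth`).
    k_field : array or float
        Agonist concentration per node of the concatenated grid (or scalar).
    loads : LoadCase
    mat : MaterialParams
    r1_bracket : pair of float, optional
        Search bracket for the deformed inner radius; defaults to
        ``[0.05*xi1, 3*xi1]``.
    r1_init : float, optional
        Warm start (e.g. the previous growth step's solution); a narrow
        bracket around it is tried before the full one.

    Returns
    -------
    MechanicalState
        Full transmural stress profiles including the fibre stress tau.
        ``closed`` is flagged (not raised) when r1 falls below the closure
        threshold.

    Raises
    ------
    EquilibriumError
        If the residual does not change sign over the bracket.
    """
    xi = geom.xi_all
    n_in = geom.n_inner
    phi_c, phi_p, phi_e, k = _gather_fields(geom, fields, k_field)

    def profile(r1):
        r = np.sqrt(r1**2 + xi**2 - geom.xi1**2)
        dth, dzz = _stress_differences(xi, r, phi_c, phi_p, phi_e, k, mat)
        integrand = dth * xi / r**2  # dT_rr/dxi
        Trr = np.empty_like(xi)
        Trr[:n_in] = -loads.P1 + cumulative_simpson(
            integrand[:n_in], x=xi[:n_in], initial=0.0)
        Trr[n_in:] = Trr[n_in - 1] + cumulative_simpson(
            integrand[n_in:], x=xi[n_in:], initial=0.0)
        return Trr, r, dth, dzz

    def residual(r1):
        Trr, *_ = profile(r1)
        return Trr[-1] + loads.P2

    lo = r1_bracket[0] if r1_bracket[0] is not None else 0.05 * geom.xi1
    hi = r1_bracket[1] if r1_bracket[1] is not None else 3.0 * geom.xi1

    if loads.P1 == loads.P2 and not np.any(k > 0):
        # the grown configuration is stress-free: with no load difference and
        # no active tone the identity map is the exact equilibrium, with a
        # purely hydrostatic stress state -P1 (exact arrays, no quadrature)
        hydro = np.full_like(xi, -loads.P1)
        return MechanicalState(
            xi=xi, r=xi.copy(), Trr=hydro, Tth=hydro.copy(), Tzz=hydro.copy(),
            p_lagrange=np.full_like(xi, loads.P1), tau=-loads.P1 * np.ones_like(xi),
            r1=geom.xi1, r_int=geom.xi_int, r2=geom.xi2,
            closed=bool(geom.xi1 < CLOSURE_RADIUS_MM),
        )
    else:
        r1 = None
        if r1_init is not None and r1_init > 0:
            wlo, whi = 0.95 * r1_init, 1.05 * r1_init
            if residual(wlo) * residual(whi) < 0:
                r1 = brentq(residual, wlo, whi, xtol=xtol)
        if r1 is None:
            g_lo, g_hi = residual(lo), residual(hi)
            if g_lo * g_hi > 0:
                lo2 = 0.25 * CLOSURE_RADIUS_MM  # widen toward closure before giving up
                g_lo2 = residual(lo2)
                if g_lo2 * g_hi > 0:
                    raise EquilibriumError(
                        f"no sign change in equilibrium residual over r1 in "
                        f"[{lo2:g}, {hi:g}] (residuals {g_lo2:g}, {g_hi:g})",
                        g_lo2, g_hi)
                lo, g_lo = lo2, g_lo2
            r1 = brentq(residual, lo, hi, xtol=xtol)

    Trr, r, dth, dzz = profile(r1)
    Tth = Trr + dth
    Tzz = Trr + dzz
    # recover p from the radial extra stress (stress-free-reference normalisation)
    lam_th = r / xi
    W1 = 0.5 * (phi_c * mat.c_ground + phi_p * mat.c_neo + phi_e * mat.c_ground)
    Trr_hat = 2.0 * W1 * (1.0 / lam_th**2 - 1.0)
    p = Trr_hat - Trr
    c2, s2 = np.cos(mat.alpha) ** 2, np.sin(mat.alpha) ** 2
    tau = Tth * c2 + Tzz * s2
    return MechanicalState(
        xi=xi, r=r, Trr=Trr, Tth=Tth, Tzz=Tzz, p_lagrange=p, tau=tau,
        r1=float(r[0]), r_int=float(r[n_in - 1]), r2=float(r[-1]),
        closed=bool(r[0] < CLOSURE_RADIUS_MM),
    )


def pressure_radius_curve(geom: GrownGeometry, fields, k_field, mat: MaterialParams,
                          pressure_grid, P2: float = 0.0):
    """Inner radius vs luminal pressure: one equilibrium solve per pressure.

    Returns a list of ``(P1, r1, converged)`` tuples; equilibrium failures are
    recorded with ``r1 = nan`` and ``converged = False`` rather than raised.
    """
    pressure_grid = np.asarray(pressure_grid, dtype=float)
    if not np.all(np.isfinite(pressure_grid)):
        raise ValueError("pressure grid must be finite")
    rows = []
    for P1 in pressure_grid:
        try:
            st = solve_equilibrium(geom, fields, k_field, LoadCase(P1=float(P1), P2=P2), mat)
            rows.append((float(P1), st.r1, True))
        except EquilibriumError:
            rows.append((float(P1), float("nan"), False))
    return rows


def quadrature_pressure_oracle(r1: float, geom: GrownGeometry, fields, k_field,
                               mat: MaterialParams, P2: float = 0.0) -> float:
    """Independent adaptive-quadrature evaluation of the inflation identity.

    For a given deformed inner radius, the luminal pressure follows from

        P1 = P2 + integral over the wall of (Tth - Trr) / r dr,

    evaluated per layer with ``scipy.integrate.quad`` on the exact integrand
    (interpolating the constituent fields linearly in xi within each layer).
    Serves as the brute-force oracle for :func:`solve_equilibrium`.
    """
    phi_c, phi_p, phi_e, k = _gather_fields(geom, fields, k_field)
    n_in = geom.n_inner
    total = 0.0
    for sl, grid in ((slice(0, n_in), geom.xi_inner_layer),
                     (slice(n_in, None), geom.xi_outer_layer)):
        pc, pp, pe, kk = phi_c[sl], phi_p[sl], phi_e[sl], k[sl]

        def integrand(xi, grid=grid, pc=pc, pp=pp, pe=pe, kk=kk):
            r = np.sqrt(r1**2 + xi**2 - geom.xi1**2)
            dth, _ = _stress_differences(
                xi, r,
                np.interp(xi, grid, pc), np.interp(xi, grid, pp),
                np.interp(xi, grid, pe), np.interp(xi, grid, kk), mat)
            return float(dth * xi / r**2)

        val, _ = quad(integrand, grid[0], grid[-1], limit=200, epsabs=1e-12, epsrel=1e-12)
        total += val
    return P2 + total
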