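"""Constituent mass balances, mixture growth, and the homeostatic state.

Each solid constituent's volume fraction obeys an advection--reaction balance
on the grown radius xi,

    dPhi_a/dt + v dPhi_a/dxi + Phi_a (1/xi) d(xi v)/dxi = S_a,

with source terms encoding phenotype switching (contractile <-> proliferative
ASMCs), logistic apoptosis, proliferation/recruitment, and ECM deposition and
degradation, several of which are modulated by the inflammation level mu
(three tiers: healthy / mild / severe) and by the local fibre stress tau
(mechanotransduction).  Constant hydration (Phi_w = 0.70) closes the system:
the mixture dilatation is q = (S_c + S_p + S_e)/(1 - Phi_w) and the growth
velocity v follows by integrating (1/xi) d(xi v)/dxi = q inward from the
pinned outer wall, v(xi2) = 0.

The balance is solved in Lagrangian (material-point) form, which removes the
advective term exactly:  dPhi_a/dt = S_a - Phi_a q and dxi/dt = v along
material trajectories, so the zero-flux interface conditions hold
identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .mechanics import GrownGeometry

__all__ = [
    "RateParams",
    "ConstituentFields",
    "GridTanglingError",
    "switching_rate",
    "proliferation_rate",
    "ecm_deposition_rate",
    "source_terms",
    "homeostatic_state",
    "mixture_dilatation",
    "growth_velocity",
    "advance_growth",
    "well_mixed_rhs",
]


class GridTanglingError(RuntimeError):
    """The material grid lost monotonicity during a growth step."""


def _H(x):
    """Heaviside with H(0) = 0 (strict-inequality convention)."""
    return np.asarray(x, dtype=float) > 0.0


@dataclass(frozen=True)
class RateParams:
    """All biochemical rate constants (1/day unless noted).

    The defaults form a self-consistent set: the homeostatic closed form
    fills the solid fraction, Phi_c* + Phi_p* + Phi_e* = 1 - phi_w = 0.30,
    with Phi_c* = 0.20, Phi_p* = 0.02, Phi_e* = 0.08 (ASM predominantly
    contractile, a small proliferative pool, ECM the remainder).

    Growth/turnover
    ---------------
    c_pc : proliferative -> contractile switch-back rate (high).
    c_a : apoptosis coefficient (volume/(mass day)); quadratic in rho_c,
        providing logistic saturation of the contractile pool.
    c_c0, c_c1, c_c2 : contractile -> proliferative switching rate at the
        healthy / mild / severe inflammation tiers.
    mu_1, mu_2 : inflammation thresholds separating the tiers.
    c_cp_f : stress-modulated switching coefficient (1/(day kPa)).
    switch_mode : 'tension' or 'compression' — which stress sign drives
        switching (the added rate is always non-negative; compressive mode
        uses the stress magnitude).
    c_p0 : baseline proliferation/recruitment rate.
    c_p_f : stress-modulated proliferation coefficient (1/(day kPa));
        0 by default (proliferation unmodulated by stress).
    prolif_mode : as switch_mode, for proliferation.
    c_pe : ECM synthesis rate by proliferative ASMCs.
    c_e0, c_e1, c_e2 : inflammation-tiered ECM deposition (mass/(volume day)).
    c_de : ECM degradation rate.
    rho_T : true density shared by all solid phases (mass/volume; 1 by
        convention, absorbing mass units into the rates).
    phi_w : fluid volume fraction, constant and uniform (0.70).

    Stimulus dynamics
    -----------------
    a_mu, c_dmu : inflammation challenge magnitude and clearance rate.
    a_k, c_dk : agonist challenge magnitude and clearance rate.
    a_kmu : inflammation-induced agonist release rate.
    a_c : stress-mediated (tensile) agonist release rate (1/(day kPa)).
    """

    c_pc: float = 1.0
    c_a: float = 0.25
    c_c0: float = 0.05
    c_c1: float = 0.1
    c_c2: float = 0.2
    mu_1: float = 0.5
    mu_2: float = 1.5
    c_cp_f: float = 0.05
    switch_mode: str = "tension"
    c_p0: float = 0.5
    c_p_f: float = 0.0
    prolif_mode: str = "tension"
    c_pe: float = 0.25
    c_e0: float = 0.035
    c_e1: float = 0.070
    c_e2: float = 0.105
    c_de: float = 0.5
    rho_T: float = 1.0
    phi_w: float = 0.70
    a_mu: float = 1.0
    c_dmu: float = 0.7
    a_k: float = 1.0
    c_dk: float = 1.0
    a_kmu: float = 0.02
    a_c: float = 0.02

    def __post_init__(self) -> None:
        for name in ("c_pc", "c_a", "c_c0", "c_c1", "c_c2", "c_cp_f", "c_p0",
                     "c_p_f", "c_pe", "c_e0", "c_e1", "c_e2", "c_de", "rho_T",
                     "a_mu", "c_dmu", "a_k", "c_dk", "a_kmu", "a_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"RateParams.{name} must be >= 0")
        if self.c_pc <= self.c_p0:
            raise ValueError("need c_pc > c_p0 for a positive homeostatic state")
        if not self.mu_1 < self.mu_2:
            raise ValueError("need mu_1 < mu_2")
        if not 0.0 < self.phi_w < 1.0:
            raise ValueError("phi_w must lie in (0, 1)")
        if self.switch_mode not in ("tension", "compression"):
            raise ValueError("switch_mode must be 'tension' or 'compression'")
        if self.prolif_mode not in ("tension", "compression"):
            raise ValueError("prolif_mode must be 'tension' or 'compression'")

    @property
    def phi_solid(self) -> float:
        return 1.0 - self.phi_w


@dataclass
class ConstituentFields:
    """Volume fractions on the material grids.

    ``phi_c``, ``phi_p``, ``phi_e`` live on the outer-layer grid; the inner
    layer (SBM) is pure ECM, ``phi_e_inner`` on the inner-layer grid
    (identically 1 - phi_w by the no-voids constraint).
    """

    phi_c: np.ndarray
    phi_p: np.ndarray
    phi_e: np.ndarray
    phi_e_inner: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phi_c", "phi_p", "phi_e", "phi_e_inner"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("phi_c", "phi_p", "phi_e"):
            arr = getattr(self, name)
            if np.any(arr < -1e-12) or np.any(arr > 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def homeostatic(cls, rates: RateParams, geom: GrownGeometry) -> "ConstituentFields":
        phi_c, phi_p, phi_e = homeostatic_state(rates)
        n_out = geom.xi_outer_layer.size
        return cls(
            phi_c=np.full(n_out, phi_c),
            phi_p=np.full(n_out, phi_p),
            phi_e=np.full(n_out, phi_e),
            phi_e_inner=np.full(geom.xi_inner_layer.size, rates.phi_solid),
        )

    @property
    def phi_solid_outer(self) -> np.ndarray:
        return self.phi_c + self.phi_p + self.phi_e


def switching_rate(mu, tau, rates: RateParams):
    """Contractile -> proliferative switching rate c_cp(mu, tau).

    Tiered in inflammation (healthy / mild / severe via strict thresholds
    mu_1 < mu_2) plus a stress-modulated term: in tension mode
    ``c_cp_f * tau * H(tau)``; in compression mode the magnitude convention
    ``c_cp_f * (-tau) * H(-tau)``, so the added rate is never negative.
    """
    base = (rates.c_c0
            + (rates.c_c1 - rates.c_c0) * _H(mu - rates.mu_1)
            + (rates.c_c2 - rates.c_c1) * _H(mu - rates.mu_2))
    tau = np.asarray(tau, dtype=float)
    if rates.switch_mode == "tension":
        stress_term = rates.c_cp_f * np.where(tau > 0.0, tau, 0.0)
    else:
        stress_term = rates.c_cp_f * np.where(tau < 0.0, -tau, 0.0)
    out = base + stress_term
    if np.any(out < 0.0):
        warnings.warn("switching rate clipped at zero", RuntimeWarning)
        out = np.clip(out, 0.0, None)
    return out if np.ndim(out) else float(out)


def proliferation_rate(tau, rates: RateParams):
    """Proliferation/recruitment rate c_p(tau), stress-modulated as above."""
    tau = np.asarray(tau, dtype=float)
    if rates.prolif_mode == "tension":
        stress_term = rates.c_p_f * np.where(tau > 0.0, tau, 0.0)
    else:
        stress_term = rates.c_p_f * np.where(tau < 0.0, -tau, 0.0)
    out = rates.c_p0 + stress_term
    return out if np.ndim(out) else float(out)


def ecm_deposition_rate(mu, rates: RateParams):
    """Inflammation-tiered ECM deposition rate c_be(mu) (right-continuous steps)."""
    out = (rates.c_e0
           + (rates.c_e1 - rates.c_e0) * _H(mu - rates.mu_1)
           + (rates.c_e2 - rates.c_e1) * _H(mu - rates.mu_2))
    return out if np.ndim(out) else float(out)


def source_terms(fields: ConstituentFields, mu, tau, rates: RateParams,
                 sbm_thickening: bool = False):
    """Volume-fraction source terms per node (1/day).

    ``tau`` is the fibre stress on the outer-layer nodes (array or scalar).
    Returns ``(S_c, S_p, S_e, S_e_inner)``.

    Outer layer (with rho_T equal for all phases):

        S_c = c_pc Phi_p - c_a rho_T Phi_c^2 - c_cp(mu,tau) Phi_c
        S_p = (c_p(tau) - c_pc) Phi_p + c_cp(mu,tau) Phi_c
        S_e = c_pe Phi_p + c_be(mu)/rho_T - c_de Phi_e

    Inner layer (SBM): zero unless ``sbm_thickening``, in which case ECM
    turnover uses the outer-layer tier increments on top of a baseline
    deposition balanced against degradation of the resting SBM (so the
    unchallenged SBM is in equilibrium and only inflammation drives its
    thickening).
    """
    c_cp = switching_rate(mu, tau, rates)
    c_p = proliferation_rate(tau, rates)
    c_be = ecm_deposition_rate(mu, rates)
    S_c = rates.c_pc * fields.phi_p - rates.c_a * rates.rho_T * fields.phi_c**2 \
        - c_cp * fields.phi_c
    S_p = (c_p - rates.c_pc) * fields.phi_p + c_cp * fields.phi_c
    S_e = rates.c_pe * fields.phi_p + c_be / rates.rho_T - rates.c_de * fields.phi_e
    if sbm_thickening:
        # baseline deposition re-balanced for the pure-ECM resting SBM
        c_be_inner = rates.c_de * rates.rho_T * rates.phi_solid + (c_be - rates.c_e0)
        S_e_inner = (c_be_inner / rates.rho_T
                     - rates.c_de * fields.phi_e_inner) * np.ones_like(fields.phi_e_inner)
    else:
        S_e_inner = np.zeros_like(fields.phi_e_inner)
    return S_c, S_p, S_e, S_e_inner


def homeostatic_state(rates: RateParams):
    """Closed-form non-trivial steady state (Phi_c*, Phi_p*, Phi_e*).

    Setting the source terms to zero at mu = tau = 0 gives

        Phi_c* = c_p0 c_c0 / (c_a (c_pc - c_p0) rho_T)
        Phi_p* = c_p0 c_c0^2 / (c_a (c_pc - c_p0)^2 rho_T)
        Phi_e* = (c_e0/rho_T + c_pe Phi_p*) / c_de

    Warns if the triple does not fill the solid fraction 1 - phi_w (the
    config loader re-solves c_e0 to enforce the partition).
    """
    if rates.c_pc <= rates.c_p0:
        raise ValueError("no positive steady state: need c_pc > c_p0")
    denom = rates.c_a * (rates.c_pc - rates.c_p0) * rates.rho_T
    phi_c = rates.c_p0 * rates.c_c0 / denom
    phi_p = phi_c * rates.c_c0 / (rates.c_pc - rates.c_p0)
    phi_e = (rates.c_e0 / rates.rho_T + rates.c_pe * phi_p) / rates.c_de
    total = phi_c + phi_p + phi_e
    if abs(total - rates.phi_solid) > 1e-9:
        warnings.warn(
            f"homeostatic fractions sum to {total:.6f}, not {rates.phi_solid:.2f}; "
            "re-solve c_e0 to fill the solid fraction", RuntimeWarning)
    return phi_c, phi_p, phi_e


def balanced_c_e0(rates: RateParams) -> float:
    """c_e0 that makes the homeostatic state fill the solid fraction exactly."""
    denom = rates.c_a * (rates.c_pc - rates.c_p0) * rates.rho_T
    phi_c = rates.c_p0 * rates.c_c0 / denom
    phi_p = phi_c * rates.c_c0 / (rates.c_pc - rates.c_p0)
    phi_e = rates.phi_solid - phi_c - phi_p
    if phi_e <= 0:
        raise ValueError("ASMC fractions already exceed the solid fraction; "
                         "no admissible c_e0")
    return (rates.c_de * phi_e - rates.c_pe * phi_p) * rates.rho_T


def well_mixed_rhs(phi, mu, tau, rates: RateParams):
    """RHS of the spatially homogeneous (well-mixed) 3-ODE system.

    Used for linear-stability analysis and as the root-finding oracle for
    the homeostatic closed form.  Evaluates the source formulas directly
    (no volume-fraction range validation), so iterative solvers may probe
    unphysical states.
    """
    phi_c, phi_p, phi_e = phi
    c_cp = switching_rate(mu, tau, rates)
    c_p = proliferation_rate(tau, rates)
    c_be = ecm_deposition_rate(mu, rates)
    S_c = rates.c_pc * phi_p - rates.c_a * rates.rho_T * phi_c**2 - c_cp * phi_c
    S_p = (c_p - rates.c_pc) * phi_p + c_cp * phi_c
    S_e = rates.c_pe * phi_p + c_be / rates.rho_T - rates.c_de * phi_e
    return np.array([S_c, S_p, S_e])


def mixture_dilatation(S_c, S_p, S_e, rates: RateParams):
    """Mixture dilatation q = (S_c + S_p + S_e)/(1 - phi_w) (1/day)."""
    return (np.asarray(S_c) + np.asarray(S_p) + np.asarray(S_e)) / rates.phi_solid


def growth_velocity(q_inner, q_outer, geom: GrownGeometry):
    """Radial growth velocity v(xi) on both layer grids (mm/day).

    Integrates (1/xi) d(xi v)/dxi = q inward from the pinned outer wall:

        v(xi) = -(1/xi) * integral_{xi}^{xi2} zeta q(zeta) dzeta,

    by cumulative trapezoid per layer; velocity continuity at the interface
    is automatic and v(xi2) = 0 exactly.  Returns ``(v_inner, v_outer)``.
    """
    q_inner = np.asarray(q_inner, dtype=float) * np.ones_like(geom.xi_inner_layer)
    q_outer = np.asarray(q_outer, dtype=float) * np.ones_like(geom.xi_outer_layer)
    zq_out = geom.xi_outer_layer * q_outer
    # I_out[j] = integral from xi_j to xi2 of zeta q dzeta
    cum_out = np.concatenate([[0.0], np.cumsum(
        0.5 * (zq_out[1:] + zq_out[:-1]) * np.diff(geom.xi_outer_layer))])
    I_out = cum_out[-1] - cum_out
    v_outer = -I_out / geom.xi_outer_layer
    zq_in = geom.xi_inner_layer * q_inner
    cum_in = np.concatenate([[0.0], np.cumsum(
        0.5 * (zq_in[1:] + zq_in[:-1]) * np.diff(geom.xi_inner_layer))])
    I_in = I_out[0] + (cum_in[-1] - cum_in)
    v_inner = -I_in / geom.xi_inner_layer
    return v_inner, v_outer


def advance_growth(fields: ConstituentFields, geom: GrownGeometry, sources,
                   q_inner, q_outer, v_inner, v_outer, dt: float):
    """One explicit Lagrangian growth step: material points carry the fields.

    Updates ``dPhi_a/dt = S_a - Phi_a q`` and ``dxi/dt = v`` per node; the
    outer wall stays pinned (v(xi2) = 0 by construction, and xi2 is re-pinned
    to R2 against drift).  Returns ``(fields', geom')``.

    Raises
    ------
    GridTanglingError
        If a step destroys the monotonicity of either grid.
    """
    S_c, S_p, S_e, S_e_inner = sources
    q_outer = np.asarray(q_outer, dtype=float)
    q_inner = np.asarray(q_inner, dtype=float)
    xi_in = geom.xi_inner_layer + dt * v_inner
    xi_out = geom.xi_outer_layer + dt * v_outer
    xi_out[-1] = geom.R2
    xi_in[-1] = xi_out[0]  # keep grids conforming at the interface
    if np.any(np.diff(xi_in) <= 0) or np.any(np.diff(xi_out) <= 0) or xi_in[0] <= 0:
        raise GridTanglingError(
            f"growth step dt={dt} tangled the material grid "
            f"(xi1={xi_in[0]:.4g}, xi_int={xi_out[0]:.4g})")
    new_fields = ConstituentFields(
        phi_c=fields.phi_c + dt * (S_c - fields.phi_c * q_outer),
        phi_p=fields.phi_p + dt * (S_p - fields.phi_p * q_outer),
        phi_e=fields.phi_e + dt * (S_e - fields.phi_e * q_outer),
        phi_e_inner=fields.phi_e_inner + dt * (S_e_inner - fields.phi_e_inner * q_inner),
    )
    new_geom = GrownGeometry(xi_inner_layer=xi_in, xi_outer_layer=xi_out,
                             R1=geom.R1, Rint=geom.Rint, R2=geom.R2)
    return new_fields, new_geom
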