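"""Hyperelastic constitutive law for the multiphase airway wall.

The wall is a constrained mixture of three solid phases sharing one elastic
deformation: contractile airway smooth muscle cells (ASMCs, ``c``),
proliferative ASMCs (``p``) and a collagen-dominated extracellular matrix
(``e``), plus a mechanically inert fluid phase.  The mixture strain energy is
the volume-fraction-weighted sum of per-constituent strain energies,

    Psi = Phi_c W_c + Phi_p W_p + Phi_e W_e,

with the proliferative phase an isotropic neo-Hookean solid and the
contractile/ECM phases fibre-reinforced solids: a neo-Hookean ground matrix
plus two symmetric helical fibre families (angle ``alpha`` from the
circumferential direction) with an exponential stress-stretch response.
ECM collagen is crimped and bears load only once the fibre stretch exceeds
the recruitment stretch ``lambda_u``.

Contraction enters as an active fibre stress ``Phi_c * A_c(k)`` along the
two families, where ``A_c`` saturates with agonist concentration ``k``
following a Hill curve.

All functions accept scalars or numpy arrays for the kinematic/field
arguments and broadcast elementwise.  Stresses are in kPa; the deformation
is plane strain (``lam_z = 1``) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "PointKinematics",
    "StressComponents",
    "active_force_density",
    "passive_stress_deviatoric",
    "total_stress",
    "fibre_invariant",
    "mixture_strain_energy",
]


@dataclass(frozen=True)
class MaterialParams:
    """Hyperelastic and active-tone coefficients.

    Stiffnesses are per unit *constituent* volume (they are weighted by the
    volume fractions when assembling the mixture stress).

    Attributes
    ----------
    c_ground : float
        Neo-Hookean ground-matrix stiffness (kPa) shared by the contractile
        and ECM phases.
    c_neo : float
        Neo-Hookean stiffness (kPa) of the proliferative phase.
    k1_c, k2_c : float
        Exponential fibre coefficients of the contractile ASMC phase
        (kPa, dimensionless).
    k1_e, k2_e : float
        Exponential fibre coefficients of the ECM collagen phase.
    lambda_u : float
        Collagen recruitment stretch (>= 1); ECM fibres are slack below it.
    alpha : float
        Helical fibre angle from the circumferential direction (radians).
    T_c : float
        Maximal contractile force density (kPa); a measure of
        hyper-responsiveness.
    K_d : float
        Agonist dissociation constant (in units of k**n_hill).
    n_hill : float
        Hill coefficient (cooperativity).
    """

    c_ground: float = 8.0
    c_neo: float = 8.0
    k1_c: float = 4.0
    k2_c: float = 1.5
    k1_e: float = 25.0
    k2_e: float = 2.0
    lambda_u: float = 1.2
    alpha: float = np.deg2rad(5.0)
    T_c: float = 20.0
    K_d: float = 0.5
    n_hill: float = 2.0

    def __post_init__(self) -> None:
        for name in ("c_ground", "c_neo", "k1_c", "k2_c", "k1_e", "k2_e", "T_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"MaterialParams.{name} must be >= 0")
        if self.lambda_u < 1.0:
            raise ValueError("lambda_u must be >= 1")
        if not 0.0 <= self.alpha < np.pi / 2:
            raise ValueError("alpha must lie in [0, pi/2)")
        if self.K_d <= 0:
            raise ValueError("K_d must be > 0")
        if self.n_hill <= 0:
            raise ValueError("n_hill must be > 0")


@dataclass(frozen=True)
class PointKinematics:
    """Principal elastic stretches at a material point (plane strain).

    Incompressibility requires ``lam_r * lam_th * lam_z == 1``.
    """

    lam_r: float
    lam_th: float
    lam_z: float = 1.0

    def __post_init__(self) -> None:
        det = np.asarray(self.lam_r) * np.asarray(self.lam_th) * np.asarray(self.lam_z)
        if not np.allclose(det, 1.0, rtol=1e-8, atol=1e-10):
            raise ValueError("stretches violate incompressibility: lam_r*lam_th*lam_z != 1")

    def I4(self, alpha: float) -> np.ndarray | float:
        """Squared fibre stretch for a helical family at angle ``alpha``."""
        return fibre_invariant(self.lam_th, self.lam_z, alpha)


@dataclass(frozen=True)
class StressComponents:
    """Cauchy stress at a material point (axisymmetric, torsion-free)."""

    Trr: float
    Tth: float
    Tzz: float
    p_lagrange: float
    tau: float


def fibre_invariant(lam_th, lam_z, alpha: float):
    """I4 = lam_th^2 cos^2(alpha) + lam_z^2 sin^2(alpha) for a helical family."""
    c2, s2 = np.cos(alpha) ** 2, np.sin(alpha) ** 2
    return np.asarray(lam_th) ** 2 * c2 + np.asarray(lam_z) ** 2 * s2


def active_force_density(k, mat: MaterialParams):
    """Hill-saturating contractile force density A_c(k) = T_c k^n / (K_d + k^n).

    Parameters
    ----------
    k : float or array
        Agonist concentration (non-negative, arbitrary concentration units).
    mat : MaterialParams

    Returns
    -------
    float or array
        Force density in kPa, bounded in [0, T_c).
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("agonist concentration k must be >= 0")
    kn = k**mat.n_hill
    out = mat.T_c * kn / (mat.K_d + kn)
    return out if out.ndim else float(out)


def _dW_dI1(phi_c, phi_p, phi_e, mat: MaterialParams):
    """Mixture d(Psi)/dI1 (isotropic ground-matrix part)."""
    return 0.5 * (
        np.asarray(phi_c) * mat.c_ground
        + np.asarray(phi_p) * mat.c_neo
        + np.asarray(phi_e) * mat.c_ground
    )


def _dW_dI4(phi_c, phi_e, I4, mat: MaterialParams):
    """Mixture d(Psi)/dI4 (fibre part; tension-only, ECM recruitment-shifted)."""
    I4 = np.asarray(I4, dtype=float)
    xc = np.maximum(I4 - 1.0, 0.0)  # tension-only fibre response
    dWc = mat.k1_c * xc * np.exp(mat.k2_c * xc**2)
    xe = np.maximum(I4 - mat.lambda_u**2, 0.0)  # crimped below recruitment
    dWe = mat.k1_e * xe * np.exp(mat.k2_e * xe**2)
    return np.asarray(phi_c) * dWc + np.asarray(phi_e) * dWe


def mixture_strain_energy(kin: PointKinematics, phi, mat: MaterialParams) -> float:
    """Strain energy per unit mixture volume, Psi = sum_a Phi_a W_a (kPa).

    Used mainly as an independent check that the analytic stress equals
    2 F (dPsi/dC) F^T.
    """
    phi_c, phi_p, phi_e = phi
    I1 = kin.lam_r**2 + kin.lam_th**2 + kin.lam_z**2
    I4 = kin.I4(mat.alpha)
    W_iso = 0.5 * (I1 - 3.0)
    xc = max(I4 - 1.0, 0.0)
    W_fib_c = (mat.k1_c / (2.0 * mat.k2_c)) * (np.exp(mat.k2_c * xc**2) - 1.0)
    xe = max(I4 - mat.lambda_u**2, 0.0)
    W_fib_e = (mat.k1_e / (2.0 * mat.k2_e)) * (np.exp(mat.k2_e * xe**2) - 1.0)
    W_c = mat.c_ground * W_iso + W_fib_c
    W_p = mat.c_neo * W_iso
    W_e = mat.c_ground * W_iso + W_fib_e
    return float(phi_c * W_c + phi_p * W_p + phi_e * W_e)


def passive_stress_deviatoric(kin: PointKinematics, phi, mat: MaterialParams):
    """Passive extra stress components (Trr_hat, Tth_hat, Tzz_hat) in kPa.

    Computed as 2 F (dPsi/dC) F^T with the two symmetric helical fibre
    families, normalised so that the unstrained reference state is exactly
    stress-free (the isotropic offset 2*dPsi/dI1 at identity is absorbed
    into the Lagrange multiplier, which only shifts the pressure split and
    never the stress differences that drive equilibrium).

    The ECM fibre term vanishes identically below the recruitment stretch
    ``lambda_u``; both fibre terms are tension-only.
    """
    phi_c, phi_p, phi_e = phi
    W1 = _dW_dI1(phi_c, phi_p, phi_e, mat)
    I4 = fibre_invariant(kin.lam_th, kin.lam_z, mat.alpha)
    W4 = _dW_dI4(phi_c, phi_e, I4, mat)
    c2, s2 = np.cos(mat.alpha) ** 2, np.sin(mat.alpha) ** 2
    ref = 2.0 * W1  # isotropic value at identity, subtracted for a stress-free reference
    Trr = 2.0 * W1 * kin.lam_r**2 - ref
    Tth = 2.0 * W1 * kin.lam_th**2 + 2.0 * W4 * kin.lam_th**2 * c2 - ref
    Tzz = 2.0 * W1 * kin.lam_z**2 + 2.0 * W4 * kin.lam_z**2 * s2 - ref
    return Trr, Tth, Tzz


def total_stress(kin: PointKinematics, phi, k, p_lagrange, mat: MaterialParams) -> StressComponents:
    """Total Cauchy stress T = -p 1 + T_passive + T_active and fibre stress tau.

    The active stress is distributed over the two symmetric helical families
    (half of ``Phi_c A_c`` each) so that the total force density along the
    fibres is ``Phi_c A_c``; with both families at angle +/- alpha the theta-z
    shear cancels and the normal components are
    ``Phi_c A_c cos^2(alpha)`` (hoop) and ``Phi_c A_c sin^2(alpha)`` (axial).

    tau projects the stress on the fibre directions:
    ``tau = Tth cos^2(alpha) + Tzz sin^2(alpha)``.
    """
    phi_c = phi[0]
    Trr_hat, Tth_hat, Tzz_hat = passive_stress_deviatoric(kin, phi, mat)
    A = active_force_density(k, mat)
    c2, s2 = np.cos(mat.alpha) ** 2, np.sin(mat.alpha) ** 2
    Trr = -p_lagrange + Trr_hat
    Tth = -p_lagrange + Tth_hat + phi_c * A * c2
    Tzz = -p_lagrange + Tzz_hat + phi_c * A * s2
    tau = Tth * c2 + Tzz * s2
    return StressComponents(Trr=Trr, Tth=Tth, Tzz=Tzz, p_lagrange=p_lagrange, tau=tau)
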