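"""Full simulation orchestration, outcome metrics, and parameter sweeps.

One growth step couples the sub-models by operator splitting in a fixed
order — stimuli (challenge train, inflammation), mechanics (quasi-static
equilibrium on the current grown geometry), agonist update (using the fresh
fibre-stress field), then growth (sources, dilatation, velocity, Lagrangian
advance) — so that the mechanotransductive terms always see the current
constricted state.  The default step is 0.05 day.

Outcome metrics follow the experimental read-outs: the remodelled
(grown-configuration) inner radius 5 days after the final challenge, and the
agonist resolution time — days from the final challenge until the
cross-sectional agonist total falls below 1e-6 (censored at the horizon if
it never does).  Runs in which the airway grows or contracts completely into
the lumen are flagged closed and discarded from sweep surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .config import SimulationConfig, set_param
from .growth import (ConstituentFields, GridTanglingError, advance_growth,
                     growth_velocity, mixture_dilatation, source_terms)
from .mechanics import (EquilibriumError, GrownGeometry, LoadCase,
                        solve_equilibrium)
from .stimuli import step_agonist, step_inflammation, total_agonist

__all__ = [
    "SimulationResult",
    "SweepResult",
    "ResolutionTime",
    "run_simulation",
    "remodelled_inner_radius",
    "agonist_resolution_time",
    "parameter_sweep",
]

log = logging.getLogger("airwaymorph")

AGONIST_RESOLUTION_THRESHOLD = 1e-6


@dataclass
class SimulationResult:
    """Scalar time series plus transmural snapshots from one run.

    All series are aligned with ``t`` (days).  ``xi1`` is the grown
    (unloaded) inner radius; ``r1`` the loaded/constricted one from the
    equilibrium solve.  ``snapshots`` maps requested day -> dict of nodal
    arrays (xi, r, phi_c, phi_p, phi_e, k, Trr, Tth, Tzz, tau).
    """

    t: np.ndarray
    mu: np.ndarray
    k_total: np.ndarray
    xi1: np.ndarray
    xi_int: np.ndarray
    r1: np.ndarray
    wall_thickness: np.ndarray
    mean_phi_c: np.ndarray
    mean_phi_p: np.ndarray
    mean_phi_e: np.ndarray
    min_tau: np.ndarray
    max_tau: np.ndarray
    snapshots: dict = field(default_factory=dict)
    max_solid_fraction_err: float = 0.0
    max_incompressibility_err_mm2: float = 0.0
    closed: bool = False
    aborted: str | None = None
    config: SimulationConfig | None = None
    final_fields: ConstituentFields | None = None
    final_geom: GrownGeometry | None = None
    final_k: np.ndarray | None = None

    @property
    def last_challenge(self) -> float:
        return self.config.protocol.last_event if self.config else 0.0


class ResolutionTime(NamedTuple):
    """Agonist resolution time; ``days`` is None when censored."""

    days: float | None
    censored: bool


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run one coupled mechanochemical growth simulation.

    Deterministic given the config.  Aborts (with partial series and a
    diagnostic) on airway closure, equilibrium failure or grid tangling.
    """
    rates = cfg.effective_rates()
    proto = cfg.protocol
    mat = cfg.mat
    loads = LoadCase(P1=cfg.P1, P2=cfg.P2)
    geom = GrownGeometry.reference(cfg.R1, cfg.Rint, cfg.R2, cfg.nodes_per_layer)
    fields = ConstituentFields.homeostatic(rates, geom)
    n_nodes = geom.xi_all.size
    n_in = geom.n_inner
    mu = 0.0
    k = np.zeros(n_nodes)

    n_steps = int(round(proto.horizon / cfg.dt))
    snap_steps = {int(round(d / cfg.dt)): d for d in cfg.snapshot_days}
    series = {name: np.empty(n_steps + 1) for name in
              ("t", "mu", "k_total", "xi1", "xi_int", "r1", "wall_thickness",
               "mean_phi_c", "mean_phi_p", "mean_phi_e", "min_tau", "max_tau")}
    snapshots: dict = {}
    closed = False
    aborted = None
    max_solid_err = 0.0
    max_incomp_err = 0.0
    phi_solid = rates.phi_solid

    def record(i, t, mech):
        series["t"][i] = t
        series["mu"][i] = mu
        series["k_total"][i] = total_agonist(k, geom, cfg.agonist_weighting)
        series["xi1"][i] = geom.xi1
        series["xi_int"][i] = geom.xi_int
        series["r1"][i] = mech.r1
        series["wall_thickness"][i] = geom.xi2 - geom.xi1
        series["mean_phi_c"][i] = fields.phi_c.mean()
        series["mean_phi_p"][i] = fields.phi_p.mean()
        series["mean_phi_e"][i] = fields.phi_e.mean()
        series["min_tau"][i] = mech.tau.min()
        series["max_tau"][i] = mech.tau.max()
        nonlocal max_solid_err, max_incomp_err
        max_solid_err = max(
            max_solid_err,
            float(np.abs(fields.phi_solid_outer - phi_solid).max()),
            float(np.abs(fields.phi_e_inner - phi_solid).max()))
        max_incomp_err = max(max_incomp_err, float(np.abs(
            mech.r**2 - (mech.r1**2 + mech.xi**2 - mech.xi[0]**2)).max()))

    i_last = 0
    r1_prev = None
    try:
        mech = solve_equilibrium(geom, fields, k, loads, mat)
        record(0, 0.0, mech)
        for i in range(1, n_steps + 1):
            t = (i - 1) * cfg.dt
            mu = step_inflammation(mu, t, cfg.dt, proto, rates)
            mech = solve_equilibrium(geom, fields, k, loads, mat, r1_init=r1_prev)
            r1_prev = mech.r1
            k = step_agonist(k, mu, mech.tau, cfg.dt, proto, rates, t=t)
            tau_outer = mech.tau[n_in:]
            S = source_terms(fields, mu, tau_outer, rates,
                             sbm_thickening=cfg.sbm_thickening)
            q_outer = mixture_dilatation(S[0], S[1], S[2], rates)
            q_inner = np.asarray(S[3]) / rates.phi_solid
            v_inner, v_outer = growth_velocity(q_inner, q_outer, geom)
            if geom.xi1 + cfg.dt * v_inner[0] < cfg.closure_radius_mm:
                closed = True  # inward growth would cross the lumen this step
                log.info("airway grew into the lumen at day %.2f; run discarded",
                         i * cfg.dt)
                break
            fields, geom = advance_growth(fields, geom, S, q_inner, q_outer,
                                          v_inner, v_outer, cfg.dt)
            record(i, i * cfg.dt, mech)
            i_last = i
            if i in snap_steps:
                snapshots[snap_steps[i]] = {
                    "xi": geom.xi_all.copy(), "r": mech.r.copy(),
                    "phi_c": np.concatenate([np.zeros(n_in), fields.phi_c]),
                    "phi_p": np.concatenate([np.zeros(n_in), fields.phi_p]),
                    "phi_e": np.concatenate([fields.phi_e_inner, fields.phi_e]),
                    "k": k.copy(), "Trr": mech.Trr.copy(), "Tth": mech.Tth.copy(),
                    "Tzz": mech.Tzz.copy(), "tau": mech.tau.copy(),
                }
            if mech.closed or geom.xi1 < cfg.closure_radius_mm:
                closed = True
                log.info("airway closed at day %.2f; run discarded from sweeps",
                         i * cfg.dt)
                break
    except (EquilibriumError, GridTanglingError) as exc:
        aborted = f"{type(exc).__name__}: {exc}"
        log.warning("run aborted at day %.2f: %s", i_last * cfg.dt, aborted)

    sl = slice(0, i_last + 1)
    return SimulationResult(
        **{name: arr[sl] for name, arr in series.items()},
        snapshots=snapshots, closed=closed, aborted=aborted, config=cfg,
        max_solid_fraction_err=max_solid_err,
        max_incompressibility_err_mm2=max_incomp_err,
        final_fields=fields, final_geom=geom, final_k=k,
    )


def remodelled_inner_radius(result: SimulationResult, days_post: float = 5.0) -> float:
    """Grown-configuration inner radius xi1 at ``days_post`` after the final
    challenge (linear interpolation on the stored series)."""
    t_query = result.last_challenge + days_post
    if result.t[-1] + 1e-9 < t_query:
        raise ValueError(
            f"series ends at day {result.t[-1]:.2f}, before query day {t_query:.2f}")
    return float(np.interp(t_query, result.t, result.xi1))


def loaded_inner_radius(result: SimulationResult, days_post: float = 5.0) -> float:
    """Loaded (pressurized/constricted) inner radius at the same query time."""
    t_query = result.last_challenge + days_post
    return float(np.interp(t_query, result.t, result.r1))


def agonist_resolution_time(result: SimulationResult,
                            threshold: float = AGONIST_RESOLUTION_THRESHOLD) -> ResolutionTime:
    """Days from the final challenge until the cross-sectional agonist total
    first falls below ``threshold``; censored if it never does.

    The crossing is located by log-linear interpolation between bracketing
    samples (exact for exponential decay).
    """
    t0 = result.last_challenge
    mask = result.t >= t0
    t = result.t[mask]
    ktot = result.k_total[mask]
    if t.size == 0:
        return ResolutionTime(days=None, censored=True)
    below = ktot < threshold
    if below[0]:
        return ResolutionTime(days=0.0, censored=False)
    idx = np.argmax(below)
    if not below[idx]:
        return ResolutionTime(days=None, censored=True)
    ta, tb = t[idx - 1], t[idx]
    ka, kb = ktot[idx - 1], ktot[idx]
    if ka > 0 and kb > 0:
        frac = (np.log(ka) - np.log(threshold)) / (np.log(ka) - np.log(kb))
    else:
        frac = (ka - threshold) / (ka - kb)
    return ResolutionTime(days=float(ta + frac * (tb - ta) - t0), censored=False)


@dataclass
class SweepResult:
    """Two-parameter sweep surfaces.

    ``radius`` is the remodelled inner radius (mm), ``resolution_days`` the
    agonist resolution time (NaN where censored), with masks for closed
    (discarded) and censored runs.  Axis 1 varies along rows, axis 2 along
    columns.
    """

    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    radius: np.ndarray
    resolution_days: np.ndarray
    closed_mask: np.ndarray
    censored_mask: np.ndarray


def parameter_sweep(cfg: SimulationConfig, axis1, axis2,
                    days_post: float = 5.0) -> SweepResult:
    """Independent runs over a 2-D parameter grid (order-independent).

    ``axis1``/``axis2`` are ``(dotted_name, grid)`` pairs understood by
    :func:`airwaymorph.config.set_param`.  Closed runs are masked and their
    surfaces set to NaN (the discard rule).
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    shape = (grid1.size, grid2.size)
    radius = np.full(shape, np.nan)
    res_days = np.full(shape, np.nan)
    closed = np.zeros(shape, dtype=bool)
    censored = np.zeros(shape, dtype=bool)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            cfg_ij = set_param(set_param(cfg, name1, v1), name2, v2)
            result = run_simulation(cfg_ij)
            if result.closed or result.aborted:
                closed[i, j] = True
                continue
            radius[i, j] = remodelled_inner_radius(result, days_post)
            rt = agonist_resolution_time(result)
            censored[i, j] = rt.censored
            if not rt.censored:
                res_days[i, j] = rt.days
    return SweepResult(
        axis1_name=name1, axis1_grid=grid1, axis2_name=name2, axis2_grid=grid2,
        radius=radius, resolution_days=res_days,
        closed_mask=closed, censored_mask=censored,
    )
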