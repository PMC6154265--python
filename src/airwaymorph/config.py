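"""Run configuration: schema, defaults, validation, JSON round-trip.

A :class:`SimulationConfig` aggregates the geometry, material and rate
parameters, the challenge protocol and the numerical settings of one
simulation.  ``load_config``/``dump_config`` provide a strict JSON
round-trip: unknown keys are a hard error, and invariants (e.g. the
positive-steady-state condition c_pc > c_p0) are enforced on load.

On load the baseline ECM deposition rate ``c_e0`` is re-solved so that the
homeostatic state fills the solid fraction exactly (logged at INFO); the
partition Phi_c* + Phi_p* + Phi_e* = 1 - phi_w is a model requirement, not a
free choice.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constitutive import MaterialParams
from .growth import RateParams, balanced_c_e0
from .stimuli import ChallengeProtocol

__all__ = ["SimulationConfig", "load_config", "dump_config", "set_param"]

log = logging.getLogger("airwaymorph")

_MODES = ("combined", "inflammation_only", "agonist_only")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, validated description of one simulation run.

    Geometry defaults follow large (generation-4-sized) airways: inner
    radius 1.8 mm, a thin collagenous SBM to 1.9 mm, outer wall at 2.3 mm.
    The simulator itself is deterministic; ``seed`` only feeds synthetic
    data generation for fitting fixtures.
    """

    R1: float = 1.8
    Rint: float = 1.9
    R2: float = 2.3
    nodes_per_layer: int = 101
    dt: float = 0.05
    P1: float = 0.0
    P2: float = 0.0
    challenge_mode: str = "combined"
    sbm_thickening: bool = False
    closure_radius_mm: float = 0.01
    agonist_weighting: str = "area"
    snapshot_days: tuple = ()
    seed: int = 0
    mat: MaterialParams = field(default_factory=MaterialParams)
    rates: RateParams = field(default_factory=RateParams)
    protocol: ChallengeProtocol = field(
        default_factory=lambda: ChallengeProtocol.periodic(omega=0.2))

    def __post_init__(self) -> None:
        if not 0 < self.R1 < self.Rint < self.R2:
            raise ValueError("need 0 < R1 < Rint < R2")
        if self.nodes_per_layer < 3:
            raise ValueError("nodes_per_layer must be >= 3")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.challenge_mode not in _MODES:
            raise ValueError(f"challenge_mode must be one of {_MODES}")
        if self.agonist_weighting not in ("area", "radial"):
            raise ValueError("agonist_weighting must be 'area' or 'radial'")
        object.__setattr__(self, "snapshot_days",
                           tuple(float(d) for d in self.snapshot_days))

    def effective_rates(self) -> RateParams:
        """Rates with the challenge mode applied (a_k or a_mu zeroed)."""
        if self.challenge_mode == "inflammation_only":
            return replace(self.rates, a_k=0.0)
        if self.challenge_mode == "agonist_only":
            return replace(self.rates, a_mu=0.0)
        return self.rates


def _as_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["snapshot_days"] = list(d["snapshot_days"])
    d["protocol"]["event_times"] = list(d["protocol"]["event_times"])
    return d


def dump_config(cfg: SimulationConfig, path) -> None:
    """Serialize the config to JSON (full float precision)."""
    Path(path).write_text(json.dumps(_as_dict(cfg), indent=2))


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict, rebalance_c_e0: bool = True) -> SimulationConfig:
    """Load and validate a config from a JSON file (or an already-parsed dict).

    Missing blocks/keys take their defaults; unknown keys raise ``ValueError``
    naming the offending key.  ``c_e0`` is re-solved so the homeostatic state
    fills the solid fraction (disable with ``rebalance_c_e0=False``).
    """
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        data = json.loads(Path(path_or_dict).read_text())
    mat = _build(MaterialParams, data.pop("mat", {}), "mat")
    rates = _build(RateParams, data.pop("rates", {}), "rates")
    proto_data = dict(data.pop("protocol", {}))
    if "omega" in proto_data:
        omega = proto_data.pop("omega")
        t1 = proto_data.pop("t1", 1.0)
        proto = ChallengeProtocol.periodic(omega=omega, t1=t1, **proto_data)
    else:
        proto = _build(ChallengeProtocol, proto_data, "protocol")
    if rebalance_c_e0:
        c_e0 = balanced_c_e0(rates)
        if not np.isclose(c_e0, rates.c_e0, rtol=0, atol=1e-12):
            log.info("re-solved c_e0 = %.6g (was %.6g) to fill the solid fraction",
                     c_e0, rates.c_e0)
            rates = replace(rates, c_e0=c_e0)
    cfg = _build(SimulationConfig,
                 {**data, "mat": mat, "rates": rates, "protocol": proto},
                 "config")
    return cfg


def set_param(cfg: SimulationConfig, name: str, value) -> SimulationConfig:
    """Return a copy of ``cfg`` with one dotted-path parameter replaced.

    Accepted paths: top-level fields (``"dt"``), ``"mat.<field>"``,
    ``"rates.<field>"``, ``"protocol.<field>"``, and the special
    ``"protocol.omega"`` which rebuilds a periodic challenge train with the
    existing window, width and horizon.
    """
    if "." not in name:
        return replace(cfg, **{name: value})
    block, _, key = name.partition(".")
    if block == "mat":
        return replace(cfg, mat=replace(cfg.mat, **{key: value}))
    if block == "rates":
        return replace(cfg, rates=replace(cfg.rates, **{key: value}))
    if block == "protocol":
        p = cfg.protocol
        if key == "omega":
            t1 = p.event_times[0] if p.event_times else 1.0
            proto = ChallengeProtocol.periodic(
                omega=value, t1=t1, challenge_window=p.challenge_window,
                sigma=p.sigma, d=p.d, horizon=p.horizon)
        else:
            proto = replace(p, **{key: value})
        return replace(cfg, protocol=proto)
    raise ValueError(f"unresolvable parameter path: {name!r}")
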