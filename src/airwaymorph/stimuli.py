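"""Challenge trains, global inflammation, and the local agonist field.

Environmental challenges (allergen or administered contractile agonist) are a
train of Gaussian pulses f(t).  They drive two stimulus variables:

* ``mu(t)`` — a single global inflammatory status,
  d(mu)/dt = a_mu f(t) - c_dmu mu;
* ``k(xi, t)`` — the local contractile-agonist concentration on the material
  grid, d(k)/dt = a_k f(t) - c_dk k + a_kmu mu + a_c tau H(tau).

The last term is the mechanotransductive feedback: tensile fibre stress
(tau > 0, strictly) releases further agonist (e.g. stretch-activated latent
TGF-beta).  ``k`` is a material field riding the Lagrangian grid — no
diffusion or explicit advection.

Both ODEs are linear in their own variable, so each time step uses the exact
exponential integrator with the source held at its mid-step value: decay is
exact (important for long resolution phases) and non-negativity is preserved
whenever the sources are non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "ChallengeProtocol",
    "StimulusState",
    "challenge_train",
    "step_inflammation",
    "step_agonist",
    "total_agonist",
]


@dataclass(frozen=True)
class ChallengeProtocol:
    """Timing and shape of the challenge train.

    Attributes
    ----------
    event_times : tuple of float
        Challenge days t_i (sorted, inside the challenge window).
    sigma : float
        Gaussian peak width (days).
    d : float
        Dimensionless shape constant in the exponent (default 1; it shares
        sigma's role and is kept only for fidelity to the printed form).
    horizon : float
        Total simulated time (days).
    challenge_window : float
        Days within which all challenges fall.
    """

    event_times: tuple = ()
    sigma: float = 0.5
    d: float = 1.0
    horizon: float = 1000.0
    challenge_window: float = 50.0

    def __post_init__(self) -> None:
        events = tuple(float(t) for t in self.event_times)
        object.__setattr__(self, "event_times", events)
        if any(b < a for a, b in zip(events, events[1:])):
            raise ValueError("event_times must be sorted")
        if events and (events[0] < 0 or events[-1] > self.challenge_window):
            raise ValueError("event_times must lie within the challenge window")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.horizon < self.challenge_window:
            raise ValueError("horizon must be >= challenge_window")

    @classmethod
    def periodic(cls, omega: float, t1: float = 1.0, challenge_window: float = 50.0,
                 **kwargs) -> "ChallengeProtocol":
        """Periodic events t_i = t1 + (i-1)/omega within the challenge window."""
        if omega <= 0:
            raise ValueError("challenge frequency omega must be > 0")
        times = np.arange(t1, challenge_window + 1e-12, 1.0 / omega)
        return cls(event_times=tuple(times), challenge_window=challenge_window, **kwargs)

    @property
    def last_event(self) -> float:
        return self.event_times[-1] if self.event_times else 0.0


@dataclass
class StimulusState:
    """Global inflammation mu plus the agonist field k on the material grid."""

    mu: float
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.mu < 0 or np.any(self.k < 0):
            raise ValueError("stimulus state must be non-negative")


def challenge_train(t, proto: ChallengeProtocol):
    """Challenge rate f(t): a sum of normalised Gaussian peaks.

    f(t) = (2 pi sigma^2)^(-1/2) sum_i exp(-d (t - t_i)^2 / (2 sigma^2));
    with d = 1 each peak integrates to one.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pref = 1.0 / np.sqrt(2.0 * np.pi * proto.sigma**2)
    for ti in proto.event_times:
        out = out + pref * np.exp(-proto.d * (t - ti) ** 2 / (2.0 * proto.sigma**2))
    return out if out.ndim else float(out)


def step_inflammation(mu: float, t: float, dt: float, proto: ChallengeProtocol,
                      rates) -> float:
    """Advance mu over [t, t+dt] by the exact exponential integrator.

    The challenge source is frozen at the mid-step value, the linear decay is
    integrated exactly:  mu' = mu e^{-c dt} + a_mu f(t+dt/2) (1-e^{-c dt})/c.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = rates.c_dmu
    src = rates.a_mu * challenge_train(t + 0.5 * dt, proto)
    if c == 0.0:
        return mu + dt * src
    decay = np.exp(-c * dt)
    return mu * decay + src * (1.0 - decay) / c


def step_agonist(k_field, mu: float, tau_field, dt: float, proto: ChallengeProtocol,
                 rates, t: float = 0.0):
    """Advance the nodal agonist field over [t, t+dt].

    Sources: administered challenges (a_k f), inflammation-induced release
    (a_kmu mu, global), and stress-mediated release (a_c tau, strictly tensile
    nodes only).  Exponential integrator as in :func:`step_inflammation`;
    any numerical undershoot below zero is clipped with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k = np.asarray(k_field, dtype=float)
    tau = np.asarray(tau_field, dtype=float)
    src = (rates.a_k * challenge_train(t + 0.5 * dt, proto)
           + rates.a_kmu * mu
           + rates.a_c * np.where(tau > 0.0, tau, 0.0))
    c = rates.c_dk
    if c == 0.0:
        out = k + dt * src
    else:
        decay = np.exp(-c * dt)
        out = k * decay + src * (1.0 - decay) / c
    if np.any(out < 0.0):
        warnings.warn("agonist step undershot zero; clipping", RuntimeWarning)
        out = np.clip(out, 0.0, None)
    return out


def total_agonist(k_field, geom, weighting: str = "area") -> float:
    """Cross-sectional agonist total over both layers of the grown annulus.

    ``weighting='area'`` (default) integrates k over the annular cross
    section, integral of k(xi) 2 pi xi dxi; ``weighting='radial'`` is the
    plain radial integral of k dxi.  Composite Simpson rule per layer on the
    material grid (interface node duplicated in ``k_field``); exact for
    fields varying linearly in xi.
    """
    k = np.asarray(k_field, dtype=float)
    n_in = geom.n_inner
    if k.ndim == 0:
        k = np.full(geom.xi_all.size, float(k))
    if weighting == "area":
        w_in = 2.0 * np.pi * geom.xi_inner_layer
        w_out = 2.0 * np.pi * geom.xi_outer_layer
    elif weighting == "radial":
        w_in = np.ones_like(geom.xi_inner_layer)
        w_out = np.ones_like(geom.xi_outer_layer)
    else:
        raise ValueError("weighting must be 'area' or 'radial'")
    return float(simpson(k[:n_in] * w_in, x=geom.xi_inner_layer)
                 + simpson(k[n_in:] * w_out, x=geom.xi_outer_layer))
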