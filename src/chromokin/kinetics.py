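"""Steady-state photophosphorylation kinetics of a chromatophore vesicle.

Maps light intensity to absorbed photon flux, interpolates the quinone
cycling time at the reaction centers between a diffusion-limited low-light
value and a cytochrome-bc1-limited high-light value via a zero-event Poisson
weight, and closes the steady-state balance to obtain RC availability, the
quinol formation rate, the ATP synthesis rate and the overall energy
conversion efficiency.

Times are seconds, photon fluxes photons/s, energies wavenumbers (cm^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KineticParameters",
    "KineticsResult",
    "photon_flux",
    "bc1_electron_capacity",
    "tau_high",
    "cycling_time",
    "rc_availability",
    "atp_rate",
    "efficiency",
    "evaluate",
    "intensity_curve",
    "capacity_report",
]


@dataclass(frozen=True)
class KineticParameters:
    """All stage II/III constants.

    ``poisson_exponent_factor`` multiplies I q / B in the low-light survival
    weight; the printed two-state formula uses 1/2, while the accompanying
    derivation implies 1 (both are exposed, 1/2 is the default).  The
    steady-state identity k_ATP = k_Q->QH2 requires protons_per_quinol ==
    protons_per_atp; unequal values are allowed only with
    ``allow_unbalanced_protons`` and then scale k_ATP by their ratio.
    """

    tau_l: float = 3e-3
    tau_b: float = 25e-3
    q: float = 0.91
    #: photons s^-1 per W m^-2, anchored to 1860 photons/s at 50 W/m^2
    alpha: float = 37.2
    e_atp: float = 4197.0
    e_gamma: float = 11765.0
    protons_per_quinol: int = 4
    protons_per_atp: int = 4
    atp_synthase_capacity: float = 270.0
    n_rc: int = 24
    n_bc1_dimers: int = 4
    n_atp_synthase: int = 2
    poisson_exponent_factor: float = 0.5
    allow_unbalanced_protons: bool = False

    def __post_init__(self) -> None:
        if self.tau_l <= 0 or self.tau_b <= 0:
            raise ValueError("cycling and turnover times must be positive")
        if not (0.0 < self.q <= 1.0):
            raise ValueError("quantum yield must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("photon-flux conversion must be non-negative")
        if self.e_atp <= 0 or self.e_gamma <= 0:
            raise ValueError("energies must be positive")
        if self.protons_per_quinol <= 0 or self.protons_per_atp <= 0:
            raise ValueError("proton stoichiometries must be positive")
        if self.n_rc < 0 or self.n_bc1_dimers < 0 or self.n_atp_synthase < 0:
            raise ValueError("complex counts must be non-negative")
        if self.protons_per_quinol != self.protons_per_atp and not self.allow_unbalanced_protons:
            raise ValueError(
                "protons_per_quinol must equal protons_per_atp for the steady-state "
                "identity k_ATP = k_Q->QH2; set allow_unbalanced_protons=True to "
                "scale k_ATP by the proton ratio instead"
            )

    @property
    def proton_ratio(self) -> float:
        return self.protons_per_quinol / self.protons_per_atp

    def with_overrides(self, **kwargs: object) -> "KineticParameters":
        return replace(self, **kwargs)  # type: ignore[arg-type]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown kinetic parameter keys: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


@dataclass(frozen=True)
class KineticsResult:
    """Per-intensity state of the steady-state model."""

    intensity: float  # W m^-2
    photon_rate: float  # absorbed photons s^-1
    bc1_capacity: float  # electron capacity B, s^-1
    c_l: float
    c_h: float
    tau_rc: float  # s
    p_rc: float
    #: 1 - p_RC evaluated cancellation-free as x/(1+x), x = I q tau_RC / (2 n_RC)
    rc_closed_fraction: float
    k_q_to_qh2: float  # s^-1
    k_atp: float  # s^-1
    eta_atp: float
    eta_is_low_light_limit: bool = False


def photon_flux(intensity: float, alpha: float = 37.2) -> float:
    """Absorbed photons/s for an incident intensity in W m^-2 (linear)."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    return alpha * intensity


def bc1_electron_capacity(n_b: int, tau_b: float) -> float:
    """Total electron turnover capacity B = 2 n_B / tau_B (two electrons per quinol)."""
    if n_b < 0:
        raise ValueError("n_b must be non-negative")
    if tau_b <= 0:
        raise ValueError("tau_b must be positive")
    return 2.0 * n_b / tau_b

def tau_high(n_rc: int, n_b: int, tau_b: float) -> float:
    """High-light cycling time tau_H = (n_RC / n_B) tau_B."""
    if n_b < 1:
        raise ValueError("tau_high requires at least one cytbc1 dimer")
    if tau_b <= 0:
        raise ValueError("tau_b must be positive")
    return n_rc / n_b * tau_b


def cycling_time(
    photon_rate: float,
    q: float,
    tau_l: float,
    tau_h: float,
    bc1_capacity: float,
    exponent_factor: float = 0.5,
) -> float:
    """tau_RC(I) = tau_L + (tau_H - tau_L) (1 - exp(-f I q / B)).

    The zero-event Poisson weight exp(-f I q / B) is the probability of
    remaining in the low-light regime; f defaults to 1/2.
    """
    if photon_rate < 0:
        raise ValueError("photon rate must be non-negative")
    if bc1_capacity <= 0:
        raise ValueError("bc1 capacity must be positive")
    c_l = math.exp(-exponent_factor * photon_rate * q / bc1_capacity)
    return tau_l + (tau_h - tau_l) * (1.0 - c_l)


def rc_availability(photon_rate: float, q: float, tau_rc: float, n_rc: int) -> float:
    """p_RC = (1 + I q tau_RC / (2 n_RC))^-1, closing the steady-state balance."""
    if photon_rate < 0:
        raise ValueError("photon rate must be non-negative")
    if n_rc < 1:
        raise ValueError("rc_availability requires at least one RC")
    return 1.0 / (1.0 + 0.5 * photon_rate * q * tau_rc / n_rc)


def atp_rate(photon_rate: float, params: KineticParameters) -> float:
    """k_ATP(I) = (I q / 2) p_RC(I) (times the proton ratio if unbalanced)."""
    result = _evaluate_photon_rate(photon_rate, params, intensity=float("nan"))
    return result.k_atp


def efficiency(
    intensity_photons: float,
    k_atp: float,
    e_atp: float = 4197.0,
    e_gamma: float = 11765.0,
    q: float | None = None,
) -> tuple[float, bool]:
    """eta = E_ATP k_ATP / (E_gamma I), with I the absorbed photon rate.

    At I = 0 the ratio is undefined; the analytic low-light limit
    E_ATP q / (2 E_gamma) is returned instead together with a True flag
    (requires ``q``).
    """
    if intensity_photons < 0:
        raise ValueError("photon rate must be non-negative")
    if intensity_photons == 0:
        if q is None:
            raise ValueError("the I -> 0 limit requires the quantum yield q")
        return e_atp * q / (2.0 * e_gamma), True
    return e_atp * k_atp / (e_gamma * intensity_photons), False


def _evaluate_photon_rate(photon_rate: float, params: KineticParameters, intensity: float) -> KineticsResult:
    B = bc1_electron_capacity(params.n_bc1_dimers, params.tau_b)
    t_h = tau_high(params.n_rc, params.n_bc1_dimers, params.tau_b)
    c_l = math.exp(-params.poisson_exponent_factor * photon_rate * params.q / B)
    tau_rc = params.tau_l + (t_h - params.tau_l) * (1.0 - c_l)
    p_rc = rc_availability(photon_rate, params.q, tau_rc, params.n_rc)
    x = 0.5 * photon_rate * params.q * tau_rc / params.n_rc
    closed = x / (1.0 + x)
    k_q = 0.5 * photon_rate * params.q * p_rc
    k_atp = k_q * params.proton_ratio
    eta, is_limit = efficiency(photon_rate, k_atp, params.e_atp, params.e_gamma, q=params.q)
    return KineticsResult(
        intensity=intensity,
        photon_rate=photon_rate,
        bc1_capacity=B,
        c_l=c_l,
        c_h=1.0 - c_l,
        tau_rc=tau_rc,
        p_rc=p_rc,
        rc_closed_fraction=closed,
        k_q_to_qh2=k_q,
        k_atp=k_atp,
        eta_atp=eta,
        eta_is_low_light_limit=is_limit,
    )


def evaluate(intensity: float, params: KineticParameters | None = None) -> KineticsResult:
    """Evaluate the full chain at one incident intensity in W m^-2."""
    params = params or KineticParameters()
    photon_rate = photon_flux(intensity, params.alpha)
    return _evaluate_photon_rate(photon_rate, params, intensity=intensity)


def intensity_curve(intensities: Iterable[float], params: KineticParameters | None = None) -> pd.DataFrame:
    """Tabulate the model over an intensity grid (one row per intensity)."""
    params = params or KineticParameters()
    rows = [evaluate(float(i), params) for i in intensities]
    return pd.DataFrame(
        {
            "intensity_w_m2": [r.intensity for r in rows],
            "photon_rate_s": [r.photon_rate for r in rows],
            "c_l": [r.c_l for r in rows],
            "tau_rc_s": [r.tau_rc for r in rows],
            "p_rc": [r.p_rc for r in rows],
            "k_atp_s": [r.k_atp for r in rows],
            "eta_atp": [r.eta_atp for r in rows],
        }
    )


def capacity_report(params: KineticParameters | None = None, intensity: float | None = None) -> dict[str, float]:
    """Turnover capacities of the three candidate bottlenecks.

    ``intensity`` (W m^-2) sets the photon rate for the RC quinol capacity
    I q / 2; when omitted, the 5%-of-full-sunlight calibration point
    (50 W/m^2) is used.  Also reports the intensity at which the RC electron
    turnover I q crosses the cytbc1 electron capacity.
    """
    params = params or KineticParameters()
    if intensity is None:
        intensity = 50.0
    photon_rate = photon_flux(intensity, params.alpha)
    B = bc1_electron_capacity(params.n_bc1_dimers, params.tau_b)
    crossover = B / (params.q * params.alpha) if params.alpha > 0 else math.inf
    return {
        "intensity_w_m2": intensity,
        "photon_rate_s": photon_rate,
        "rc_quinol_capacity_s": 0.5 * photon_rate * params.q,
        "bc1_quinol_capacity_s": params.n_bc1_dimers / params.tau_b,
        "bc1_electron_capacity_s": B,
        "bc1_proton_capacity_s": params.protons_per_quinol * params.n_bc1_dimers / params.tau_b,
        "atp_synthase_proton_capacity_s": params.protons_per_atp
        * params.n_atp_synthase
        * params.atp_synthase_capacity,
        "crossover_intensity_w_m2": crossover,
    }
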