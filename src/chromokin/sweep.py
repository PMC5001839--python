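"""Composition optimality sweep at fixed vesicle surface area.

Scans a grid of (cytbc1 dimer count, RC-LH1 dimer count), fills the surface
area freed or consumed by those changes with LH2 complexes, assigns the
quantum yield from the LH2:RC stoichiometry interpolation, and evaluates the
steady-state ATP rate at each grid point to locate the optimal composition
and the reference vesicle's fraction of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .kinetics import KineticParameters, atp_rate, photon_flux
from .qyield import interpolated_q

__all__ = [
    "FootprintAreas",
    "SweepPoint",
    "SweepResult",
    "lh2_count",
    "sweep",
    "reference_fraction",
]

REFERENCE_N_B = 4
REFERENCE_N_L = 12
REFERENCE_N_LH2 = 63

#: BChls per complex: LH2 carries 18 B850 + 9 B800, an RC-LH1 dimer two
#: 28-pigment B875 rings plus two 4-pigment RCs.
BCHL_PER_LH2 = 27
BCHL_PER_L_DIMER = 64
REFERENCE_BCHL = BCHL_PER_LH2 * REFERENCE_N_LH2 + BCHL_PER_L_DIMER * REFERENCE_N_L


def _absorption_scale(n_lh2: int, n_l: int) -> float:
    """Absorbed photon flux scales with the absorption cross-section, i.e.
    with the composition's pigment count relative to the reference vesicle."""
    return (BCHL_PER_LH2 * n_lh2 + BCHL_PER_L_DIMER * n_l) / REFERENCE_BCHL


@dataclass(frozen=True)
class FootprintAreas:
    """Membrane footprints in nm^2; the total budget is pinned so that the
    reference composition (4 bc1, 12 core dimers, 63 LH2) fills it exactly."""

    area_lh2: float = 41.0
    area_rclh1_dimer: float = 180.0
    area_bc1_dimer: float = 60.0
    total_protein_area: float | None = None

    def __post_init__(self) -> None:
        if min(self.area_lh2, self.area_rclh1_dimer, self.area_bc1_dimer) <= 0:
            raise ValueError("footprint areas must be positive")
        if self.total_protein_area is None:
            total = (
                REFERENCE_N_LH2 * self.area_lh2
                + REFERENCE_N_L * self.area_rclh1_dimer
                + REFERENCE_N_B * self.area_bc1_dimer
            )
            object.__setattr__(self, "total_protein_area", total)
        elif self.total_protein_area <= 0:
            raise ValueError("total_protein_area must be positive")


@dataclass(frozen=True)
class SweepPoint:
    n_b: int
    n_l: int
    n_lh2: int
    s: float
    q: float
    k_atp: float
    feasible: bool


@dataclass
class SweepResult:
    intensity: float
    photon_rate: float
    grid: dict[tuple[int, int], SweepPoint]
    optimum: tuple[int, int]
    reference_k_atp: float

    @property
    def optimum_point(self) -> SweepPoint:
        return self.grid[self.optimum]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.grid.values(), key=lambda p: (p.n_b, p.n_l))
        return pd.DataFrame(
            {
                "n_b": [p.n_b for p in rows],
                "n_l": [p.n_l for p in rows],
                "n_lh2": [p.n_lh2 for p in rows],
                "s": [p.s for p in rows],
                "q": [p.q for p in rows],
                "k_atp_s": [p.k_atp for p in rows],
                "feasible": [p.feasible for p in rows],
            }
        )


def lh2_count(n_b: int, n_l: int, areas: FootprintAreas | None = None) -> tuple[int, bool]:
    """LH2 complexes filling the area left by n_b bc1 and n_l core dimers.

    Returns ``(count, feasible)``; a negative available area yields
    ``(0, False)``.  Rounding is half-away-from-zero so the reference
    composition maps to exactly 63 LH2.
    """
    if n_b < 0 or n_l < 0:
        raise ValueError("complex counts must be non-negative")
    areas = areas or FootprintAreas()
    free = areas.total_protein_area - n_b * areas.area_bc1_dimer - n_l * areas.area_rclh1_dimer
    if free < 0:
        return 0, False
    return int(math.floor(free / areas.area_lh2 + 0.5)), True


def _point(
    n_b: int,
    n_l: int,
    photon_rate: float,
    areas: FootprintAreas,
    params: KineticParameters,
    scale_absorption: bool,
) -> SweepPoint:
    n_lh2, area_ok = lh2_count(n_b, n_l, areas)
    feasible = area_ok and n_b >= 1 and n_l >= 1
    if not feasible:
        s = float("nan")
        return SweepPoint(n_b, n_l, n_lh2, s, float("nan"), 0.0, False)
    s = n_lh2 / (2.0 * n_l)
    q = interpolated_q(s)
    point_params = params.with_overrides(q=q, n_rc=2 * n_l, n_bc1_dimers=n_b)
    rate = photon_rate * _absorption_scale(n_lh2, n_l) if scale_absorption else photon_rate
    k = atp_rate(rate, point_params)
    return SweepPoint(n_b, n_l, n_lh2, s, q, k, True)


def sweep(
    intensity: float,
    nb_range: Iterable[int],
    nl_range: Iterable[int],
    areas: FootprintAreas | None = None,
    params: KineticParameters | None = None,
    scale_absorption: bool = True,
) -> SweepResult:
    """ATP rate over the (n_B, n_L) grid at one incident intensity (W m^-2).

    With ``scale_absorption`` (default) the absorbed photon rate of each
    composition scales with its BChl count relative to the reference vesicle,
    reflecting that the absorption cross-section tracks pigment content.
    Ties at the maximum break toward the smallest n_B, then smallest n_L.
    The reference k_ATP is always evaluated at (4, 12) even when that point
    is outside the requested grid.
    """
    areas = areas or FootprintAreas()
    params = params or KineticParameters()
    nb_values = sorted(set(int(n) for n in nb_range))
    nl_values = sorted(set(int(n) for n in nl_range))
    if not nb_values or not nl_values:
        raise ValueError("sweep ranges must be non-empty")
    photon_rate = photon_flux(intensity, params.alpha)
    grid: dict[tuple[int, int], SweepPoint] = {}
    for n_b in nb_values:
        for n_l in nl_values:
            grid[(n_b, n_l)] = _point(n_b, n_l, photon_rate, areas, params, scale_absorption)
    feasible = [p for p in grid.values() if p.feasible]
    if not feasible:
        raise ValueError("no feasible composition in the requested sweep ranges")
    best = max(feasible, key=lambda p: (p.k_atp, -p.n_b, -p.n_l))
    reference = grid.get((REFERENCE_N_B, REFERENCE_N_L))
    if reference is None or not reference.feasible:
        reference = _point(REFERENCE_N_B, REFERENCE_N_L, photon_rate, areas, params, scale_absorption)
    return SweepResult(
        intensity=intensity,
        photon_rate=photon_rate,
        grid=grid,
        optimum=(best.n_b, best.n_l),
        reference_k_atp=reference.k_atp,
    )


def reference_fraction(result: SweepResult) -> float:
    """100 * k_ATP(reference) / k_ATP(optimum), in percent."""
    best = result.optimum_point.k_atp
    if best <= 0:
        raise ValueError("optimum has non-positive ATP rate")
    return 100.0 * result.reference_k_atp / best
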