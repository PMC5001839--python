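"""Excitation-migration rate matrix and light-harvesting quantum yield.

The cluster-level master equation dP/dt = K P carries inter-cluster transfer
rates plus two loss channels: internal-conversion dissipation on every
cluster and charge separation on RC clusters.  The quantum yield is the total
probability captured through the charge-separation channel, obtained from a
single linear solve; an explicit time-propagation oracle is provided as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .excitons import ExcitonParameters, pairwise_rates
from .geometry import ClusterType, VesicleModel

__all__ = [
    "TransferNetwork",
    "rate_matrix",
    "build_transfer_network",
    "quantum_yield",
    "quantum_yield_oracle",
    "capture_probabilities",
    "interpolated_q",
    "make_random_network",
]

K_DISS_DEFAULT = 1.0 / 1e-9
K_CS_DEFAULT = 1.0 / 3e-12


@dataclass
class TransferNetwork:
    """Master-equation ingredients for one pigment-cluster network."""

    cluster_ids: list[str]
    rate_matrix_K: np.ndarray
    k_diss: float
    k_cs: float
    rc_indicator: np.ndarray
    initial_state_P0: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cluster_ids)
        self.rate_matrix_K = np.asarray(self.rate_matrix_K, dtype=float)
        self.rc_indicator = np.asarray(self.rc_indicator, dtype=float)
        self.initial_state_P0 = np.asarray(self.initial_state_P0, dtype=float)
        if self.rate_matrix_K.shape != (n, n):
            raise ValueError("rate matrix shape does not match cluster count")
        if np.any(self.initial_state_P0 < 0) or not np.isclose(self.initial_state_P0.sum(), 1.0):
            raise ValueError("initial state must be a probability vector")


def rate_matrix(
    rates: Mapping[tuple[str, str], float],
    k_diss: float = K_DISS_DEFAULT,
    k_cs: float = K_CS_DEFAULT,
    rc_indicator: Mapping[str, bool] | Sequence[bool] | None = None,
    cluster_ids: Sequence[str] | None = None,
    initial_state: Sequence[float] | None = None,
) -> TransferNetwork:
    """Assemble K with K[I,J] = k_JI off-diagonal and
    K[I,I] = -(sum_M k_IM + k_diss + k_cs * 1_RC[I]).

    Column sums then equal -(k_diss + k_cs * 1_RC[J]) exactly.  ``rates`` maps
    ordered (donor, acceptor) cluster-id pairs to non-negative rates; missing
    pairs are zero.
    """
    if cluster_ids is None:
        seen: dict[str, None] = {}
        for donor, acceptor in rates:
            seen.setdefault(donor)
            seen.setdefault(acceptor)
        cluster_ids = list(seen)
    ids = list(cluster_ids)
    index = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    if rc_indicator is None:
        rc = np.array([cid.startswith("RC") for cid in ids], dtype=float)
    elif isinstance(rc_indicator, Mapping):
        rc = np.array([float(bool(rc_indicator.get(cid, False))) for cid in ids])
    else:
        rc = np.asarray(rc_indicator, dtype=float)
    K = np.zeros((n, n))
    outflow = np.zeros(n)
    for (donor, acceptor), k in rates.items():
        if k < 0:
            raise ValueError(f"negative transfer rate for pair ({donor}, {acceptor})")
        if donor == acceptor:
            raise ValueError("rates must have zero diagonal (donor == acceptor)")
        K[index[acceptor], index[donor]] += k
        outflow[index[donor]] += k
    K[np.diag_indices(n)] = -(outflow + k_diss + k_cs * rc)
    p0 = np.full(n, 1.0 / n) if initial_state is None else np.asarray(initial_state, dtype=float)
    return TransferNetwork(ids, K, k_diss, k_cs, rc, p0)


def build_transfer_network(
    vesicle: VesicleModel, params: ExcitonParameters | None = None
) -> tuple[TransferNetwork, dict[tuple[str, str], float]]:
    """Full pipeline from a vesicle to its transfer network.

    The initial state weights each cluster by its network pigment count N_I
    (B800 pigments relay absorbed energy to the B850 ring essentially
    instantaneously and are not counted).
    """
    params = params or ExcitonParameters()
    rates, _, _ = pairwise_rates(vesicle, params)
    ids = [c.cluster_id for c in vesicle.clusters]
    counts = np.array([c.n_pigments for c in vesicle.clusters], dtype=float)
    p0 = counts / counts.sum()
    rc = {c.cluster_id: c.cluster_type is ClusterType.RC for c in vesicle.clusters}
    network = rate_matrix(
        rates,
        k_diss=params.k_diss,
        k_cs=params.k_cs,
        rc_indicator=rc,
        cluster_ids=ids,
        initial_state=p0,
    )
    return network, rates


def _solve(network: TransferNetwork) -> np.ndarray:
    try:
        x = np.linalg.solve(network.rate_matrix_K, network.initial_state_P0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "rate matrix is singular; with k_diss > 0 every state drains, so this "
            "indicates k_diss = 0 together with a sink-free component"
        ) from exc
    return x


def quantum_yield(network: TransferNetwork) -> float:
    """q = -k_cs 1_RC^T K^-1 P(0), via a linear solve."""
    x = _solve(network)
    return float(-network.k_cs * network.rc_indicator @ x)


def capture_probabilities(network: TransferNetwork) -> np.ndarray:
    """Per-cluster charge-separation capture; sums to the quantum yield."""
    x = _solve(network)
    return -network.k_cs * network.rc_indicator * x


def quantum_yield_oracle(
    network: TransferNetwork, horizon: float | None = None, tol: float = 1e-8
) -> float:
    """Quantum yield by stiff time propagation of dP/dt = K P.

    Integrates the master equation with the charge-separation and dissipation
    fluxes accumulated as two extra state variables, then checks that the
    remaining excited-state probability has decayed below ``tol``.
    """
    K = network.rate_matrix_K
    n = K.shape[0]
    if horizon is None:
        horizon = 100.0 / network.k_diss if network.k_diss > 0 else 1e-6
    aug = np.zeros((n + 2, n + 2))
    aug[:n, :n] = K
    aug[n, :n] = network.k_cs * network.rc_indicator
    aug[n + 1, :n] = network.k_diss

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return aug @ y

    y0 = np.concatenate([network.initial_state_P0, [0.0, 0.0]])
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="Radau",
        jac=lambda _t, _y: aug,
        rtol=1e-10,
        atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"time propagation failed: {sol.message}")
    remaining = float(sol.y[:n, -1].sum())
    if abs(remaining) > tol:
        raise RuntimeError(
            f"time propagation did not converge: {remaining:.3e} probability "
            f"remains after horizon {horizon:.3e} s"
        )
    return float(sol.y[n, -1])


def interpolated_q(s: float, s0: float = 2.625, q0: float = 0.91, slope: float = 0.0152, floor: float = 0.85) -> float:
    """Quantum yield from the LH2:RC stoichiometry interpolation
    q = q0 + slope (s0 - s), clamped below at ``floor``."""
    if s < 0:
        raise ValueError("stoichiometry must be non-negative")
    return max(floor, q0 + slope * (s0 - s))


def make_random_network(
    n_clusters: int,
    rng: np.random.Generator,
    k_diss: float = K_DISS_DEFAULT,
    k_cs: float = K_CS_DEFAULT,
    rate_scale: float = 1e11,
    edge_probability: float = 0.6,
) -> TransferNetwork:
    """Random small network for solver-vs-oracle validation.

    At least one cluster is an RC; the initial state is a random probability
    vector.  Deterministic given ``rng``.
    """
    ids = [f"C{i}" for i in range(n_clusters)]
    rc_flags = rng.random(n_clusters) < 0.4
    rc_flags[int(rng.integers(n_clusters))] = True
    rates: dict[tuple[str, str], float] = {}
    for i in range(n_clusters):
        for j in range(n_clusters):
            if i != j and rng.random() < edge_probability:
                rates[(ids[i], ids[j])] = float(rng.random() * rate_scale)
    p0 = rng.random(n_clusters) + 1e-3
    p0 /= p0.sum()
    return rate_matrix(
        rates,
        k_diss=k_diss,
        k_cs=k_cs,
        rc_indicator={cid: bool(f) for cid, f in zip(ids, rc_flags)},
        cluster_ids=ids,
        initial_state=p0,
    )
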