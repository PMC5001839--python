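"""Effective Hamiltonians, exciton bases and generalized-Forster transfer rates.

Each pigment cluster gets a site-basis effective Hamiltonian whose diagonal
carries registry site energies, whose cyclic nearest-neighbor elements carry
registry couplings (alternating intra/inter alpha-beta dimer values for the
B850 and B875 rings, a fixed special-pair coupling for the RC), and whose
remaining elements come from the point-dipole approximation.  Inter-cluster
rates follow the generalized-Forster expression: thermally weighted donor
excitons, donor-acceptor pigment couplings rotated into the exciton bases,
and Gaussian donor-emission/acceptor-absorption spectral overlaps.

Energies are wavenumbers (cm^-1), distances angstroms, rates s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .geometry import ClusterType, Pigment, PigmentClass, PigmentCluster, VesicleModel

__all__ = [
    "ExcitonParameters",
    "ExcitonBasis",
    "BOLTZMANN_CM",
    "site_hamiltonian",
    "dipole_coupling",
    "coupling_matrix",
    "exciton_states",
    "spectral_overlap",
    "transfer_rate",
    "neighbor_graph",
    "pairwise_rates",
]

#: Boltzmann constant in cm^-1 per kelvin.
BOLTZMANN_CM = 0.695034800


@dataclass(frozen=True)
class ExcitonParameters:
    """Registry of exciton-model constants (wavenumber bookkeeping).

    Defaults carry the full constants table: site energies, nearest-neighbor
    couplings, the point-dipole constant C = 348000 A^3 cm^-1, exciton
    linewidths, the fixed intra-complex LH1<->RC rates, and the loss/charge
    separation channels used downstream.  ``lineshape`` selects between the
    normalized Gaussian convention (default) and the literal printed form
    whose prefactor and exponent are mutually inconsistent.
    """

    site_energies: Mapping[PigmentClass, float] = field(
        default_factory=lambda: {
            PigmentClass.B850_ALPHA: 12459.0,
            PigmentClass.B850_BETA: 12625.0,
            PigmentClass.B800: 12500.0,
            PigmentClass.B875: 12344.0,
            PigmentClass.RC_SPECIAL: 12092.0,
            PigmentClass.RC_ACCESSORY: 12581.0,
        }
    )
    v1_lh2: float = 363.0
    v2_lh2: float = 320.0
    v1_lh1: float = 806.0
    v2_lh1: float = 377.0
    v_rc: float = 500.0
    dipole_constant_c: float = 348000.0
    sigma_lh2: float = 188.0
    sigma_lh1: float = 235.0
    #: RC exciton linewidth is not tabulated; default to the LH1 value.
    sigma_rc: float = 235.0
    spectral_shift_s: float = 0.0
    temperature: float = 300.0
    hbar_cm_s: float = 5.3088e-12
    k_lh1_to_rc: float = 1.0 / 35e-12
    k_rc_to_lh1: float = 1.0 / 8e-12
    k_diss: float = 1.0 / 1e-9
    k_cs: float = 1.0 / 3e-12
    neighbor_cutoff: float = 70.0
    lineshape: str = "normalized"

    def __post_init__(self) -> None:
        positive = [
            self.v1_lh2,
            self.v2_lh2,
            self.v1_lh1,
            self.v2_lh1,
            self.v_rc,
            self.dipole_constant_c,
            self.sigma_lh2,
            self.sigma_lh1,
            self.sigma_rc,
            self.temperature,
            self.hbar_cm_s,
            self.k_lh1_to_rc,
            self.k_rc_to_lh1,
            self.k_diss,
            self.k_cs,
            self.neighbor_cutoff,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all exciton registry constants must be positive")
        if self.lineshape not in ("normalized", "literal"):
            raise ValueError("lineshape must be 'normalized' or 'literal'")
        if any(v <= 0 for v in self.site_energies.values()):
            raise ValueError("site energies must be positive")

    def linewidth(self, cluster_type: ClusterType) -> float:
        return {
            ClusterType.LH2: self.sigma_lh2,
            ClusterType.LH1: self.sigma_lh1,
            ClusterType.RC: self.sigma_rc,
        }[cluster_type]

    def with_overrides(self, **kwargs: object) -> "ExcitonParameters":
        return replace(self, **kwargs)  # type: ignore[arg-type]


@dataclass
class ExcitonBasis:
    """Eigen-decomposition of one cluster Hamiltonian with thermal weights."""

    cluster_id: str
    energies: np.ndarray
    coefficients: np.ndarray
    boltzmann_weights: np.ndarray
    linewidth: float


def dipole_coupling(pigment_i: Pigment, pigment_j: Pigment, C: float = 348000.0) -> float:
    """Point-dipole coupling C [d.d / r^3 - 3 (d.r)(d.r) / r^5] in cm^-1."""
    r_vec = pigment_j.mg_position - pigment_i.mg_position
    r = float(np.linalg.norm(r_vec))
    if r < 1e-9:
        raise ValueError("pigments have coincident Mg positions; coupling undefined")
    di, dj = pigment_i.dipole, pigment_j.dipole
    return float(C * (np.dot(di, dj) / r**3 - 3.0 * np.dot(di, r_vec) * np.dot(dj, r_vec) / r**5))


def coupling_matrix(
    donors: Sequence[Pigment], acceptors: Sequence[Pigment], C: float, same_set: bool = False
) -> np.ndarray:
    """Vectorized point-dipole couplings for all donor-acceptor pigment pairs.

    With ``same_set`` the (zero-distance) diagonal is set to zero instead of
    raising, for intra-cluster Hamiltonian assembly.
    """
    mg_a = np.array([p.mg_position for p in donors])
    mg_b = np.array([p.mg_position for p in acceptors])
    d_a = np.array([p.dipole for p in donors])
    d_b = np.array([p.dipole for p in acceptors])
    r_vec = mg_b[None, :, :] - mg_a[:, None, :]
    r2 = np.einsum("ijk,ijk->ij", r_vec, r_vec)
    mask = r2 < 1e-18
    if np.any(mask):
        if not (same_set and np.array_equal(mask, np.eye(len(donors), dtype=bool))):
            raise ValueError("coincident Mg positions between donor and acceptor pigments")
        r2 = np.where(mask, np.inf, r2)
    r = np.sqrt(r2)
    dd = d_a @ d_b.T
    da_r = np.einsum("ik,ijk->ij", d_a, r_vec)
    db_r = np.einsum("jk,ijk->ij", d_b, r_vec)
    return C * (dd / r**3 - 3.0 * da_r * db_r / r**5)


def site_hamiltonian(cluster: PigmentCluster, params: ExcitonParameters | None = None) -> np.ndarray:
    """Symmetric site-basis Hamiltonian of one cluster, in cm^-1.

    Diagonal entries are registry site energies per pigment class; cyclic
    nearest-neighbor entries of the B850/B875 rings alternate between the
    intra- and inter-dimer registry couplings (first ring bond treated as
    intra-dimer); the RC special-pair entry is fixed; everything else is
    point-dipole.
    """
    params = params or ExcitonParameters()
    pigments = cluster.network_pigments
    n = len(pigments)
    if n == 0:
        raise ValueError(f"cluster {cluster.cluster_id!r} has no network pigments")
    H = np.zeros((n, n))
    for i, p in enumerate(pigments):
        H[i, i] = params.site_energies[p.pigment_class]
    if n > 1:
        H_dip = coupling_matrix(pigments, pigments, params.dipole_constant_c, same_set=True)
        np.fill_diagonal(H_dip, 0.0)
        H = np.where(np.eye(n, dtype=bool), H, H_dip)
    if cluster.cluster_type in (ClusterType.LH2, ClusterType.LH1):
        if n % 2 != 0:
            raise ValueError(
                f"cluster {cluster.cluster_id!r} has an odd ring length {n}; "
                "alternating nearest-neighbor couplings are undefined"
            )
        v1 = params.v1_lh2 if cluster.cluster_type is ClusterType.LH2 else params.v1_lh1
        v2 = params.v2_lh2 if cluster.cluster_type is ClusterType.LH2 else params.v2_lh1
        for i in range(n):
            j = (i + 1) % n
            H[i, j] = H[j, i] = v1 if i % 2 == 0 else v2
    elif cluster.cluster_type is ClusterType.RC:
        special = [i for i, p in enumerate(pigments) if p.pigment_class is PigmentClass.RC_SPECIAL]
        if len(special) != 2:
            raise ValueError(f"RC cluster {cluster.cluster_id!r} must carry exactly two special-pair pigments")
        i, j = special
        H[i, j] = H[j, i] = params.v_rc
    return H


def exciton_states(H: np.ndarray, params: ExcitonParameters | None = None, *, cluster_id: str = "", linewidth: float | None = None) -> ExcitonBasis:
    """Diagonalize a symmetric Hamiltonian; energies ascending, Boltzmann
    weights evaluated at ``params.temperature``."""
    params = params or ExcitonParameters()
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("Hamiltonian must be symmetric")
    energies, coefficients = np.linalg.eigh(H)
    beta = 1.0 / (BOLTZMANN_CM * params.temperature)
    logw = -beta * (energies - energies.min())
    weights = np.exp(logw)
    weights /= weights.sum()
    return ExcitonBasis(
        cluster_id=cluster_id,
        energies=energies,
        coefficients=coefficients,
        boltzmann_weights=weights,
        linewidth=params.sigma_lh2 if linewidth is None else linewidth,
    )


def spectral_overlap(
    eps_donor,
    eps_acceptor,
    sigma_donor: float,
    sigma_acceptor: float,
    shift_s: float = 0.0,
    lineshape: str = "normalized",
):
    """Donor-emission/acceptor-absorption Gaussian overlap, in (cm^-1)^-1.

    The donor emission line is the acceptor-style line red-shifted by
    ``shift_s``.  ``normalized`` uses unit-area Gaussians of standard
    deviation sigma; ``literal`` reproduces the printed lineshape whose
    exponent is -((E-eps)/sigma)^2 under a 1/(sqrt(2 pi) sigma) prefactor.
    Broadcasts over array-valued energies.
    """
    if sigma_donor <= 0 or sigma_acceptor <= 0:
        raise ValueError("linewidths must be positive")
    delta = (np.asarray(eps_donor, dtype=float) - shift_s) - np.asarray(eps_acceptor, dtype=float)
    s2 = sigma_donor**2 + sigma_acceptor**2
    if lineshape == "normalized":
        return np.exp(-(delta**2) / (2.0 * s2)) / math.sqrt(2.0 * math.pi * s2)
    if lineshape == "literal":
        return np.exp(-(delta**2) / s2) / (2.0 * math.sqrt(math.pi) * math.sqrt(s2))
    raise ValueError("lineshape must be 'normalized' or 'literal'")


def transfer_rate(
    donor: PigmentCluster,
    acceptor: PigmentCluster,
    donor_basis: ExcitonBasis,
    acceptor_basis: ExcitonBasis,
    params: ExcitonParameters | None = None,
) -> float:
    """Generalized-Forster rate donor -> acceptor in s^-1.

    LH1<->RC pairs belonging to the same core complex return the fixed
    empirical rates instead of the computed value.
    """
    params = params or ExcitonParameters()
    if donor is acceptor or donor.cluster_id == acceptor.cluster_id:
        raise ValueError("donor and acceptor must be distinct clusters")
    if donor.complex_id is not None and donor.complex_id == acceptor.complex_id:
        if donor.cluster_type is ClusterType.LH1 and acceptor.cluster_type is ClusterType.RC:
            return params.k_lh1_to_rc
        if donor.cluster_type is ClusterType.RC and acceptor.cluster_type is ClusterType.LH1:
            return params.k_rc_to_lh1
    H_ij = coupling_matrix(donor.network_pigments, acceptor.network_pigments, params.dipole_constant_c)
    M = donor_basis.coefficients.T @ H_ij @ acceptor_basis.coefficients
    J = spectral_overlap(
        donor_basis.energies[:, None],
        acceptor_basis.energies[None, :],
        donor_basis.linewidth,
        acceptor_basis.linewidth,
        params.spectral_shift_s,
        params.lineshape,
    )
    prefactor = 2.0 * math.pi / params.hbar_cm_s
    return float(prefactor * np.sum(donor_basis.boltzmann_weights[:, None] * M**2 * J))


def _min_distance(a: PigmentCluster, b: PigmentCluster) -> float:
    mg_a = np.array([p.mg_position for p in a.network_pigments])
    mg_b = np.array([p.mg_position for p in b.network_pigments])
    return float(cdist(mg_a, mg_b).min())


def neighbor_graph(vesicle: VesicleModel, cutoff: float = 70.0) -> nx.Graph:
    """Cluster adjacency: edge iff the minimal inter-cluster Mg-Mg distance is
    within ``cutoff``; intra-complex LH1-RC edges are always present."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph = nx.Graph()
    clusters = vesicle.clusters
    for c in clusters:
        graph.add_node(c.cluster_id)
    centers = np.array([c.ring_center for c in clusters])
    # generous prefilter: rings extend at most ~b875_radius from their center
    reach = 2.0 * 55.0 + cutoff
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            same_complex = a.complex_id is not None and a.complex_id == b.complex_id
            if not same_complex:
                if np.linalg.norm(centers[i] - centers[j]) > reach:
                    continue
                if _min_distance(a, b) > cutoff:
                    continue
            graph.add_edge(a.cluster_id, b.cluster_id)
    return graph


def pairwise_rates(
    vesicle: VesicleModel,
    params: ExcitonParameters | None = None,
    graph: nx.Graph | None = None,
) -> tuple[dict[tuple[str, str], float], dict[str, ExcitonBasis], nx.Graph]:
    """All directed inter-cluster rates over the neighbor graph.

    Returns ``(rates, bases, graph)`` where ``rates`` maps ordered cluster-id
    pairs to rates in s^-1; non-neighboring pairs are omitted (rate zero).
    """
    params = params or ExcitonParameters()
    if graph is None:
        graph = neighbor_graph(vesicle, params.neighbor_cutoff)
    by_id = {c.cluster_id: c for c in vesicle.clusters}
    bases = {}
    for cluster in vesicle.clusters:
        H = site_hamiltonian(cluster, params)
        bases[cluster.cluster_id] = exciton_states(
            H, params, cluster_id=cluster.cluster_id, linewidth=params.linewidth(cluster.cluster_type)
        )
    rates: dict[tuple[str, str], float] = {}
    for u, v in graph.edges:
        a, b = by_id[u], by_id[v]
        rates[(u, v)] = transfer_rate(a, b, bases[u], bases[v], params)
        rates[(v, u)] = transfer_rate(b, a, bases[v], bases[u], params)
    return rates, bases, graph
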