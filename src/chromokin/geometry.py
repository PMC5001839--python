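"""Synthetic chromatophore vesicle geometry.

Builds idealized pigment geometries for spherical photosynthetic vesicles:
LH2 complexes (18-pigment B850 ring with alternating alpha/beta sites plus a
9-pigment B800 ring that is kept out of the exciton network), RC-LH1 core
complexes (28-pigment B875 ring enclosing a 4-pigment reaction center), and
composition bookkeeping for cytochrome bc1 dimers and ATP synthases (which
carry no pigments).

Complex centers are placed on a sphere by random sequential adsorption with
hard-core exclusion, so placement is deterministic for a fixed seed.  All
coordinates are Cartesian angstroms with the vesicle center at the origin.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PigmentClass",
    "ClusterType",
    "Pigment",
    "PigmentCluster",
    "VesicleModel",
    "CompositionSpec",
    "GeometryConfig",
    "PlacementError",
    "PigmentTableError",
    "DEFAULT_SITE_ENERGIES",
    "transition_dipole",
    "build_reference_vesicle",
    "build_vesicle",
    "write_pigment_table",
    "read_pigment_table",
    "read_pigment_pdb",
    "rotate_vesicle",
]


class PigmentClass(str, Enum):
    """Spectroscopic class of a bacteriochlorophyll site."""

    B850_ALPHA = "B850_alpha"
    B850_BETA = "B850_beta"
    B800 = "B800"
    B875 = "B875"
    RC_SPECIAL = "RC_special"
    RC_ACCESSORY = "RC_accessory"


class ClusterType(str, Enum):
    LH2 = "LH2"
    LH1 = "LH1"
    RC = "RC"


#: Default site energies in wavenumbers (cm^-1) keyed by pigment class.
#: B800 pigments are excluded from the exciton network; their entry is only
#: used for bookkeeping when tables are round-tripped.
DEFAULT_SITE_ENERGIES: dict[PigmentClass, float] = {
    PigmentClass.B850_ALPHA: 12459.0,
    PigmentClass.B850_BETA: 12625.0,
    PigmentClass.B800: 12500.0,
    PigmentClass.B875: 12344.0,
    PigmentClass.RC_SPECIAL: 12092.0,
    PigmentClass.RC_ACCESSORY: 12581.0,
}

#: Expected network pigment counts per cluster type.
NETWORK_SIZES: dict[ClusterType, int] = {
    ClusterType.LH2: 18,
    ClusterType.LH1: 28,
    ClusterType.RC: 4,
}


class PlacementError(RuntimeError):
    """Raised when complexes cannot be packed onto the sphere."""


class PigmentTableError(ValueError):
    """Raised on malformed pigment tables; carries a line number when known."""


def transition_dipole(nb_position: np.ndarray, nd_position: np.ndarray) -> np.ndarray:
    """Unit transition-dipole vector of a BChl from its NB and ND atoms.

    The Qy transition dipole points from NB to ND and is normalized.
    """
    nb = np.asarray(nb_position, dtype=float)
    nd = np.asarray(nd_position, dtype=float)
    diff = nd - nb
    norm = float(np.linalg.norm(diff))
    if norm < 1e-9:
        raise ValueError("NB and ND positions coincide; dipole direction undefined")
    return diff / norm


@dataclass
class Pigment:
    """One bacteriochlorophyll site.

    ``dipole`` and ``site_energy`` are derived in ``__post_init__`` unless
    supplied explicitly.
    """

    cluster_id: str
    pigment_class: PigmentClass
    ring_index: int
    mg_position: np.ndarray
    nb_position: np.ndarray
    nd_position: np.ndarray
    dipole: np.ndarray | None = None
    site_energy: float | None = None

    def __post_init__(self) -> None:
        self.pigment_class = PigmentClass(self.pigment_class)
        self.mg_position = np.asarray(self.mg_position, dtype=float)
        self.nb_position = np.asarray(self.nb_position, dtype=float)
        self.nd_position = np.asarray(self.nd_position, dtype=float)
        if self.dipole is None:
            self.dipole = transition_dipole(self.nb_position, self.nd_position)
        else:
            self.dipole = np.asarray(self.dipole, dtype=float)
        if self.site_energy is None:
            self.site_energy = DEFAULT_SITE_ENERGIES[self.pigment_class]

    @property
    def in_network(self) -> bool:
        return self.pigment_class is not PigmentClass.B800


@dataclass
class PigmentCluster:
    """One excitonically coupled BChl group (LH2 B850, LH1 B875 or RC).

    ``pigments`` is ring-ordered: network pigments come first with cyclic
    nearest neighbors at adjacent indices; non-network B800 pigments follow.
    ``complex_id`` ties the LH1 ring and RC of one core complex together.
    """

    cluster_id: str
    cluster_type: ClusterType
    pigments: list[Pigment]
    complex_id: str | None = None

    def __post_init__(self) -> None:
        self.cluster_type = ClusterType(self.cluster_type)

    @property
    def network_pigments(self) -> list[Pigment]:
        return [p for p in self.pigments if p.in_network]

    @property
    def n_pigments(self) -> int:
        """Number of network pigments N_I."""
        return len(self.network_pigments)

    @property
    def ring_center(self) -> np.ndarray:
        return np.mean([p.mg_position for p in self.network_pigments], axis=0)

    def validate(self) -> None:
        expected = NETWORK_SIZES[self.cluster_type]
        if self.n_pigments != expected:
            raise PigmentTableError(
                f"cluster {self.cluster_id!r} of type {self.cluster_type.value} has "
                f"{self.n_pigments} network pigments, expected {expected}"
            )
        for pigment in self.pigments:
            if not math.isclose(float(np.linalg.norm(pigment.dipole)), 1.0, abs_tol=1e-9):
                raise PigmentTableError(
                    f"pigment {pigment.ring_index} of cluster {self.cluster_id!r} "
                    "has a non-unit dipole"
                )


@dataclass(frozen=True)
class CompositionSpec:
    """Requested complex counts; core complexes in dimer-equivalents.

    ``n_l_monomers`` standalone RC-LH1 monomers are included within the
    ``n_l_dimers`` dimer-equivalents (two monomers count as one dimer), so it
    must be even and at most ``2 * n_l_dimers``.
    """

    n_bc1_dimers: int
    n_l_dimers: int
    n_lh2: int
    n_l_monomers: int = 0
    n_atp_synthase: int = 2

    def __post_init__(self) -> None:
        if min(self.n_bc1_dimers, self.n_l_dimers, self.n_lh2, self.n_l_monomers) < 0:
            raise ValueError("composition counts must be non-negative")
        if self.n_l_monomers % 2 != 0:
            raise ValueError("n_l_monomers must be even (two monomers = one dimer-equivalent)")
        if self.n_l_monomers > 2 * self.n_l_dimers:
            raise ValueError("n_l_monomers exceeds the requested dimer-equivalents")


REFERENCE_COMPOSITION = CompositionSpec(
    n_bc1_dimers=4, n_l_dimers=12, n_lh2=63, n_l_monomers=2, n_atp_synthase=2
)


@dataclass(frozen=True)
class GeometryConfig:
    """Geometric defaults for synthetic vesicles.

    Ring radii and dipole tilts are chosen so that nearest-neighbor Mg-Mg
    spacings in the B850 ring are ~9 A and inter-complex separations exceed
    1 nm; nearest-neighbor couplings are overridden by registry constants so
    only the long-range dipolar geometry matters.
    """

    inner_diameter_nm: float = 50.0
    #: radius of the sphere carrying the ring centers, A
    placement_radius: float = 250.0
    b850_radius: float = 26.0
    b800_radius: float = 31.0
    b800_plane_offset: float = -16.5
    b875_radius: float = 50.0
    rc_special_half_separation: float = 4.0
    rc_accessory_half_separation: float = 13.0
    #: hard-core radii for placement, A
    lh2_hardcore: float = 34.0
    lh1_hardcore: float = 54.0
    #: center-to-center separation of the two monomers of a dimer, A
    dimer_gap: float = 110.0
    #: uniform extra spacing added on top of hard-core contact, A
    contact_jitter: float = 3.0
    #: grow the sphere with total complex footprint so packing density stays
    #: at the reference value for non-reference compositions
    scale_radius_with_composition: bool = True
    #: alternating in-plane dipole tilt for alpha/beta ring sites, degrees
    dipole_tilt_deg: float = 10.0
    #: half distance between the NB and ND atoms along the dipole, A
    nb_nd_half_length: float = 1.7
    seed: int = 0
    max_attempts: int = 20000
    max_restarts: int = 20

    def __post_init__(self) -> None:
        for name in (
            "inner_diameter_nm",
            "placement_radius",
            "b850_radius",
            "b875_radius",
            "lh2_hardcore",
            "lh1_hardcore",
            "dimer_gap",
            "nb_nd_half_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"GeometryConfig.{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "GeometryConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


@dataclass
class VesicleModel:
    """A pigment-resolved vesicle plus composition bookkeeping."""

    clusters: list[PigmentCluster]
    n_lh2: int
    n_l_dimers: int
    n_dimeric: int
    n_monomeric: int
    n_bc1_dimers: int
    n_atp_synthase: int
    inner_diameter_nm: float = 50.0

    @property
    def n_rc(self) -> int:
        return 2 * self.n_l_dimers

    @property
    def total_bchl(self) -> int:
        """All BChls including non-network B800 pigments."""
        return sum(len(c.pigments) for c in self.clusters)

    @property
    def stoichiometry_s(self) -> float:
        """LH2:RC stoichiometry s = n_LH2 / (2 n_L)."""
        return self.n_lh2 / self.n_rc

    def clusters_of(self, cluster_type: ClusterType) -> list[PigmentCluster]:
        return [c for c in self.clusters if c.cluster_type is cluster_type]

    def validate(self) -> None:
        if self.n_rc != 2 * self.n_l_dimers:
            raise ValueError("n_rc must equal 2 * n_l_dimers")
        for cluster in self.clusters:
            cluster.validate()


# ---------------------------------------------------------------------------
# local frames and ring construction
# ---------------------------------------------------------------------------


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangent pair for a unit normal."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(normal)))] = 1.0
    t1 = np.cross(normal, axis)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def _ring_pigments(
    cluster_id: str,
    center: np.ndarray,
    normal: np.ndarray,
    radius: float,
    n: int,
    classes: Sequence[PigmentClass],
    phase: float,
    tilt_deg: float,
    half_length: float,
    start_index: int = 0,
) -> list[Pigment]:
    """Pigments on a circle in the tangent plane with near-tangential dipoles."""
    t1, t2 = _tangent_frame(normal)
    tilt = math.radians(tilt_deg)
    pigments = []
    for k in range(n):
        theta = phase + 2.0 * math.pi * k / n
        radial = math.cos(theta) * t1 + math.sin(theta) * t2
        tangent = -math.sin(theta) * t1 + math.cos(theta) * t2
        mg = center + radius * radial
        sign = 1.0 if k % 2 == 0 else -1.0
        dipole = math.cos(tilt) * tangent + sign * math.sin(tilt) * radial
        dipole /= np.linalg.norm(dipole)
        pigments.append(
            Pigment(
                cluster_id=cluster_id,
                pigment_class=classes[k % len(classes)],
                ring_index=start_index + k,
                mg_position=mg,
                nb_position=mg - half_length * dipole,
                nd_position=mg + half_length * dipole,
            )
        )
    return pigments


def _make_lh2(cluster_id: str, center: np.ndarray, normal: np.ndarray, phase: float, cfg: GeometryConfig) -> PigmentCluster:
    b850 = _ring_pigments(
        cluster_id,
        center,
        normal,
        cfg.b850_radius,
        18,
        [PigmentClass.B850_ALPHA, PigmentClass.B850_BETA],
        phase,
        cfg.dipole_tilt_deg,
        cfg.nb_nd_half_length,
    )
    b800 = _ring_pigments(
        cluster_id,
        center + cfg.b800_plane_offset * normal,
        normal,
        cfg.b800_radius,
        9,
        [PigmentClass.B800],
        phase,
        0.0,
        cfg.nb_nd_half_length,
        start_index=18,
    )
    return PigmentCluster(cluster_id, ClusterType.LH2, b850 + b800)


def _make_lh1(cluster_id: str, complex_id: str, center: np.ndarray, normal: np.ndarray, phase: float, cfg: GeometryConfig) -> PigmentCluster:
    b875 = _ring_pigments(
        cluster_id,
        center,
        normal,
        cfg.b875_radius,
        28,
        [PigmentClass.B875],
        phase,
        cfg.dipole_tilt_deg,
        cfg.nb_nd_half_length,
    )
    return PigmentCluster(cluster_id, ClusterType.LH1, b875, complex_id=complex_id)


def _make_rc(cluster_id: str, complex_id: str, center: np.ndarray, normal: np.ndarray, phase: float, cfg: GeometryConfig) -> PigmentCluster:
    t1, t2 = _tangent_frame(normal)
    c, s = math.cos(phase), math.sin(phase)
    axis1 = c * t1 + s * t2
    axis2 = -s * t1 + c * t2
    h = cfg.nb_nd_half_length
    pigments = []
    offsets = [
        (-cfg.rc_special_half_separation * axis1, PigmentClass.RC_SPECIAL, axis2),
        (cfg.rc_special_half_separation * axis1, PigmentClass.RC_SPECIAL, -axis2),
        (-cfg.rc_accessory_half_separation * axis2, PigmentClass.RC_ACCESSORY, axis1),
        (cfg.rc_accessory_half_separation * axis2, PigmentClass.RC_ACCESSORY, -axis1),
    ]
    for k, (offset, cls, direction) in enumerate(offsets):
        mg = center + offset
        pigments.append(
            Pigment(
                cluster_id=cluster_id,
                pigment_class=cls,
                ring_index=k,
                mg_position=mg,
                nb_position=mg - h * direction,
                nd_position=mg + h * direction,
            )
        )
    return PigmentCluster(cluster_id, ClusterType.RC, pigments, complex_id=complex_id)


# ---------------------------------------------------------------------------
# sphere placement
# ---------------------------------------------------------------------------


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _step_on_sphere(point: np.ndarray, radius: float, chord: float, direction: np.ndarray) -> np.ndarray:
    """Move along a great circle so the chord to the start equals ``chord``."""
    angle = 2.0 * math.asin(min(1.0, chord / (2.0 * radius)))
    normal = point / radius
    tangent = direction - np.dot(direction, normal) * normal
    tangent /= np.linalg.norm(tangent)
    return radius * (math.cos(angle) * normal + math.sin(angle) * tangent)


def _clear(candidates: list[np.ndarray], positions: np.ndarray, radii: np.ndarray, hardcore: float) -> bool:
    n_placed = len(radii)
    if not n_placed:
        return True
    cand = np.array(candidates)
    dists = np.linalg.norm(cand[:, None, :] - positions[None, :n_placed, :], axis=2)
    return not np.any(dists < hardcore + radii[None, :n_placed] - 1e-9)


def _try_place(
    rng: np.random.Generator,
    radius: float,
    positions: np.ndarray,
    radii: np.ndarray,
    hardcore: float,
    max_attempts: int,
    contact_jitter: float,
    pair_gap: float | None = None,
) -> list[np.ndarray] | None:
    """Attach one site (or a rigid dimer pair) at hard-core contact with an
    already-placed site, avoiding overlap with everything else.

    The first site of a vesicle goes to a random point.  Contact growth keeps
    the packing connected and near-contact, emulating the tight protein
    packing of native membranes.
    """
    n_placed = len(radii)
    for _ in range(max_attempts):
        if n_placed == 0:
            first = radius * _random_unit(rng)
        else:
            anchor = int(rng.integers(n_placed))
            chord = hardcore + radii[anchor] + contact_jitter * rng.random()
            first = _step_on_sphere(positions[anchor], radius, chord, _random_unit(rng))
        if pair_gap is None:
            candidates = [first]
        else:
            partner = _step_on_sphere(first, radius, pair_gap, _random_unit(rng))
            candidates = [first, partner]
        if _clear(candidates, positions, radii, hardcore):
            return candidates
    return None


def _place_centers(composition: CompositionSpec, cfg: GeometryConfig) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """RSA placement; returns (LH1 monomer centers, LH2 centers).

    Dimeric core complexes contribute two adjacent monomer centers.  Restarts
    the whole adsorption with a fresh stream a bounded number of times before
    declaring the composition geometrically infeasible.
    """
    n_dimeric = composition.n_l_dimers - composition.n_l_monomers // 2
    n_sites = 2 * n_dimeric + composition.n_l_monomers + composition.n_lh2
    units = ["D"] * n_dimeric + ["M"] * composition.n_l_monomers + ["L"] * composition.n_lh2
    radius = cfg.placement_radius
    if cfg.scale_radius_with_composition:
        footprint = composition.n_lh2 * cfg.lh2_hardcore**2 + 2 * composition.n_l_dimers * cfg.lh1_hardcore**2
        reference = (
            REFERENCE_COMPOSITION.n_lh2 * cfg.lh2_hardcore**2
            + 2 * REFERENCE_COMPOSITION.n_l_dimers * cfg.lh1_hardcore**2
        )
        radius *= math.sqrt(footprint / reference) if footprint > 0 else 1.0
        radius = max(radius, cfg.dimer_gap)  # tiny compositions still need room
    cfg = replace(cfg, placement_radius=radius)
    last_failure = ""
    for restart in range(cfg.max_restarts):
        rng = np.random.default_rng([cfg.seed, 0, restart])
        order = list(units)
        rng.shuffle(order)  # interleave complex types so cores spread out
        positions = np.zeros((n_sites, 3))
        radii = np.zeros(0)
        lh1_centers: list[np.ndarray] = []
        lh2_centers: list[np.ndarray] = []
        failed = False

        def _commit(point: np.ndarray, hardcore: float) -> None:
            nonlocal radii
            positions[len(radii)] = point
            radii = np.append(radii, hardcore)

        for unit in order:
            hardcore = cfg.lh2_hardcore if unit == "L" else cfg.lh1_hardcore
            sites = _try_place(
                rng,
                cfg.placement_radius,
                positions,
                radii,
                hardcore,
                cfg.max_attempts,
                cfg.contact_jitter,
                pair_gap=cfg.dimer_gap if unit == "D" else None,
            )
            if sites is None:
                failed = True
                last_failure = {"D": "RC-LH1 dimer", "M": "RC-LH1 monomer", "L": "LH2"}[unit]
                break
            for p in sites:
                (lh2_centers if unit == "L" else lh1_centers).append(p)
                _commit(p, hardcore)
        if not failed:
            return lh1_centers, lh2_centers
    raise PlacementError(
        f"could not place a {last_failure} after {cfg.max_restarts} restarts: "
        f"sphere of radius {cfg.placement_radius} A is too crowded for "
        f"{composition.n_lh2} LH2 + {composition.n_l_dimers} RC-LH1 dimer-equivalents"
    )


def build_vesicle(composition: CompositionSpec, config: GeometryConfig | None = None) -> VesicleModel:
    """Generate a synthetic vesicle with the requested composition.

    Deterministic for a fixed ``config.seed``.  Raises :class:`PlacementError`
    when the composition cannot be packed onto the configured sphere.
    """
    cfg = config or GeometryConfig()
    rng = np.random.default_rng([cfg.seed, 1])
    lh1_centers, lh2_centers = _place_centers(composition, cfg)
    clusters: list[PigmentCluster] = []
    for i, center in enumerate(lh2_centers):
        normal = center / np.linalg.norm(center)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        clusters.append(_make_lh2(f"LH2_{i:03d}", center, normal, phase, cfg))
    for i, center in enumerate(lh1_centers):
        normal = center / np.linalg.norm(center)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        complex_id = f"RCLH1_{i:03d}"
        clusters.append(_make_lh1(f"LH1_{i:03d}", complex_id, center, normal, phase, cfg))
        clusters.append(_make_rc(f"RC_{i:03d}", complex_id, center, normal, phase, cfg))
    model = VesicleModel(
        clusters=clusters,
        n_lh2=composition.n_lh2,
        n_l_dimers=composition.n_l_dimers,
        n_dimeric=composition.n_l_dimers - composition.n_l_monomers // 2,
        n_monomeric=composition.n_l_monomers,
        n_bc1_dimers=composition.n_bc1_dimers,
        n_atp_synthase=composition.n_atp_synthase,
        inner_diameter_nm=cfg.inner_diameter_nm,
    )
    model.validate()
    return model


def build_reference_vesicle(config: GeometryConfig | None = None) -> VesicleModel:
    """The low-light reference vesicle: 63 LH2, 11 dimeric + 2 monomeric
    RC-LH1 core complexes, 4 cytochrome bc1 dimers and 2 ATP synthases."""
    return build_vesicle(REFERENCE_COMPOSITION, config)


# ---------------------------------------------------------------------------
# pigment table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "cluster_id",
    "cluster_type",
    "pigment_class",
    "ring_index",
    "mg_x",
    "mg_y",
    "mg_z",
    "nb_x",
    "nb_y",
    "nb_z",
    "nd_x",
    "nd_y",
    "nd_z",
]


def write_pigment_table(model: VesicleModel, path: str | Path) -> None:
    """Write the vesicle as a TSV pigment table (angstroms, 6 decimals).

    Composition counts that are not derivable from the pigments (bc1 dimers,
    ATP synthases, the dimer/monomer split) go into ``#``-prefixed header
    lines so that read/write round-trips reproduce the model.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# n_bc1_dimers = {model.n_bc1_dimers}\n")
        fh.write(f"# n_atp_synthase = {model.n_atp_synthase}\n")
        fh.write(f"# n_monomeric = {model.n_monomeric}\n")
        fh.write(f"# inner_diameter_nm = {model.inner_diameter_nm}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for cluster in model.clusters:
            for p in cluster.pigments:
                row = [cluster.cluster_id, cluster.cluster_type.value, p.pigment_class.value, p.ring_index]
                for vec in (p.mg_position, p.nb_position, p.nd_position):
                    row.extend(f"{x:.6f}" for x in vec)
                writer.writerow(row)


def _complex_id_for(cluster_id: str, cluster_type: ClusterType) -> str | None:
    match = re.fullmatch(r"(?:LH1|RC)_(\w+)", cluster_id)
    if cluster_type in (ClusterType.LH1, ClusterType.RC) and match:
        return f"RCLH1_{match.group(1)}"
    return None


def read_pigment_table(path: str | Path) -> VesicleModel:
    """Read a TSV pigment table (the dialect written by
    :func:`write_pigment_table`) back into a :class:`VesicleModel`."""
    path = Path(path)
    meta = {"n_bc1_dimers": 0, "n_atp_synthase": 0, "n_monomeric": 0, "inner_diameter_nm": 50.0}
    order: list[str] = []
    rows: dict[str, list[tuple[int, ClusterType, Pigment]]] = {}
    seen: set[tuple[str, int]] = set()
    with path.open() as fh:
        lineno = 0
        header: list[str] | None = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m and m.group(1) in meta:
                    cast = float if m.group(1) == "inner_diameter_nm" else int
                    meta[m.group(1)] = cast(m.group(2))
                continue
            parts = line.split("\t")
            if header is None:
                if parts != _TABLE_COLUMNS:
                    raise PigmentTableError(f"line {lineno}: unexpected header {parts!r}")
                header = parts
                continue
            if len(parts) != len(_TABLE_COLUMNS):
                raise PigmentTableError(f"line {lineno}: expected {len(_TABLE_COLUMNS)} fields, got {len(parts)}")
            cluster_id = parts[0]
            try:
                ctype = ClusterType(parts[1])
            except ValueError as exc:
                raise PigmentTableError(f"line {lineno}: unknown cluster_type {parts[1]!r}") from exc
            try:
                pclass = PigmentClass(parts[2])
            except ValueError as exc:
                raise PigmentTableError(f"line {lineno}: unknown pigment_class {parts[2]!r}") from exc
            try:
                ring_index = int(parts[3])
                coords = [float(x) for x in parts[4:13]]
            except ValueError as exc:
                raise PigmentTableError(f"line {lineno}: {exc}") from exc
            key = (cluster_id, ring_index)
            if key in seen:
                raise PigmentTableError(f"line {lineno}: duplicate (cluster_id, ring_index) {key!r}")
            seen.add(key)
            try:
                pigment = Pigment(
                    cluster_id=cluster_id,
                    pigment_class=pclass,
                    ring_index=ring_index,
                    mg_position=np.array(coords[0:3]),
                    nb_position=np.array(coords[3:6]),
                    nd_position=np.array(coords[6:9]),
                )
            except ValueError as exc:
                raise PigmentTableError(f"line {lineno}: {exc}") from exc
            if cluster_id not in rows:
                rows[cluster_id] = []
                order.append(cluster_id)
            rows[cluster_id].append((ring_index, ctype, pigment))
    if header is None:
        raise PigmentTableError("empty pigment table")
    clusters = []
    for cluster_id in order:
        entries = sorted(rows[cluster_id], key=lambda t: t[0])
        ctypes = {t[1] for t in entries}
        if len(ctypes) != 1:
            raise PigmentTableError(f"cluster {cluster_id!r} mixes cluster types {sorted(c.value for c in ctypes)}")
        ctype = ctypes.pop()
        cluster = PigmentCluster(
            cluster_id,
            ctype,
            [t[2] for t in entries],
            complex_id=_complex_id_for(cluster_id, ctype),
        )
        cluster.validate()
        clusters.append(cluster)
    return _model_from_clusters(clusters, meta)


def _model_from_clusters(clusters: list[PigmentCluster], meta: Mapping[str, float]) -> VesicleModel:
    n_lh2 = sum(1 for c in clusters if c.cluster_type is ClusterType.LH2)
    n_lh1 = sum(1 for c in clusters if c.cluster_type is ClusterType.LH1)
    n_rc = sum(1 for c in clusters if c.cluster_type is ClusterType.RC)
    if n_lh1 != n_rc:
        raise PigmentTableError(f"unbalanced core complexes: {n_lh1} LH1 rings vs {n_rc} RCs")
    if n_rc % 2 != 0:
        raise PigmentTableError(f"odd RC count {n_rc} cannot be expressed in dimer-equivalents")
    n_l_dimers = n_rc // 2
    n_monomeric = int(meta["n_monomeric"])
    model = VesicleModel(
        clusters=clusters,
        n_lh2=n_lh2,
        n_l_dimers=n_l_dimers,
        n_dimeric=n_l_dimers - n_monomeric // 2,
        n_monomeric=n_monomeric,
        n_bc1_dimers=int(meta["n_bc1_dimers"]),
        n_atp_synthase=int(meta["n_atp_synthase"]),
        inner_diameter_nm=float(meta["inner_diameter_nm"]),
    )
    model.validate()
    return model


def read_pigment_pdb(path: str | Path, n_bc1_dimers: int = 0, n_atp_synthase: int = 0) -> VesicleModel:
    """Read PDB-style records (residues named BCL with MG/NB/ND atoms).

    Each chain becomes one cluster; the cluster type is inferred from the
    residue count (4 -> RC, 28 -> LH1, 18 or 27 -> LH2) and pigment classes
    are assigned in residue order (alternating alpha/beta for B850, first two
    RC residues as the special pair, trailing LH2 residues beyond 18 as B800).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("vesicle", str(path))
    clusters: list[PigmentCluster] = []
    model0 = next(structure.get_models())
    for chain in model0:
        residues = [r for r in chain if r.get_resname().strip() == "BCL"]
        if not residues:
            continue
        n = len(residues)
        if n == 4:
            ctype = ClusterType.RC
        elif n == 28:
            ctype = ClusterType.LH1
        elif n in (18, 27):
            ctype = ClusterType.LH2
        else:
            raise PigmentTableError(
                f"chain {chain.id!r} has {n} BCL residues; cannot infer cluster type (expected 4, 18, 27 or 28)"
            )
        cluster_id = f"{ctype.value}_{chain.id}"
        pigments = []
        for k, res in enumerate(residues):
            atoms = {a.get_name().strip(): a for a in res}
            missing = [name for name in ("MG", "NB", "ND") if name not in atoms]
            if missing:
                raise PigmentTableError(
                    f"chain {chain.id!r} residue {res.get_id()[1]}: missing atoms {missing}"
                )
            if ctype is ClusterType.RC:
                pclass = PigmentClass.RC_SPECIAL if k < 2 else PigmentClass.RC_ACCESSORY
            elif ctype is ClusterType.LH1:
                pclass = PigmentClass.B875
            elif k >= 18:
                pclass = PigmentClass.B800
            else:
                pclass = PigmentClass.B850_ALPHA if k % 2 == 0 else PigmentClass.B850_BETA
            pigments.append(
                Pigment(
                    cluster_id=cluster_id,
                    pigment_class=pclass,
                    ring_index=k,
                    mg_position=atoms["MG"].get_coord().astype(float),
                    nb_position=atoms["NB"].get_coord().astype(float),
                    nd_position=atoms["ND"].get_coord().astype(float),
                )
            )
        cluster = PigmentCluster(cluster_id, ctype, pigments, complex_id=None)
        cluster.validate()
        clusters.append(cluster)
    # pair LH1 and RC clusters by order of appearance within the file
    lh1s = [c for c in clusters if c.cluster_type is ClusterType.LH1]
    rcs = [c for c in clusters if c.cluster_type is ClusterType.RC]
    for i, (lh1, rc) in enumerate(zip(lh1s, rcs)):
        lh1.complex_id = rc.complex_id = f"RCLH1_{i:03d}"
    meta = {
        "n_bc1_dimers": n_bc1_dimers,
        "n_atp_synthase": n_atp_synthase,
        "n_monomeric": 0,
        "inner_diameter_nm": 50.0,
    }
    return _model_from_clusters(clusters, meta)


def rotate_vesicle(model: VesicleModel, rotation: np.ndarray, translation: np.ndarray | None = None) -> VesicleModel:
    """Rigidly transform all pigment coordinates (used for invariance checks)."""
    rotation = np.asarray(rotation, dtype=float)
    shift = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    clusters = []
    for cluster in model.clusters:
        pigments = [
            Pigment(
                cluster_id=p.cluster_id,
                pigment_class=p.pigment_class,
                ring_index=p.ring_index,
                mg_position=rotation @ p.mg_position + shift,
                nb_position=rotation @ p.nb_position + shift,
                nd_position=rotation @ p.nd_position + shift,
            )
            for p in cluster.pigments
        ]
        clusters.append(PigmentCluster(cluster.cluster_id, cluster.cluster_type, pigments, complex_id=cluster.complex_id))
    return replace(model, clusters=clusters)
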