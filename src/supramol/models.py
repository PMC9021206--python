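"""Coarse-grained monomer models of supramolecular polymers.

Three monomer species are provided:

``M``
    A minimalistic directional monomer: a flat hexagonal unit of seven beads
    (one core, six shielding vertices).  Cores attract strongly (epsilon of
    several kT), the shielding beads interact weakly (0.2 kJ/mol) and screen
    the core laterally so that monomers can only stack face-to-face, which
    drives one-dimensional fibre growth.

``BTA``
    An 18-bead discotic monomer representative of threefold-symmetric
    supramolecular motifs (benzene-1,3,5-tricarboxamide-like) in a good
    solvent: a central core bead carrying a rigid +/-1.4 e charge dipole
    along the stacking axis, and three flexible five-bead arms.

``BTA_w``
    Structurally identical to ``BTA`` but amphiphilic: the six innermost arm
    beads become solvophobic (their mutual Lennard-Jones epsilon raised from
    1 to 4 kJ/mol), mimicking water-soluble monomers whose assembly mixes
    directional and non-directional interactions.

All geometries are built so that every harmonic bond and angle is exactly at
its rest value in the reference conformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .constants import SIGMA

__all__ = [
    "BeadRole",
    "BeadSpec",
    "HarmonicBond",
    "HarmonicAngle",
    "LJPair",
    "MonomerTopology",
    "ForceField",
    "SystemConfiguration",
    "build_monomer",
    "build_forcefield",
    "build_random_config",
    "build_stacked_config",
]


class BeadRole(str, Enum):
    CORE = "core"
    SHIELD = "shield"
    DIPOLE_PLUS = "dipole_plus"
    DIPOLE_MINUS = "dipole_minus"
    ARM_INNER = "arm_inner"
    ARM = "arm"


#: default CG bead mass, amu (4-to-1 mapping convention)
BEAD_MASS = 72.0
#: charge beads are small, amu
CHARGE_BEAD_MASS = 36.0
#: dipole charge magnitude, e
DIPOLE_CHARGE = 1.4
#: half-length of the rigid dipole, nm
DIPOLE_OFFSET = 0.10

K_STIFF = 20000.0     # kJ mol^-1 nm^-2, rigid-frame bonds
K_CROSS = 15000.0     # kJ mol^-1 nm^-2, hexagon cross-braces
K_ARM_BOND = 1250.0   # kJ mol^-1 nm^-2, flexible arm bonds
K_ARM_ANGLE = 25.0    # kJ mol^-1 rad^-2, flexible arm angles
K_DIPOLE_ANGLE = 500.0  # keeps the two charge beads antipodal

BOND_LENGTH = SIGMA  # 0.47 nm: hexagon edge, spoke and arm spacing alike


@dataclass(frozen=True)
class BeadSpec:
    bead_id: int
    role: BeadRole
    mass: float
    charge: float = 0.0


@dataclass(frozen=True)
class HarmonicBond:
    """V = 1/2 k (r - r0)^2 between beads i, j of one monomer."""

    i: int
    j: int
    k: float      # kJ mol^-1 nm^-2
    r0: float     # nm

    def __post_init__(self) -> None:
        if self.k <= 0 or self.r0 <= 0:
            raise ValueError("bond force constant and rest length must be positive")


@dataclass(frozen=True)
class HarmonicAngle:
    """V = 1/2 k (theta - theta0)^2 over beads i-j-k; theta0 in degrees."""

    i: int
    j: int
    k: int
    k_theta: float   # kJ mol^-1 rad^-2
    theta0: float    # degrees

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 <= 180.0:
            raise ValueError("theta0 must lie in (0, 180] degrees")


@dataclass(frozen=True)
class LJPair:
    role_a: BeadRole
    role_b: BeadRole
    epsilon: float   # kJ mol^-1
    sigma: float = SIGMA

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class MonomerTopology:
    species: str
    beads: list[BeadSpec]
    bonds: list[HarmonicBond]
    angles: list[HarmonicAngle]
    reference_geometry: np.ndarray  # (n_beads, 3), nm, core at the origin

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def core_index(self) -> int:
        """Index of the (single) core bead used for contact analysis."""
        for b in self.beads:
            if b.role is BeadRole.CORE:
                return b.bead_id
        raise ValueError(f"topology {self.species!r} has no core bead")

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def bond_graph_distances(self) -> np.ndarray:
        """All-pairs shortest bond-path lengths (for exclusion rules)."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import shortest_path

        n = self.n_beads
        rows = [b.i for b in self.bonds] + [b.j for b in self.bonds]
        cols = [b.j for b in self.bonds] + [b.i for b in self.bonds]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return shortest_path(adj, unweighted=True)

    def validate(self, tol: float = 1e-6) -> None:
        """Check that the reference geometry realises every bond rest length."""
        x = self.reference_geometry
        for b in self.bonds:
            r = float(np.linalg.norm(x[b.i] - x[b.j]))
            if abs(r - b.r0) > tol:
                raise ValueError(
                    f"{self.species}: bond {b.i}-{b.j} length {r:.8f} != r0 {b.r0}"
                )


@dataclass
class ForceField:
    """Non-bonded interaction table.

    Lennard-Jones potentials (one sigma for every pair) plus, for the
    BTA-family models, a truncated-shifted Coulomb term between the dipole
    charge beads.  Both potentials are cut and shifted to zero at
    ``r_cutoff`` so the energy is continuous.
    """

    lj_pairs: list[LJPair]
    coulomb_on: bool = False
    r_cutoff: float = 1.1          # nm
    shift_at_cutoff: bool = True
    dielectric: float = 15.0       # implicit-solvent relative permittivity

    def epsilon(self, a: BeadRole, b: BeadRole) -> float:
        for p in self.lj_pairs:
            if {p.role_a, p.role_b} == {a, b} or (p.role_a == a and p.role_b == b):
                return p.epsilon
        return 0.0

    def epsilon_matrix(self, roles: list[BeadRole]) -> np.ndarray:
        n = len(roles)
        eps = np.zeros((n, n))
        for i, a in enumerate(roles):
            for j, b in enumerate(roles):
                eps[i, j] = self.epsilon(a, b)
        return eps


@dataclass
class SystemConfiguration:
    topology: MonomerTopology
    n_monomers: int
    box_length: float                 # nm, cubic periodic box
    positions: np.ndarray             # (n_beads_total, 3), wrapped to [0, L)
    monomer_index: np.ndarray         # (n_beads_total,), owning monomer id
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = self.n_monomers * self.topology.n_beads
        if self.positions.shape != (expected, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({expected}, 3)"
            )
        self.positions = np.mod(self.positions, self.box_length)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def core_positions(self) -> np.ndarray:
        """(n_monomers, 3) positions of each monomer's core bead."""
        nb = self.topology.n_beads
        return self.positions[self.topology.core_index::nb][: self.n_monomers]

    @property
    def density(self) -> float:
        """Monomer number density, nm^-3."""
        return self.n_monomers / self.box_length**3

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            topology=self.topology,
            n_monomers=self.n_monomers,
            box_length=self.box_length,
            positions=self.positions.copy(),
            monomer_index=self.monomer_index.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------


def _build_m() -> MonomerTopology:
    # Hexagon edge 0.47 nm == circumradius, so spokes and edges share r0.
    beads = [BeadSpec(0, BeadRole.CORE, BEAD_MASS)]
    beads += [BeadSpec(i, BeadRole.SHIELD, BEAD_MASS) for i in range(1, 7)]
    ang = np.arange(6) * np.pi / 3.0
    geom = np.zeros((7, 3))
    geom[1:, 0] = BOND_LENGTH * np.cos(ang)
    geom[1:, 1] = BOND_LENGTH * np.sin(ang)

    bonds = []
    for k in range(6):
        bonds.append(HarmonicBond(1 + k, 1 + (k + 1) % 6, K_STIFF, BOND_LENGTH))
    for k in range(6):
        bonds.append(HarmonicBond(0, 1 + k, K_STIFF, BOND_LENGTH))
    # cross-braces keep the hexagon planar
    for k in range(3):
        bonds.append(HarmonicBond(1 + k, 1 + k + 3, K_CROSS, 2 * BOND_LENGTH))
    return MonomerTopology("M", beads, bonds, [], geom)


def _build_bta(species: str) -> MonomerTopology:
    beads = [
        BeadSpec(0, BeadRole.CORE, BEAD_MASS),
        BeadSpec(1, BeadRole.DIPOLE_PLUS, CHARGE_BEAD_MASS, +DIPOLE_CHARGE),
        BeadSpec(2, BeadRole.DIPOLE_MINUS, CHARGE_BEAD_MASS, -DIPOLE_CHARGE),
    ]
    geom = [np.zeros(3), np.array([0.0, 0.0, DIPOLE_OFFSET]),
            np.array([0.0, 0.0, -DIPOLE_OFFSET])]
    bonds = [
        HarmonicBond(0, 1, K_STIFF, DIPOLE_OFFSET),
        HarmonicBond(0, 2, K_STIFF, DIPOLE_OFFSET),
    ]
    angles = [HarmonicAngle(1, 0, 2, K_DIPOLE_ANGLE, 180.0)]

    arm_first: list[int] = []
    for a in range(3):
        theta = a * 2.0 * np.pi / 3.0
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        prev = 0
        for s in range(5):
            idx = len(beads)
            role = BeadRole.ARM_INNER if s < 2 else BeadRole.ARM
            beads.append(BeadSpec(idx, role, BEAD_MASS))
            geom.append(BOND_LENGTH * (s + 1) * u)
            bonds.append(HarmonicBond(prev, idx, K_ARM_BOND, BOND_LENGTH))
            if s == 0:
                arm_first.append(idx)
            prev = idx
        # straight-arm angles: core-a1-a2, a1-a2-a3, ...
        base = arm_first[a]
        chain = [0] + list(range(base, base + 5))
        for t in range(len(chain) - 2):
            angles.append(
                HarmonicAngle(chain[t], chain[t + 1], chain[t + 2], K_ARM_ANGLE, 180.0)
            )
    # threefold symmetry between arms and dipole orthogonality
    for a in range(3):
        angles.append(
            HarmonicAngle(arm_first[a], 0, arm_first[(a + 1) % 3], K_ARM_ANGLE, 120.0)
        )
        angles.append(HarmonicAngle(1, 0, arm_first[a], K_ARM_ANGLE, 90.0))
        angles.append(HarmonicAngle(2, 0, arm_first[a], K_ARM_ANGLE, 90.0))
    return MonomerTopology(species, beads, bonds, angles, np.array(geom))


def build_monomer(species: str) -> MonomerTopology:
    """Construct the reference topology of one monomer species."""
    if species == "M":
        topo = _build_m()
    elif species in ("BTA", "BTA_w"):
        topo = _build_bta(species)
    else:
        raise ValueError(f"unknown monomer species {species!r}")
    topo.validate()
    return topo


# default core-core epsilon (kJ/mol) per species; M is scanned 40/45/50
_DEFAULT_EPS_CORE = {"M": 45.0, "BTA": 2.5, "BTA_w": 2.5}
_EPS_SHIELD = 0.2
_EPS_ARM = 1.0
_EPS_ARM_CORE = 0.5
_EPS_SOLVOPHOBIC = 4.0  # BTA_w inner-arm beads


def build_forcefield(
    species: str,
    epsilon_core: float | None = None,
    r_cutoff: float = 1.1,
    dielectric: float = 15.0,
) -> ForceField:
    """Non-bonded parameter set for one species.

    ``epsilon_core`` overrides the core-core LJ well depth (the control
    parameter of the M model: 40, 45 or 50 kJ/mol in the reference systems).
    """
    if species not in _DEFAULT_EPS_CORE:
        raise ValueError(f"unknown monomer species {species!r}")
    eps_cc = _DEFAULT_EPS_CORE[species] if epsilon_core is None else float(epsilon_core)
    R = BeadRole
    if species == "M":
        pairs = [
            LJPair(R.CORE, R.CORE, eps_cc),
            LJPair(R.CORE, R.SHIELD, _EPS_SHIELD),
            LJPair(R.SHIELD, R.SHIELD, _EPS_SHIELD),
        ]
        return ForceField(pairs, coulomb_on=False, r_cutoff=r_cutoff,
                          dielectric=dielectric)
    eps_inner = _EPS_SOLVOPHOBIC if species == "BTA_w" else _EPS_ARM
    pairs = [
        LJPair(R.CORE, R.CORE, eps_cc),
        LJPair(R.CORE, R.ARM, _EPS_ARM_CORE),
        LJPair(R.CORE, R.ARM_INNER, _EPS_ARM_CORE),
        LJPair(R.ARM, R.ARM, _EPS_ARM),
        LJPair(R.ARM, R.ARM_INNER, _EPS_ARM),
        LJPair(R.ARM_INNER, R.ARM_INNER, eps_inner),
        # dipole charge beads have no LJ interactions at all
    ]
    return ForceField(pairs, coulomb_on=True, r_cutoff=r_cutoff,
                      dielectric=dielectric)


# ---------------------------------------------------------------------------
# configuration builders
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _assemble(topology: MonomerTopology, centres: np.ndarray,
              rotations: list[np.ndarray] | None, box: float) -> SystemConfiguration:
    n = len(centres)
    nb = topology.n_beads
    pos = np.empty((n * nb, 3))
    for m in range(n):
        g = topology.reference_geometry
        if rotations is not None:
            g = g @ rotations[m].T
        pos[m * nb:(m + 1) * nb] = g + centres[m]
    monomer_index = np.repeat(np.arange(n), nb)
    return SystemConfiguration(topology, n, box, pos, monomer_index)


def build_random_config(
    topology: MonomerTopology,
    n_monomers: int,
    box_length: float,
    min_separation: float = 1.2,
    seed: int = 0,
    max_tries_per_monomer: int = 2000,
) -> SystemConfiguration:
    """Randomly dispersed monomers (the "R" initial condition).

    Monomer centres are placed by rejection sampling so that every pair of
    centres is at least ``min_separation`` apart under minimum image, and each
    monomer gets an independent uniform random orientation.  The default
    separation of 1.2 nm exceeds the 1.1 nm interaction cutoff, so the system
    starts fully disassembled.
    """
    rng = np.random.default_rng(seed)
    centres = np.empty((n_monomers, 3))
    placed = 0
    tries = 0
    budget = max_tries_per_monomer * n_monomers
    while placed < n_monomers:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {n_monomers} monomers with min separation "
                f"{min_separation} nm in a {box_length} nm box; achieved "
                f"{placed} (density {placed / box_length**3:.4f} nm^-3)"
            )
        tries += 1
        cand = rng.uniform(0.0, box_length, size=3)
        if placed:
            d = _min_image(centres[:placed] - cand, box_length)
            if np.min(np.einsum("ij,ij->i", d, d)) < min_separation**2:
                continue
        centres[placed] = cand
        placed += 1
    rotations = [_random_rotation(rng) for _ in range(n_monomers)]
    return _assemble(topology, centres, rotations, box_length)


def build_stacked_config(
    topology: MonomerTopology,
    n_fibres: int,
    monomers_per_fibre: int,
    stack_spacing: float,
    box_length: float,
    seed: int = 0,
    lateral_pitch: float = 2.0,
) -> SystemConfiguration:
    """Pre-stacked straight fibres (the "S" initial condition).

    Each fibre is a stack of coplanar-parallel monomers along z with the
    given core-core spacing; fibre axes sit on a square lattice in x-y.  The
    reference system uses 20 fibres of 25 monomers.
    """
    fibre_len = (monomers_per_fibre - 1) * stack_spacing
    if fibre_len >= box_length - stack_spacing:
        raise ValueError(
            f"fibre of {monomers_per_fibre} monomers at spacing {stack_spacing} "
            f"nm does not fit a {box_length} nm periodic box"
        )
    per_side = int(np.floor(box_length / lateral_pitch))
    if n_fibres > per_side**2:
        raise ValueError(
            f"{n_fibres} fibres do not fit a {per_side}x{per_side} lateral "
            f"grid at pitch {lateral_pitch} nm"
        )
    rng = np.random.default_rng(seed)
    centres = np.empty((n_fibres * monomers_per_fibre, 3))
    m = 0
    for f in range(n_fibres):
        gx = (f % per_side + 0.5) * lateral_pitch
        gy = (f // per_side + 0.5) * lateral_pitch
        z0 = rng.uniform(0.0, box_length)
        for s in range(monomers_per_fibre):
            centres[m] = (gx, gy, z0 + s * stack_spacing)
            m += 1
    return _assemble(topology, centres, None, box_length)
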