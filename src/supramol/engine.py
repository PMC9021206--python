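"""Implicit-solvent Langevin dynamics for the coarse-grained models.

The solvent enters only through friction and thermal noise (Langevin
equation, NVT); solute-solvent energetics are folded into the non-bonded
potentials.  Integration uses the BAOAB splitting with friction
``gamma = 1/tau_t`` and Gaussian noise satisfying fluctuation-dissipation at
the target temperature.

Two force paths exist on purpose:

* :func:`potential_energy` / :func:`forces` — straightforward vectorised
  all-pairs NumPy implementations.  These are the reference: simple enough
  to audit, used directly for small systems and as the correctness oracle.
* a numba-compiled inner loop with a Verlet pair list (cutoff + 0.3 nm
  skin, rebuilt on a displacement criterion), used by
  :func:`step_langevin` / :func:`run_simulation`.  Its forces are required
  to match the all-pairs path to floating-point accuracy; a property test
  enforces this.

Non-bonded potentials are truncated and shifted to zero at ``r_cutoff``
(1.1 nm by default), Lennard-Jones and Coulomb alike; minimum-image
convention in a cubic periodic box.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .constants import F_ELEC, KB
from .models import ForceField, MonomerTopology, SystemConfiguration

__all__ = [
    "SimulationParams",
    "TrajectoryFrame",
    "potential_energy",
    "forces",
    "step_langevin",
    "run_simulation",
]

log = logging.getLogger(__name__)

#: Verlet-list skin, nm
SKIN = 0.3

#: default integration time step per species, ps
DEFAULT_DT = {"M": 0.020, "BTA": 0.015, "BTA_w": 0.015}


@dataclass
class SimulationParams:
    """Run-control parameters (GROMACS ``sd``-equivalent contract)."""

    dt: float = 0.020              # ps (20 fs for M, 15 fs for BTA/BTA_w)
    tau_t: float = 0.1             # ps, inverse friction constant
    temperature: float = 300.0     # K
    n_steps: int = 0
    sample_interval: float = 0.3   # ps between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_t <= 0:
            raise ValueError("dt and tau_t must be positive")
        if self.sample_interval < self.dt:
            raise ValueError("sample_interval must be >= dt")

    @property
    def gamma(self) -> float:
        """Friction constant, ps^-1."""
        return 1.0 / self.tau_t


@dataclass
class TrajectoryFrame:
    time: float                    # ps
    positions: np.ndarray          # (n_beads, 3) nm, wrapped
    box_length: float              # nm
    velocities: np.ndarray | None = None


# ---------------------------------------------------------------------------
# system tables shared by both force paths
# ---------------------------------------------------------------------------


@dataclass
class _Tables:
    type_index: np.ndarray   # (n_beads,) int
    eps_table: np.ndarray    # (n_types, n_types)
    sigma: float
    charges: np.ndarray      # (n_beads,)
    excl_local: np.ndarray   # (nb, nb) bool, intra-monomer exclusions
    bonds: np.ndarray        # (n_bonds_total, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray       # (n_angles_total, 3) int
    angle_k: np.ndarray
    angle_t0: np.ndarray     # radians


_TABLE_CACHE: dict[tuple, _Tables] = {}


def _build_tables(topo: MonomerTopology, ff: ForceField, n_monomers: int) -> _Tables:
    key = (topo.species, id(ff), n_monomers, tuple(p.epsilon for p in ff.lj_pairs))
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    roles = sorted({b.role for b in topo.beads}, key=lambda r: r.value)
    role_to_type = {r: t for t, r in enumerate(roles)}
    per_mono_type = np.array([role_to_type[b.role] for b in topo.beads])
    nb = topo.n_beads
    type_index = np.tile(per_mono_type, n_monomers)
    eps_table = ff.epsilon_matrix(roles)
    charges = np.tile(topo.charges, n_monomers)
    if not ff.coulomb_on:
        charges = np.zeros_like(charges)
    # exclusion rule: intra-monomer pairs within two bonds (nrexcl = 2)
    d = topo.bond_graph_distances()
    excl_local = d <= 2.0

    offs = (np.arange(n_monomers) * nb)[:, None, None]
    if topo.bonds:
        b = np.array([[x.i, x.j] for x in topo.bonds])
        bonds = (b[None, :, :] + offs).reshape(-1, 2)
        bond_k = np.tile(np.array([x.k for x in topo.bonds]), n_monomers)
        bond_r0 = np.tile(np.array([x.r0 for x in topo.bonds]), n_monomers)
    else:
        bonds = np.zeros((0, 2), dtype=int)
        bond_k = bond_r0 = np.zeros(0)
    if topo.angles:
        a = np.array([[x.i, x.j, x.k] for x in topo.angles])
        angles = (a[None, :, :] + offs).reshape(-1, 3)
        angle_k = np.tile(np.array([x.k_theta for x in topo.angles]), n_monomers)
        angle_t0 = np.tile(
            np.deg2rad([x.theta0 for x in topo.angles]), n_monomers
        )
    else:
        angles = np.zeros((0, 3), dtype=int)
        angle_k = angle_t0 = np.zeros(0)
    tab = _Tables(
        type_index=type_index, eps_table=eps_table,
        sigma=ff.lj_pairs[0].sigma if ff.lj_pairs else 0.47,
        charges=charges, excl_local=excl_local,
        bonds=bonds, bond_k=bond_k, bond_r0=bond_r0,
        angles=angles, angle_k=angle_k, angle_t0=angle_t0,
    )
    _TABLE_CACHE[key] = tab
    return tab


def _pair_list(
    pos: np.ndarray, box: float, r_list: float, tab: _Tables, nb: int,
    ff: ForceField,
):
    """Candidate non-bonded pairs within ``r_list``, exclusions removed.

    Returns per-pair index arrays plus precomputed epsilon, LJ shift and
    Coulomb prefactor/shift so the inner kernel does no table lookups.
    """
    wrapped = np.mod(pos, box)
    # guard the cKDTree boxsize contract against x == box after rounding
    wrapped[wrapped >= box] -= box
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r_list, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        same = (i // nb) == (j // nb)
        excl = np.zeros(len(i), dtype=bool)
        excl[same] = tab.excl_local[i[same] % nb, j[same] % nb]
        pairs = pairs[~excl]
    i, j = pairs[:, 0], pairs[:, 1]
    eps = tab.eps_table[tab.type_index[i], tab.type_index[j]]
    qq = np.zeros(len(i))
    if ff.coulomb_on:
        qq = F_ELEC / ff.dielectric * tab.charges[i] * tab.charges[j]
    rc = ff.r_cutoff
    sr6 = (tab.sigma / rc) ** 6
    lj_shift = 4.0 * eps * (sr6 * sr6 - sr6) if ff.shift_at_cutoff else 0.0 * eps
    coul_shift = qq / rc if ff.shift_at_cutoff else 0.0 * qq
    return (
        np.ascontiguousarray(i, dtype=np.int64),
        np.ascontiguousarray(j, dtype=np.int64),
        eps, qq, lj_shift, coul_shift,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _nb_seed(seed):
    np.random.seed(seed)


@njit(cache=False)
def _kernel_forces(pos, box, pi, pj, eps, qq, lj_shift, coul_shift,
                   rc2, sigma, bonds, bond_k, bond_r0,
                   angles, angle_k, angle_t0, f_out):
    n = pos.shape[0]
    for a in range(n):
        f_out[a, 0] = 0.0
        f_out[a, 1] = 0.0
        f_out[a, 2] = 0.0
    e_lj = 0.0
    e_coul = 0.0
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        inv_r2 = 1.0 / r2
        fr = 0.0
        if eps[p] != 0.0:
            sr2 = sigma * sigma * inv_r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e_lj += 4.0 * eps[p] * (sr12 - sr6) - lj_shift[p]
            fr += 24.0 * eps[p] * (2.0 * sr12 - sr6) * inv_r2
        if qq[p] != 0.0:
            inv_r = math.sqrt(inv_r2)
            e_coul += qq[p] * inv_r - coul_shift[p]
            fr += qq[p] * inv_r * inv_r2
        if fr != 0.0:
            f_out[i, 0] += fr * dx
            f_out[i, 1] += fr * dy
            f_out[i, 2] += fr * dz
            f_out[j, 0] -= fr * dx
            f_out[j, 1] -= fr * dy
            f_out[j, 2] -= fr * dz
    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += 0.5 * bond_k[b] * dr * dr
        fr = -bond_k[b] * dr / r
        f_out[i, 0] += fr * dx
        f_out[i, 1] += fr * dy
        f_out[i, 2] += fr * dz
        f_out[j, 0] -= fr * dx
        f_out[j, 1] -= fr * dy
        f_out[j, 2] -= fr * dz
    e_angle = 0.0
    for a in range(angles.shape[0]):
        ii = angles[a, 0]
        jj = angles[a, 1]
        kk = angles[a, 2]
        ux = pos[ii, 0] - pos[jj, 0]
        uy = pos[ii, 1] - pos[jj, 1]
        uz = pos[ii, 2] - pos[jj, 2]
        vx = pos[kk, 0] - pos[jj, 0]
        vy = pos[kk, 1] - pos[jj, 1]
        vz = pos[kk, 2] - pos[jj, 2]
        ux -= box * round(ux / box)
        uy -= box * round(uy / box)
        uz -= box * round(uz / box)
        vx -= box * round(vx / box)
        vy -= box * round(vy / box)
        vz -= box * round(vz / box)
        ru = math.sqrt(ux * ux + uy * uy + uz * uz)
        rv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = math.acos(c)
        dth = theta - angle_t0[a]
        e_angle += 0.5 * angle_k[a] * dth * dth
        s = math.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = -angle_k[a] * dth / s
        fix = (coef / ru) * (vx / rv - c * ux / ru)
        fiy = (coef / ru) * (vy / rv - c * uy / ru)
        fiz = (coef / ru) * (vz / rv - c * uz / ru)
        fkx = (coef / rv) * (ux / ru - c * vx / rv)
        fky = (coef / rv) * (uy / ru - c * vy / rv)
        fkz = (coef / rv) * (uz / ru - c * vz / rv)
        f_out[ii, 0] += fix
        f_out[ii, 1] += fiy
        f_out[ii, 2] += fiz
        f_out[kk, 0] += fkx
        f_out[kk, 1] += fky
        f_out[kk, 2] += fkz
        f_out[jj, 0] -= fix + fkx
        f_out[jj, 1] -= fiy + fky
        f_out[jj, 2] -= fiz + fkz
    return e_bond, e_angle, e_lj, e_coul


@njit(cache=False)
def _kernel_baoab(pos, vel, forces_buf, masses, box,
                  pi, pj, eps, qq, lj_shift, coul_shift, rc2, sigma,
                  bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
                  dt, c1, kT, ref_pos, skin_half2, n_steps):
    """Advance up to ``n_steps`` BAOAB steps with a frozen pair list.

    Returns the number of steps actually taken; stops early when any bead
    has moved more than half the Verlet skin since the list was built (the
    caller then rebuilds the list and re-enters), or when a coordinate goes
    non-finite (returns ``-(step+1)``).
    """
    n = pos.shape[0]
    half_dt = 0.5 * dt
    c2kt = (1.0 - c1 * c1) * kT
    done = 0
    for step in range(n_steps):
        for a in range(n):
            im = half_dt / masses[a]
            vel[a, 0] += im * forces_buf[a, 0]
            vel[a, 1] += im * forces_buf[a, 1]
            vel[a, 2] += im * forces_buf[a, 2]
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        for a in range(n):
            sd = math.sqrt(c2kt / masses[a])
            vel[a, 0] = c1 * vel[a, 0] + sd * np.random.standard_normal()
            vel[a, 1] = c1 * vel[a, 1] + sd * np.random.standard_normal()
            vel[a, 2] = c1 * vel[a, 2] + sd * np.random.standard_normal()
            pos[a, 0] += half_dt * vel[a, 0]
            pos[a, 1] += half_dt * vel[a, 1]
            pos[a, 2] += half_dt * vel[a, 2]
        _kernel_forces(pos, box, pi, pj, eps, qq, lj_shift, coul_shift,
                       rc2, sigma, bonds, bond_k, bond_r0,
                       angles, angle_k, angle_t0, forces_buf)
        for a in range(n):
            im = half_dt / masses[a]
            vel[a, 0] += im * forces_buf[a, 0]
            vel[a, 1] += im * forces_buf[a, 1]
            vel[a, 2] += im * forces_buf[a, 2]
        done = step + 1
        if not math.isfinite(pos[0, 0]):
            return -done
        # displacement criterion for pair-list validity
        maxd2 = 0.0
        for a in range(n):
            dx = pos[a, 0] - ref_pos[a, 0]
            dy = pos[a, 1] - ref_pos[a, 1]
            dz = pos[a, 2] - ref_pos[a, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half2:
            return done
    return done


# ---------------------------------------------------------------------------
# reference all-pairs path (public energies and forces)
# ---------------------------------------------------------------------------


def _all_pairs_arrays(state: SystemConfiguration, ff: ForceField):
    tab = _build_tables(state.topology, ff, state.n_monomers)
    nbeads = state.n_beads
    # every unordered pair; exclusions removed
    i, j = np.triu_indices(nbeads, k=1)
    nb = state.topology.n_beads
    same = (i // nb) == (j // nb)
    keep = np.ones(len(i), dtype=bool)
    keep[same] = ~tab.excl_local[i[same] % nb, j[same] % nb]
    return tab, i[keep], j[keep]


def potential_energy(state: SystemConfiguration, ff: ForceField) -> dict[str, float]:
    """Decomposed potential energy, kJ/mol (all-pairs reference path).

    Raises on bead overlaps closer than 1e-6 nm, which would be a broken
    configuration for these soft-bead models.
    """
    tab, i, j = _all_pairs_arrays(state, ff)
    pos = state.positions
    box = state.box_length
    d = pos[i] - pos[j]
    d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    if len(r2) and np.min(r2) < 1e-12:
        raise ValueError("overlapping beads (distance < 1e-6 nm)")
    rc = ff.r_cutoff
    within = r2 < rc * rc
    r2w = r2[within]
    eps = tab.eps_table[tab.type_index[i[within]], tab.type_index[j[within]]]
    sr6 = (tab.sigma**2 / r2w) ** 3
    sr6_c = (tab.sigma / rc) ** 6
    shift = 4.0 * eps * (sr6_c**2 - sr6_c) if ff.shift_at_cutoff else 0.0
    e_lj = float(np.sum(4.0 * eps * (sr6**2 - sr6) - shift))
    e_coul = 0.0
    if ff.coulomb_on:
        qq = F_ELEC / ff.dielectric * tab.charges[i[within]] * tab.charges[j[within]]
        r = np.sqrt(r2w)
        cshift = qq / rc if ff.shift_at_cutoff else 0.0
        e_coul = float(np.sum(qq / r - cshift))

    e_bond = 0.0
    if len(tab.bonds):
        db = pos[tab.bonds[:, 0]] - pos[tab.bonds[:, 1]]
        db -= box * np.round(db / box)
        rb = np.linalg.norm(db, axis=1)
        e_bond = float(np.sum(0.5 * tab.bond_k * (rb - tab.bond_r0) ** 2))
    e_angle = 0.0
    if len(tab.angles):
        u = pos[tab.angles[:, 0]] - pos[tab.angles[:, 1]]
        v = pos[tab.angles[:, 2]] - pos[tab.angles[:, 1]]
        u -= box * np.round(u / box)
        v -= box * np.round(v / box)
        cu = np.linalg.norm(u, axis=1)
        cv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (cu * cv), -1.0, 1.0)
        theta = np.arccos(c)
        e_angle = float(np.sum(0.5 * tab.angle_k * (theta - tab.angle_t0) ** 2))
    total = e_bond + e_angle + e_lj + e_coul
    return {"bond": e_bond, "angle": e_angle, "lj": e_lj,
            "coulomb": e_coul, "total": total}


def forces(state: SystemConfiguration, ff: ForceField) -> np.ndarray:
    """Analytic forces -grad U, kJ mol^-1 nm^-1 (all-pairs reference path)."""
    tab, i, j = _all_pairs_arrays(state, ff)
    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    box = state.box_length
    rc = ff.r_cutoff
    eps = tab.eps_table[tab.type_index[i], tab.type_index[j]]
    qq = np.zeros(len(i))
    if ff.coulomb_on:
        qq = F_ELEC / ff.dielectric * tab.charges[i] * tab.charges[j]
    sr6_c = (tab.sigma / rc) ** 6
    lj_shift = 4.0 * eps * (sr6_c**2 - sr6_c)
    coul_shift = qq / rc
    out = np.zeros_like(pos)
    _kernel_forces(
        pos, box, i.astype(np.int64), j.astype(np.int64), eps, qq,
        lj_shift, coul_shift, rc * rc, tab.sigma,
        tab.bonds.astype(np.int64), tab.bond_k, tab.bond_r0,
        tab.angles.astype(np.int64), tab.angle_k, tab.angle_t0, out,
    )
    return out


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def _maxwell_velocities(masses: np.ndarray, temperature: float,
                        rng: np.random.Generator) -> np.ndarray:
    sd = np.sqrt(KB * temperature / masses)[:, None]
    return rng.normal(size=(len(masses), 3)) * sd


def kinetic_energy(masses: np.ndarray, vel: np.ndarray) -> float:
    return float(0.5 * np.sum(masses[:, None] * vel**2))


def instantaneous_temperature(masses: np.ndarray, vel: np.ndarray) -> float:
    return 2.0 * kinetic_energy(masses, vel) / (3.0 * len(masses) * KB)


class _Integrator:
    """Holds mutable integration state between sampling intervals."""

    def __init__(self, state: SystemConfiguration, ff: ForceField,
                 params: SimulationParams):
        self.ff = ff
        self.params = params
        self.topo = state.topology
        self.n_monomers = state.n_monomers
        self.monomer_index = state.monomer_index
        self.box = state.box_length
        self.tab = _build_tables(state.topology, ff, state.n_monomers)
        self.masses = np.tile(state.topology.masses, state.n_monomers)
        # private copies: integration must never mutate the caller's state
        self.pos = np.array(state.positions, dtype=np.float64, order="C")
        rng = np.random.default_rng(params.seed)
        if state.velocities is not None:
            self.vel = np.array(state.velocities, dtype=np.float64, order="C")
        else:
            self.vel = _maxwell_velocities(self.masses, params.temperature, rng)
        _nb_seed(params.seed % 2**31)
        self.step_count = 0
        self._rebuild()
        self.fbuf = np.zeros_like(self.pos)
        self._forces_now()

    def _rebuild(self) -> None:
        r_list = self.ff.r_cutoff + SKIN
        (self.pi, self.pj, self.eps, self.qq,
         self.lj_shift, self.coul_shift) = _pair_list(
            self.pos, self.box, r_list, self.tab, self.topo.n_beads, self.ff,
        )
        self.ref_pos = self.pos.copy()

    def _forces_now(self) -> None:
        _kernel_forces(
            self.pos, self.box, self.pi, self.pj, self.eps, self.qq,
            self.lj_shift, self.coul_shift,
            self.ff.r_cutoff**2, self.tab.sigma,
            self.tab.bonds.astype(np.int64), self.tab.bond_k, self.tab.bond_r0,
            self.tab.angles.astype(np.int64), self.tab.angle_k,
            self.tab.angle_t0, self.fbuf,
        )

    def advance(self, n_steps: int) -> None:
        p = self.params
        c1 = math.exp(-p.dt / p.tau_t)
        kT = KB * p.temperature
        remaining = n_steps
        while remaining > 0:
            done = _kernel_baoab(
                self.pos, self.vel, self.fbuf, self.masses, self.box,
                self.pi, self.pj, self.eps, self.qq,
                self.lj_shift, self.coul_shift,
                self.ff.r_cutoff**2, self.tab.sigma,
                self.tab.bonds.astype(np.int64), self.tab.bond_k,
                self.tab.bond_r0, self.tab.angles.astype(np.int64),
                self.tab.angle_k, self.tab.angle_t0,
                p.dt, c1, kT, self.ref_pos, (SKIN / 2.0) ** 2, remaining,
            )
            if done < 0:
                raise FloatingPointError(
                    f"non-finite coordinates at step {self.step_count - done}"
                )
            self.step_count += done
            remaining -= done
            if remaining > 0:
                self._rebuild()
                self._forces_now()

    def snapshot(self) -> SystemConfiguration:
        return SystemConfiguration(
            topology=self.topo, n_monomers=self.n_monomers,
            box_length=self.box, positions=self.pos.copy(),
            monomer_index=self.monomer_index.copy(),
            velocities=self.vel.copy(),
        )


def step_langevin(state: SystemConfiguration, ff: ForceField,
                  params: SimulationParams, n: int) -> SystemConfiguration:
    """Advance ``n`` Langevin (BAOAB) steps and return the new state.

    Velocities are drawn from Maxwell-Boltzmann at ``params.temperature``
    when the input state carries none.  Bit-reproducible for a fixed seed.
    """
    integ = _Integrator(state, ff, params)
    integ.advance(n)
    return integ.snapshot()


def run_simulation(config: SystemConfiguration, ff: ForceField,
                   params: SimulationParams, writer=None,
                   log_interval: int = 50) -> list[TrajectoryFrame]:
    """Run ``params.n_steps`` of dynamics, sampling every ``sample_interval``.

    ``writer``, when given, receives each :class:`TrajectoryFrame` through
    ``writer.write_frame(frame)`` as it is produced (streaming).  The frame
    list is returned as well; the final frame's state (with velocities) can
    seed a continuation run, which is the checkpoint mechanism.
    """
    steps_per_sample = max(1, int(round(params.sample_interval / params.dt)))
    integ = _Integrator(config, ff, params)
    frames: list[TrajectoryFrame] = []

    def emit(time_ps: float) -> None:
        frame = TrajectoryFrame(
            time=time_ps,
            positions=np.mod(integ.pos, integ.box),
            box_length=integ.box,
            velocities=integ.vel.copy(),
        )
        frames.append(frame)
        if writer is not None:
            try:
                writer.write_frame(frame)
            except Exception as exc:  # surface I/O failures with context
                raise IOError(
                    f"trajectory writer failed at frame {len(frames) - 1} "
                    f"(t = {time_ps} ps): {exc}"
                ) from exc

    emit(0.0)
    n_samples = params.n_steps // steps_per_sample
    leftover = params.n_steps - n_samples * steps_per_sample
    for s in range(n_samples):
        integ.advance(steps_per_sample)
        emit(integ.step_count * params.dt)
        if (s + 1) % log_interval == 0:
            T = instantaneous_temperature(integ.masses, integ.vel)
            log.info("step %d  t=%.1f ps  T=%.1f K",
                     integ.step_count, integ.step_count * params.dt, T)
    if leftover:
        integ.advance(leftover)
        emit(integ.step_count * params.dt)
    return frames
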