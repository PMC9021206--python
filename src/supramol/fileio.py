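"""Readers and writers: GROMACS-dialect GRO/ITP/TOP/MDP, HDF5 trajectories,
membership tables and analysis outputs.

The GROMACS exporters exist so the full-scale systems (500 monomers, tens
of microseconds) can be run externally with the ``sd`` integrator and the
resulting XTC/GRO trajectories ingested back for analysis; the built-in
engine covers reduced systems.  All units are GROMACS-native (nm, ps,
kJ/mol, amu, e), so exported files need no conversion.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .clustering import AssemblyPartition, MembershipTrajectory
from .engine import DEFAULT_DT, SimulationParams, TrajectoryFrame
from .models import (
    BeadRole,
    ForceField,
    HarmonicAngle,
    HarmonicBond,
    LJPair,
    MonomerTopology,
    SystemConfiguration,
)

__all__ = [
    "write_gromacs_inputs",
    "write_gro",
    "read_gro_frames",
    "parse_itp",
    "parse_top_forcefield",
    "write_membership_tsv",
    "read_membership_tsv",
    "H5TrajectoryWriter",
    "read_trajectory",
    "write_mechanism_json",
]

# short atom-type names per (species-family, role)
_ROLE_TYPE = {
    BeadRole.CORE: "C",
    BeadRole.SHIELD: "S",
    BeadRole.DIPOLE_PLUS: "DP",
    BeadRole.DIPOLE_MINUS: "DM",
    BeadRole.ARM_INNER: "AI",
    BeadRole.ARM: "A",
}

_TYPE_ROLE = {v: k for k, v in _ROLE_TYPE.items()}


def _res_name(species: str) -> str:
    return {"M": "M", "BTA": "BTA", "BTA_w": "BTAW"}[species]


def _atom_names(topo: MonomerTopology) -> list[str]:
    names = []
    seen: dict[str, int] = {}
    for b in topo.beads:
        base = _ROLE_TYPE[b.role]
        seen[base] = seen.get(base, 0) + 1
        names.append(f"{base}{seen[base]}")
    return names


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------


def write_gro(path: str, config: SystemConfiguration, title: str = "supramol",
              append: bool = False) -> None:
    """Fixed-format GRO snapshot (nm, 3 decimals, 1-based atom numbering)."""
    topo = config.topology
    names = _atom_names(topo)
    res = _res_name(topo.species)
    nb = topo.n_beads
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{title}\n{config.n_beads:5d}\n")
        for a in range(config.n_beads):
            mono = a // nb
            x, y, z = config.positions[a]
            fh.write(
                f"{(mono + 1) % 100000:5d}{res:<5s}{names[a % nb]:>5s}"
                f"{(a + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        L = config.box_length
        fh.write(f"{L:10.5f}{L:10.5f}{L:10.5f}\n")


def read_gro_frames(path: str, topology: MonomerTopology):
    """Iterate SystemConfiguration frames from a (possibly concatenated) GRO.

    Coordinates come back at the format's 3-decimal quantisation.  Raises a
    descriptive error on truncated or malformed frames.
    """
    nb = topology.n_beads
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: no frames (empty file)")
    k = 0
    frame_no = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            natoms = int(lines[k + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed frame header at line {k + 1} "
                f"(frame {frame_no})"
            ) from exc
        body = lines[k + 2: k + 2 + natoms]
        if len(body) < natoms or k + 2 + natoms >= len(lines):
            raise ValueError(
                f"{path}: truncated frame {frame_no} at line {k + 2} "
                f"(expected {natoms} atom records)"
            )
        pos = np.empty((natoms, 3))
        for a, ln in enumerate(body):
            try:
                pos[a] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: bad atom record at line {k + 3 + a}"
                ) from exc
        box_line = lines[k + 2 + natoms].split()
        box = float(box_line[0])
        n_monomers = natoms // nb
        yield SystemConfiguration(
            topology, n_monomers, box, pos,
            np.repeat(np.arange(n_monomers), nb),
        )
        frame_no += 1
        k += natoms + 3


# ---------------------------------------------------------------------------
# ITP / TOP / MDP
# ---------------------------------------------------------------------------


def _type_name(species: str, role: BeadRole) -> str:
    prefix = {"M": "M", "BTA": "B", "BTA_w": "W"}[species]
    return prefix + _ROLE_TYPE[role]


def write_itp(path: str, topo: MonomerTopology) -> None:
    names = _atom_names(topo)
    res = _res_name(topo.species)
    with open(path, "w") as fh:
        fh.write("[ moleculetype ]\n; name  nrexcl\n")
        fh.write(f"{res}  2\n\n[ atoms ]\n")
        fh.write(";  nr  type  resnr  residue  atom  cgnr  charge  mass\n")
        for b in topo.beads:
            fh.write(
                f"{b.bead_id + 1:5d}  {_type_name(topo.species, b.role):<4s}"
                f"  1  {res:<5s}  {names[b.bead_id]:<4s}  {b.bead_id + 1:4d}"
                f"  {b.charge:8.3f}  {b.mass:8.3f}\n"
            )
        fh.write("\n[ bonds ]\n;  i   j  func      b0          kb\n")
        for bd in topo.bonds:
            fh.write(
                f"{bd.i + 1:4d}{bd.j + 1:4d}    1  {bd.r0:10.5f}  {bd.k:12.3f}\n"
            )
        if topo.angles:
            fh.write("\n[ angles ]\n;  i   j   k  func    th0        cth\n")
            for an in topo.angles:
                fh.write(
                    f"{an.i + 1:4d}{an.j + 1:4d}{an.k + 1:4d}    1"
                    f"  {an.theta0:8.2f}  {an.k_theta:10.3f}\n"
                )


def parse_itp(path: str) -> tuple[list, list[HarmonicBond], list[HarmonicAngle]]:
    """Parse [atoms], [bonds], [angles] back out of an ITP file.

    Returns (atoms, bonds, angles) where atoms is a list of
    (type_name, charge, mass) tuples and indices are 0-based again.
    """
    section = None
    atoms: list[tuple[str, float, float]] = []
    bonds: list[HarmonicBond] = []
    angles: list[HarmonicAngle] = []
    with open(path) as fh:
        for raw_line in fh:
            line = raw_line.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            parts = line.split()
            if section == "atoms":
                atoms.append((parts[1], float(parts[6]), float(parts[7])))
            elif section == "bonds":
                i, j, func, b0, kb = parts[:5]
                bonds.append(HarmonicBond(int(i) - 1, int(j) - 1,
                                          float(kb), float(b0)))
            elif section == "angles":
                i, j, k, func, th0, cth = parts[:6]
                angles.append(HarmonicAngle(int(i) - 1, int(j) - 1, int(k) - 1,
                                            float(cth), float(th0)))
    return atoms, bonds, angles


def write_top(path: str, topo: MonomerTopology, ff: ForceField,
              n_monomers: int, itp_name: str) -> None:
    roles = sorted({b.role for b in topo.beads}, key=lambda r: r.value)
    sp = topo.species
    with open(path, "w") as fh:
        fh.write("[ defaults ]\n; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ\n")
        fh.write("  1      2         no        1.0     1.0\n\n[ atomtypes ]\n")
        fh.write("; name  mass  charge  ptype  sigma  epsilon\n")
        for r in roles:
            mass = next(b.mass for b in topo.beads if b.role == r)
            eps = ff.epsilon(r, r)
            sigma = ff.lj_pairs[0].sigma if ff.lj_pairs else 0.47
            fh.write(
                f"{_type_name(sp, r):<4s}  {mass:8.3f}  0.000  A"
                f"  {sigma:7.4f}  {eps:9.4f}\n"
            )
        fh.write("\n[ nonbond_params ]\n; i  j  func  sigma  epsilon\n")
        for a in range(len(roles)):
            for b in range(a, len(roles)):
                eps = ff.epsilon(roles[a], roles[b])
                sigma = ff.lj_pairs[0].sigma if ff.lj_pairs else 0.47
                fh.write(
                    f"{_type_name(sp, roles[a]):<4s} {_type_name(sp, roles[b]):<4s}"
                    f"  1  {sigma:7.4f}  {eps:9.4f}\n"
                )
        fh.write(f'\n#include "{itp_name}"\n')
        fh.write("\n[ system ]\nsupramolecular polymer system\n")
        fh.write(f"\n[ molecules ]\n{_res_name(sp)}  {n_monomers}\n")


def parse_top_forcefield(path: str, coulomb_on: bool | None = None,
                         r_cutoff: float = 1.1,
                         dielectric: float = 15.0) -> ForceField:
    """Rebuild a ForceField from the [nonbond_params] table of a TOP file."""
    pairs: list[LJPair] = []
    section = None
    has_charge_types = False
    with open(path) as fh:
        for raw_line in fh:
            line = raw_line.split(";")[0].strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            parts = line.split()
            if section == "nonbond_params":
                a, b = parts[0], parts[1]
                sigma, eps = float(parts[3]), float(parts[4])
                role_a = _TYPE_ROLE[a[1:]]
                role_b = _TYPE_ROLE[b[1:]]
                if eps > 0:
                    pairs.append(LJPair(role_a, role_b, eps, sigma))
            elif section == "atomtypes":
                if parts[0][1:] in ("DP", "DM"):
                    has_charge_types = True
    if coulomb_on is None:
        coulomb_on = has_charge_types
    return ForceField(pairs, coulomb_on=coulomb_on, r_cutoff=r_cutoff,
                      dielectric=dielectric)


def write_mdp(path: str, params: SimulationParams, species: str = "M",
              r_cutoff: float = 1.1, dielectric: float = 15.0,
              coulomb_on: bool = False) -> None:
    dt = params.dt if params.dt else DEFAULT_DT[species]
    nstout = max(1, int(round(params.sample_interval / dt)))
    lines = [
        "integrator               = sd",
        f"dt                       = {dt:.3f}",
        f"nsteps                   = {params.n_steps}",
        "tc-grps                  = System",
        f"tau-t                    = {params.tau_t}",
        f"ref-t                    = {params.temperature}",
        f"ld-seed                  = {params.seed}",
        "cutoff-scheme            = Verlet",
        f"rvdw                     = {r_cutoff}",
        "vdw-modifier             = Potential-shift",
        f"rcoulomb                 = {r_cutoff}",
        "coulombtype              = Cut-off",
        "coulomb-modifier         = Potential-shift",
        f"epsilon-r                = {dielectric if coulomb_on else 1}",
        "pbc                      = xyz",
        f"nstxout-compressed       = {nstout}",
        f"nstenergy                = {nstout}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gromacs_inputs(config: SystemConfiguration, ff: ForceField,
                         params: SimulationParams, outdir: str) -> dict[str, str]:
    """Export a runnable GROMACS input set: GRO + ITP + TOP + MDP.

    Returns the mapping of file kinds to paths.
    """
    os.makedirs(outdir, exist_ok=True)
    sp = config.topology.species
    stem = sp.lower()
    paths = {
        "gro": os.path.join(outdir, f"{stem}.gro"),
        "itp": os.path.join(outdir, f"{stem}.itp"),
        "top": os.path.join(outdir, f"{stem}.top"),
        "mdp": os.path.join(outdir, f"{stem}.mdp"),
    }
    write_gro(paths["gro"], config)
    write_itp(paths["itp"], config.topology)
    write_top(paths["top"], config.topology, ff, config.n_monomers,
              os.path.basename(paths["itp"]))
    write_mdp(paths["mdp"], params, species=sp, r_cutoff=ff.r_cutoff,
              dielectric=ff.dielectric, coulomb_on=ff.coulomb_on)
    return paths


# ---------------------------------------------------------------------------
# membership tables
# ---------------------------------------------------------------------------


def write_membership_tsv(path: str, membership: MembershipTrajectory,
                         header_comment: str = "") -> None:
    """Tabular per-frame partition: frame_time, monomer_id, assembly_id,
    assembly_size (contact edges are not serialised)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("frame_time\tmonomer_id\tassembly_id\tassembly_size\n")
        for frame in membership:
            sizes = frame.monomer_sizes
            for m in range(frame.n_monomers):
                fh.write(
                    f"{frame.frame_time:g}\t{m}\t{frame.labels[m]}\t{sizes[m]}\n"
                )


def read_membership_tsv(path: str) -> MembershipTrajectory:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no frames")
    frames = []
    for t, grp in df.groupby("frame_time", sort=True):
        grp = grp.sort_values("monomer_id")
        labels = grp["assembly_id"].to_numpy()
        sizes = np.bincount(labels)
        frames.append(AssemblyPartition(float(t), labels, sizes))
    return MembershipTrajectory(frames)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


class H5TrajectoryWriter:
    """Streaming HDF5 trajectory: float32 positions, time in ps."""

    def __init__(self, path: str, n_beads: int, box_length: float,
                 species: str = "M"):
        self._fh = h5py.File(path, "w")
        self._pos = self._fh.create_dataset(
            "positions", shape=(0, n_beads, 3), maxshape=(None, n_beads, 3),
            dtype="f4", chunks=(1, n_beads, 3),
        )
        self._time = self._fh.create_dataset(
            "time", shape=(0,), maxshape=(None,), dtype="f8"
        )
        self._fh.attrs["box_length"] = box_length
        self._fh.attrs["species"] = species

    def write_frame(self, frame: TrajectoryFrame) -> None:
        k = self._pos.shape[0]
        self._pos.resize(k + 1, axis=0)
        self._time.resize(k + 1, axis=0)
        self._pos[k] = frame.positions
        self._time[k] = frame.time

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _read_hdf5(path: str):
    with h5py.File(path, "r") as fh:
        box = float(fh.attrs["box_length"])
        times = fh["time"][:]
        if len(times) == 0:
            raise ValueError(f"{path}: no frames")
        for k in range(len(times)):
            yield TrajectoryFrame(
                time=float(times[k]),
                positions=fh["positions"][k].astype(np.float64),
                box_length=box,
            )


def _read_xtc(path: str, topology_gro: str):
    import MDAnalysis as mda

    u = mda.Universe(topology_gro, path)
    for ts in u.trajectory:
        yield TrajectoryFrame(
            time=float(ts.time),
            positions=ts.positions.astype(np.float64) / 10.0,  # A -> nm
            box_length=float(ts.dimensions[0]) / 10.0,
        )


def read_trajectory(path: str, fmt: str, topology: MonomerTopology | None = None,
                    topology_gro: str | None = None):
    """Streaming frame iterator for the supported trajectory layouts.

    ``fmt`` is one of ``gro_sequence``, ``xtc``, ``hdf5``,
    ``membership_tsv``.  XTC requires a GRO for the topology
    (``topology_gro``); gro_sequence requires the in-memory topology.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "gro_sequence":
        if topology is None:
            raise ValueError("gro_sequence needs the monomer topology")
        return read_gro_frames(path, topology)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "xtc":
        if topology_gro is None:
            raise ValueError("xtc needs a GRO topology file")
        return _read_xtc(path, topology_gro)
    if fmt == "membership_tsv":
        return read_membership_tsv(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def system_frames_from_trajectory(frames, topology: MonomerTopology):
    """Adapt TrajectoryFrame records into SystemConfiguration objects."""
    nb = topology.n_beads
    for fr in frames:
        n_monomers = fr.positions.shape[0] // nb
        yield SystemConfiguration(
            topology, n_monomers, fr.box_length, fr.positions,
            np.repeat(np.arange(n_monomers), nb),
        )


def write_mechanism_json(path: str, report) -> None:
    payload = {
        "classes": {
            c: {"count": report.counts[c], "pct": report.percentages[c]}
            for c in report.counts
        },
        "A": report.A,
        "E": report.E,
        "delta_tau_ps": report.delta_tau,
        "r_cut_nm": report.r_cut,
        "small_species_pct": report.small_species_pct,
        "large_fragment_pct": report.large_fragment_pct,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
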