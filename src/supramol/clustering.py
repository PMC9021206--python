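"""Frame-wise assembly detection and structural statistics.

Two monomers belong to the same assembly when their core beads lie within
``r_cut`` (0.6 nm by default, a radius that encloses the first peak of the
core-core radial distribution function; 0.7 nm is used as a robustness
check).  Assemblies are the connected components of the resulting
contact graph under minimum-image distances, so assemblies may wrap the
periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .models import MonomerTopology, SystemConfiguration

__all__ = [
    "ClusteringParams",
    "AssemblyPartition",
    "MembershipTrajectory",
    "detect_assemblies",
    "size_distribution",
    "coordination_number",
    "radial_distribution",
    "label_domains",
    "LOG2_BINS",
]

#: logarithmic size classes used for display: {1},{2},{3-4},...,{257-512}
LOG2_BINS: list[tuple[int, int]] = [(1, 1), (2, 2)] + [
    (2**k + 1, 2**(k + 1)) for k in range(1, 9)
]


def log2_bin_label(lo: int, hi: int) -> str:
    return str(lo) if lo == hi else f"{lo}-{hi}"


def log2_bin_index(size: int) -> int:
    for b, (lo, hi) in enumerate(LOG2_BINS):
        if lo <= size <= hi:
            return b
    raise ValueError(f"size {size} outside supported range 1..512")


@dataclass
class ClusteringParams:
    r_cut: float = 0.6       # nm, core-core contact radius
    alt_r_cut: float = 0.7   # nm, robustness re-analysis radius

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")


@dataclass
class AssemblyPartition:
    """One frame's partition of monomers into assemblies."""

    frame_time: float              # ps
    labels: np.ndarray             # (N,) contiguous assembly ids 0..K-1
    sizes: np.ndarray              # (K,) monomer counts per assembly
    edges: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    # (E, 2) core-core contact edges as monomer-index pairs, i < j

    @property
    def n_monomers(self) -> int:
        return len(self.labels)

    @property
    def n_assemblies(self) -> int:
        return len(self.sizes)

    @property
    def monomer_sizes(self) -> np.ndarray:
        """Size of the assembly each monomer belongs to, (N,)."""
        return self.sizes[self.labels]

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("assembly sizes must sum to the monomer count")


@dataclass
class MembershipTrajectory:
    """Sequence of partitions at a fixed sampling interval delta_tau."""

    frames: list[AssemblyPartition]

    def __post_init__(self) -> None:
        ns = {f.n_monomers for f in self.frames}
        if len(ns) > 1:
            raise ValueError(f"inconsistent monomer counts across frames: {ns}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        return self.frames[k]

    @property
    def n_monomers(self) -> int:
        return self.frames[0].n_monomers

    @property
    def delta_tau(self) -> float:
        """Sampling interval, ps (from the first two frame times)."""
        if len(self.frames) < 2:
            raise ValueError("need at least two frames for a sampling interval")
        return self.frames[1].frame_time - self.frames[0].frame_time

    @property
    def times(self) -> np.ndarray:
        return np.array([f.frame_time for f in self.frames])

    def mean_assembly_size(self) -> float:
        """Time-averaged mean assembly size N / <number of assemblies>."""
        return self.n_monomers / float(
            np.mean([f.n_assemblies for f in self.frames])
        )


def _contact_edges(core_pos: np.ndarray, box: float, r_cut: float) -> np.ndarray:
    wrapped = np.mod(core_pos, box)
    wrapped[wrapped >= box] -= box
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    return pairs if len(pairs) else np.zeros((0, 2), dtype=int)


def _core_positions(frame, topology: MonomerTopology | None) -> tuple[np.ndarray, float]:
    if isinstance(frame, SystemConfiguration):
        return frame.core_positions, frame.box_length
    raise TypeError(
        "frame must be a SystemConfiguration (or pass core positions through "
        "cluster_cores)"
    )


def cluster_cores(core_pos: np.ndarray, box: float, r_cut: float,
                  frame_time: float = 0.0) -> AssemblyPartition:
    """Partition core positions into contact-graph connected components."""
    n = len(core_pos)
    edges = _contact_edges(core_pos, box, r_cut)
    if len(edges):
        adj = csr_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        n_comp, raw_labels = connected_components(adj, directed=False)
    else:
        n_comp, raw_labels = n, np.arange(n)
    # relabel contiguously in order of first appearance
    order = {}
    labels = np.empty(n, dtype=int)
    for m, lab in enumerate(raw_labels):
        if lab not in order:
            order[lab] = len(order)
        labels[m] = order[lab]
    sizes = np.bincount(labels, minlength=len(order))
    return AssemblyPartition(frame_time, labels, sizes, edges)


def detect_assemblies(frame: SystemConfiguration,
                      topology: MonomerTopology | None = None,
                      params: ClusteringParams | None = None,
                      frame_time: float = 0.0) -> AssemblyPartition:
    """Assemblies of one frame: connected components of core-core contacts."""
    params = params or ClusteringParams()
    core_pos, box = _core_positions(frame, topology)
    return cluster_cores(core_pos, box, params.r_cut, frame_time)


def coordination_number(frame, topology: MonomerTopology | None = None,
                        params: ClusteringParams | None = None) -> float:
    """Mean number of core-core contacts per monomer, phi = 2 E / N.

    phi = 2 signals perfectly stacked infinite (or ring-closed) fibres;
    a finite linear n-mer gives 2(n-1)/n; a gas of singletons gives 0.
    """
    params = params or ClusteringParams()
    if isinstance(frame, AssemblyPartition):
        return 2.0 * len(frame.edges) / frame.n_monomers
    core_pos, box = _core_positions(frame, topology)
    edges = _contact_edges(core_pos, box, params.r_cut)
    return 2.0 * len(edges) / len(core_pos)


def size_distribution(membership: MembershipTrajectory | list[AssemblyPartition],
                      grouping: str = "log2") -> pd.DataFrame:
    """Frame-averaged assembly-size histogram.

    Returns one row per occupied size class with two normalisations:
    ``monomer_pct`` (percentage of monomers residing in that class, i.e.
    mass-weighted) and ``assembly_pct`` (percentage over the average number
    of assemblies).  ``grouping`` is ``log2`` (classes {1},{2},{3-4},...,
    {257-512}), ``linear`` or ``none`` (exact sizes).
    """
    frames = list(membership)
    if not frames:
        raise ValueError("empty trajectory")
    if grouping not in ("log2", "linear", "none"):
        raise ValueError(f"unknown grouping {grouping!r}")
    n_mono = frames[0].n_monomers
    max_size = max(int(f.sizes.max()) for f in frames)

    if grouping == "log2":
        nbins = log2_bin_index(max_size) + 1
        labels = [log2_bin_label(*LOG2_BINS[b]) for b in range(nbins)]
        def bin_of(s): return log2_bin_index(s)
    else:  # linear and none coincide for integer sizes
        nbins = max_size
        labels = [str(s) for s in range(1, max_size + 1)]
        def bin_of(s): return s - 1

    mono_mass = np.zeros(nbins)
    asm_count = np.zeros(nbins)
    for f in frames:
        for s, c in zip(*np.unique(f.sizes, return_counts=True)):
            b = bin_of(int(s))
            asm_count[b] += c
            mono_mass[b] += c * int(s)
    mono_pct = 100.0 * mono_mass / (n_mono * len(frames))
    asm_pct = 100.0 * asm_count / asm_count.sum()
    return pd.DataFrame(
        {"size_class": labels, "monomer_pct": mono_pct, "assembly_pct": asm_pct}
    )


def radial_distribution(trajectory, topology: MonomerTopology | None = None,
                        r_max: float = 2.0, dr: float = 0.01) -> pd.DataFrame:
    """Core-core pair correlation g(r) over a sequence of frames.

    Normalised by the ideal-gas shell count in the periodic box, so a
    uniform gas gives g(r) = 1.  ``r_max`` must not exceed half the box.
    """
    frames = list(trajectory)
    if not frames:
        raise ValueError("empty trajectory")
    nbins = int(np.ceil(r_max / dr))
    hist = np.zeros(nbins)
    n = None
    for frame in frames:
        core_pos, box = _core_positions(frame, topology)
        if r_max > box / 2.0:
            raise ValueError(f"r_max {r_max} exceeds half the box {box / 2.0}")
        n = len(core_pos)
        wrapped = np.mod(core_pos, box)
        wrapped[wrapped >= box] -= box
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs):
            d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=1)
            h, _ = np.histogram(r, bins=nbins, range=(0.0, nbins * dr))
            hist += h
    edges = np.arange(nbins + 1) * dr
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_pairs = n * (n - 1) / 2.0 / box**3   # pair density of the ideal gas
    ideal = rho_pairs * shell_vol * len(frames)
    g = np.divide(hist, ideal, out=np.zeros(nbins), where=ideal > 0)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"r": r_mid, "g": g})


def label_domains(frame, topology: MonomerTopology | None = None,
                  params: ClusteringParams | None = None,
                  partition: AssemblyPartition | None = None) -> np.ndarray:
    """Per-monomer structural domain label: tip / bulk_ordered / bulk_defect.

    Based on contact degree in the core-core graph: degree 1 (and free
    monomers) are fibre tips, degree 2 is ordered fibre bulk, degree >= 3 is
    a branching defect.  A degree-1 monomer attached to a branch point is a
    dangling defect rather than a true tip and is labelled bulk_defect.
    """
    params = params or ClusteringParams()
    if partition is None:
        partition = detect_assemblies(frame, topology, params)
    n = partition.n_monomers
    deg = np.zeros(n, dtype=int)
    for a, b in partition.edges:
        deg[a] += 1
        deg[b] += 1
    labels = np.empty(n, dtype=object)
    labels[deg <= 1] = "tip"
    labels[deg == 2] = "bulk_ordered"
    labels[deg >= 3] = "bulk_defect"
    # degree-1 monomer hanging off a branch point
    for a, b in partition.edges:
        if deg[a] == 1 and deg[b] >= 3:
            labels[a] = "bulk_defect"
        if deg[b] == 1 and deg[a] >= 3:
            labels[b] = "bulk_defect"
    return labels
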