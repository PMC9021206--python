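"""Ground-truth generators for testing the analysis pipeline without MD.

Two kinds of fixtures:

* geometric configurations with known cluster structure (ideal straight
  fibres, ring-closed fibres, dispersed gases, branched defect clusters);
* stochastic aggregation-fragmentation membership trajectories produced by
  an exact Gillespie kinetic Monte Carlo simulation with a full event log,
  emulating the equilibrium exchange dynamics of a supramolecular system.

The KMC state is a set of linear chains (ordered monomer lists).  A merge
joins two chains end-to-end (one new internal bond); a fragmentation breaks
one internal bond chosen uniformly.  With a constant merge kernel and a
per-bond fragmentation rate this process satisfies detailed balance on the
space of chain partitions and relaxes to a nontrivial stationary cluster
size distribution, which makes it a faithful desk-scale stand-in for the
equilibrium exchange the transition-matrix analysis is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .clustering import AssemblyPartition, MembershipTrajectory
from .models import (
    MonomerTopology,
    SystemConfiguration,
    build_monomer,
    build_random_config,
)

__all__ = ["KMCParams", "EventLog", "run_kmc", "make_fixture"]


@dataclass
class KMCParams:
    n_monomers: int = 200
    k_merge: float = 1.0      # rate per cluster pair (times merge_kernel)
    k_frag: float = 0.05      # rate per internal chain bond
    t_end: float = 100.0      # same arbitrary time unit as the rates
    sample_dt: float = 0.5
    seed: int = 0
    merge_kernel: Callable[[int, int], float] | None = None  # multiplier K(n1,n2)
    frag_kernel: Callable[[int], float] | None = None  # bonds-at-risk per size-n
    initial_sizes: list[int] | None = None  # default: all singletons

    def __post_init__(self) -> None:
        if self.k_merge < 0 or self.k_frag < 0:
            raise ValueError("rates must be non-negative")
        if self.initial_sizes is not None and sum(self.initial_sizes) != self.n_monomers:
            raise ValueError("initial_sizes must sum to n_monomers")


@dataclass
class EventLog:
    """Chronological record of every merge/fragmentation event."""

    times: list[float] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)      # "merge" | "fragment"
    p1: list[int] = field(default_factory=list)         # smaller partner size
    p2: list[int] = field(default_factory=list)         # larger partner size
    result: list[int] = field(default_factory=list)     # merged / fragmented size

    def add(self, t: float, kind: str, a: int, b: int, result: int) -> None:
        assert a + b == result
        self.times.append(t)
        self.kinds.append(kind)
        self.p1.append(min(a, b))
        self.p2.append(max(a, b))
        self.result.append(result)

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "kind": self.kinds, "p1": self.p1,
             "p2": self.p2, "result": self.result}
        )

    def counts_per_interval(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(merges, fragments) falling in each (grid[k-1], grid[k]] interval."""
        t = np.asarray(self.times)
        kind_merge = np.array([k == "merge" for k in self.kinds])
        b = np.zeros(len(grid) - 1, dtype=int)
        u = np.zeros(len(grid) - 1, dtype=int)
        idx = np.searchsorted(grid, t, side="left") - 1
        for e, k in enumerate(idx):
            if 0 <= k < len(b):
                if kind_merge[e]:
                    b[k] += 1
                else:
                    u[k] += 1
        return b, u


def _partition_from_chains(chains: list[list[int]], n: int,
                           t: float) -> AssemblyPartition:
    labels = np.empty(n, dtype=int)
    sizes = np.empty(len(chains), dtype=int)
    edges = []
    for c, chain in enumerate(chains):
        sizes[c] = len(chain)
        for m in chain:
            labels[m] = c
        for a, b in zip(chain[:-1], chain[1:]):
            edges.append((min(a, b), max(a, b)))
    edges_arr = (np.array(sorted(edges), dtype=int)
                 if edges else np.zeros((0, 2), dtype=int))
    return AssemblyPartition(t, labels, sizes, edges_arr)


def run_kmc(params: KMCParams) -> tuple[MembershipTrajectory, EventLog]:
    """Exact stochastic aggregation-fragmentation trajectory.

    Returns the membership trajectory sampled on the ``sample_dt`` grid
    (with chain-adjacency contact edges) and the complete event log.  Total
    monomer count is conserved by every event.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_monomers
    if params.initial_sizes is None:
        chains: list[list[int]] = [[m] for m in range(n)]
    else:
        chains = []
        m = 0
        for s in params.initial_sizes:
            chains.append(list(range(m, m + s)))
            m += s
    log = EventLog()
    frames = [_partition_from_chains(chains, n, 0.0)]
    grid = np.arange(1, int(np.floor(params.t_end / params.sample_dt)) + 1)
    grid_times = grid * params.sample_dt
    next_sample = 0
    t = 0.0

    K = params.merge_kernel
    G = params.frag_kernel
    while True:
        sizes = [len(c) for c in chains]
        nc = len(chains)
        if K is None:
            merge_total = params.k_merge * nc * (nc - 1) / 2.0
        else:
            pair_rates = np.array(
                [params.k_merge * K(sizes[a], sizes[b])
                 for a in range(nc) for b in range(a + 1, nc)]
            )
            merge_total = float(pair_rates.sum()) if len(pair_rates) else 0.0
        if G is None:
            bonds = np.array([s - 1 for s in sizes], dtype=float)
        else:
            bonds = np.array([G(s) for s in sizes], dtype=float)
        frag_rates = params.k_frag * bonds
        frag_total = float(frag_rates.sum())
        total = merge_total + frag_total
        if total <= 0.0:
            # absorbing state; emit remaining samples and stop
            import warnings

            warnings.warn(
                f"KMC reached zero total rate at t = {t:.3g} < t_end "
                f"{params.t_end}; trajectory is constant from here",
                stacklevel=2,
            )
            while next_sample < len(grid_times):
                frames.append(
                    _partition_from_chains(chains, n, grid_times[next_sample])
                )
                next_sample += 1
            break
        t_next = t + rng.exponential(1.0 / total)
        while next_sample < len(grid_times) and grid_times[next_sample] < t_next:
            frames.append(_partition_from_chains(chains, n, grid_times[next_sample]))
            next_sample += 1
        if t_next > params.t_end:
            break
        t = t_next
        if rng.uniform() * total < merge_total:
            if K is None:
                a, b = rng.choice(nc, size=2, replace=False)
            else:
                pick = rng.uniform() * merge_total
                acc = 0.0
                flat = 0
                a = b = 0
                stop = False
                for aa in range(nc):
                    for bb in range(aa + 1, nc):
                        acc += pair_rates[flat]
                        flat += 1
                        if acc >= pick:
                            a, b = aa, bb
                            stop = True
                            break
                    if stop:
                        break
            ca, cb = chains[a], chains[b]
            log.add(t, "merge", len(ca), len(cb), len(ca) + len(cb))
            # random end-to-end join orientation
            if rng.uniform() < 0.5:
                ca = ca[::-1]
            if rng.uniform() < 0.5:
                cb = cb[::-1]
            merged = ca + cb
            chains = [c for k, c in enumerate(chains) if k not in (a, b)]
            chains.append(merged)
        else:
            pick = rng.uniform() * frag_total
            c = int(np.searchsorted(np.cumsum(frag_rates), pick, side="left"))
            chain = chains.pop(c)
            cut = int(rng.integers(1, len(chain)))  # internal bond index
            left, right = chain[:cut], chain[cut:]
            log.add(t, "fragment", len(left), len(right), len(chain))
            chains.extend([left, right])
    return MembershipTrajectory(frames), log


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------


def _rotation_z_to(v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the z axis onto unit vector v."""
    z = np.array([0.0, 0.0, 1.0])
    v = v / np.linalg.norm(v)
    c = float(np.dot(z, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def make_fixture(kind: str, n: int, spacing: float = 0.5,
                 box: float = 22.056, topology: MonomerTopology | None = None,
                 min_separation: float = 1.2, seed: int = 0) -> SystemConfiguration:
    """Deterministic geometries with known cluster structure.

    ``ideal_fibre``  — straight n-mer stack (phi = 2(n-1)/n, two tips);
    ``ring_fibre``   — periodically closed stack (phi = 2, no tips);
    ``dispersed``    — random gas with pairwise min separation (singletons);
    ``branched``     — linear fibre with one side-branch (one degree-3 core).
    """
    topo = topology or build_monomer("M")
    nb = topo.n_beads
    if kind == "dispersed":
        return build_random_config(topo, n, box, min_separation, seed)

    if kind == "ideal_fibre":
        if (n - 1) * spacing >= box - spacing:
            raise ValueError("fibre does not fit the periodic box")
        centres = np.zeros((n, 3))
        centres[:, 2] = np.arange(n) * spacing
        centres += box / 2.0
        rots = None
    elif kind == "ring_fibre":
        radius = spacing / (2.0 * np.sin(np.pi / n))
        if 2.0 * radius >= box:
            raise ValueError("ring does not fit the periodic box")
        ang = 2.0 * np.pi * np.arange(n) / n
        centres = np.stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1
        ) + box / 2.0
        # monomer plane normal along the local ring tangent
        tangents = np.stack([-np.sin(ang), np.cos(ang), np.zeros(n)], axis=1)
        rots = [_rotation_z_to(tv) for tv in tangents]
    elif kind == "branched":
        if n < 4:
            raise ValueError("branched fixture needs at least 4 monomers")
        centres = np.zeros((n, 3))
        centres[: n - 1, 2] = np.arange(n - 1) * spacing
        mid = (n - 1) // 2
        centres[n - 1] = (spacing, 0.0, mid * spacing)  # side branch
        centres += box / 2.0
        rots = None
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    pos = np.empty((n * nb, 3))
    for m in range(n):
        g = topo.reference_geometry
        if rots is not None:
            g = g @ rots[m].T
        pos[m * nb:(m + 1) * nb] = g + centres[m]
    return SystemConfiguration(topo, n, box, pos, np.repeat(np.arange(n), nb))
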