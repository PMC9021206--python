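"""Transition-matrix analysis of monomer exchange between assemblies.

Every monomer is tracked across the membership trajectory with lag
``delta_tau`` (300 ps by default; 3 ns is the robustness lag).  The raw
transition matrix counts monomer moves from an assembly of size i (row) to
size j (column), diagonal included (persistence).  At equilibrium detailed
balance makes the raw matrix symmetric within sampling error; the
row-normalised probability matrix loses that symmetry.

Dividing the raw entries by the row index above the diagonal and by the
column index below it converts monomer counts into *assembly-level* binary
events (a merging fragment of size i contributes i monomer transitions),
producing the assembly transition matrix.  Binary events are then
classified by the sizes (p1 <= p2) of the two partner fragments against two
thresholds — A, the mean assembly size, and E = A/5:

    yellow  p1 < E,  p2 < A    small species joining/leaving small fibres
    green   p1 < E,  p2 >= A   small species joining/leaving large fibres
    red     E <= p1 < A        coalescence/fragmentation of medium fibres
    blue    p1 >= A            coalescence/fragmentation of large fibres

Grouping (i) = yellow + green + red (communication via small/medium
species) versus (ii) = blue (via large fragments) summarises the mechanism
of inter-assembly communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import (
    LOG2_BINS,
    AssemblyPartition,
    ClusteringParams,
    MembershipTrajectory,
    detect_assemblies,
    label_domains,
    log2_bin_index,
    log2_bin_label,
)
from .synthetic import EventLog

__all__ = [
    "TransitionAnalysisConfig",
    "TransitionMatrices",
    "MechanismReport",
    "monomer_transition_matrix",
    "probability_matrix",
    "assembly_transition_matrix",
    "classify_mechanisms",
    "localize_exchange",
    "interconnection_graph",
    "group_matrix",
]

CLASSES = ("yellow", "green", "red", "blue")


@dataclass
class TransitionAnalysisConfig:
    delta_tau: float = 300.0          # ps; 3000 ps for the robustness check
    grouping: str = "log2"            # display grouping only
    A: int | None = None              # defaults to round(mean assembly size)
    E: int | None = None              # defaults to max(2, round(A/5))

    def resolve_thresholds(
        self, membership: MembershipTrajectory | None = None
    ) -> tuple[int, int]:
        A = self.A
        if A is None:
            if membership is None:
                raise ValueError("A not set and no trajectory to infer it from")
            A = int(round(membership.mean_assembly_size()))
        E = self.E if self.E is not None else max(2, round(A / 5))
        if E >= A:
            raise ValueError(f"need E < A, got E={E}, A={A}")
        return A, E


@dataclass
class TransitionMatrices:
    raw: np.ndarray           # (S, S) monomer-transition counts, sizes 1..S
    probability: np.ndarray   # row-normalised raw; all-zero rows are NaN
    assembly: np.ndarray      # triangular-rescaled binary-event counts
    delta_tau: float
    sizes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            self.sizes = np.arange(1, self.raw.shape[0] + 1)


def monomer_transition_matrix(
    membership: MembershipTrajectory,
    config: TransitionAnalysisConfig | None = None,
) -> np.ndarray:
    """Raw monomer-transition counts raw[i-1, j-1] for sizes i -> j at lag
    delta_tau.  The lag must be a multiple of the trajectory sampling step;
    frames are strided accordingly."""
    config = config or TransitionAnalysisConfig(delta_tau=0.0)
    frames = list(membership)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    ns = {f.n_monomers for f in frames}
    if len(ns) != 1:
        raise ValueError(f"inconsistent monomer count across frames: {ns}")
    dt = membership.delta_tau
    if config.delta_tau and config.delta_tau > 0:
        stride = config.delta_tau / dt
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"delta_tau {config.delta_tau} is not a multiple of the "
                f"sampling interval {dt}"
            )
        stride = int(round(stride))
    else:
        stride = 1
    n = frames[0].n_monomers
    raw = np.zeros((n, n), dtype=np.int64)
    for k in range(len(frames) - stride):
        s_from = frames[k].monomer_sizes
        s_to = frames[k + stride].monomer_sizes
        np.add.at(raw, (s_from - 1, s_to - 1), 1)
    smax = int(max(np.max(np.nonzero(raw.sum(0) + raw.sum(1))), 0)) + 1
    return raw[:smax, :smax]


def probability_matrix(raw: np.ndarray) -> np.ndarray:
    """Row-stochastic transition probabilities; empty rows become NaN."""
    raw = np.asarray(raw, dtype=float)
    row_sums = raw.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = raw / row_sums
    prob[row_sums[:, 0] == 0] = np.nan
    return prob


def assembly_transition_matrix(raw: np.ndarray) -> np.ndarray:
    """Convert monomer counts into assembly-level binary-event counts.

    Entry (i, j) above the diagonal is divided by the row size i (a
    fragment of size i that merges contributes i monomer transitions) and
    below the diagonal by the column size j.  Diagonal untouched.  Valid
    under the binary-event assumption: each transition involves exactly two
    assemblies, which holds to good approximation at short lags.
    """
    raw = np.asarray(raw, dtype=float)
    s = raw.shape[0]
    sizes = np.arange(1, s + 1, dtype=float)
    out = raw.copy()
    iu = np.triu_indices(s, k=1)
    il = np.tril_indices(s, k=-1)
    out[iu] = raw[iu] / sizes[iu[0]]
    out[il] = raw[il] / sizes[il[1]]
    return out


def compute_transition_matrices(
    membership: MembershipTrajectory,
    config: TransitionAnalysisConfig | None = None,
) -> TransitionMatrices:
    """Raw, probability and assembly matrices in one pass."""
    config = config or TransitionAnalysisConfig(delta_tau=0.0)
    raw = monomer_transition_matrix(membership, config)
    return TransitionMatrices(
        raw=raw,
        probability=probability_matrix(raw),
        assembly=assembly_transition_matrix(raw),
        delta_tau=config.delta_tau if config.delta_tau else membership.delta_tau,
    )


def group_matrix(mat: np.ndarray, grouping: str = "log2") -> pd.DataFrame:
    """Aggregate a size-indexed matrix into display bins (log2 or linear)."""
    s = mat.shape[0]
    if grouping == "none":
        labels = [str(k) for k in range(1, s + 1)]
        return pd.DataFrame(mat, index=labels, columns=labels)
    if grouping == "linear":
        width = 10
        edges = list(range(0, s, width)) + [s]
        labels = [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
        idx = np.repeat(np.arange(len(labels)), np.diff(edges))
    elif grouping == "log2":
        nb = log2_bin_index(s) + 1
        labels = [log2_bin_label(*LOG2_BINS[b]) for b in range(nb)]
        idx = np.array([log2_bin_index(k) for k in range(1, s + 1)])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = np.zeros((len(labels), len(labels)))
    np.add.at(out, (idx[:, None], idx[None, :]), mat)
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class MechanismReport:
    counts: dict[str, float]       # per class, assembly-event counts
    percentages: dict[str, float]  # per class, % of off-diagonal events
    A: int
    E: int
    delta_tau: float | None = None
    r_cut: float | None = None

    @property
    def small_species_pct(self) -> float:
        """Grouping (i): communication via small/medium species."""
        return (self.percentages["yellow"] + self.percentages["green"]
                + self.percentages["red"])

    @property
    def large_fragment_pct(self) -> float:
        """Grouping (ii): communication via large coalescence/fragmentation."""
        return self.percentages["blue"]


def classify_event(p1: int, p2: int, A: int, E: int) -> str:
    """Class of one binary event from its partner fragment sizes p1 <= p2."""
    if p1 > p2:
        p1, p2 = p2, p1
    if p1 < E:
        return "yellow" if p2 < A else "green"
    return "red" if p1 < A else "blue"


def classify_mechanisms(
    source: np.ndarray | EventLog,
    config: TransitionAnalysisConfig | None = None,
    membership: MembershipTrajectory | None = None,
    A: int | None = None,
    E: int | None = None,
) -> MechanismReport:
    """Mechanism-of-communication statistics from binary exchange events.

    ``source`` is either an assembly transition matrix (off-diagonal
    entries are weighted binary events; an entry at (i, j) implies partner
    fragments of sizes min(i, j) and |i - j|) or an explicit
    :class:`~supramol.synthetic.EventLog` with exact partner sizes.
    Diagonal entries are persistence, not transitions, and are excluded.
    """
    config = config or TransitionAnalysisConfig()
    if A is None or E is None:
        if config.A is None and membership is None and not isinstance(source, EventLog):
            raise ValueError("thresholds A, E must be set or inferable")
        if config.A is not None or membership is not None:
            A_r, E_r = config.resolve_thresholds(membership)
        else:
            # infer from the event log's mean result size
            sizes = np.asarray(source.result)
            A_r = max(2, int(round(float(np.mean(sizes)))))
            E_r = max(2, round(A_r / 5))
        A = A if A is not None else A_r
        E = E if E is not None else E_r
    if E >= A:
        raise ValueError(f"need E < A, got E={E}, A={A}")

    counts = {c: 0.0 for c in CLASSES}
    if isinstance(source, EventLog):
        if len(source) == 0:
            raise ValueError("no events to classify")
        for p1, p2 in zip(source.p1, source.p2):
            counts[classify_event(p1, p2, A, E)] += 1.0
    else:
        mat = np.asarray(source, dtype=float)
        s = mat.shape[0]
        i_idx, j_idx = np.nonzero(mat)
        off = i_idx != j_idx
        if not np.any(off):
            raise ValueError("no off-diagonal events to classify")
        for i, j in zip(i_idx[off], j_idx[off]):
            si, sj = i + 1, j + 1
            # partner fragments of the binary event: the smaller assembly
            # and its complement within the larger one
            small, large = min(si, sj), max(si, sj)
            p1, p2 = sorted((small, large - small))
            counts[classify_event(p1, p2, A, E)] += mat[i, j]
    total = sum(counts.values())
    pct = {c: 100.0 * v / total for c, v in counts.items()}
    return MechanismReport(counts=counts, percentages=pct, A=A, E=E,
                           delta_tau=config.delta_tau)


def interconnection_graph(assembly_matrix: np.ndarray,
                          grouping: str = "log2") -> nx.DiGraph:
    """Weighted directed graph of assembly-event counts between size classes."""
    df = group_matrix(np.asarray(assembly_matrix, dtype=float), grouping)
    g = nx.DiGraph()
    labels = list(df.index)
    g.add_nodes_from(labels)
    vals = df.to_numpy()
    for a, la in enumerate(labels):
        for b, lb in enumerate(labels):
            if a != b and vals[a, b] > 0:
                g.add_edge(la, lb, weight=float(vals[a, b]))
    return g


def localize_exchange(
    membership: MembershipTrajectory,
    frames: list,
    topology=None,
    params: ClusteringParams | None = None,
) -> dict[str, float]:
    """Attribute each contact-level event to the fibre domain it occurred at.

    For an unbinding event (contact edge lost between consecutive frames)
    the leaving monomer is the endpoint ending up in the smaller cluster,
    and the event inherits that monomer's domain label — tip or bulk — in
    the frame *before* the event (a monomer detaching from a fibre end was
    a degree-1 tip; one extracted mid-fibre was bulk).  Binding events use
    the arriving monomer's label in the frame *after*.  Returns the
    fractions of all events attributed to tips and to the fibre bulk.
    """
    params = params or ClusteringParams()
    parts = list(membership)
    if len(parts) != len(frames):
        raise ValueError("membership and geometric frames must align")
    if len(parts) < 2:
        raise ValueError("need at least two frames")
    domain = [
        label_domains(fr, topology, params, partition=pt)
        for fr, pt in zip(frames, parts)
    ]

    def site_kind(lab: str) -> str:
        return "tip" if lab == "tip" else "bulk"

    tallies = {"bind_tip": 0, "bind_bulk": 0, "unbind_tip": 0, "unbind_bulk": 0}
    for k in range(1, len(parts)):
        prev, cur = parts[k - 1], parts[k]
        prev_edges = {(int(a), int(b)) for a, b in prev.edges}
        cur_edges = {(int(a), int(b)) for a, b in cur.edges}
        for a, b in prev_edges - cur_edges:  # unbinding
            # leaving monomer = endpoint in the smaller cluster afterwards
            leave = a if cur.monomer_sizes[a] <= cur.monomer_sizes[b] else b
            tallies["unbind_" + site_kind(domain[k - 1][leave])] += 1
        for a, b in cur_edges - prev_edges:  # binding
            arrive = a if prev.monomer_sizes[a] <= prev.monomer_sizes[b] else b
            tallies["bind_" + site_kind(domain[k][arrive])] += 1
    n_bind = tallies["bind_tip"] + tallies["bind_bulk"]
    n_unbind = tallies["unbind_tip"] + tallies["unbind_bulk"]
    n_all = n_bind + n_unbind
    if n_all == 0:
        raise ValueError("no binding/unbinding events found")
    return {
        "tip_fraction": (tallies["bind_tip"] + tallies["unbind_tip"]) / n_all,
        "bulk_fraction": (tallies["bind_bulk"] + tallies["unbind_bulk"]) / n_all,
        "n_binding": n_bind,
        "n_unbinding": n_unbind,
    }
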