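"""Binding/unbinding event detection and cumulative traffic/flux.

Between consecutive sampled frames (lag delta_tau), binding events ``b(t)``
and unbinding events ``u(t)`` are counted; the cumulative molecular traffic
and flux per monomer are then

    T(tau) = sum_{t <= tau} (b(t) + u(t)) / N
    F(tau) = sum_{t <= tau} (b(t) - u(t)) / N

At dynamic equilibrium the flux plateaus (binding balances unbinding) while
the traffic keeps growing — the signature of assemblies that are stable in
size yet continuously exchange material.

Events can be defined two ways (both exposed for sensitivity analysis):

``contact_pairs`` (default)
    b = core-core contact edges present now but not in the previous frame,
    u = edges lost.  Symmetric, frame-local and independent of any cluster
    relabelling heuristic.

``membership_change``
    assemblies of consecutive frames are matched by maximal member overlap;
    b counts monomers their current assembly gained, u counts monomers
    their previous assembly lost.

Multiple make/break of the same contact within one sampling interval is
invisible by construction, so delta_tau should be chosen small enough that
assemblies rarely undergo several events per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import AssemblyPartition, MembershipTrajectory

__all__ = ["EventSeries", "TrafficFluxSeries", "detect_events", "traffic_flux"]


@dataclass
class EventSeries:
    times: np.ndarray   # ps, right edge of each interval
    b: np.ndarray       # binding events per interval
    u: np.ndarray       # unbinding events per interval

    def __post_init__(self) -> None:
        if np.any(self.b < 0) or np.any(self.u < 0):
            raise ValueError("event counts must be non-negative")


@dataclass
class TrafficFluxSeries:
    times: np.ndarray
    traffic: np.ndarray   # T(tau), cumulative events per monomer
    flux: np.ndarray      # F(tau), cumulative net events per monomer
    n_monomers: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "T": self.traffic, "F": self.flux}
        )


def _edge_set(frame: AssemblyPartition) -> set[tuple[int, int]]:
    return {(int(a), int(b)) for a, b in frame.edges}


def _membership_events(prev: AssemblyPartition,
                       cur: AssemblyPartition) -> tuple[int, int]:
    # match assemblies across the lag by maximal member overlap
    members_prev = [set(np.flatnonzero(prev.labels == k))
                    for k in range(prev.n_assemblies)]
    members_cur = [set(np.flatnonzero(cur.labels == k))
                   for k in range(cur.n_assemblies)]

    def best_match(src: set[int], pool: list[set[int]]) -> set[int]:
        overlaps = [len(src & other) for other in pool]
        return pool[int(np.argmax(overlaps))] if pool else set()

    b = u = 0
    for m in range(prev.n_monomers):
        cur_asm = members_cur[cur.labels[m]]
        prev_asm = members_prev[prev.labels[m]]
        if m not in best_match(cur_asm, members_prev):
            b += 1
        if m not in best_match(prev_asm, members_cur):
            u += 1
    return b, u


def detect_events(membership: MembershipTrajectory,
                  mode: str = "contact_pairs") -> EventSeries:
    """Per-interval binding/unbinding counts between consecutive frames."""
    frames = list(membership)
    if len(frames) < 2:
        raise ValueError("event detection needs at least two frames")
    if mode not in ("contact_pairs", "membership_change"):
        raise ValueError(f"unknown event mode {mode!r}")
    times = np.array([f.frame_time for f in frames[1:]])
    b = np.zeros(len(frames) - 1, dtype=int)
    u = np.zeros(len(frames) - 1, dtype=int)
    if mode == "contact_pairs":
        prev_edges = _edge_set(frames[0])
        for k, frame in enumerate(frames[1:]):
            cur_edges = _edge_set(frame)
            b[k] = len(cur_edges - prev_edges)
            u[k] = len(prev_edges - cur_edges)
            prev_edges = cur_edges
    else:
        for k in range(1, len(frames)):
            b[k - 1], u[k - 1] = _membership_events(frames[k - 1], frames[k])
    return EventSeries(times, b, u)


def traffic_flux(events: EventSeries, n_monomers: int) -> TrafficFluxSeries:
    """Cumulative traffic T(tau) and flux F(tau), events per monomer."""
    if n_monomers <= 0:
        raise ValueError("n_monomers must be positive")
    times = np.concatenate([[0.0], events.times])
    T = np.concatenate([[0.0], np.cumsum(events.b + events.u) / n_monomers])
    F = np.concatenate([[0.0], np.cumsum(events.b - events.u) / n_monomers])
    return TrafficFluxSeries(times, T, F, n_monomers)
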