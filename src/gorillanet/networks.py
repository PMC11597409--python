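"""Proximity association networks and strength scores.

For one group and one time window (half-open, [start, end)) the network is
built from the 5 m proximity scans:

* ``N_a``  - number of scans with female ``a`` as the focal animal;
* ``N_ab`` - number of scans, from either member's focals, in which the two
  females were within 5 m of each other;
* dyadic strength = ``N_ab / (N_a + N_b)`` (simple ratio, in [0, 1]);
* node strength  = weighted degree, the sum of an individual's dyadic
  strengths (default), or optionally the raw per-capita neighbour rate.

Symmetry of the dyadic index is exact by construction; it accrues from both
members' focal scans.
"""
from __future__ import annotations

import datetime as dt
import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import Demography, as_date

log = logging.getLogger("gorillanet")

__all__ = ["WindowSpec", "AssociationNetwork", "calendar_window",
           "build_network", "dyadic_strength", "node_strength",
           "networks_frame", "node_strength_frame"]


@dataclass(frozen=True)
class WindowSpec:
    """A half-open observation window [window_start, window_end) of one group."""

    group_id: str
    window_start: dt.date
    window_end: dt.date
    anchor: str = "calendar_year"        # or "event_offset"
    offset_label: int | None = None

    def __post_init__(self):
        if self.window_end <= self.window_start:
            raise ValueError("window_end must be after window_start")
        if self.anchor == "event_offset":
            if (self.window_end - self.window_start).days != 365:
                raise ValueError("event windows must span exactly 365 days")
            if self.offset_label is None:
                raise ValueError("event windows need an offset_label")

    def contains(self, d) -> bool:
        return self.window_start <= as_date(d) < self.window_end


def calendar_window(group_id: str, year: int) -> WindowSpec:
    return WindowSpec(group_id, dt.date(year, 1, 1), dt.date(year + 1, 1, 1),
                      anchor="calendar_year")


def dyadic_strength(n_ab: int, n_a: int, n_b: int) -> float:
    """Simple-ratio association index N_ab / (N_a + N_b)."""
    denom = n_a + n_b
    if denom == 0:
        raise ZeroDivisionError("dyadic strength undefined: N_a + N_b = 0")
    return n_ab / denom


@dataclass
class AssociationNetwork:
    """One group x window proximity network."""

    window: WindowSpec
    nodes: list[str]
    focal_counts: dict[str, int]                       # N_a
    joint_counts: dict[frozenset, int]                 # N_ab per unordered dyad
    node_strength_mode: str = "weighted_degree"
    dropped_dyads: list[frozenset] = field(default_factory=list)
    neighbor_tallies: dict[str, int] = field(default_factory=dict)

    def dyads(self) -> list[frozenset]:
        return [frozenset(p) for p in itertools.combinations(sorted(self.nodes), 2)]

    def strength(self, a: str, b: str) -> float:
        d = frozenset((a, b))
        if d in self.dropped_dyads:
            return float("nan")
        return dyadic_strength(self.joint_counts.get(d, 0),
                               self.focal_counts.get(a, 0),
                               self.focal_counts.get(b, 0))

    def node_strength(self, iid: str) -> float:
        if iid not in self.nodes:
            raise KeyError(iid)
        if self.node_strength_mode == "raw_rate":
            n = self.focal_counts.get(iid, 0)
            return self.neighbor_tallies.get(iid, 0) / n if n else float("nan")
        s = 0.0
        for other in self.nodes:
            if other == iid:
                continue
            v = self.strength(iid, other)
            if v == v:                               # skip NaN (dropped dyads)
                s += v
        return s


def build_network(scans: pd.DataFrame, demography: Demography,
                  window: WindowSpec, node_strength: str = "weighted_degree",
                  min_focals: int = 0) -> AssociationNetwork:
    """Tally focal and joint counts for one group x window.

    Nodes are the adult females resident in the group for at least one day
    of the window (optionally also requiring ``min_focals`` focal scans).
    A scan contributes 1 to ``N_focal`` and, for each neighbour ``b`` within
    5 m, 1 to ``N_{focal,b}``.  Dyads with ``N_a + N_b = 0`` are dropped
    with a warning.
    """
    nodes = demography.residents_in_window(window.group_id, window.window_start,
                                           window.window_end, sex="female",
                                           adult_only=True)
    in_win = scans[(scans["group_id"] == window.group_id)
                   & (scans["date"] >= window.window_start)
                   & (scans["date"] < window.window_end)]
    if len(in_win) == 0:
        log.warning("no scans for %s in [%s, %s)", window.group_id,
                    window.window_start, window.window_end)
    focal_counts: dict[str, int] = {n: 0 for n in nodes}
    joint: dict[frozenset, int] = {}
    tallies: dict[str, int] = {n: 0 for n in nodes}
    node_set = set(nodes)
    for row in in_win.itertuples(index=False):
        f = row.focal_id
        if f not in node_set:
            continue
        focal_counts[f] += 1
        for b in row.neighbors_5m:
            if b in node_set:
                joint[frozenset((f, b))] = joint.get(frozenset((f, b)), 0) + 1
                tallies[f] += 1
                tallies[b] += 1
    if min_focals > 0:
        nodes = [n for n in nodes if focal_counts[n] >= min_focals]
        node_set = set(nodes)
        joint = {d: v for d, v in joint.items() if d <= node_set}
    net = AssociationNetwork(window, nodes, focal_counts, joint,
                             node_strength_mode=node_strength,
                             neighbor_tallies=tallies)
    for d in net.dyads():
        a, b = sorted(d)
        if focal_counts.get(a, 0) + focal_counts.get(b, 0) == 0:
            net.dropped_dyads.append(d)
            log.warning("dyad (%s, %s) dropped: no focal scans in window", a, b)
    return net


def node_strength(network: AssociationNetwork, iid: str) -> float:
    """Node (individual) strength of `iid` in `network`."""
    return network.node_strength(iid)


# ---------------------------------------------------------------------------
# long-format output tables


def networks_frame(networks: list[AssociationNetwork]) -> pd.DataFrame:
    """Long dyadic table: one row per dyad per window."""
    rows = []
    for net in networks:
        w = net.window
        for d in net.dyads():
            a, b = sorted(d)
            n_ab = net.joint_counts.get(d, 0)
            n_a, n_b = net.focal_counts.get(a, 0), net.focal_counts.get(b, 0)
            s = net.strength(a, b)
            rows.append((w.group_id, w.window_start, w.window_end,
                         w.anchor, w.offset_label, a, b, n_ab, n_a, n_b, s))
    return pd.DataFrame(rows, columns=["group_id", "window_start", "window_end",
                                       "anchor", "offset_label", "id1", "id2",
                                       "N_ab", "N_a", "N_b", "strength"])


def node_strength_frame(networks: list[AssociationNetwork]) -> pd.DataFrame:
    rows = []
    for net in networks:
        w = net.window
        for n in net.nodes:
            rows.append((w.group_id, w.window_start, w.window_end, w.anchor,
                         w.offset_label, n, net.focal_counts.get(n, 0),
                         net.node_strength(n)))
    return pd.DataFrame(rows, columns=["group_id", "window_start", "window_end",
                                       "anchor", "offset_label", "id", "N_focal",
                                       "strength"])
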