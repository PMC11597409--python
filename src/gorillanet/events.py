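"""Time-matched event-centred association windows.

Instead of calendar years ending 31 December, association networks are
recomputed in 365-day windows anchored on the date of a demographic event:

* ``second_birth`` - both members of a dyad have dependent infants; the
  anchor is the birth date of the later infant; offsets -2..+2;
* ``immigration``  - an adult female joins the group; the anchor is her
  entry date; offsets 0..+4.

Offset ``k`` spans [anchor + k*365 d, anchor + (k+1)*365 d): the anchor date
replaces the 31 December boundary, so the offset-0 window *starts* at the
event.  For every event all group dyads resident in each window are scored,
flagged by the event condition (both-infant yes/no, immigrant-member
yes/no), and compiled into long tables for the additive-model fits.
"""
from __future__ import annotations

import datetime as dt
import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .io import Demography, INFANT_AGE_DAYS
from .networks import WindowSpec, build_network

log = logging.getLogger("gorillanet")

__all__ = ["EventAnchor", "OFFSETS", "find_events", "event_windows",
           "event_strength_series", "compile_event_tables"]

OFFSETS = {"second_birth": (-2, -1, 0, 1, 2), "immigration": (0, 1, 2, 3, 4)}
WINDOW_DAYS = 365


@dataclass(frozen=True)
class EventAnchor:
    """One demographic event anchoring a five-window series.

    ``focal_dyad`` is the unique dyad experiencing a second-birth event.
    Immigration events have no single focal dyad - the immigrant pairs with
    every resident - so ``focal_dyad`` is None and ``focal_id`` names her.
    """

    event_id: str
    event_type: str                      # "second_birth" | "immigration"
    group_id: str
    anchor_date: dt.date
    focal_dyad: frozenset | None = None
    focal_id: str | None = None


def _dependency_overlap(b1: dt.date, b2: dt.date,
                        start: dt.date | None = None,
                        end: dt.date | None = None) -> bool:
    """True if the two infants' dependency periods [b, b+365) overlap
    (optionally restricted to [start, end))."""
    lo = max(b1, b2) if start is None else max(b1, b2, start)
    hi = min(b1 + dt.timedelta(days=INFANT_AGE_DAYS),
             b2 + dt.timedelta(days=INFANT_AGE_DAYS))
    if end is not None:
        hi = min(hi, end)
    return lo < hi


def find_events(demography: Demography) -> list[EventAnchor]:
    """Enumerate second-birth and immigration anchors from demography."""
    anchors: list[EventAnchor] = []
    females = sorted(i for i, ind in demography.individuals.items()
                     if ind.sex == "female")
    # second births: dyads whose infants' dependency periods overlap
    for a, b in itertools.combinations(females, 2):
        for ba in demography[a].offspring_births:
            for bb in demography[b].offspring_births:
                if not _dependency_overlap(ba, bb):
                    continue
                anchor = max(ba, bb)
                ga = demography.resident_group(a, anchor)
                if ga is None or ga != demography.resident_group(b, anchor):
                    continue
                if demography.resident_group(a, ba) != ga or \
                   demography.resident_group(b, bb) != ga:
                    continue
                anchors.append(EventAnchor(
                    f"birth-{ga}-{anchor.isoformat()}-{a}-{b}",
                    "second_birth", ga, anchor, frozenset((a, b))))
    # immigrations: every immigration tenure entry of an adult female
    for f in females:
        for t in demography[f].tenures:
            if t.entry_type == "immigration" and demography[f].is_adult(t.entry_date):
                anchors.append(EventAnchor(
                    f"imm-{t.group_id}-{t.entry_date.isoformat()}-{f}",
                    "immigration", t.group_id, t.entry_date, None, f))
    return sorted(anchors, key=lambda e: (e.anchor_date, e.event_id))


def event_windows(anchor: EventAnchor) -> list[WindowSpec]:
    """The five contiguous 365-day windows of one event series."""
    out = []
    for k in OFFSETS[anchor.event_type]:
        start = anchor.anchor_date + dt.timedelta(days=k * WINDOW_DAYS)
        end = start + dt.timedelta(days=WINDOW_DAYS)
        out.append(WindowSpec(anchor.group_id, start, end,
                              anchor="event_offset", offset_label=k))
    return out


def _series_span(anchor: EventAnchor) -> tuple[dt.date, dt.date]:
    ks = OFFSETS[anchor.event_type]
    start = anchor.anchor_date + dt.timedelta(days=ks[0] * WINDOW_DAYS)
    end = anchor.anchor_date + dt.timedelta(days=(ks[-1] + 1) * WINDOW_DAYS)
    return start, end


def _dyad_condition(demography: Demography, anchor: EventAnchor,
                    a: str, b: str) -> bool:
    """Event condition of a dyad, evaluated over the whole series span.

    A comparison dyad that itself experienced the event type during the five
    windows (its own both-infant episode, or a member's own first residency
    year) is truthfully in the event condition, not a clean control.
    """
    span0, span1 = _series_span(anchor)
    if anchor.event_type == "immigration":
        for iid in (a, b):
            for t in demography[iid].tenures:
                if t.entry_type != "immigration":
                    continue
                e0, e1 = t.entry_date, t.entry_date + dt.timedelta(days=WINDOW_DAYS)
                if e0 < span1 and e1 > span0:
                    return True
        return False
    return any(_dependency_overlap(ba, bb, span0, span1)
               for ba in demography[a].offspring_births
               for bb in demography[b].offspring_births)


def event_strength_series(scans: pd.DataFrame, demography: Demography,
                          anchor: EventAnchor,
                          node_strength: str = "weighted_degree") -> pd.DataFrame:
    """Recompute dyadic strengths in the five windows around one event.

    Returns one row per (dyad, offset) for every dyad resident in that
    window; windows with no scans yield missing strengths (logged) so events
    near the edges of the observation period keep partial series.
    """
    group_scans = scans[scans["group_id"] == anchor.group_id]
    if len(group_scans):
        obs_start = min(group_scans["date"])
        obs_end = max(group_scans["date"]) + dt.timedelta(days=1)
    else:
        obs_start = obs_end = None
    rows = []
    for window in event_windows(anchor):
        # a window only partly inside the observed period would yield a
        # mechanically deflated score; treat it as missing instead
        covered = (obs_start is not None
                   and window.window_start >= obs_start
                   and window.window_end <= obs_end)
        net = build_network(scans, demography, window, node_strength=node_strength)
        if not covered:
            log.info("event %s offset %+d: window outside observed scan period",
                     anchor.event_id, window.offset_label)
        n_days = (window.window_end - window.window_start).days
        for d in net.dyads():
            a, b = sorted(d)
            # score a dyad only in windows both members span completely: a
            # mid-window entry or exit deflates the index mechanically
            full = all(demography.resident_days(i, anchor.group_id,
                                                window.window_start,
                                                window.window_end) == n_days
                       for i in (a, b))
            strength = net.strength(a, b) if (covered and full) else float("nan")
            rows.append(dict(
                event_id=anchor.event_id, event_type=anchor.event_type,
                group_id=anchor.group_id, anchor_date=anchor.anchor_date,
                id1=a, id2=b, dyad_id=f"{a}|{b}",
                offset=window.offset_label, strength=strength,
                condition=_dyad_condition(demography, anchor, a, b),
                is_focal_dyad=(anchor.focal_dyad == d)))
    return pd.DataFrame(rows)


def compile_event_tables(series: list[pd.DataFrame],
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-event series into the two model input tables.

    Rows with missing strength are excluded (count logged).  Returns
    (infant_table, immigrant_table) with columns event_id, dyad_id, offset,
    condition, strength, is_focal_dyad.
    """
    cols = ["event_id", "event_type", "group_id", "dyad_id", "id1", "id2",
            "offset", "condition", "is_focal_dyad", "strength"]
    if series:
        allrows = pd.concat(series, ignore_index=True)[cols]
    else:
        allrows = pd.DataFrame(columns=cols)
    n_missing = int(allrows["strength"].isna().sum())
    if n_missing:
        log.info("event tables: %d missing-strength rows excluded", n_missing)
    allrows = allrows.dropna(subset=["strength"]).reset_index(drop=True)
    infant = allrows[allrows["event_type"] == "second_birth"].reset_index(drop=True)
    imm = allrows[allrows["event_type"] == "immigration"].reset_index(drop=True)
    return infant, imm
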