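"""Elo-rating dominance hierarchies, yearly averages and standardized ranks.

Hierarchies are computed separately per group and sex from dated
displacement/avoidance records.  Individuals start at 1000 points with
k = 100; an individual entering a hierarchy that already has rated members
enters at the bottom, i.e. at the current minimum rating among active
members.  Daily ratings are carried forward between interactions, truncated
at group exit, then averaged per calendar year (1 January - 31 December,
active days only), min-max standardized to [0, 1] among the females of a
group-year, and used to identify each group-year's alpha male.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Demography, ReferentialError, as_date

__all__ = ["elo_update", "run_elo", "EloTrajectory", "EloResult",
           "yearly_mean_elo", "standardize_ranks", "dyad_average_rank",
           "alpha_of_year", "build_rank_table", "elo_daily_frame"]

START_RATING = 1000.0
DEFAULT_K = 100.0


def elo_update(rating_winner: float, rating_loser: float,
               k: float = DEFAULT_K) -> tuple[float, float]:
    """One zero-sum Elo update with the classic base-10, scale-400 curve.

    The winner's expected score is p = 1 / (1 + 10**((loser - winner)/400));
    the winner gains k*(1-p) and the loser loses the same amount.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    p = 1.0 / (1.0 + 10.0 ** ((rating_loser - rating_winner) / 400.0))
    delta = k * (1.0 - p)
    return rating_winner + delta, rating_loser - delta


@dataclass
class EloTrajectory:
    """Piecewise-constant daily rating of one individual in one hierarchy.

    ``points`` holds (date, rating) change points: the rating applies from
    that date (inclusive) until the next change point.  ``intervals`` holds
    the half-open residency intervals during which the rating is defined.
    """

    id: str
    group_id: str
    sex: str
    points: list[tuple[dt.date, float]] = field(default_factory=list)
    intervals: list[tuple[dt.date, dt.date | None]] = field(default_factory=list)

    def is_active(self, d: dt.date) -> bool:
        return any(lo <= d and (hi is None or d < hi) for lo, hi in self.intervals)

    def rating_on(self, d) -> float | None:
        d = as_date(d)
        if not self.is_active(d):
            return None
        r = None
        for pd_, rating in self.points:
            if pd_ <= d:
                r = rating
            else:
                break
        return r

    def active_days(self, start: dt.date, end: dt.date) -> list[dt.date]:
        out = []
        for lo, hi in self.intervals:
            a = max(lo, start)
            b = min(hi, end) if hi is not None else end
            d = a
            while d < b:
                out.append(d)
                d += dt.timedelta(days=1)
        return out

    def final_rating(self) -> float:
        return self.points[-1][1]


@dataclass
class EloResult:
    """All trajectories of one run, keyed by (individual id, group id).

    An individual transferring between groups has one trajectory per group:
    hierarchies are independent and she re-enters the new one at the bottom.
    """

    trajectories: dict[tuple[str, str], EloTrajectory]
    start: float
    k: float

    def get(self, iid: str, group_id: str | None = None) -> EloTrajectory:
        if group_id is not None:
            return self.trajectories[(iid, group_id)]
        matches = [t for (i, _), t in self.trajectories.items() if i == iid]
        if len(matches) != 1:
            raise KeyError(f"{iid}: {len(matches)} trajectories; specify group_id")
        return matches[0]

    def by_hierarchy(self) -> dict[tuple[str, str], list[EloTrajectory]]:
        out: dict[tuple[str, str], list[EloTrajectory]] = {}
        for t in self.trajectories.values():
            out.setdefault((t.group_id, t.sex), []).append(t)
        return out


def _event_sort_key(row) -> tuple:
    return (row.date, row.group_id, row.sex_class, row.winner_id,
            row.loser_id, row.behaviour)


def run_elo(events: pd.DataFrame, demography: Demography,
            start: float = START_RATING, k: float = DEFAULT_K) -> EloResult:
    """Run sequential Elo updates per (group, sex) hierarchy.

    Events are sorted internally by (date, group, sex, winner, loser,
    behaviour), so any input permutation yields the same result.  An
    individual's rating is defined from its group entry: founders (no rated
    member active yet) start at `start`; later entrants are initialized at
    the minimum current rating among active members (bottom entry).
    Trajectories are truncated at group exit; an individual holding several
    tenures in one group resumes at its carried-forward rating.
    """
    rows = sorted(events.itertuples(index=False), key=_event_sort_key)
    for i, r in enumerate(rows):
        for iid in (r.winner_id, r.loser_id):
            if iid not in demography:
                raise ReferentialError(f"event {i}: unknown id {iid!r}")
            if not demography.is_resident(iid, r.group_id, r.date):
                raise ReferentialError(
                    f"event {i}: {iid!r} not resident in {r.group_id!r} on {r.date}")

    trajectories: dict[tuple[str, str], EloTrajectory] = {}
    # membership change stream per hierarchy: (date, order, kind, id)
    streams: dict[tuple[str, str], list[tuple]] = {}
    for ind in demography.individuals.values():
        for t in ind.tenures:
            key = (t.group_id, ind.sex)
            streams.setdefault(key, []).append((t.entry_date, 0, "entry", ind.id))
            if t.exit_date is not None:
                streams.setdefault(key, []).append((t.exit_date, 0, "exit", ind.id))
    for r in rows:
        key = (r.group_id, r.sex_class)
        streams.setdefault(key, []).append(
            (as_date(r.date), 1, "contest", (r.winner_id, r.loser_id)))

    for (group, sex), stream in sorted(streams.items()):
        # entries/exits on a day precede that day's contests
        stream.sort(key=lambda e: (e[0], e[1]))
        ratings: dict[str, float] = {}          # currently active members
        for date, _, kind, payload in stream:
            if kind == "entry":
                iid = payload
                traj = trajectories.get((iid, group))
                if traj is None:
                    traj = EloTrajectory(iid, group, sex)
                    trajectories[(iid, group)] = traj
                if traj.points:                 # returning member: carry forward
                    ratings[iid] = traj.final_rating()
                else:
                    ratings[iid] = min(ratings.values()) if ratings else start
                    traj.points.append((date, ratings[iid]))
                traj.intervals.append((date, None))
            elif kind == "exit":
                iid = payload
                ratings.pop(iid, None)
                traj = trajectories[(iid, group)]
                lo, _ = traj.intervals[-1]
                traj.intervals[-1] = (lo, date)
            else:
                w, l = payload
                if w not in ratings or l not in ratings:
                    raise ReferentialError(
                        f"contest on {date} in {group}/{sex} involves inactive id")
                nw, nl = elo_update(ratings[w], ratings[l], k)
                ratings[w], ratings[l] = nw, nl
                for iid, val in ((w, nw), (l, nl)):
                    traj = trajectories[(iid, group)]
                    if traj.points and traj.points[-1][0] == date:
                        traj.points[-1] = (date, val)
                    else:
                        traj.points.append((date, val))
    return EloResult(trajectories, start, k)


def yearly_mean_elo(traj: EloTrajectory, year: int) -> float:
    """Arithmetic mean of daily ratings over the individual's active days of
    the calendar year.  Raises if the individual has no active day."""
    y0, y1 = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
    total, n = 0.0, 0
    dates = [p[0] for p in traj.points]
    vals = [p[1] for p in traj.points]
    for lo, hi in traj.intervals:
        a = max(lo, y0)
        b = min(hi, y1) if hi is not None else y1
        if a >= b:
            continue
        # piecewise-constant integral over [a, b)
        idx = np.searchsorted(dates, a, side="right") - 1
        cur = a
        while cur < b:
            nxt = dates[idx + 1] if idx + 1 < len(dates) else b
            seg_end = min(b, max(nxt, a))
            if idx >= 0:
                days = (seg_end - cur).days
                total += vals[idx] * days
                n += days
            cur = seg_end
            idx += 1
    if n == 0:
        raise ValueError(f"{traj.id}: no active days in {year}")
    return total / n


def standardize_ranks(mean_elos: dict[str, float]) -> dict[str, float]:
    """Min-max standardize a group-year's mean Elo scores to [0, 1].

    1 = highest-ranked, 0 = lowest-ranked.  With a single individual, or
    when all scores are equal, every value maps to 0.5 (with a warning)."""
    if not mean_elos:
        raise ValueError("standardize_ranks: empty input")
    vals = list(mean_elos.values())
    lo, hi = min(vals), max(vals)
    if len(mean_elos) == 1 or hi == lo:
        warnings.warn("degenerate rank standardization; emitting 0.5")
        return {i: 0.5 for i in mean_elos}
    return {i: (v - lo) / (hi - lo) for i, v in mean_elos.items()}


def dyad_average_rank(std_rank_a: float, std_rank_b: float) -> float:
    """Mean of the two members' standardized ranks."""
    return (std_rank_a + std_rank_b) / 2.0


def _entry_date(demography: Demography, iid: str, group: str) -> dt.date:
    dates = [t.entry_date for t in demography[iid].tenures if t.group_id == group]
    return min(dates) if dates else dt.date.max


def alpha_of_year(male_means: dict[str, float], demography: Demography,
                  group: str, year: int) -> str:
    """Male with the maximal yearly mean Elo; a lone male is alpha by default.

    Ties are broken by earlier group-entry date, then lexicographic id."""
    if not male_means:
        raise ValueError(f"no male resident in {group} in {year}")
    return min(male_means,
               key=lambda i: (-male_means[i], _entry_date(demography, i, group), i))


def build_rank_table(elo: EloResult, demography: Demography,
                     years: list[int] | None = None) -> pd.DataFrame:
    """RankTable: one row per (group, year, individual) with mean Elo,
    standardized rank (females) and alpha flag (males)."""
    if years is None:
        dates = [d for t in elo.trajectories.values() for d, _ in t.points]
        if not dates:
            return pd.DataFrame(columns=["group_id", "year", "id", "sex",
                                         "mean_elo", "std_rank", "is_alpha"])
        years = list(range(min(dates).year, max(dates).year + 1))
    rows = []
    for (group, sex), trajs in sorted(elo.by_hierarchy().items()):
        for year in years:
            means = {}
            for t in sorted(trajs, key=lambda t: t.id):
                try:
                    means[t.id] = yearly_mean_elo(t, year)
                except ValueError:
                    continue
            if not means:
                continue
            if sex == "female":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    std = standardize_ranks(means)
                for iid in sorted(means):
                    rows.append((group, year, iid, sex, means[iid], std[iid], False))
            else:
                alpha = alpha_of_year(means, demography, group, year)
                for iid in sorted(means):
                    rows.append((group, year, iid, sex, means[iid],
                                 np.nan, iid == alpha))
    return pd.DataFrame(rows, columns=["group_id", "year", "id", "sex",
                                       "mean_elo", "std_rank", "is_alpha"])


def elo_daily_frame(elo: EloResult) -> pd.DataFrame:
    """Long-format daily ratings (one row per individual-day)."""
    rows = []
    for key in sorted(elo.trajectories):
        t = elo.trajectories[key]
        iid = t.id
        if not t.points:
            continue
        last = max((hi for _, hi in t.intervals if hi is not None),
                   default=None)
        if last is None:
            last = max(d for d, _ in t.points) + dt.timedelta(days=1)
        for d in t.active_days(t.points[0][0], last):
            rows.append((t.group_id, t.sex, iid, d, t.rating_on(d)))
    return pd.DataFrame(rows, columns=["group_id", "sex", "id", "date", "rating"])
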