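"""Demographic predictor variables and analysis-ready model tables.

Variables follow annual resolution (calendar years):

* dependent infant - the female had an offspring younger than 12 months for
  strictly more than 183 days of the year;
* new immigrant    - the first scored year of an immigration tenure; a female
  joining after 1 July is first scored the following calendar year, and her
  entry year is excluded from scoring altogether;
* last year        - an emigration exit occurs in the following calendar year;
* new alpha male   - the group's alpha male identity changed relative to the
  previous year (undefined, and the row dropped, in a group's first year);
* tenure           - years since the current tenure's entry, at mid-year;
* female number    - adult females resident the majority (>182 days) of the year;
* group size       - weaned adults (both sexes) resident the majority of the year.
"""
from __future__ import annotations

import datetime as dt
import itertools
import logging

import pandas as pd

from .io import Demography, INFANT_AGE_DAYS
from .elo import dyad_average_rank

log = logging.getLogger("gorillanet")

__all__ = ["flag_dependent_infant", "flag_new_immigrant", "flag_last_year",
           "flag_new_alpha", "first_scored_year", "is_scored_year",
           "tenure_years", "female_number", "group_size", "build_model_tables"]

#: "more than 6 months of a given year", read strictly as > 183 days
DEPENDENT_DAYS_THRESHOLD = 183
#: mid-year cut-off for the immigrant first-scored-year rule
MIDYEAR = (7, 1)


def _year_span(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year, 1, 1), dt.date(year + 1, 1, 1)


def dependent_infant_days(birth: dt.date, year: int) -> int:
    """Days of `year` on which an offspring born on `birth` is under 12 months."""
    y0, y1 = _year_span(year)
    lo = max(birth, y0)
    hi = min(birth + dt.timedelta(days=INFANT_AGE_DAYS), y1)
    return max(0, (hi - lo).days)


def flag_dependent_infant(demography: Demography, female: str, year: int) -> bool:
    """True iff some offspring is under 12 months on > 183 days of the year."""
    return any(dependent_infant_days(b, year) > DEPENDENT_DAYS_THRESHOLD
               for b in demography[female].offspring_births)


def first_scored_year(entry_date: dt.date) -> int:
    """First calendar year scored for a tenure: the entry year when entry is
    on or before 1 July, otherwise the following year."""
    cutoff = dt.date(entry_date.year, *MIDYEAR)
    return entry_date.year if entry_date <= cutoff else entry_date.year + 1


def flag_new_immigrant(demography: Demography, female: str, year: int) -> bool:
    """True iff `year` is the first scored year of an immigration tenure."""
    return any(t.entry_type == "immigration" and first_scored_year(t.entry_date) == year
               for t in demography[female].tenures)


def is_scored_year(demography: Demography, female: str, group: str, year: int) -> bool:
    """False for the unscored partial entry year of a mid-year immigrant."""
    y0, y1 = _year_span(year)
    for t in demography[female].tenures:
        if t.group_id != group or not t.overlaps(y0, y1):
            continue
        if t.entry_type == "immigration" and year < first_scored_year(t.entry_date):
            return False
        return True
    return False


def flag_last_year(demography: Demography, female: str, group: str, year: int) -> bool:
    """True iff an emigration exit from `group` occurs in calendar year+1."""
    return any(t.group_id == group and t.exit_type == "emigration"
               and t.exit_date is not None and t.exit_date.year == year + 1
               for t in demography[female].tenures)


def flag_new_alpha(alpha_assignments: dict[tuple[str, int], str],
                   group: str, year: int) -> bool | None:
    """True iff the alpha male changed from year-1 to year; None when the
    previous year's alpha is unknown (first observed year of a group)."""
    cur = alpha_assignments.get((group, year))
    prev = alpha_assignments.get((group, year - 1))
    if cur is None or prev is None:
        return None
    return cur != prev


def tenure_years(demography: Demography, female: str, group: str, year: int) -> float | None:
    """Years since the entry of the tenure active at mid-year."""
    mid = dt.date(year, *MIDYEAR)
    for t in demography[female].tenures:
        if t.group_id == group and t.contains(mid):
            return (mid - t.entry_date).days / 365.25
    # resident only part of the year: use the tenure overlapping the year
    y0, y1 = _year_span(year)
    for t in demography[female].tenures:
        if t.group_id == group and t.overlaps(y0, y1):
            return max(0.0, (mid - t.entry_date).days) / 365.25
    return None


def _majority_residents(demography: Demography, group: str, year: int,
                        sex: str | None = None) -> list[str]:
    y0, y1 = _year_span(year)
    out = []
    for iid in demography.residents_in_window(group, y0, y1, sex=sex, adult_only=True):
        if demography.resident_days(iid, group, y0, y1) > 182:
            out.append(iid)
    return out


def female_number(demography: Demography, group: str, year: int) -> int:
    """Adult females resident the majority of the year."""
    return len(_majority_residents(demography, group, year, sex="female"))


def group_size(demography: Demography, group: str, year: int) -> int:
    """Weaned adults of both sexes resident the majority of the year."""
    return len(_majority_residents(demography, group, year, sex=None))


# ---------------------------------------------------------------------------


def alpha_assignments_from_ranks(ranks: pd.DataFrame) -> dict[tuple[str, int], str]:
    out = {}
    males = ranks[(ranks["sex"] == "male") & (ranks["is_alpha"])]
    for row in males.itertuples(index=False):
        out[(row.group_id, int(row.year))] = row.id
    return out


def build_model_tables(node_strengths: pd.DataFrame, dyad_strengths: pd.DataFrame,
                       ranks: pd.DataFrame, demography: Demography,
                       alpha_assignments: dict[tuple[str, int], str] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join strengths, ranks and demographic flags into the two model tables.

    Inputs are the calendar-year outputs of the association and dominance
    modules (`node_strength_frame`, `networks_frame`, `build_rank_table`).
    Rows with any undefined predictor (unknown previous alpha, unscored
    immigrant entry year, no focal scans, missing rank) are dropped and
    logged.  Returns (individual_year, dyad_year) tables.
    """
    if alpha_assignments is None:
        alpha_assignments = alpha_assignments_from_ranks(ranks)
    fem_ranks = {(r.group_id, int(r.year), r.id): r.std_rank
                 for r in ranks[ranks["sex"] == "female"].itertuples(index=False)}

    cal_nodes = node_strengths[node_strengths["anchor"] == "calendar_year"]
    ind_rows, dropped = [], 0
    for row in cal_nodes.itertuples(index=False):
        group, iid = row.group_id, row.id
        year = row.window_start.year
        new_alpha = flag_new_alpha(alpha_assignments, group, year)
        rank = fem_ranks.get((group, year, iid))
        reasons = []
        if not is_scored_year(demography, iid, group, year):
            reasons.append("unscored immigrant entry year")
        if row.N_focal == 0:
            reasons.append("no focal scans")
        if new_alpha is None:
            reasons.append("previous alpha unknown")
        if rank is None:
            reasons.append("no rank (no agonistic data)")
        ten = tenure_years(demography, iid, group, year)
        if ten is None:
            reasons.append("no tenure")
        if reasons:
            dropped += 1
            log.info("individual row (%s, %s, %s) dropped: %s",
                     group, year, iid, "; ".join(reasons))
            continue
        ind_rows.append(dict(
            group_id=group, year=year, id=iid, strength=row.strength,
            dominance_rank=rank,
            dependent_infant=flag_dependent_infant(demography, iid, year),
            new_immigrant=flag_new_immigrant(demography, iid, year),
            tenure=ten,
            new_alpha_male=new_alpha,
            last_year_in_group=flag_last_year(demography, iid, group, year),
            female_number=female_number(demography, group, year),
            group_size=group_size(demography, group, year)))
    individual = pd.DataFrame(ind_rows)
    scored = {(r["group_id"], r["year"], r["id"]) for r in ind_rows}

    cal_dyads = dyad_strengths[dyad_strengths["anchor"] == "calendar_year"]
    dyad_rows, ddropped = [], 0
    for row in cal_dyads.itertuples(index=False):
        group, a, b = row.group_id, row.id1, row.id2
        year = row.window_start.year
        if (group, year, a) not in scored or (group, year, b) not in scored:
            ddropped += 1
            continue
        if row.strength != row.strength:          # dropped dyad (NaN)
            ddropped += 1
            log.info("dyad row (%s, %s, %s-%s) dropped: undefined strength",
                     group, year, a, b)
            continue
        fa = flag_dependent_infant(demography, a, year)
        fb = flag_dependent_infant(demography, b, year)
        cat = "both" if fa and fb else ("one" if fa or fb else "none")
        dyad_rows.append(dict(
            group_id=group, year=year, id1=a, id2=b, dyad_id=f"{a}|{b}",
            strength=row.strength,
            rank_average=dyad_average_rank(fem_ranks[(group, year, a)],
                                           fem_ranks[(group, year, b)]),
            dependent_infant_cat=cat,
            new_immigrant=(flag_new_immigrant(demography, a, year)
                           or flag_new_immigrant(demography, b, year)),
            new_alpha_male=flag_new_alpha(alpha_assignments, group, year),
            female_number=female_number(demography, group, year),
            group_size=group_size(demography, group, year)))
    dyad = pd.DataFrame(dyad_rows)
    log.info("model tables: %d individual rows (%d dropped), %d dyad rows (%d dropped)",
             len(individual), dropped, len(dyad), ddropped)
    return individual, dyad
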