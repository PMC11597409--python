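"""On-disk schemas, validated readers/writers and the demography container.

All tables are comma-separated UTF-8 text with ISO-8601 dates.  Set-valued
fields are serialised inside a single CSV field: semicolons separate items
and, where an item is itself structured (a tenure), pipes separate its parts.

Three tables exist:

``scans``       one row per instantaneous scan of a focal female, listing the
                adult females within 5 m of her at that moment;
``agonistic``   dated winner/loser displacement or avoidance records;
``demography``  one row per individual: birth date, group tenures, offspring
                birth dates (females) and alpha tenures (males).
"""
from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger("gorillanet")

ACTIVITIES = ("feeding", "resting", "travelling", "other")
BEHAVIOURS = ("displacement", "avoidance")
SEX_CLASSES = ("female", "male")
ENTRY_TYPES = ("natal", "immigration")
EXIT_TYPES = ("emigration", "death", "censored")

#: adulthood threshold: aged 10 years or older
ADULT_AGE_DAYS = 3653
#: an infant is dependent while younger than 12 months
INFANT_AGE_DAYS = 365

SCAN_COLUMNS = ["scan_id", "date", "time", "group_id", "focal_id", "activity", "neighbors_5m"]
AGONISTIC_COLUMNS = ["date", "group_id", "winner_id", "loser_id", "behaviour", "sex_class"]
DEMOGRAPHY_COLUMNS = ["id", "sex", "birth_date", "tenures", "offspring_births", "alpha_tenures"]


class SchemaError(ValueError):
    """A file's header or a field's format does not match the schema."""


class ReferentialError(ValueError):
    """A record refers to an individual unknown to, or not resident per, demography."""


class DemographyError(ValueError):
    """A demography table violates its invariants (e.g. overlapping tenures)."""


def as_date(x) -> dt.date:
    """Coerce str / Timestamp / datetime / date to a plain date."""
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


# ---------------------------------------------------------------------------
# demography


@dataclass(frozen=True)
class Tenure:
    group_id: str
    entry_date: dt.date
    entry_type: str
    exit_date: dt.date | None = None
    exit_type: str | None = None

    def contains(self, d: dt.date) -> bool:
        return self.entry_date <= d and (self.exit_date is None or d < self.exit_date)

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        """Overlap with the half-open window [start, end)."""
        return self.entry_date < end and (self.exit_date is None or self.exit_date > start)


@dataclass(frozen=True)
class AlphaTenure:
    group_id: str
    start_date: dt.date
    end_date: dt.date | None = None

    def contains(self, d: dt.date) -> bool:
        return self.start_date <= d and (self.end_date is None or d < self.end_date)


@dataclass
class Individual:
    id: str
    sex: str
    birth_date: dt.date
    tenures: list[Tenure] = field(default_factory=list)
    offspring_births: list[dt.date] = field(default_factory=list)
    alpha_tenures: list[AlphaTenure] = field(default_factory=list)

    def age_days(self, on: dt.date) -> int:
        return (on - self.birth_date).days

    def is_adult(self, on: dt.date) -> bool:
        return self.age_days(on) >= ADULT_AGE_DAYS

    def tenure_on(self, d: dt.date) -> Tenure | None:
        for t in self.tenures:
            if t.contains(d):
                return t
        return None

    def has_dependent_infant(self, on: dt.date) -> bool:
        """True if any offspring is alive and under 12 months on `on`."""
        return any(0 <= (on - b).days < INFANT_AGE_DAYS for b in self.offspring_births)


class Demography:
    """Per-individual life histories with residency lookups.

    The container is the referential backbone of the pipeline: scan and
    agonistic records are validated against it, covariates are derived from
    it, and the synthetic generator produces one.
    """

    def __init__(self, individuals: list[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise DemographyError(f"duplicate individual id {ind.id!r}")
            ind.tenures = sorted(ind.tenures, key=lambda t: t.entry_date)
            ind.offspring_births = sorted(ind.offspring_births)
            self.individuals[ind.id] = ind
        self.validate()

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def groups(self) -> list[str]:
        gs = {t.group_id for ind in self.individuals.values() for t in ind.tenures}
        return sorted(gs)

    def validate(self) -> None:
        for ind in self.individuals.values():
            if ind.sex not in SEX_CLASSES:
                raise DemographyError(f"{ind.id}: unknown sex {ind.sex!r}")
            prev_exit: dt.date | None = None
            for t in ind.tenures:
                if t.entry_type not in ENTRY_TYPES:
                    raise DemographyError(f"{ind.id}: unknown entry_type {t.entry_type!r}")
                if t.exit_date is not None and t.exit_type not in EXIT_TYPES:
                    raise DemographyError(f"{ind.id}: unknown exit_type {t.exit_type!r}")
                if t.exit_date is not None and t.exit_date <= t.entry_date:
                    raise DemographyError(f"{ind.id}: tenure exit not after entry")
                if prev_exit is None and ind.tenures.index(t) > 0:
                    raise DemographyError(f"{ind.id}: open tenure followed by another tenure")
                if prev_exit is not None and t.entry_date < prev_exit:
                    raise DemographyError(f"{ind.id}: overlapping tenures")
                prev_exit = t.exit_date
            for b in ind.offspring_births:
                if ind.sex != "female":
                    raise DemographyError(f"{ind.id}: offspring births on non-female")
                if b < ind.birth_date:
                    raise DemographyError(f"{ind.id}: offspring born before mother")
            for a in ind.alpha_tenures:
                if ind.sex != "male":
                    raise DemographyError(f"{ind.id}: alpha tenure on non-male")

    # -- residency lookups ---------------------------------------------------

    def resident_group(self, iid: str, d) -> str | None:
        t = self.individuals[iid].tenure_on(as_date(d))
        return t.group_id if t else None

    def is_resident(self, iid: str, group_id: str, d) -> bool:
        return iid in self.individuals and self.resident_group(iid, d) == group_id

    def residents(self, group_id: str, d, sex: str | None = None,
                  adult_only: bool = False) -> list[str]:
        d = as_date(d)
        out = []
        for ind in self.individuals.values():
            if sex is not None and ind.sex != sex:
                continue
            if adult_only and not ind.is_adult(d):
                continue
            t = ind.tenure_on(d)
            if t is not None and t.group_id == group_id:
                out.append(ind.id)
        return sorted(out)

    def residents_in_window(self, group_id: str, start, end, sex: str | None = None,
                            adult_only: bool = False) -> list[str]:
        """Ids resident in `group_id` for >= 1 day of [start, end)."""
        start, end = as_date(start), as_date(end)
        out = []
        for ind in self.individuals.values():
            if sex is not None and ind.sex != sex:
                continue
            if adult_only and not ind.is_adult(end - dt.timedelta(days=1)):
                continue
            if any(t.group_id == group_id and t.overlaps(start, end) for t in ind.tenures):
                out.append(ind.id)
        return sorted(out)

    def resident_days(self, iid: str, group_id: str, start, end) -> int:
        """Number of days of [start, end) the individual is resident in the group."""
        start, end = as_date(start), as_date(end)
        n = 0
        for t in self.individuals[iid].tenures:
            if t.group_id != group_id:
                continue
            lo = max(t.entry_date, start)
            hi = min(t.exit_date or end, end)
            n += max(0, (hi - lo).days)
        return n

    def alpha_on(self, group_id: str, d) -> str | None:
        d = as_date(d)
        for ind in self.individuals.values():
            if any(a.group_id == group_id and a.contains(d) for a in ind.alpha_tenures):
                return ind.id
        return None

    # -- (de)serialisation ---------------------------------------------------

    @staticmethod
    def _fmt_date(d: dt.date | None) -> str:
        return "" if d is None else d.isoformat()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in sorted(self.individuals.values(), key=lambda i: i.id):
            tenures = ";".join(
                "|".join([t.group_id, t.entry_date.isoformat(), t.entry_type,
                          self._fmt_date(t.exit_date), t.exit_type or ""])
                for t in ind.tenures)
            births = ";".join(b.isoformat() for b in ind.offspring_births)
            alphas = ";".join(
                "|".join([a.group_id, a.start_date.isoformat(), self._fmt_date(a.end_date)])
                for a in ind.alpha_tenures)
            rows.append((ind.id, ind.sex, ind.birth_date.isoformat(), tenures, births, alphas))
        return pd.DataFrame(rows, columns=DEMOGRAPHY_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Demography":
        _check_header(df, DEMOGRAPHY_COLUMNS, "demography")
        inds = []
        for _, row in df.iterrows():
            tenures = []
            for chunk in _split(row["tenures"]):
                parts = chunk.split("|")
                if len(parts) != 5:
                    raise SchemaError(f"bad tenure field {chunk!r} for id {row['id']!r}")
                g, entry, etype, exit_, xtype = parts
                tenures.append(Tenure(g, as_date(entry), etype,
                                      as_date(exit_) if exit_ else None,
                                      xtype or None))
            births = [as_date(b) for b in _split(row["offspring_births"])]
            alphas = []
            for chunk in _split(row["alpha_tenures"]):
                parts = chunk.split("|")
                if len(parts) != 3:
                    raise SchemaError(f"bad alpha_tenure field {chunk!r} for id {row['id']!r}")
                g, start, end = parts
                alphas.append(AlphaTenure(g, as_date(start), as_date(end) if end else None))
            inds.append(Individual(str(row["id"]), str(row["sex"]), as_date(row["birth_date"]),
                                   tenures, births, alphas))
        return cls(inds)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _split(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return [c for c in str(value).split(";") if c]


def _check_header(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing column(s): {', '.join(missing)}")


def read_demography(path) -> Demography:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Demography.from_frame(df)


# ---------------------------------------------------------------------------
# scans


def _report(errors: list[str], exc_type: type[Exception], lax: bool) -> None:
    if not errors:
        return
    msg = "; ".join(errors[:20]) + (f"; ... {len(errors) - 20} more" if len(errors) > 20 else "")
    if lax:
        warnings.warn(msg)
        log.warning("lax mode: %d validation problem(s) downgraded: %s", len(errors), msg)
    else:
        raise exc_type(msg)


def validate_scans(df: pd.DataFrame, demography: Demography | None = None,
                   lax: bool = False) -> None:
    """Check scan invariants; raise (or warn under `lax`) listing offending lines.

    Line numbers are 1-based data rows (header excluded).
    """
    schema_errors, ref_errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.activity not in ACTIVITIES:
            schema_errors.append(f"line {i}: unknown activity {row.activity!r}")
        neighbors = row.neighbors_5m
        if row.focal_id in neighbors:
            ref_errors.append(f"line {i}: focal {row.focal_id!r} listed in neighbors_5m")
        if demography is not None:
            d = row.date
            for iid in (row.focal_id, *neighbors):
                if iid not in demography:
                    ref_errors.append(f"line {i}: unknown id {iid!r}")
                elif not demography.is_resident(iid, row.group_id, d):
                    ref_errors.append(f"line {i}: {iid!r} not resident in {row.group_id!r} on {d}")
            for iid in neighbors:
                if iid in demography:
                    ind = demography[iid]
                    if ind.sex != "female" or not ind.is_adult(as_date(d)):
                        ref_errors.append(f"line {i}: neighbor {iid!r} not an adult female")
    _report(schema_errors, SchemaError, lax)
    _report(ref_errors, ReferentialError, lax)


def read_scans(path, demography: Demography | None = None, lax: bool = False) -> pd.DataFrame:
    """Read a scan table; `neighbors_5m` becomes a tuple of ids per row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, SCAN_COLUMNS, "scans")
    df = df[SCAN_COLUMNS].copy()
    df["date"] = df["date"].map(as_date)
    df["neighbors_5m"] = df["neighbors_5m"].map(lambda s: tuple(_split(s)))
    validate_scans(df, demography, lax=lax)
    return df


def write_scans(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].map(lambda d: as_date(d).isoformat())
    out["neighbors_5m"] = out["neighbors_5m"].map(lambda ns: ";".join(ns))
    out[SCAN_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# agonistic events


def read_agonistic(path, demography: Demography | None = None, lax: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, AGONISTIC_COLUMNS, "agonistic")
    df = df[AGONISTIC_COLUMNS].copy()
    df["date"] = df["date"].map(as_date)
    schema_errors, ref_errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.behaviour not in BEHAVIOURS:
            schema_errors.append(f"line {i}: unknown behaviour {row.behaviour!r}")
        if row.sex_class not in SEX_CLASSES:
            schema_errors.append(f"line {i}: unknown sex_class {row.sex_class!r}")
        if row.winner_id == row.loser_id:
            ref_errors.append(f"line {i}: winner equals loser ({row.winner_id!r})")
        if demography is not None:
            for iid in (row.winner_id, row.loser_id):
                if iid not in demography:
                    ref_errors.append(f"line {i}: unknown id {iid!r}")
                elif not demography.is_resident(iid, row.group_id, row.date):
                    ref_errors.append(
                        f"line {i}: {iid!r} not resident in {row.group_id!r} on {row.date}")
                elif demography[iid].sex != row.sex_class:
                    ref_errors.append(f"line {i}: {iid!r} is not {row.sex_class!r}")
    _report(schema_errors, SchemaError, lax)
    _report(ref_errors, ReferentialError, lax)
    return df


def write_agonistic(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].map(lambda d: as_date(d).isoformat())
    out[AGONISTIC_COLUMNS].to_csv(path, index=False)
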