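"""Synthetic demography, agonistic events and proximity scans.

The generator emulates a multi-year, multi-group field study of adult female
gorillas: focal follows of 15-60 min with instantaneous scans every 10 min,
recording which other adult females are within 5 m of the focal; dated
displacement/avoidance records for dominance; and a demography of births,
immigrations, emigrations and alpha-male turnover.

Proximity is generated focal-centrically.  For every scan of focal ``a``,
each co-resident adult female ``b`` appears in the neighbour set with
probability::

    logit p = beta0 + affinity_ab + beta_rank_avg * meanrank_ab
              + beta_both_infant * [both have infant < 1 y]
              + beta_one_infant  * [exactly one has infant < 1 y]
              + beta_immigrant   * [either in first residency year]
              + u_a + u_b + w_year

so the symmetry of the downstream dyadic index is emergent, not imposed.
The realised latent ranks, dyad affinities and random effects are persisted
(``truth``) so recovery tests can compare estimates against known values.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import (Demography, Individual, Tenure, AlphaTenure, ACTIVITIES,
                 SCAN_COLUMNS, AGONISTIC_COLUMNS, write_scans, write_agonistic)

__all__ = ["Effects", "ScenarioConfig", "Truth", "SimulatedData", "simulate",
           "simulate_demography", "draw_truth", "simulate_agonistic", "simulate_scans",
           "ScenarioError"]


class ScenarioError(ValueError):
    """Scenario parameters are inconsistent or imply a degenerate study."""


@dataclass(frozen=True)
class Effects:
    """Injected effect sizes on the log-odds (logit) of 5 m proximity."""

    beta0: float = -2.4              # baseline log-odds; logistic(-2.4) ~ 0.083
    beta_rank_avg: float = 0.5       # per unit of dyad mean standardized rank (0..1)
    beta_both_infant: float = 1.0    # both members have an infant < 1 y on scan date
    beta_one_infant: float = 0.0     # exactly one member has an infant < 1 y
    beta_immigrant: float = -1.0     # either member within 1 y of immigration entry
    dyad_affinity_sd: float = 0.5    # sd of the static per-dyad affinity
    female_re_sd: float = 0.3        # sd of the per-female random effect
    year_re_sd: float = 0.2          # sd of the per-calendar-year random effect


@dataclass(frozen=True)
class ScenarioConfig:
    """Study design of the simulated population.

    Defaults mirror the observed field design: 2-7 adult females per group,
    ~80-160 focal observations per female per year, 2-6 scans per focal
    (15-60 min at 10-min intervals), a ~0.2 per female-year birth rate
    (inter-birth interval around five years) and occasional female transfer
    and alpha-male turnover.
    """

    n_groups: int = 3
    years: int = 8
    start_year: int = 2012
    females_per_group: tuple[int, int] = (2, 7)
    focals_per_female_year: tuple[float, float] = (100.0, 50.0)   # mean, sd
    scans_per_focal: tuple[int, int] = (2, 6)
    latent_rank_sd: float = 1.5
    birth_rate: float = 0.2
    immigration_rate: float = 0.06
    emigration_rate: float = 0.06
    alpha_turnover_rate: float = 0.1
    male_turnover_rate: float = 0.2
    events_per_dyad_year: float = 20.0
    effects: Effects = field(default_factory=Effects)
    seed: int = 0

    def validate(self) -> None:
        for name in ("birth_rate", "immigration_rate", "emigration_rate",
                     "alpha_turnover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name}={v} outside [0, 1]")
        lo, hi = self.scans_per_focal
        if not (1 <= lo <= hi <= 6):
            raise ScenarioError(f"scans_per_focal={self.scans_per_focal} outside 1..6")
        if self.n_groups < 1 or self.years < 1:
            raise ScenarioError("need at least one group and one year")
        flo, fhi = self.females_per_group
        if flo < 2:
            raise ScenarioError("groups need at least 2 females")
        mean_init = (flo + fhi) / 2.0
        growth = 1.0 - self.emigration_rate + self.immigration_rate
        if mean_init * growth ** self.years < 2.0:
            raise ScenarioError("rates imply expected group size below 2 females")

    def study_start(self) -> dt.date:
        return dt.date(self.start_year, 1, 1)

    def study_end(self) -> dt.date:
        return dt.date(self.start_year + self.years, 1, 1)


@dataclass
class Truth:
    """Realised latent quantities behind one simulated dataset."""

    effects: Effects
    latent_rank: dict[str, float]                      # id -> latent dominance
    affinity: dict[frozenset, float]                   # dyad -> static affinity
    female_re: dict[str, float]                        # id -> random intercept
    year_re: dict[int, float]                          # calendar year -> intercept
                                                       # (shared across groups, as
                                                       # the year random intercept
                                                       # of the fitted models)

    def std_latent_ranks(self, demography: Demography, group_id: str,
                         year: int) -> dict[str, float]:
        """Min-max standardized latent ranks among the females resident in a
        group-year (1 = highest latent rank); single female maps to 0.5."""
        start, end = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
        ids = demography.residents_in_window(group_id, start, end,
                                             sex="female", adult_only=True)
        vals = {i: self.latent_rank[i] for i in ids}
        if not vals:
            return {}
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            return {i: 0.5 for i in vals}
        return {i: (v - lo) / (hi - lo) for i, v in vals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [("effects", "", "", k, "", v) for k, v in asdict(self.effects).items()]
        rows += [("latent_rank", "", "", i, "", v)
                 for i, v in sorted(self.latent_rank.items())]
        rows += [("affinity", "", "", *sorted(d), v)
                 for d, v in sorted(self.affinity.items(), key=lambda kv: sorted(kv[0]))]
        rows += [("female_re", "", "", i, "", v)
                 for i, v in sorted(self.female_re.items())]
        rows += [("year_re", "", y, "", "", v)
                 for y, v in sorted(self.year_re.items())]
        return pd.DataFrame(rows, columns=["kind", "group_id", "year", "id1", "id2", "value"])


@dataclass
class SimulatedData:
    scenario: ScenarioConfig
    demography: Demography
    truth: Truth
    scans: pd.DataFrame
    agonistic: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.demography.write(outdir / "demography.csv")
        write_scans(self.scans, outdir / "scans.csv")
        write_agonistic(self.agonistic, outdir / "agonistic.csv")
        self.truth.to_frame().to_csv(outdir / "truth.csv", index=False)


# ---------------------------------------------------------------------------
# helpers

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _uniform_date(rng, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, max(span, 1))))


def _rngs(scenario: ScenarioConfig, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(scenario.seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


# ---------------------------------------------------------------------------
# demography

def simulate_demography(scenario: ScenarioConfig,
                        rng: np.random.Generator | None = None) -> Demography:
    """Generate group membership histories at the configured rates.

    Each group starts with natal adult females and two males (one alpha).
    Per female-year: a birth with probability ``birth_rate``, an emigration
    with probability ``emigration_rate`` (vetoed if it would leave fewer than
    two females) and an immigration with probability ``immigration_rate``
    (entry date uniform within the year).  Half of the emigrants re-join a
    different group after a short gap (secondary dispersal).  Alpha-male
    turnover occurs per group-year at ``alpha_turnover_rate``: a new male
    joins and takes over the alpha position at a uniform date.
    """
    scenario.validate()
    if rng is None:
        rng = _rngs(scenario, 5)[0]
    start, end = scenario.study_start(), scenario.study_end()
    inds: dict[str, Individual] = {}
    counters: dict[str, int] = {}

    def new_id(group: str, prefix: str) -> str:
        key = f"{group}{prefix}"
        counters[key] = counters.get(key, 0) + 1
        return f"{key}{counters[key]:02d}"

    def add_female(group: str, entry: dt.date, entry_type: str,
                   age_years: float) -> Individual:
        iid = new_id(group, "F")
        birth = entry - dt.timedelta(days=int(age_years * 365.25))
        ind = Individual(iid, "female", birth,
                         [Tenure(group, entry, entry_type)])
        inds[iid] = ind
        return ind

    def add_male(group: str, entry: dt.date, entry_type: str,
                 age_years: float) -> Individual:
        iid = new_id(group, "M")
        birth = entry - dt.timedelta(days=int(age_years * 365.25))
        ind = Individual(iid, "male", birth, [Tenure(group, entry, entry_type)])
        inds[iid] = ind
        return ind

    groups = [f"G{g + 1}" for g in range(scenario.n_groups)]
    pending_transfers: list[tuple[Individual, dt.date]] = []
    for group in groups:
        n0 = int(rng.integers(scenario.females_per_group[0],
                              scenario.females_per_group[1] + 1))
        for _ in range(n0):
            # natal adult females, present from the study start
            add_female(group, start, "natal", float(rng.uniform(10.0, 30.0)))
        alpha = add_male(group, start, "natal", float(rng.uniform(15.0, 25.0)))
        alpha.alpha_tenures.append(AlphaTenure(group, start))
        for _ in range(int(rng.integers(1, 4))):
            add_male(group, start, "natal", float(rng.uniform(12.0, 20.0)))

    for year in range(scenario.start_year, scenario.start_year + scenario.years):
        y0, y1 = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
        # transfers decided in earlier years that land in this one
        def n_females(group: str, d: dt.date) -> int:
            return sum(1 for i in inds.values()
                       if i.sex == "female" and i.tenure_on(d) is not None
                       and i.tenure_on(d).group_id == group)

        cap = scenario.females_per_group[1]
        for ind, entry in [t for t in pending_transfers if y0 <= t[1] < y1]:
            pending_transfers.remove((ind, entry))
            open_groups = [g for g in groups
                           if g != ind.tenures[-1].group_id
                           and n_females(g, entry) < cap]
            if not open_groups:
                continue
            target = rng.choice(open_groups)
            ind.tenures.append(Tenure(str(target), entry, "immigration"))
        for group in groups:
            females = [inds[i] for i in sorted(inds)
                       if inds[i].sex == "female"
                       and inds[i].tenure_on(y0) is not None
                       and inds[i].tenure_on(y0).group_id == group]
            n_res = len(females)
            for f in females:
                if rng.random() < scenario.birth_rate:
                    f.offspring_births.append(_uniform_date(rng, max(y0, f.tenures[-1].entry_date), y1))
                if rng.random() < scenario.emigration_rate and n_res > 2:
                    exit_date = _uniform_date(rng, y0, y1)
                    t = f.tenures[-1]
                    if t.exit_date is None and t.entry_date < exit_date:
                        f.tenures[-1] = Tenure(t.group_id, t.entry_date,
                                               t.entry_type, exit_date, "emigration")
                        n_res -= 1
                        if rng.random() < 0.5:
                            gap = int(rng.integers(30, 200))
                            re_entry = exit_date + dt.timedelta(days=gap)
                            if re_entry < end:
                                pending_transfers.append((f, re_entry))
            n_imm = int(rng.binomial(max(n_res, 1), scenario.immigration_rate))
            for _ in range(n_imm):
                # groups stay within the observed female-number range
                if n_res >= cap:
                    break
                add_female(group, _uniform_date(rng, y0, y1), "immigration",
                           float(rng.uniform(10.0, 20.0)))
                n_res += 1
            # subordinate (non-alpha) males drift in and out, so weaned-adult
            # group size varies independently of female number
            males = [inds[i] for i in sorted(inds)
                     if inds[i].sex == "male"
                     and inds[i].tenure_on(y0) is not None
                     and inds[i].tenure_on(y0).group_id == group]
            subordinates = [m for m in males
                            if not any(a.group_id == group and a.end_date is None
                                       for a in m.alpha_tenures)]
            if subordinates and len(males) > 1 and \
                    rng.random() < scenario.male_turnover_rate:
                m = subordinates[int(rng.integers(0, len(subordinates)))]
                exit_date = _uniform_date(rng, y0, y1)
                t = m.tenures[-1]
                if t.exit_date is None and t.entry_date < exit_date:
                    m.tenures[-1] = Tenure(t.group_id, t.entry_date, t.entry_type,
                                           exit_date, "emigration")
            if rng.random() < scenario.male_turnover_rate:
                add_male(group, _uniform_date(rng, y0, y1), "immigration",
                         float(rng.uniform(12.0, 20.0)))
            if rng.random() < scenario.alpha_turnover_rate:
                turn = _uniform_date(rng, y0, y1)
                for ind in inds.values():
                    for k, a in enumerate(ind.alpha_tenures):
                        if a.group_id == group and a.end_date is None:
                            ind.alpha_tenures[k] = AlphaTenure(group, a.start_date, turn)
                newm = add_male(group, turn, "immigration", float(rng.uniform(15.0, 25.0)))
                newm.alpha_tenures.append(AlphaTenure(group, turn))
    return Demography(list(inds.values()))


# ---------------------------------------------------------------------------
# latent truth

def draw_truth(demography: Demography, scenario: ScenarioConfig,
               rng: np.random.Generator | None = None) -> Truth:
    """Draw the latent quantities the scan and agonistic generators share.

    Female latent ranks are drawn once per female from N(0, latent_rank_sd);
    a female whose first tenure is an immigration enters below the current
    minimum among her new group mates (bottom entry).  Males are ranked so
    that the demography's designated alpha holds the top latent rank during
    his tenure.
    """
    eff = scenario.effects
    if rng is None:
        rng = _rngs(scenario, 5)[1]
    latent: dict[str, float] = {}
    # chronological assignment so bottom entry can see incumbents
    events = []
    for ind in demography.individuals.values():
        events.append((ind.tenures[0].entry_date, ind.id))
    for entry, iid in sorted(events, key=lambda e: (e[0], e[1])):
        ind = demography[iid]
        if ind.sex == "male":
            n_alpha = len(ind.alpha_tenures)
            peers = [latent[j] for j, o in demography.individuals.items()
                     if o.sex == "male" and j in latent]
            if n_alpha:
                latent[iid] = (max(peers) if peers else 0.0) + 1.0 + float(rng.uniform(0, 1))
            else:
                latent[iid] = float(rng.normal(0.0, scenario.latent_rank_sd))
            continue
        if ind.tenures[0].entry_type == "immigration":
            group = ind.tenures[0].group_id
            peers = [latent[j] for j in demography.residents(group, entry, sex="female")
                     if j in latent and j != iid]
            base = min(peers) if peers else 0.0
            latent[iid] = base - abs(float(rng.normal(0.0, scenario.latent_rank_sd / 2)))
        else:
            latent[iid] = float(rng.normal(0.0, scenario.latent_rank_sd))

    females = sorted(i for i, o in demography.individuals.items() if o.sex == "female")
    affinity = {}
    for a in females:
        for b in females:
            if a < b:
                affinity[frozenset((a, b))] = float(rng.normal(0.0, eff.dyad_affinity_sd))
    female_re = {i: float(rng.normal(0.0, eff.female_re_sd)) for i in females}
    year_re = {year: float(rng.normal(0.0, eff.year_re_sd))
               for year in range(scenario.start_year,
                                 scenario.start_year + scenario.years)}
    return Truth(eff, latent, affinity, female_re, year_re)


# ---------------------------------------------------------------------------
# agonistic events

def simulate_agonistic(demography: Demography, truth: Truth,
                       scenario: ScenarioConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Dated displacement/avoidance records from latent ranks.

    For each same-sex co-resident dyad and calendar year the number of events
    is Poisson with mean ``events_per_dyad_year`` scaled by the fraction of
    the year the dyad overlaps; the higher-latent individual wins each event
    with probability logistic(latent_i - latent_j).
    """
    if rng is None:
        rng = _rngs(scenario, 5)[2]
    rows = []
    start, end = scenario.study_start(), scenario.study_end()
    for group in demography.groups:
        for sex in ("female", "male"):
            members = demography.residents_in_window(group, start, end, sex=sex,
                                                     adult_only=True)
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    a, b = members[ai], members[bi]
                    for year in range(scenario.start_year,
                                      scenario.start_year + scenario.years):
                        y0, y1 = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
                        days = sorted(set(_overlap_days(demography, a, b, group, y0, y1)))
                        if not days:
                            continue
                        lam = scenario.events_per_dyad_year * len(days) / 365.0
                        n = int(rng.poisson(lam))
                        if n == 0:
                            continue
                        p_a = float(_logistic(truth.latent_rank[a] - truth.latent_rank[b]))
                        for _ in range(n):
                            d = days[int(rng.integers(0, len(days)))]
                            win_a = rng.random() < p_a
                            w, l = (a, b) if win_a else (b, a)
                            beh = "displacement" if rng.random() < 0.7 else "avoidance"
                            rows.append((d, group, w, l, beh, sex))
    df = pd.DataFrame(rows, columns=AGONISTIC_COLUMNS)
    return df.sort_values(AGONISTIC_COLUMNS, kind="mergesort").reset_index(drop=True)


def _overlap_days(demography: Demography, a: str, b: str, group: str,
                  start: dt.date, end: dt.date) -> list[dt.date]:
    out = []
    for ta in demography[a].tenures:
        if ta.group_id != group:
            continue
        for tb in demography[b].tenures:
            if tb.group_id != group:
                continue
            lo = max(ta.entry_date, tb.entry_date, start)
            hi = min(ta.exit_date or end, tb.exit_date or end, end)
            d = lo
            while d < hi:
                out.append(d)
                d += dt.timedelta(days=1)
    return out


# ---------------------------------------------------------------------------
# scans

def simulate_scans(demography: Demography, truth: Truth, scenario: ScenarioConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Focal-rotation scan records with the injected proximity structure."""
    if rng is None:
        rng = _rngs(scenario, 5)[3]
    eff = truth.effects
    lo_s, hi_s = scenario.scans_per_focal
    mean_f, sd_f = scenario.focals_per_female_year
    rows = []

    imm_entries = {i: np.array([t.entry_date.toordinal()
                                for t in ind.tenures if t.entry_type == "immigration"],
                               dtype=np.int64)
                   for i, ind in demography.individuals.items()}
    births = {i: np.array([b.toordinal() for b in ind.offspring_births], dtype=np.int64)
              for i, ind in demography.individuals.items()}

    def _flag(ordinals: np.ndarray, entries: np.ndarray) -> np.ndarray:
        if entries.size == 0:
            return np.zeros(ordinals.shape, dtype=bool)
        diff = ordinals[:, None] - entries[None, :]
        return ((diff >= 0) & (diff < 365)).any(axis=1)

    for group in demography.groups:
        for year in range(scenario.start_year, scenario.start_year + scenario.years):
            y0, y1 = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
            females = demography.residents_in_window(group, y0, y1, sex="female",
                                                     adult_only=True)
            if len(females) < 2:
                continue
            std_rank = truth.std_latent_ranks(demography, group, year)
            w_year = truth.year_re[year]
            for f in females:
                res_days = _residency_ordinals(demography, f, group, y0, y1)
                if res_days.size == 0:
                    continue
                frac = res_days.size / 365.0
                n_focals = int(round(max(0.0, rng.normal(mean_f, sd_f)) * frac))
                if n_focals == 0:
                    continue
                focal_days = np.sort(rng.choice(res_days, size=n_focals, replace=True))
                n_scans = rng.integers(lo_s, hi_s + 1, size=n_focals)
                scan_days = np.repeat(focal_days, n_scans)
                start_min = rng.integers(8 * 60, 14 * 60, size=n_focals)
                scan_min = np.concatenate(
                    [s + 10 * np.arange(k) for s, k in zip(start_min, n_scans)])
                total = scan_days.size
                acts = rng.choice(len(ACTIVITIES), size=total,
                                  p=[0.5, 0.3, 0.15, 0.05])
                neighbors: list[list[str]] = [[] for _ in range(total)]
                f_inf = _flag(scan_days, births[f])
                f_imm = _flag(scan_days, imm_entries[f])
                for p in females:
                    if p == f:
                        continue
                    p_res = _residency_mask(demography, p, group, scan_days)
                    if not p_res.any():
                        continue
                    p_inf = _flag(scan_days, births[p])
                    p_imm = _flag(scan_days, imm_entries[p])
                    both = f_inf & p_inf
                    one = f_inf ^ p_inf
                    imm = f_imm | p_imm
                    meanrank = 0.5 * (std_rank[f] + std_rank[p])
                    logit = (eff.beta0
                             + truth.affinity[frozenset((f, p))]
                             + eff.beta_rank_avg * meanrank
                             + eff.beta_both_infant * both
                             + eff.beta_one_infant * one
                             + eff.beta_immigrant * imm
                             + truth.female_re[f] + truth.female_re[p]
                             + w_year)
                    hit = p_res & (rng.random(total) < _logistic(logit))
                    for k in np.flatnonzero(hit):
                        neighbors[k].append(p)
                for k in range(total):
                    d = dt.date.fromordinal(int(scan_days[k]))
                    hh, mm = divmod(int(scan_min[k]), 60)
                    rows.append(("", d, f"{hh:02d}:{mm:02d}", group, f,
                                 ACTIVITIES[acts[k]], tuple(sorted(neighbors[k]))))
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    df = df.sort_values(["group_id", "date", "focal_id", "time"],
                        kind="mergesort").reset_index(drop=True)
    df["scan_id"] = [f"S{k:06d}" for k in range(1, len(df) + 1)]
    return df


def _residency_ordinals(demography: Demography, iid: str, group: str,
                        start: dt.date, end: dt.date) -> np.ndarray:
    chunks = []
    for t in demography[iid].tenures:
        if t.group_id != group:
            continue
        lo = max(t.entry_date, start)
        hi = min(t.exit_date or end, end)
        if lo < hi:
            chunks.append(np.arange(lo.toordinal(), hi.toordinal(), dtype=np.int64))
    return np.concatenate(chunks) if chunks else np.array([], dtype=np.int64)


def _residency_mask(demography: Demography, iid: str, group: str,
                    ordinals: np.ndarray) -> np.ndarray:
    mask = np.zeros(ordinals.shape, dtype=bool)
    for t in demography[iid].tenures:
        if t.group_id != group:
            continue
        lo = t.entry_date.toordinal()
        hi = t.exit_date.toordinal() if t.exit_date else np.iinfo(np.int64).max
        mask |= (ordinals >= lo) & (ordinals < hi)
    return mask


# ---------------------------------------------------------------------------

def simulate(scenario: ScenarioConfig) -> SimulatedData:
    """Run the full generator: demography, truth, agonistic events, scans.

    Deterministic given ``scenario`` (including its ``seed``)."""
    scenario.validate()
    r_dem, r_truth, r_ago, r_scan, _ = _rngs(scenario, 5)
    demography = simulate_demography(scenario, r_dem)
    truth = draw_truth(demography, scenario, r_truth)
    agonistic = simulate_agonistic(demography, truth, scenario, r_ago)
    scans = simulate_scans(demography, truth, scenario, r_scan)
    return SimulatedData(scenario, demography, truth, scans, agonistic)
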