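import datetime as dt
import itertools

import pandas as pd
import pytest

from gorillanet import (Demography, flag_dependent_infant, flag_new_immigrant,
                        flag_last_year, flag_new_alpha, first_scored_year,
                        female_number, group_size, build_model_tables,
                        ScenarioConfig, simulate, run_elo, build_rank_table,
                        calendar_window, build_network, networks_frame,
                        node_strength_frame)
from gorillanet.covariates import dependent_infant_days, is_scored_year, tenure_years

from conftest import D, make_female, make_male


def infant_days_oracle(birth, year):
    """Literal day loop: count days of `year` with infant age in [0, 365)."""
    n = 0
    d = dt.date(year, 1, 1)
    while d < dt.date(year + 1, 1, 1):
        if 0 <= (d - birth).days < 365:
            n += 1
        d += dt.timedelta(days=1)
    return n


class TestDependentInfant:
    def test_early_year_birth_flags_that_year(self):
        demog = Demography([make_female("A", births=["2015-01-15"])])
        assert flag_dependent_infant(demog, "A", 2015)
        assert not flag_dependent_infant(demog, "A", 2016)  # only ~14 days left

    def test_december_birth_flags_next_year_only(self):
        demog = Demography([make_female("A", births=["2015-12-01"])])
        assert not flag_dependent_infant(demog, "A", 2015)   # <= 31 days
        assert flag_dependent_infant(demog, "A", 2016)       # ~334 days

    def test_midsummer_boundary_is_strict(self):
        # born July 2 of a non-leap year: 183 days of that year under 1 y,
        # not strictly more than 183 -> not flagged
        demog = Demography([make_female("A", births=["2015-07-02"])])
        assert infant_days_oracle(D("2015-07-02"), 2015) == 183
        assert not flag_dependent_infant(demog, "A", 2015)
        # one day earlier crosses the threshold
        demog2 = Demography([make_female("A", births=["2015-07-01"])])
        assert flag_dependent_infant(demog2, "A", 2015)

    @pytest.mark.parametrize("birth", ["2014-03-05", "2015-02-28", "2015-06-30",
                                       "2015-07-03", "2015-11-11", "2016-01-01"])
    def test_day_counts_match_loop_oracle(self, birth):
        for year in (2014, 2015, 2016, 2017):
            assert dependent_infant_days(D(birth), year) == \
                infant_days_oracle(D(birth), year)


class TestNewImmigrant:
    def test_early_entry_flags_entry_year_only(self):
        demog = Demography([make_female("A", entry="2016-03-01",
                                        entry_type="immigration")])
        assert flag_new_immigrant(demog, "A", 2016)
        assert not flag_new_immigrant(demog, "A", 2017)
        assert is_scored_year(demog, "A", "G1", 2016)

    def test_late_entry_shifts_flag_to_next_year(self):
        demog = Demography([make_female("A", entry="2016-09-01",
                                        entry_type="immigration")])
        assert not flag_new_immigrant(demog, "A", 2016)
        assert flag_new_immigrant(demog, "A", 2017)
        assert not is_scored_year(demog, "A", "G1", 2016)  # entry year unscored
        assert is_scored_year(demog, "A", "G1", 2017)

    def test_july_first_entry_counts_as_early(self):
        demog = Demography([make_female("A", entry="2016-07-01",
                                        entry_type="immigration")])
        assert first_scored_year(D("2016-07-01")) == 2016
        assert first_scored_year(D("2016-07-02")) == 2017

    def test_natal_female_never_flagged(self):
        demog = Demography([make_female("A")])
        for year in range(2014, 2020):
            assert not flag_new_immigrant(demog, "A", year)


class TestLastYear:
    def test_emigration_next_year_flags_this_year(self):
        demog = Demography([make_female("A", exit="2018-05-10",
                                        exit_type="emigration")])
        assert flag_last_year(demog, "A", "G1", 2017)
        assert not flag_last_year(demog, "A", "G1", 2018)
        assert not flag_last_year(demog, "A", "G1", 2016)

    def test_death_never_flags(self):
        demog = Demography([make_female("A", exit="2018-05-10",
                                        exit_type="death")])
        assert not flag_last_year(demog, "A", "G1", 2017)

    def test_no_exit_never_flags(self):
        demog = Demography([make_female("A")])
        assert not any(flag_last_year(demog, "A", "G1", y)
                       for y in range(2014, 2025))


class TestNewAlpha:
    def test_identity_comparison(self):
        alphas = {("G1", 2015): "M0", ("G1", 2016): "M0", ("G1", 2017): "M1"}
        assert flag_new_alpha(alphas, "G1", 2016) is False
        assert flag_new_alpha(alphas, "G1", 2017) is True

    def test_unknown_previous_year_is_undefined(self):
        alphas = {("G1", 2015): "M0"}
        assert flag_new_alpha(alphas, "G1", 2015) is None


class TestGroupCounts:
    def test_majority_residency_rule(self):
        demog = Demography([
            make_female("A"),                                     # full year
            make_female("B", entry="2016-10-01",
                        entry_type="immigration"),                # 92 days
            make_female("C", exit="2016-09-01",
                        exit_type="emigration"),                  # 244 days
            make_male("M0"),
        ])
        assert female_number(demog, "G1", 2016) == 2              # A and C
        assert group_size(demog, "G1", 2016) == 3                 # + M0

    def test_tenure_years_at_midyear(self):
        demog = Demography([make_female("A", entry="2014-07-01")])
        assert tenure_years(demog, "A", "G1", 2016) == pytest.approx(2.0, abs=0.01)


@pytest.fixture(scope="module")
def pipeline_tables():
    sc = ScenarioConfig(seed=21)
    sim = simulate(sc)
    elo = run_elo(sim.agonistic, sim.demography)
    years = list(range(sc.start_year, sc.start_year + sc.years))
    ranks = build_rank_table(elo, sim.demography, years)
    nets = [build_network(sim.scans, sim.demography, calendar_window(g, y))
            for g in sim.demography.groups for y in years]
    ind, dyad = build_model_tables(node_strength_frame(nets),
                                   networks_frame(nets), ranks,
                                   sim.demography)
    return sim, ind, dyad


class TestBuildModelTables:
    def test_dyad_rows_are_pairs_of_scored_females(self, pipeline_tables):
        _, ind, dyad = pipeline_tables
        scored = set(map(tuple, ind[["group_id", "year", "id"]].to_numpy()))
        for r in dyad.itertuples(index=False):
            assert (r.group_id, r.year, r.id1) in scored
            assert (r.group_id, r.year, r.id2) in scored

    def test_dyad_count_is_choose_two_of_scored(self, pipeline_tables):
        _, ind, dyad = pipeline_tables
        n_scored = ind.groupby(["group_id", "year"]).size()
        n_dyads = dyad.groupby(["group_id", "year"]).size()
        for key, n in n_scored.items():
            expected = n * (n - 1) // 2
            assert n_dyads.get(key, 0) == expected

    def test_infant_category_consistent_with_individual_flags(self, pipeline_tables):
        sim, _, dyad = pipeline_tables
        for r in dyad.itertuples(index=False):
            fa = flag_dependent_infant(sim.demography, r.id1, r.year)
            fb = flag_dependent_infant(sim.demography, r.id2, r.year)
            expected = "both" if fa and fb else ("one" if fa or fb else "none")
            assert r.dependent_infant_cat == expected

    def test_first_year_dropped_for_unknown_alpha_history(self, pipeline_tables):
        _, ind, _ = pipeline_tables
        assert 2012 not in set(ind["year"])

    def test_row_count_matches_join_oracle(self, pipeline_tables):
        """Brute-force enumeration of scored female-years with all predictors
        defined equals the individual table's row set."""
        sim, ind, _ = pipeline_tables
        demog = sim.demography
        elo = run_elo(sim.agonistic, demog)
        years = list(range(2012, 2020))
        ranks = build_rank_table(elo, demog, years)
        ranked = {(r.group_id, int(r.year), r.id)
                  for r in ranks[ranks["sex"] == "female"].itertuples(index=False)}
        alpha_years = {(r.group_id, int(r.year))
                       for r in ranks[ranks["is_alpha"]].itertuples(index=False)}
        scans_by = sim.scans.groupby(
            ["group_id", "focal_id", sim.scans["date"].map(lambda d: d.year)]
        ).size()
        expected = set()
        for g in demog.groups:
            for y in years:
                y0, y1 = dt.date(y, 1, 1), dt.date(y + 1, 1, 1)
                for f in demog.residents_in_window(g, y0, y1, sex="female",
                                                   adult_only=True):
                    if not is_scored_year(demog, f, g, y):
                        continue
                    if scans_by.get((g, f, y), 0) == 0:
                        continue
                    if (g, y, f) not in ranked:
                        continue
                    if (g, y) not in alpha_years or (g, y - 1) not in alpha_years:
                        continue
                    expected.add((g, y, f))
        got = set(map(tuple, ind[["group_id", "year", "id"]].to_numpy()))
        assert got == expected

    def test_female_with_no_scans_dropped(self):
        demog = Demography([make_female("A"), make_female("B"),
                            make_female("C"), make_male("M0",
                                                        alpha_from="2014-01-01")])
        ranks = pd.DataFrame(
            [("G1", y, f, "female", 1000.0 + i, i / 2.0, False)
             for y in (2015, 2016) for i, f in enumerate("ABC")]
            + [("G1", y, "M0", "male", 1000.0, float("nan"), True)
               for y in (2015, 2016)],
            columns=["group_id", "year", "id", "sex", "mean_elo", "std_rank",
                     "is_alpha"])
        windows = [calendar_window("G1", 2015), calendar_window("G1", 2016)]
        from gorillanet.io import SCAN_COLUMNS
        rows = []
        for y in (2015, 2016):
            for f in ("A", "B"):    # C is never focal
                rows.append((f"S{y}{f}", dt.date(y, 6, 1), "08:00", "G1", f,
                             "feeding", ("C",) if f == "A" else ()))
        scans = pd.DataFrame(rows, columns=SCAN_COLUMNS)
        nets = [build_network(scans, demog, w) for w in windows]
        ind, dyad = build_model_tables(node_strength_frame(nets),
                                       networks_frame(nets), ranks, demog)
        assert "C" not in set(ind["id"])
        assert set(ind["year"]) == {2016}   # 2015 dropped: no 2014 alpha
        assert all("C" not in (r.id1, r.id2) for r in dyad.itertuples(index=False))
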