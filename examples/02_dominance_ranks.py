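"""Elo dominance hierarchies and yearly standardized ranks.

Each displacement/avoidance updates the winner's and loser's ratings
(start 1000, k = 100, bottom entry for newcomers).  Daily ratings are
averaged per calendar year and min-max standardized to [0, 1] among the
females of each group-year; the top-rated male is that year's alpha.
"""
from gorillanet import (ScenarioConfig, simulate, run_elo, build_rank_table,
                        elo_update)

print("single update, equal ratings:", elo_update(1000, 1000, k=100))

sim = simulate(ScenarioConfig(seed=1))
elo = run_elo(sim.agonistic, sim.demography)
ranks = build_rank_table(elo, sim.demography, years=list(range(2012, 2020)))

females = ranks[ranks["sex"] == "female"]
print("\nfemale ranks, one group-year:")
one = females[(females["group_id"] == "G1") & (females["year"] == 2015)]
print(one[["id", "mean_elo", "std_rank"]].to_string(index=False))

alphas = ranks[ranks["is_alpha"]]
print(f"\nalpha male assignments: {len(alphas)} group-years")
print(alphas[["group_id", "year", "id"]].head(8).to_string(index=False))
print()
print("std_rank 1 is the top-ranked female of her group that year, 0 the"
      " lowest; the alpha male is the male with the highest yearly mean Elo.")
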