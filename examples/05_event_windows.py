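"""Time-matched event-centred analysis.

Instead of calendar years, association is recomputed in 365-day windows
anchored on the date of a second infant birth within a dyad (offsets -2..+2)
or a female's immigration (offsets 0..+4).  The event dyads' series are
compared with all co-resident dyads over the same matched windows using a
per-condition smooth of strength over the offset.
"""
from gorillanet import (ScenarioConfig, Effects, simulate, find_events,
                        event_strength_series, compile_event_tables,
                        fit_event_gam, INFANT_GAM_SPEC)

effects = Effects(beta_rank_avg=0.0, beta_one_infant=0.0, beta_immigrant=0.0,
                  beta_both_infant=1.0, year_re_sd=0.0)
sim = simulate(ScenarioConfig(seed=204, effects=effects))

anchors = [a for a in find_events(sim.demography)
           if a.event_type == "second_birth"]
print(f"second-birth events found: {len(anchors)}")
series = [event_strength_series(sim.scans, sim.demography, a) for a in anchors]
infant, _ = compile_event_tables(series)
print(f"compiled rows: {len(infant)} "
      f"({int(infant['condition'].sum())} in the both-infant condition)")

print("\nmean strength by offset and condition:")
print(infant.groupby(["condition", "offset"])["strength"].mean()
      .unstack(0).round(3).to_string())

fit = fit_event_gam(INFANT_GAM_SPEC, infant, seed=204)
print("\nsmooth tests (per-condition spline over the offset):")
print(fit.smooth_tests.round(4).to_string(index=False))
print()
print("The both-infant dyads' strength should peak in the window that starts"
      " at the second birth (offset 0) and fall away afterwards; comparison"
      " dyads should stay flat, so only the 'yes' smooth is meaningful.")
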