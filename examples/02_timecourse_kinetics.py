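"""Stage-wise kinetics of the oxidation course.

Evaluates the packaged concentration trajectories on days 0-16 and reports the
per-stage degradation rates of the linoleic acyl groups, the share of that
loss accounted for by conjugated-diene hydroperoxide formation, and the
appearance/maximum events of a few marker oxylipins.
"""

from oxynmr import (
    StageScheme,
    detect_events,
    formation_fraction,
    make_timecourse,
    packaged_fixture,
    stage_rates,
)

tc = make_timecourse(packaged_fixture(), range(17))
scheme = StageScheme()  # breakpoints at days 0, 8, 11, 14, 16

rates = stage_rates(tc.series("linoleic"), scheme)
print("linoleic degradation rate per stage (mmol/mol TG per day):")
for (lo, hi), r in zip(scheme.stages, rates):
    print(f"  day {lo:4.0f} - {hi:4.0f}: {r:8.1f}")

ze = tc.series("mHPO_cZE_dE")
ee = tc.series("mHPO_cEE_dE")
total = [(d, a + b) for (d, a), (_, b) in zip(ze, ee)]
frac = formation_fraction(total, tc.series("linoleic"), (8.0, 11.0))
print(f"\ndays 8-11: hydroperoxide formation accounts for {frac:.0f}% of the")
print(f"linoleic loss; at least {100 - frac:.0f}% is routed to other products.")

print("\nevents (LOD 0.5 mmol/mol TG):")
for cid in ["mHPO_cEE_dE", "mHO_cZE_dE", "HPO_EPO_mE", "Z_EPO_Z_mE"]:
    ev = detect_events(tc.series(cid), lod=0.5)
    gone = f", gone day {ev.disappeared_day:.0f}" if ev.disappeared_day else ""
    print(f"  {cid:12s} appears day {ev.appearance_day:.0f}, "
          f"max {ev.max_value:6.1f} on day {ev.max_day:.0f}{gone}")
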