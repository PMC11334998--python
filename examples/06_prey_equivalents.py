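"""Translate daily energy expenditure into insect-intake equivalents.

With 75% assimilation efficiency, a 45.65 kJ/day budget needs 33 June
beetles (1.86 kJ each); one beetle fuels different activities for very
different durations.
"""

from hrenergetics.prey import (
    JUNE_BEETLE, PreyParams, fresh_mass_fraction, insects_needed,
    minutes_fueled, prey_report,
)

for label, dee in (("spring", 32.17), ("summer", 45.65)):
    count, exact = insects_needed(dee, JUNE_BEETLE)
    print(f"{label}: {count} beetles/day ({exact:.1f} exact) for {dee} kJ/day")

pct, _ = fresh_mass_fraction(10.6, 27.4)
print(f"10.6 g of midges on a 27.4 g bat = {pct}% of body mass")

for activity, rate in (("flight", 4.43), ("night resting", 2.12),
                       ("day resting", 1.42), ("torpor", 0.12)):
    print(f"one beetle fuels {minutes_fueled(JUNE_BEETLE, rate):6.1f} min of {activity}")

print(prey_report({"spring": 32.17, "summer": 45.65}, JUNE_BEETLE, 27.4).round(2))
# torpor is dramatically cheaper: a single beetle buys hours of torpor
# but only ~20 min of flight
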