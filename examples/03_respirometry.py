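"""Invert a multiplexed open-flow respirometry recording.

Four 800 ml chambers are pulled at 150 ml/min through a shared analyzer;
the forward model simulates washout dynamics, analyzer drift, CO2 lag and
water-vapour dilution, and the processing chain (discard, drift-correct,
lag-align, dry-correct, nitrogen balance) recovers the animals' VO2.
"""

from hrenergetics import respirometry, synth

chamber = synth.ChamberConfig()  # 800 ml, 150 ml/min, 4 chambers + baseline
trace, truth = synth.gen_respirometry(
    {"ch1": 25.0, "ch2": 40.0},  # ml O2/h per chamber
    chamber,
    duration_min=60,
    lag_co2_s=8.0,
    wvp_kpa=1.0,
    drift_o2=lambda t_s: 2e-7 * t_s,
    seed=3,
)

rates = respirometry.recover_metabolic_rates(trace)
summary = rates.groupby("channel")[["vo2_ml_h", "rer"]].mean().round(3)
print(summary)
met = respirometry.mass_specific_and_energy(
    rates.loc[rates["channel"] == "ch1"], mass_before_g=27.0, mass_after_g=27.8
)
print(f"\nch1 mean energy expenditure: {met.data['ee_kj_h'].mean():.3f} kJ/h "
      f"(body mass {met.body_mass_g:.1f} g)")
# recovered VO2 matches the injected 25 and 40 ml/h within ~1%; empty
# chambers read ~0
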