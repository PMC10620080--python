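"""Score a developmental delay from a mixed-culture pupation experiment.

Four replicate cultures are each seeded with 100 wild-type and 100
knock-in larvae; the knock-in genotype pupates on average 4 hours later.
The delay is estimated from observed pupation times and tested with the
culture-stratified log-rank (Mantel-Haenszel) test and pairwise t-tests on
per-culture means.
"""

from soadc import (
    TimingSimConfig,
    cumulative_emergence,
    generate_timing,
    mean_delay,
    pairwise_timing_tests,
    stratified_logrank,
)

records, truth = generate_timing(TimingSimConfig(seed=0))
print(f"cohort: {len(records)} larvae, planted shift {truth['shifts_hours']}")

delay = mean_delay(records, "WT", "SOA-KI")
print(f"estimated delay (SOA-KI - WT): {delay.delay_hours:.3f} h")
print("per-culture estimates:")
print(delay.per_culture[["culture", "delay_hours"]].to_string(index=False))

res = stratified_logrank(records, "WT", "SOA-KI")
print(f"stratified log-rank: chi2 = {res.statistic:.2f} (df=1), p = {res.p_value:.3g}")

table = pairwise_timing_tests(records)
print("pairwise t-tests on per-culture mean pupation times (BH-adjusted):")
print(table.to_string(index=False))

curve = cumulative_emergence(records)
half = curve[curve.fraction >= 0.5].groupby("genotype").time_hours.min()
print(f"median emergence time per genotype (h): {half.to_dict()}")
print()
print("A few-hour genotype shift is clearly detectable at this cohort size.")
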