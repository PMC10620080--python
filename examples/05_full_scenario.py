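"""End-to-end chain: timing phenotype -> fitness -> allele dynamics -> DC report.

Generates a pupation cohort, measures the male developmental delay,
converts it to a selection coefficient, simulates the antagonistic
dynamics with the splicing-evolution event, and writes all artifacts
(trajectory, sweep, DC report, summary) to a directory.
"""

from soadc.scenario import run_scenario

summary = run_scenario({"generations": 20_000, "seed": 0}, out_dir="scratch/scenario_demo")

print(open("scratch/scenario_demo/summary.txt").read())
print("Artifacts written to scratch/scenario_demo/:")
print("  timing_records.tsv, timing_per_culture.tsv, trajectory.tsv,")
print("  sweep.tsv, dc_report.tsv, summary.txt")
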