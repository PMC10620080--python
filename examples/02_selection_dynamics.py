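"""Fate of a male-beneficial, female-costly allele under antagonistic selection.

The allele is dominant in males (benefit s_m) and recessive in females
(cost s_f).  Both boundary invasion rates exceed one, so neither allele can
be lost: the population settles at a protected polymorphism.  Removing the
female cost (the evolution of sex-specific splicing, modelled as an event
at generation 5,000) releases the allele towards fixation.
"""

from soadc import (
    EventSchedule,
    FitnessScheme,
    classify_outcome,
    equilibrium,
    invasion_growth_rate,
    simulate_trajectory,
    sweep,
)

scheme = FitnessScheme(s_m=0.0177, s_f=0.02, h_m=1.0, h_f=0.0)
print(f"scheme: s_m={scheme.s_m}, s_f={scheme.s_f}, h_m={scheme.h_m}, h_f={scheme.h_f}")
print(f"invasion rate of the allele when rare : {invasion_growth_rate(scheme, 'plus_rare'):.5f}")
print(f"invasion rate of the wild type when rare: {invasion_growth_rate(scheme, 'minus_rare'):.5f}")
print(f"outcome: {classify_outcome(scheme)}")
print(f"interior equilibrium frequency: {equilibrium(scheme, tol=1e-10):.4f}")
print()

events = EventSchedule.from_triples([[5000, "s_f", 0.0]])
traj = simulate_trajectory(0.01, scheme, 150_000, events)
print("trajectory from p0 = 0.01 with splicing at generation 5,000:")
for gen in (0, 1000, 4999, 10_000, 50_000, 150_000):
    print(f"  generation {gen:>7}: p = {traj.p[gen]:.4f}")
print(f"  first generation with p > 0.999: {traj.generations_to_reach(0.999)}")
print()

table = sweep([0.005, 0.0177, 0.05], [0.0, 0.01, 0.05], n_generations=0)
print("grid sweep (no event; outcome and equilibrium per scheme):")
print(table[["s_m", "s_f", "outcome", "equilibrium"]].to_string(index=False))
print()
print("Any positive female cost yields coexistence; without one the allele fixes.")
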