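# Methods

This note documents the models, defaults, numerical choices and
limitations of `soadc`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The selection model

We model the dosage-compensation allele (`SOA+`) at a single autosomal
locus with two alleles, discrete non-overlapping generations, random
mating and an effectively infinite population (deterministic dynamics).
The state is the pair of allele frequencies among male-transmitted and
female-transmitted gametes, `(p_m, p_f)`. One generation consists of:

1. **Zygote formation.** Genotype frequencies among zygotes are the cross
   products of the two gamete pools — `AA = p_m p_f`,
   `Aa = p_m(1−p_f) + p_f(1−p_m)`, `aa = (1−p_m)(1−p_f)` — identical for
   sons and daughters.
2. **Sex-specific viability selection.** Relative viabilities are
   `(1, 1 + h_m s_m, 1 + s_m)` for (`--`, `+-`, `++`) males and
   `(1, 1 − h_f s_f, 1 − s_f)` for females, renormalized within each sex.
3. **Census.** The post-selection allele frequency among males becomes
   `p_m` of the next generation, and likewise for females. We census
   gametes after selection; zygote genotype frequencies are intermediate
   quantities. (A zygote census would shift exact trajectories slightly
   but not the plateau/fixation structure.)

Defaults are `h_m = 1` (the allele dominant in males) and `h_f = 0`
(recessive in females), the configuration in which a favoured allele is
expected to be dominant in the sex it benefits; both dominance values are
free parameters.

**Invasion analysis.** Linearizing at the monomorphic boundaries gives the
per-generation growth factor of the rare allele:

* rare `SOA+` in an all-wild-type population:
  `λ₊ = 1 + (h_m s_m − h_f s_f)/2`;
* rare wild-type in an all-`SOA+` population:
  `λ₋ = [(1 + h_m s_m)/(1 + s_m) + (1 − h_f s_f)/(1 − s_f)]/2`.

An allele invades iff its λ exceeds 1. With `h_m = 1`, `h_f = 0` and both
selection coefficients positive, `λ₊ = 1 + s_m/2 > 1` and
`λ₋ = [1 + 1/(1 − s_f)]/2 > 1`: both boundaries repel and the
polymorphism is protected.

**Outcome classification.** The classifier returns
`protected_polymorphism` (both λ > 1), `fixation_of_plus` (only λ₊ > 1),
`loss_of_plus` (only λ₋ > 1) or `neutral` (both λ = 1). These four cases
are not exhaustive: when dominance is reversed (the allele recessive where
favoured, dominant where costly) neither rare allele can invade, both
boundaries are stable and the outcome depends on the starting frequency.
We report this fifth case as `bistable`. Comparisons use a tolerance of
1e−12 on λ; schemes with a boundary exactly at λ = 1 (e.g. a cost that is
fully dominant, making the rare wild-type selectively neutral) fall on the
non-invading side and their approach to the boundary is algebraic rather
than geometric.

**Events.** A scheduled parameter change `(generation, name, value)` takes
effect before the selection step of its stated generation. The canonical
event is the evolution of sex-specific splicing, `(5000, s_f, 0)`. Events
beyond the simulated horizon are reported as a warning and never applied.

**Timescales.** With `h_m = 1` and `s_f = 0` the rare wild-type allele is
selectively neutral (`λ₋ = 1`), so fixation is approached only
algebraically: the wild-type frequency decays like `q ≈ 2/(s_m t)`.
Reaching `p ≥ 0.999` therefore takes on the order of `2000/s_m`
generations — about 1.2 × 10⁵ at `s_m = 0.0177` and 4 × 10⁵ at
`s_m = 0.005`. Sweep horizons in the acceptance checks are set to 10⁶
generations so the slowest grid corner completes its approach; the
"near-fixation" threshold for reporting is `p ≥ 0.999` (configurable).
The default initial frequency for trajectory runs is `p0 = 0.01`
(exposed as a flag); the plotted quantity is the overall allele frequency
`p = (p_m + p_f)/2`.

**Equilibrium solver.** Interior equilibria are found by iterating the
recursion from `p_m = p_f = 0.5` until the estimated distance to the fixed
point — `Δ·r/(1−r)` for step size Δ and empirical contraction rate r —
falls below the tolerance (default 1e−12, iteration cap 10⁷). The
iteration runs in extended (80-bit) precision because under weak selection
r approaches 1 and the required step sizes sit below the double-precision
rounding floor. Boundary outcomes are resolved analytically from the
invasion analysis. The solver is validated against a 10⁵-generation
brute-force iteration oracle on a selection-coefficient grid.

## Fitness mapping

Developmental time maps to viability through constant daily mortality:
with daily survival probability σ, completing development Δ hours sooner
multiplies survival to adulthood by `σ^(−Δ/24)`, so
`s = σ^(−Δ/24) − 1` and inversely `Δ = −24 ln(1+s)/ln σ`. Defaults
σ = 0.9 and Δ = 4 h give `s_m = 0.0177` (reported to four decimals; full
precision is propagated). The mapping assumes age-independent,
density-independent daily survival; no uncertainty propagation is
attempted beyond sweeping σ and s ranges in the selection model.

## Timing analysis

Pupation is the event of a time-to-event analysis. Individuals that die
before pupating are right-censored at their death time; this is a
convention of ours, as is treating each replicate culture as a stratum.

* **Cumulative emergence** divides observed events at or before t by the
  number seeded, per genotype (and culture); with several cultures the
  mean curve across cultures carries a normal-approximation 95% band.
* **Mean delay** is the difference of mean observed pupation times
  between two genotypes, with a per-culture breakdown. Because the
  genotypes share cultures (mixed rearing), culture-level pace offsets
  cancel from the contrast.
* **Stratified log-rank (Mantel–Haenszel).** Within each stratum, at each
  distinct event time, the observed events in group a are compared with
  the hypergeometric expectation from the risk sets; ties use the
  standard multiple-events-per-time hypergeometric variance. O−E and V
  sum over times and strata; `(ΣO−E)²/ΣV` is referred to χ²(1). The
  single-stratum case is cross-checked against an independent reference
  implementation, and the null rejection rate is verified by simulation.
* **Pairwise t-tests** act by default on per-culture mean pupation times
  (respecting the replicate structure; switchable to per-individual
  times), with Benjamini–Hochberg step-up adjustment across the genotype
  pairs.

## Dosage-compensation metrics

* **Expressed-gene filter:** mean raw count across the reference
  replicates ≥ 10.
* **Normalization.** Default is median-of-ratios size factors **anchored
  on autosomal genes**. Total-count scaling (available as `"total"`) is
  not composition-robust: when the X (~8% of genes here) shifts twofold,
  it transfers a ≈0.06 log2 bias onto every gene. Even the classic
  all-gene median-of-ratios reference drifts by a few percent in the same
  situation, because the shifted X subpopulation smears into the bulk of
  the ratio distribution under counting noise. Anchoring the size factors
  on autosomes — the genes a DC contrast presumes unchanged — removes
  both effects; `"none"` is available for pre-normalized data.
* **Per-gene log2FC** is `log2(mean_a/mean_b)` on normalized counts;
  genes with zero total count are dropped, and with the default ε = 0 a
  gene must have a positive mean in both conditions. A pseudocount is
  available but not default: ε shrinks a twofold chromosome-wide change
  toward zero by roughly `ε/(μ ln 2)` at gene mean μ, which is material
  relative to the bootstrap CI of a median over ~10³ genes.
* **Arm medians** carry percentile-bootstrap 95% CIs (default 2,000
  resamples, seeded; genes resampled within arm; values sorted first so
  results are gene-order invariant). Arms with fewer than two genes are
  omitted rather than raised.
* **X-overrepresentation** builds a 2×2 table of observed X vs autosomal
  hits against the same total distributed by a null: `gene_proportional`
  (each arm's share of universe genes — the default, matching the scale
  of published enrichment p-values) or `arm_uniform` (1/5 per arm),
  expected counts rounded to nearest integer; one-sided Fisher exact test
  for X excess. The exact construction of "homogeneously distributed"
  expected counts admits both readings, so both are provided and neither
  printed p-value is treated as a reproduction target.
* **Cluster summaries** report the median linear fold change per
  binding-strength cluster and two-sided Wilcoxon rank-sum tests between
  clusters, Bonferroni-corrected; clusters under 3 genes are flagged
  `low_n`.

## Synthetic data

The timing generator emulates the mixed-culture developmental assay: 4
replicate cultures × 100 neonate larvae per genotype; a gamma base
time-to-pupation distribution with mean 216 h (9 days) and SD 12 h
(log-normal available); a per-culture offset (SD 3 h) drawn once and
shared by all genotypes in the culture; a genotype shift map (default
WT 0 h, knock-in +4 h); and a 5% death-before-pupation probability,
emitted as right-censored records at a uniform fraction (0.3–0.9) of the
would-be pupation time. The distributions and the mortality level are our
choices of a plausible larval-rearing scale; the cohort geometry and the
+4 h shift are the study conditions.

The expression generator draws per-gene means from a log-normal
(log-mean 4, log-SD 1.5), then negative-binomial counts (dispersion 0.1,
so `var = μ + 0.1 μ²`) for 4 samples per condition over arm gene counts
approximating the *A. gambiae* complement (X 1,000; 2R 3,600; 2L 2,900;
3R 2,900; 3L 2,500). The second condition's X means are scaled by
`2^(−(1−c))`; cluster labels are assigned to X genes at the
strong/intermediate/weak proportions 50:230:577, and an optional
cluster-factor map grades knockout/rescue effects; log-normal library
factors (SD 0.1 on the log scale) multiply the means last. Truth sidecars
record every planted quantity.

What the generators do **not** emulate: batch effects, GC/length biases,
gene–gene correlation, differential dispersion, developmental-stage
mixtures, non-proportional hazards in timing, or genotyping error.
Passing recovery tests therefore demonstrates estimator correctness under
the stated sampling model, not robustness to these real-data features.

## Reproducibility plumbing

All randomness flows through explicit seeds (one `numpy` Generator per
generator call; no hidden global state). Every CLI invocation writes a
`manifest.yaml` with the subcommand, resolved configuration, seeds and
package version. TSV is the universal interchange format; scenario
configuration is YAML. Exit codes are 0/1/2 for ok/user error/internal
error.

## Known limitations

* The selection model is deterministic: no drift (finite N), mutation,
  migration, X-linkage or overlapping generations. The locus is modelled
  as autosomal even though the trait concerns the X chromosome's
  regulation — the regulator's own linkage is not represented.
* The fitness mapping compresses all life-history consequences of timing
  into a single daily-survival exponent.
* The log2FC definition is a transparent normalized ratio, not a
  shrinkage estimator from a differential-expression model; values for
  low-count genes are noisier than a moderated analysis would give.
* The bootstrap CI for an arm median has asymptotic, not exact, coverage;
  the suite checks it empirically at one configuration.
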