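"""Quantify dosage compensation from a male/female expression table.

A synthetic count table places the male X at half the female level
(compensation c = 0, i.e. no dosage compensation).  The per-arm median
log2(male/female) should sit near -1 on the X and near 0 on autosomes.
An X-overrepresentation Fisher test and binding-cluster summaries follow.
"""

from soadc import (
    ExprSimConfig,
    chromosome_median_log2fc,
    cluster_fc_summary,
    filter_expressed,
    gene_log2fc,
    generate_expression,
    x_overrepresentation_test,
)

counts, meta, annotation, truth = generate_expression(ExprSimConfig(compensation=0.0, seed=0))
print(f"table: {counts.shape[0]} genes x {counts.shape[1]} samples, planted c = {truth['compensation']}")

expressed, per_arm = filter_expressed(counts, annotation)
print(f"expressed genes (mean count >= 10): {len(expressed)}; per arm: {per_arm.to_dict()}")

fc = gene_log2fc(expressed, meta, "male", "female", annotation=annotation)
report = chromosome_median_log2fc(fc, annotation, seed=0)
print("per-arm median log2(male/female) with bootstrap 95% CI:")
print(report.to_string(index=False))

# strongly male-downregulated genes should be X-enriched when DC is absent
hits = fc[fc.log2fc < -0.8].index
fisher = x_overrepresentation_test(hits, annotation)
print(f"\n{len(hits)} genes with log2FC < -0.8: {fisher.table[0, 0]} X-linked "
      f"(expected {fisher.table[1, 0]}); one-sided Fisher p = {fisher.p_value:.3g}")

# cluster-graded knockdown scenario
ki = ExprSimConfig(
    compensation=1.0, condition_labels=("WT", "KI"),
    cluster_factors={"1": 0.608, "2": 0.8, "3": 0.95}, seed=0,
)
counts2, meta2, ann2, truth2 = generate_expression(ki)
fc2 = gene_log2fc(counts2, meta2, "KI", "WT", annotation=ann2)
x_genes = ann2[ann2.arm == "X"].gene
per_cluster, comparisons = cluster_fc_summary(fc2.loc[fc2.index.intersection(x_genes)], ann2)
print("\nknockdown scenario, per-binding-cluster median fold change:")
print(per_cluster[["cluster", "n_genes", "median_fold_change"]].to_string(index=False))
print("rank-sum comparisons (Bonferroni-adjusted):")
print(comparisons.to_string(index=False))
print()
print("The X median tracks the planted compensation level; the strongest-bound")
print("cluster shows the deepest knockdown, mirroring a graded regulatory effect.")
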