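"""Expression-level dosage-compensation statistics.

Dosage compensation (DC) equalizes X-linked expression between XY males
(one X) and XX females (two X copies).  With a compensation level c in
[0, 1] the expected male:female expression ratio on the X is
``2**(-(1 - c))``: -1 on the log2 scale with no compensation, 0 with full
compensation.  This module quantifies that signal from gene x sample count
tables: an expressed-gene filter, per-gene log2 fold changes on
composition-robust normalized counts, per-chromosome-arm medians with
percentile-bootstrap confidence intervals, a Fisher construction for
X-overrepresentation among hit genes, and fold-change summaries across
binding-strength clusters.

Counts are pandas DataFrames (genes x samples); sample metadata is a
DataFrame with columns ``sample, condition[, replicate]``; gene annotation
is a DataFrame with columns ``gene, arm[, cluster]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHROMOSOME_ARMS",
    "ExpressionDataError",
    "FisherResult",
    "normalize_counts",
    "filter_expressed",
    "gene_log2fc",
    "chromosome_median_log2fc",
    "x_overrepresentation_test",
    "cluster_fc_summary",
]

CHROMOSOME_ARMS = ("X", "2R", "2L", "3R", "3L")
_KNOWN_ARMS = CHROMOSOME_ARMS + ("UNKN",)


class ExpressionDataError(ValueError):
    """Counts, metadata or annotation violate the expected layout."""


def _check_annotation(annotation: pd.DataFrame, genes) -> pd.DataFrame:
    if "gene" not in annotation.columns or "arm" not in annotation.columns:
        raise ExpressionDataError("annotation needs 'gene' and 'arm' columns")
    unknown = set(annotation["arm"].unique()) - set(_KNOWN_ARMS)
    if unknown:
        raise ExpressionDataError(f"unknown chromosome arm labels: {sorted(unknown)}")
    ann = annotation.set_index("gene")
    missing = [g for g in genes if g not in ann.index]
    if missing:
        raise ExpressionDataError(f"{len(missing)} genes lack an annotation (e.g. {missing[:3]})")
    return ann


def normalize_counts(
    counts: pd.DataFrame,
    method: str = "median_ratio",
    reference_genes=None,
) -> pd.DataFrame:
    """Library-normalize a genes x samples count table.

    ``median_ratio`` (default) is the median-of-ratios scheme: each sample
    is divided by the median ratio of its counts to the per-gene geometric
    mean (computed over genes expressed everywhere).  ``reference_genes``
    restricts the size-factor estimation to a subset presumed unchanged —
    for dosage-compensation contrasts the autosomal genes, since the X
    shifts wholesale between the sexes and would otherwise drag the size
    factors with it.  ``total`` divides by the sample total and rescales
    to the median total; it is simpler but transfers any chromosome-wide
    change onto the unchanged genes.
    """
    if (counts.to_numpy() < 0).any():
        raise ExpressionDataError("counts must be non-negative")
    if method == "none":
        return counts.copy()
    if method == "total":
        totals = counts.sum(axis=0)
        factors = totals / np.median(totals.to_numpy())
    elif method == "median_ratio":
        ref = counts if reference_genes is None else counts.loc[counts.index.intersection(reference_genes)]
        positive = ref[(ref > 0).all(axis=1)]
        if len(positive) == 0:
            raise ExpressionDataError("no reference gene is expressed in every sample")
        logs = np.log(positive.to_numpy())
        log_ref = logs.mean(axis=1)
        size = np.exp(np.median(logs - log_ref[:, None], axis=0))
        # centre factors at 1 so normalized values stay on the counts scale
        factors = pd.Series(size / np.median(size), index=counts.columns)
    else:
        raise ExpressionDataError(f"unknown normalization method {method!r}")
    return counts / factors


def filter_expressed(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: list[str] | None = None,
    min_mean_count: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expressed-gene filter: mean raw count across replicates >= threshold.

    ``samples`` restricts the averaging to a reference condition's
    replicates (e.g. wild-type males); the default averages across all
    samples.  Returns the expressed subset of the count table and the
    per-arm tally of expressed genes.
    """
    ann = _check_annotation(annotation, counts.index)
    use = counts if samples is None else counts[samples]
    keep = use.mean(axis=1) >= min_mean_count
    expressed = counts[keep]
    per_arm = (
        ann.loc[expressed.index, "arm"]
        .value_counts()
        .reindex(_KNOWN_ARMS, fill_value=0)
        .rename("n_expressed")
    )
    return expressed, per_arm


def gene_log2fc(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.0,
    normalization: str = "median_ratio",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change of condition_a over condition_b.

    Counts are library-normalized, means are taken per condition, and
    ``log2((mean_a + eps) / (mean_b + eps))`` is reported together with the
    mean abundance over both conditions.  Genes with zero total raw count
    are dropped (the read-count > 0 filter).  When an annotation is given,
    median-of-ratios size factors are anchored on autosomal genes, so a
    wholesale X shift (the DC signal itself) cannot distort them.  With
    ``pseudocount=0`` the statistic is exactly antisymmetric in the two
    conditions.
    """
    for cond in (condition_a, condition_b):
        if not (metadata["condition"] == cond).any():
            raise ExpressionDataError(f"condition {cond!r} has no samples")
    samples_a = metadata.loc[metadata["condition"] == condition_a, "sample"].tolist()
    samples_b = metadata.loc[metadata["condition"] == condition_b, "sample"].tolist()

    reference_genes = None
    if annotation is not None:
        ann = _check_annotation(annotation, counts.index)
        arms = ann.loc[counts.index, "arm"]
        reference_genes = arms[(arms != "X") & (arms != "UNKN")].index
    keep = counts[samples_a + samples_b].sum(axis=1) > 0
    norm = normalize_counts(
        counts[samples_a + samples_b][keep], method=normalization, reference_genes=reference_genes
    )
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    if pseudocount == 0:
        # restrict to genes where the ratio is defined
        ok = (mean_a > 0) & (mean_b > 0)
        mean_a, mean_b = mean_a[ok], mean_b[ok]
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0**log2fc,
            "mean_abundance": 0.5 * (mean_a + mean_b),
        }
    )


def chromosome_median_log2fc(
    fc_table: pd.DataFrame,
    annotation: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-arm median log2 fold change with a percentile bootstrap 95% CI.

    Genes are resampled with replacement within each arm ``n_boot`` times;
    the 2.5/97.5 percentiles of the resampled medians form the CI.  Arms
    with fewer than two genes are omitted from the result rather than
    raising.
    """
    ann = _check_annotation(annotation, fc_table.index)
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    arms = ann.loc[fc_table.index, "arm"]
    for arm in CHROMOSOME_ARMS:
        vals = fc_table.loc[arms[arms == arm].index, "log2fc"].to_numpy()
        if vals.size < 2:
            continue
        vals = np.sort(vals)  # make the resampling gene-order invariant
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_medians = np.median(vals[idx], axis=1)
        lo, hi = np.percentile(boot_medians, [2.5, 97.5])
        rows.append(
            {
                "arm": arm,
                "n_genes": int(vals.size),
                "median_log2fc": float(np.median(vals)),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows, columns=["arm", "n_genes", "median_log2fc", "ci_low", "ci_high"])


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    table: np.ndarray  # [[obs X, obs autosomal], [expected X, expected autosomal]]
    n_hits: int


def x_overrepresentation_test(
    hit_genes,
    universe_annotation: pd.DataFrame,
    null_mode: str = "gene_proportional",
) -> FisherResult:
    """One-sided Fisher test for excess X-linked genes among hits.

    The observed row of the 2x2 table counts X vs autosomal hits; the
    expected row distributes the same total number of genes according to
    the null: ``gene_proportional`` by each arm's share of universe genes
    (the X's genomic gene fraction), ``arm_uniform`` equally over the five
    arms (1/5 on the X), expected counts rounded to nearest integer.  The
    alternative is an excess of X hits.
    """
    hit_genes = list(hit_genes)
    if len(hit_genes) == 0:
        raise ExpressionDataError("hit set is empty")
    ann = _check_annotation(universe_annotation, hit_genes)
    arms = ann["arm"]
    hit_arms = arms.loc[hit_genes]
    placeable = hit_arms[hit_arms != "UNKN"]
    n_hits = len(placeable)
    obs_x = int((placeable == "X").sum())
    obs_auto = n_hits - obs_x

    if null_mode == "gene_proportional":
        universe = arms[arms != "UNKN"]
        x_share = (universe == "X").mean()
    elif null_mode == "arm_uniform":
        x_share = 1.0 / len(CHROMOSOME_ARMS)
    else:
        raise ExpressionDataError(f"unknown null_mode {null_mode!r}")
    exp_x = int(round(n_hits * x_share))
    exp_auto = n_hits - exp_x

    table = np.array([[obs_x, obs_auto], [exp_x, exp_auto]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return FisherResult(float(p), float(odds), table, n_hits)


def cluster_fc_summary(
    fc_table: pd.DataFrame,
    annotation: pd.DataFrame,
    min_cluster_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change summaries across binding-strength clusters of X genes.

    Returns ``(per_cluster, comparisons)``: the median linear-scale fold
    change per cluster (clusters below ``min_cluster_size`` flagged
    ``low_n``), and two-sided Wilcoxon rank-sum tests on the log2 fold
    changes between every cluster pair, Bonferroni-corrected across the
    pairs.  A single cluster yields an empty comparison table.
    """
    ann = _check_annotation(annotation, fc_table.index)
    if "cluster" not in ann.columns:
        raise ExpressionDataError("annotation lacks a 'cluster' column")
    clusters = ann.loc[fc_table.index, "cluster"]
    labelled = clusters[clusters.notna() & (clusters.astype(str) != "none")]
    if len(labelled) == 0:
        raise ExpressionDataError("no genes carry a cluster label")

    groups: dict = {}
    rows = []
    for label in sorted(labelled.unique(), key=str):
        vals = fc_table.loc[labelled[labelled == label].index, "log2fc"].to_numpy()
        groups[label] = vals
        rows.append(
            {
                "cluster": label,
                "n_genes": int(vals.size),
                "median_fold_change": float(2.0 ** np.median(vals)),
                "median_log2fc": float(np.median(vals)),
                "low_n": vals.size < min_cluster_size,
            }
        )
    per_cluster = pd.DataFrame(rows)

    pairs = list(combinations(sorted(groups, key=str), 2))
    comp_rows = []
    for a, b in pairs:
        stat, p = stats.ranksums(groups[a], groups[b])
        comp_rows.append({"cluster_a": a, "cluster_b": b, "statistic": float(stat), "p_value": float(p)})
    comparisons = pd.DataFrame(comp_rows, columns=["cluster_a", "cluster_b", "statistic", "p_value"])
    if len(comparisons):
        comparisons["p_adjusted"] = np.minimum(comparisons["p_value"] * len(pairs), 1.0)
    else:
        comparisons["p_adjusted"] = pd.Series(dtype=float)
    return per_cluster, comparisons
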