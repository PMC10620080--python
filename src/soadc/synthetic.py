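"""Seeded generators for pupation-time cohorts and expression count tables.

Both generators emit exactly the tabular dialects the analysis stages
consume, together with a "truth sidecar" recording every planted effect,
so each estimator can be tested for recovery without any external data.

The timing generator emulates a mixed rearing experiment: replicate
cultures seeded with a fixed number of neonate larvae per genotype, a
shared per-culture pace offset, a genotype-specific shift of a few hours,
and an optional probability of dying before pupation (emitted as a
right-censored record).  The expression generator emulates bulk RNA-seq
over the five chromosome arms with negative-binomial counts, a male X
expressed at ``2**(-(1 - c))`` of the female level for compensation level
c, optional binding-cluster-graded effects, and per-sample library-size
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CHROMOSOME_ARMS

__all__ = ["TimingSimConfig", "ExprSimConfig", "generate_timing", "generate_expression"]


@dataclass
class TimingSimConfig:
    """Cohort geometry and effect sizes for the pupation-time generator.

    Defaults mirror the mixed-culture developmental assay: 100 neonate
    larvae per genotype in each of 4 replicate cultures, a wild-type
    cohort and a knock-in cohort pupating 4 h later, a gamma base
    time-to-pupation distribution centred at 9 days (216 h) with a 12 h
    spread, and a 3 h culture-to-culture pace offset.
    """

    n_per_genotype: int = 100
    n_cultures: int = 4
    shifts_hours: dict = field(default_factory=lambda: {"WT": 0.0, "SOA-KI": 4.0})
    distribution: str = "gamma"  # or "lognormal"
    mean_hours: float = 216.0
    sd_hours: float = 12.0
    culture_sd_hours: float = 3.0
    death_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 1 or self.n_cultures < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not self.shifts_hours:
            raise ValueError("shift map must cover at least one genotype")
        if not (0 <= self.death_prob <= 1):
            raise ValueError("death_prob must be in [0, 1]")
        if self.distribution not in ("gamma", "lognormal"):
            raise ValueError(f"unknown base distribution {self.distribution!r}")
        if self.mean_hours <= 0 or self.sd_hours <= 0:
            raise ValueError("mean_hours and sd_hours must be positive")


def generate_timing(config: TimingSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a pupation-record table and its truth sidecar.

    Individual time = base draw + culture offset + genotype shift.  The
    culture offset is drawn once per culture and shared by all genotypes
    reared in it (the genotypes are mixed in one tray), so within-culture
    genotype contrasts are unaffected by it.  Deaths occur with
    ``death_prob`` and are right-censored at a uniformly drawn fraction of
    the individual's would-be pupation time.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    offsets = rng.normal(0.0, config.culture_sd_hours, size=config.n_cultures)
    genotypes = list(config.shifts_hours)

    rows = {k: [] for k in ("individual", "genotype", "sex", "culture", "time_hours", "observed")}
    counter = 0
    for c in range(config.n_cultures):
        for genotype in genotypes:
            n = config.n_per_genotype
            base = _base_draw(rng, config, n)
            times = base + offsets[c] + config.shifts_hours[genotype]
            dead = rng.random(n) < config.death_prob
            death_frac = rng.uniform(0.3, 0.9, size=n)
            final = np.where(dead, times * death_frac, times)
            sexes = rng.choice(["male", "female"], size=n)
            for i in range(n):
                rows["individual"].append(f"ind{counter:05d}")
                counter += 1
            rows["genotype"].extend([genotype] * n)
            rows["sex"].extend(sexes.tolist())
            rows["culture"].extend([f"culture{c + 1}"] * n)
            rows["time_hours"].extend(np.round(final, 3).tolist())
            rows["observed"].extend((~dead).tolist())

    records = pd.DataFrame(rows)
    truth = {
        "shifts_hours": dict(config.shifts_hours),
        "culture_offsets_hours": {f"culture{c + 1}": float(offsets[c]) for c in range(config.n_cultures)},
        "mean_hours": config.mean_hours,
        "sd_hours": config.sd_hours,
        "death_prob": config.death_prob,
        "seed": config.seed,
    }
    return records, truth


def _base_draw(rng: np.random.Generator, config: TimingSimConfig, n: int) -> np.ndarray:
    mean, sd = config.mean_hours, config.sd_hours
    if config.distribution == "gamma":
        shape = (mean / sd) ** 2
        return rng.gamma(shape, sd**2 / mean, size=n)
    sigma2 = np.log1p(sd**2 / mean**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


@dataclass
class ExprSimConfig:
    """Gene counts, effect sizes and noise model for the expression generator.

    Gene counts per arm approximate the A. gambiae gene complement (~1,000
    X-linked genes of ~13,000 total).  Per-gene mean expression is
    log-normal; counts are negative-binomial with a common dispersion.
    ``compensation`` is the DC level c: the second condition's X genes are
    scaled by ``2**(-(1 - c))`` relative to the first (c=1 full DC, c=0
    none).  ``cluster_factors`` optionally multiplies the second
    condition's X means by a binding-cluster-specific factor (knockout or
    rescue scenarios); cluster assignment proportions default to the
    strong/intermediate/weak split of expressed X genes (50:230:577).
    """

    genes_per_arm: dict = field(
        default_factory=lambda: {"X": 1000, "2R": 3600, "2L": 2900, "3R": 2900, "3L": 2500}
    )
    samples_per_condition: int = 4
    condition_labels: tuple = ("female", "male")
    mean_log_mu: float = 4.0
    mean_log_sigma: float = 1.5
    dispersion: float = 0.1
    compensation: float = 1.0
    cluster_proportions: tuple = (50 / 857, 230 / 857, 577 / 857)
    cluster_factors: dict | None = None
    libsize_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.compensation <= 1):
            raise ValueError("compensation must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if abs(sum(self.cluster_proportions) - 1) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        unknown = set(self.genes_per_arm) - set(CHROMOSOME_ARMS)
        if unknown:
            raise ValueError(f"unknown arms in genes_per_arm: {sorted(unknown)}")


def generate_expression(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw a count table, sample metadata, gene annotation and truth sidecar.

    Per-gene means are drawn once and shared by both conditions; the
    second condition's X means are scaled by the compensation factor and,
    where given, by the cluster factor.  Counts are NB(mean, dispersion)
    per sample with a log-normal library-size factor applied to the means
    last.  Returns ``(counts, metadata, annotation, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    arms = []
    for arm in CHROMOSOME_ARMS:
        arms.extend([arm] * config.genes_per_arm.get(arm, 0))
    arms = np.array(arms)
    n_genes = len(arms)
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)])

    base_means = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, size=n_genes)

    is_x = arms == "X"
    clusters = np.full(n_genes, "none", dtype=object)
    clusters[is_x] = rng.choice(
        ["1", "2", "3"], size=int(is_x.sum()), p=list(config.cluster_proportions)
    )

    dc_factor = 2.0 ** (-(1.0 - config.compensation))
    cond_b_means = base_means.copy()
    cond_b_means[is_x] *= dc_factor
    if config.cluster_factors:
        for label, factor in config.cluster_factors.items():
            mask = is_x & (clusters == str(label))
            cond_b_means[mask] *= float(factor)

    cond_a, cond_b = config.condition_labels
    n_rep = config.samples_per_condition
    sample_names, conditions, replicates = [], [], []
    for cond in (cond_a, cond_b):
        for r in range(1, n_rep + 1):
            sample_names.append(f"{cond}_{r}")
            conditions.append(cond)
            replicates.append(r)
    libsizes = rng.lognormal(0.0, config.libsize_sigma, size=len(sample_names))

    size = 1.0 / config.dispersion  # NB shape: var = mu + dispersion * mu^2
    counts = np.empty((n_genes, len(sample_names)), dtype=np.int64)
    for j, cond in enumerate(conditions):
        mu = (base_means if cond == cond_a else cond_b_means) * libsizes[j]
        counts[:, j] = rng.negative_binomial(size, size / (size + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_names)
    metadata = pd.DataFrame({"sample": sample_names, "condition": conditions, "replicate": replicates})
    annotation = pd.DataFrame({"gene": genes, "arm": arms, "cluster": clusters})
    truth = {
        "compensation": config.compensation,
        "dc_factor": float(dc_factor),
        "expected_x_log2fc": float(np.log2(dc_factor)),
        "cluster_factors": dict(config.cluster_factors or {}),
        "library_factors": {s: float(f) for s, f in zip(sample_names, libsizes)},
        "condition_labels": list(config.condition_labels),
        "seed": config.seed,
    }
    return counts_df, metadata, annotation, truth
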