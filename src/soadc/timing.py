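"""Developmental-timing analysis from individual pupation records.

Pupation is treated as the event of a time-to-event analysis: larvae that
have not yet pupated remain at risk, and individuals that die before
pupation (or are still larvae at study end) are right-censored at the time
they leave observation.  Replicate rearing cultures are the strata of the
stratified log-rank (Mantel-Haenszel) test, so culture-to-culture shifts in
overall pace do not masquerade as genotype effects.

Records are tidy pandas DataFrames with columns
``individual, genotype, sex, culture, time_hours, observed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REQUIRED_COLUMNS",
    "TimingDataError",
    "LogrankResult",
    "MeanDelayResult",
    "validate_records",
    "cumulative_emergence",
    "mean_delay",
    "stratified_logrank",
    "pairwise_timing_tests",
]

REQUIRED_COLUMNS = ("individual", "genotype", "sex", "culture", "time_hours", "observed")


class TimingDataError(ValueError):
    """Pupation records violate the expected layout or content."""


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise TimingDataError(f"records are missing columns: {missing}")
    if len(records) == 0:
        raise TimingDataError("records are empty")
    if (records["time_hours"] < 0).any():
        raise TimingDataError("time_hours must be non-negative")
    return records


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed_minus_expected: float
    variance: float


@dataclass(frozen=True)
class MeanDelayResult:
    """Signed difference of mean pupation times (group b minus group a)."""

    delay_hours: float
    per_culture: pd.DataFrame


def cumulative_emergence(records: pd.DataFrame, average_cultures: bool = True) -> pd.DataFrame:
    """Cumulative fraction of each genotype's cohort pupated over time.

    Per genotype (and culture) the curve is a right-continuous step
    function: at time t, the number of observed pupation events at or
    before t divided by the number of individuals seeded.  Censored
    individuals never pupate, so curves can plateau below 1.

    With ``average_cultures=True`` and more than one culture, curves are
    evaluated on the genotype's pooled event-time grid, averaged across
    cultures, and a normal-approximation 95% CI band over cultures is
    attached (zero-width when cultures are identical).

    Returns a tidy frame with columns
    ``genotype, time_hours, fraction[, ci_low, ci_high]``.
    """
    validate_records(records)
    out = []
    for genotype, grp in records.groupby("genotype", sort=True, observed=True):
        if len(grp) == 0:
            raise TimingDataError(f"genotype group {genotype!r} is empty")
        times = np.unique(grp.loc[grp["observed"].astype(bool), "time_hours"].to_numpy())
        if times.size == 0:
            raise TimingDataError(f"genotype group {genotype!r} has no observed events")
        cultures = grp["culture"].unique()
        if average_cultures and len(cultures) > 1:
            per_culture = np.empty((len(cultures), times.size))
            for i, culture in enumerate(cultures):
                sub = grp[grp["culture"] == culture]
                per_culture[i] = _ecdf_at(sub, times)
            mean = per_culture.mean(axis=0)
            sem = per_culture.std(axis=0, ddof=1) / np.sqrt(len(cultures))
            frame = pd.DataFrame(
                {
                    "genotype": genotype,
                    "time_hours": times,
                    "fraction": mean,
                    "ci_low": np.clip(mean - 1.96 * sem, 0, 1),
                    "ci_high": np.clip(mean + 1.96 * sem, 0, 1),
                }
            )
        else:
            frame = pd.DataFrame(
                {
                    "genotype": genotype,
                    "time_hours": times,
                    "fraction": _ecdf_at(grp, times),
                }
            )
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def _ecdf_at(group: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    event_times = np.sort(group.loc[group["observed"].astype(bool), "time_hours"].to_numpy())
    return np.searchsorted(event_times, times, side="right") / len(group)


def mean_delay(records: pd.DataFrame, genotype_a: str, genotype_b: str) -> MeanDelayResult:
    """Difference of mean observed pupation times, genotype_b minus genotype_a.

    Censored records carry no pupation time and are excluded from the
    means.  Also returns the per-culture breakdown (cultures containing
    observed events of both genotypes).
    """
    validate_records(records)
    obs = records[records["observed"].astype(bool)]
    means = {}
    for g in (genotype_a, genotype_b):
        if not (records["genotype"] == g).any():
            raise TimingDataError(f"genotype {g!r} not present in records")
        sub = obs.loc[obs["genotype"] == g, "time_hours"]
        if len(sub) == 0:
            raise TimingDataError(f"genotype {g!r} has no uncensored pupation events")
        means[g] = sub.mean()

    rows = []
    for culture, grp in obs.groupby("culture", sort=True, observed=True):
        a = grp.loc[grp["genotype"] == genotype_a, "time_hours"]
        b = grp.loc[grp["genotype"] == genotype_b, "time_hours"]
        if len(a) and len(b):
            rows.append(
                {
                    "culture": culture,
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "delay_hours": b.mean() - a.mean(),
                    "n_a": len(a),
                    "n_b": len(b),
                }
            )
    per_culture = pd.DataFrame(rows, columns=["culture", "mean_a", "mean_b", "delay_hours", "n_a", "n_b"])
    return MeanDelayResult(means[genotype_b] - means[genotype_a], per_culture)


def stratified_logrank(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    strata: str = "culture",
) -> LogrankResult:
    """Stratified log-rank (Mantel-Haenszel) test between two genotypes.

    Within each stratum, at each distinct event time the observed number
    of events in group a is compared with its hypergeometric expectation
    given the risk sets, with the tie-corrected hypergeometric variance.
    O - E and V are summed over event times and strata;
    ``statistic = (sum(O - E))**2 / sum(V)`` is referred to chi-square
    with 1 df.  A single stratum reduces to the ordinary log-rank test.
    """
    validate_records(records)
    sub = records[records["genotype"].isin([group_a, group_b])]
    if not (sub["genotype"] == group_a).any() or not (sub["genotype"] == group_b).any():
        raise TimingDataError("both groups must be present in the records")
    if not sub["observed"].astype(bool).any():
        raise TimingDataError("no pupation events in the pooled data")

    oe_sum = 0.0
    var_sum = 0.0
    for _, grp in sub.groupby(strata, sort=False, observed=True):
        time = grp["time_hours"].to_numpy(dtype=float)
        event = grp["observed"].to_numpy(dtype=bool)
        in_a = (grp["genotype"] == group_a).to_numpy()
        oe, var = _logrank_stratum(time, event, in_a)
        oe_sum += oe
        var_sum += var

    if var_sum == 0:
        raise TimingDataError("log-rank variance is zero: no between-group information")
    statistic = oe_sum * oe_sum / var_sum
    p = float(stats.chi2.sf(statistic, df=1))
    return LogrankResult(float(statistic), 1, p, float(oe_sum), float(var_sum))


def _logrank_stratum(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> tuple[float, float]:
    """Summed O-E and hypergeometric variance for one stratum."""
    ev_t = time[event]
    if ev_t.size == 0:
        return 0.0, 0.0
    event_times, d_total = np.unique(ev_t, return_counts=True)
    d_total = d_total.astype(float)
    # events in group a at each distinct event time
    a_times = time[event & in_a]
    d_a = np.bincount(
        np.searchsorted(event_times, a_times), minlength=event_times.size
    ).astype(float)

    # risk set at t: individuals whose (event or censoring) time is >= t
    order = np.argsort(time)
    t_sorted = time[order]
    a_sorted = in_a[order].astype(float)
    n_total = len(time)
    cum_a = np.concatenate([[0.0], np.cumsum(a_sorted)])

    idx = np.searchsorted(t_sorted, event_times, side="left")
    n_at_risk = (n_total - idx).astype(float)
    a_at_risk = cum_a[-1] - cum_a[idx]

    frac_a = a_at_risk / n_at_risk
    oe = float(np.sum(d_a - d_total * frac_a))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = (
            d_total
            * frac_a
            * (1.0 - frac_a)
            * (n_at_risk - d_total)
            / np.where(n_at_risk > 1, n_at_risk - 1.0, np.nan)
        )
    var = float(np.nansum(var_terms))
    return oe, var


def pairwise_timing_tests(
    records: pd.DataFrame,
    genotypes: list[str] | None = None,
    summary: str = "culture_mean",
) -> pd.DataFrame:
    """Two-sided pairwise t-tests between genotypes with BH adjustment.

    By default each replicate culture contributes one summary value (the
    mean observed pupation time of the genotype in that culture), which
    respects the replicate structure; ``summary="individual"`` switches to
    per-pupa times.  Benjamini-Hochberg correction is applied across the
    family of genotype pairs (step-up on the sorted p-values).
    """
    validate_records(records)
    obs = records[records["observed"].astype(bool)]
    if genotypes is None:
        genotypes = sorted(obs["genotype"].unique())
    if len(genotypes) < 2:
        raise TimingDataError("need at least two genotypes to compare")

    samples: dict[str, np.ndarray] = {}
    for g in genotypes:
        sub = obs[obs["genotype"] == g]
        if summary == "culture_mean":
            vals = sub.groupby("culture", observed=True)["time_hours"].mean().to_numpy()
            if len(vals) < 2:
                raise TimingDataError(
                    f"genotype {g!r} has fewer than 2 replicate cultures with events"
                )
        elif summary == "individual":
            vals = sub["time_hours"].to_numpy()
            if len(vals) < 2:
                raise TimingDataError(f"genotype {g!r} has fewer than 2 observed events")
        else:
            raise TimingDataError(f"unknown summary {summary!r}")
        samples[g] = vals

    rows = []
    for a, b in combinations(genotypes, 2):
        t_stat, p = stats.ttest_ind(samples[a], samples[b])
        rows.append({"genotype_a": a, "genotype_b": b, "t_statistic": float(t_stat), "p_value": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table
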