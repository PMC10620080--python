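"""Deterministic one-locus, two-allele model of sex-differential viability selection.

The model tracks the frequency of a derived allele (``SOA+``) that is
beneficial in males and, before the evolution of sex-specific splicing,
deleterious in females.  Generations are discrete and non-overlapping, the
locus is autosomal and mating is random: zygotes are formed from the male-
and female-transmitted gamete pools, sex-specific viabilities act on the
three genotypes, and the post-selection allele frequencies in each sex
become the next generation's gamete pools.

Relative viabilities of the genotypes (``--``, ``+-``, ``++``) are

* males:   ``1,  1 + h_m*s_m,  1 + s_m``
* females: ``1,  1 - h_f*s_f,  1 - s_f``

where ``s_m`` is the selection differential favouring the allele in males,
``s_f`` the differential against it in females, and ``h_m``, ``h_f`` the
dominance coefficients.  All computations here are deterministic; no random
number generator is used anywhere in this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitnessScheme",
    "EventSchedule",
    "PopulationState",
    "Trajectory",
    "SelectionModelError",
    "EquilibriumError",
    "zygote_genotype_frequencies",
    "next_generation",
    "simulate_trajectory",
    "invasion_growth_rate",
    "classify_outcome",
    "equilibrium",
    "sweep",
]

_PARAM_NAMES = ("s_m", "s_f", "h_m", "h_f")


class SelectionModelError(ValueError):
    """Invalid input to the selection model."""


class EquilibriumError(RuntimeError):
    """Equilibrium iteration failed to converge; carries the last state."""

    def __init__(self, message: str, last_state: "PopulationState"):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class FitnessScheme:
    """Selection and dominance parameters of the two-sex viability model.

    Parameters
    ----------
    s_m
        Selection differential in favour of the derived allele in males
        (``>= 0``).
    s_f
        Selection differential against the derived allele in females
        (``0 <= s_f < 1`` so that all female viabilities stay positive).
    h_m, h_f
        Dominance of the derived allele in males and females, in [0, 1].
        Defaults are full dominance in males and full recessivity in
        females, the configuration under which a male-beneficial,
        female-costly allele is protected at both boundaries.
    """

    s_m: float
    s_f: float
    h_m: float = 1.0
    h_f: float = 0.0

    def __post_init__(self) -> None:
        if not (self.s_m >= 0):
            raise SelectionModelError(f"s_m must be >= 0, got {self.s_m}")
        if not (0 <= self.s_f < 1):
            raise SelectionModelError(f"s_f must be in [0, 1), got {self.s_f}")
        for name in ("h_m", "h_f"):
            h = getattr(self, name)
            if not (0 <= h <= 1):
                raise SelectionModelError(f"{name} must be in [0, 1], got {h}")
        if min(self.male_fitnesses() + self.female_fitnesses()) <= 0:
            raise SelectionModelError("all genotype fitnesses must be positive")

    def male_fitnesses(self) -> tuple[float, float, float]:
        """Viabilities of (``--``, ``+-``, ``++``) males."""
        return (1.0, 1.0 + self.h_m * self.s_m, 1.0 + self.s_m)

    def female_fitnesses(self) -> tuple[float, float, float]:
        """Viabilities of (``--``, ``+-``, ``++``) females."""
        return (1.0, 1.0 - self.h_f * self.s_f, 1.0 - self.s_f)

    def with_parameter(self, name: str, value: float) -> "FitnessScheme":
        if name not in _PARAM_NAMES:
            raise SelectionModelError(f"unknown scheme parameter {name!r}")
        return replace(self, **{name: float(value)})


@dataclass(frozen=True)
class EventSchedule:
    """Parameter changes applied at the start of scheduled generations.

    Each event is a ``(generation, parameter, value)`` triple; the change
    takes effect before the selection step of its stated generation.  The
    canonical use is the evolution of sex-specific splicing, modelled as
    ``(5000, "s_f", 0.0)``.
    """

    events: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self) -> None:
        prev = -1
        for gen, name, _ in self.events:
            if gen < 0 or int(gen) != gen:
                raise SelectionModelError(f"event generation must be a non-negative integer, got {gen}")
            if gen <= prev:
                raise SelectionModelError("event generations must be strictly increasing")
            if name not in _PARAM_NAMES:
                raise SelectionModelError(f"unknown scheme parameter {name!r}")
            prev = gen

    @classmethod
    def from_triples(cls, triples: Iterable[Sequence]) -> "EventSchedule":
        return cls(tuple((int(g), str(n), float(v)) for g, n, v in triples))

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class PopulationState:
    """Allele frequency among male- and female-transmitted gametes."""

    p_m: float
    p_f: float
    generation: int = 0

    def __post_init__(self) -> None:
        for name in ("p_m", "p_f"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise SelectionModelError(f"{name} must be in [0, 1], got {p}")

    @property
    def p(self) -> float:
        """Overall allele frequency, the mean of the two gamete pools."""
        return 0.5 * (self.p_m + self.p_f)


@dataclass
class Trajectory:
    """Per-generation record of a deterministic simulation.

    All arrays share the same length and generations run consecutively
    from 0.  ``p`` is the overall allele frequency ``(p_m + p_f) / 2``.
    The four scheme columns record the parameter values in force during
    each generation's selection step, so scheduled events are visible in
    the export.
    """

    generation: np.ndarray
    p_m: np.ndarray
    p_f: np.ndarray
    s_m: np.ndarray
    s_f: np.ndarray
    h_m: np.ndarray
    h_f: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return 0.5 * (self.p_m + self.p_f)

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(float(self.p_m[-1]), float(self.p_f[-1]), int(self.generation[-1]))

    def __len__(self) -> int:
        return len(self.generation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "p": self.p,
                "p_m": self.p_m,
                "p_f": self.p_f,
                "s_m": self.s_m,
                "s_f": self.s_f,
                "h_m": self.h_m,
                "h_f": self.h_f,
            }
        )

    def generations_to_reach(self, threshold: float) -> int | None:
        """First generation at which overall p >= threshold, or None."""
        hits = np.nonzero(self.p >= threshold)[0]
        return int(self.generation[hits[0]]) if hits.size else None


def zygote_genotype_frequencies(p_m: float, p_f: float) -> tuple[float, float, float]:
    """Genotype frequencies (``--``, ``+-``, ``++``) among zygotes.

    Zygotes unite one male-transmitted and one female-transmitted gamete,
    so the frequencies are the cross products of the two pools.  They are
    identical for sons and daughters (the locus is autosomal).
    """
    if not (0 <= p_m <= 1) or not (0 <= p_f <= 1):
        raise SelectionModelError("gamete frequencies must be in [0, 1]")
    aa = (1.0 - p_m) * (1.0 - p_f)
    het = p_m * (1.0 - p_f) + p_f * (1.0 - p_m)
    AA = p_m * p_f
    return (aa, het, AA)


def _step(
    p_m: float,
    p_f: float,
    wm: tuple[float, float, float],
    wf: tuple[float, float, float],
) -> tuple[float, float]:
    # Scalar inner recursion, kept free of object overhead: long runs
    # (10^5-10^6 generations) iterate this directly.
    aa = (1.0 - p_m) * (1.0 - p_f)
    het = p_m + p_f - 2.0 * p_m * p_f
    AA = p_m * p_f
    wbar_m = aa * wm[0] + het * wm[1] + AA * wm[2]
    wbar_f = aa * wf[0] + het * wf[1] + AA * wf[2]
    new_m = (AA * wm[2] + 0.5 * het * wm[1]) / wbar_m
    new_f = (AA * wf[2] + 0.5 * het * wf[1]) / wbar_f
    # clip defensively against rounding at the boundaries
    return (min(max(new_m, 0.0), 1.0), min(max(new_f, 0.0), 1.0))


def next_generation(state: PopulationState, scheme: FitnessScheme) -> PopulationState:
    """One generation of random mating followed by sex-specific selection.

    Zygote genotypes are formed from the current gamete pools, sex-specific
    viabilities are applied and renormalized within each sex, and the
    returned frequencies are the post-selection allele frequencies among
    males and females respectively.
    """
    wm = scheme.male_fitnesses()
    wf = scheme.female_fitnesses()
    p_m, p_f = _step(state.p_m, state.p_f, wm, wf)
    return PopulationState(p_m, p_f, state.generation + 1)


def simulate_trajectory(
    p0: float,
    scheme: FitnessScheme,
    n_generations: int,
    events: EventSchedule | None = None,
) -> Trajectory:
    """Iterate the recursion for ``n_generations``, recording every generation.

    ``p0`` seeds both gamete pools.  Scheduled parameter changes take
    effect before the selection step of their stated generation; events
    scheduled beyond the horizon are never applied and raise a warning.
    """
    if not (0 <= p0 <= 1):
        raise SelectionModelError(f"p0 must be in [0, 1], got {p0}")
    if n_generations < 0:
        raise SelectionModelError("n_generations must be >= 0")
    events = events or EventSchedule()
    late = [e for e in events if e[0] > n_generations]
    if late:
        warnings.warn(
            f"{len(late)} event(s) scheduled beyond generation {n_generations} are never applied",
            stacklevel=2,
        )

    n = n_generations + 1
    arr_pm = np.empty(n)
    arr_pf = np.empty(n)
    arr_sm = np.empty(n)
    arr_sf = np.empty(n)
    arr_hm = np.empty(n)
    arr_hf = np.empty(n)

    pending = list(events)
    p_m = p_f = float(p0)
    current = scheme
    wm = current.male_fitnesses()
    wf = current.female_fitnesses()
    for gen in range(n):
        while pending and pending[0][0] == gen:
            _, name, value = pending.pop(0)
            current = current.with_parameter(name, value)
            wm = current.male_fitnesses()
            wf = current.female_fitnesses()
        arr_pm[gen] = p_m
        arr_pf[gen] = p_f
        arr_sm[gen] = current.s_m
        arr_sf[gen] = current.s_f
        arr_hm[gen] = current.h_m
        arr_hf[gen] = current.h_f
        if gen < n_generations:
            p_m, p_f = _step(p_m, p_f, wm, wf)

    return Trajectory(np.arange(n), arr_pm, arr_pf, arr_sm, arr_sf, arr_hm, arr_hf)


def invasion_growth_rate(scheme: FitnessScheme, boundary: str) -> float:
    """Per-generation growth factor of the rare allele at a boundary.

    Linearizing the recursion at the two monomorphic boundaries gives

    * rare derived allele in an all-ancestral population:
      ``lambda_plus = 1 + (h_m*s_m - h_f*s_f) / 2``
    * rare ancestral allele in an all-derived population:
      ``lambda_minus = ((1 + h_m*s_m)/(1 + s_m) + (1 - h_f*s_f)/(1 - s_f)) / 2``

    The rare allele invades iff its growth factor exceeds 1; both factors
    exceeding 1 is a protected polymorphism.

    Parameters
    ----------
    boundary
        ``"plus_rare"`` for the all-ancestral boundary, ``"minus_rare"``
        for the all-derived boundary.
    """
    if boundary == "plus_rare":
        return 1.0 + 0.5 * (scheme.h_m * scheme.s_m - scheme.h_f * scheme.s_f)
    if boundary == "minus_rare":
        return 0.5 * (
            (1.0 + scheme.h_m * scheme.s_m) / (1.0 + scheme.s_m)
            + (1.0 - scheme.h_f * scheme.s_f) / (1.0 - scheme.s_f)
        )
    raise SelectionModelError(f"boundary must be 'plus_rare' or 'minus_rare', got {boundary!r}")


def classify_outcome(scheme: FitnessScheme, tol: float = 1e-12) -> str:
    """Classify the deterministic long-run outcome from the boundary analysis.

    Returns one of ``fixation_of_plus``, ``loss_of_plus``,
    ``protected_polymorphism``, ``neutral`` or ``bistable``.  ``bistable``
    covers schemes at which neither rare allele invades (e.g. the derived
    allele recessive in males and dominant in females): both boundaries
    are locally stable and the outcome depends on the starting frequency.
    """
    lam_plus = invasion_growth_rate(scheme, "plus_rare")
    lam_minus = invasion_growth_rate(scheme, "minus_rare")
    plus_invades = lam_plus > 1 + tol
    minus_invades = lam_minus > 1 + tol
    if plus_invades and minus_invades:
        return "protected_polymorphism"
    if plus_invades:
        return "fixation_of_plus"
    if minus_invades:
        return "loss_of_plus"
    if abs(lam_plus - 1) <= tol and abs(lam_minus - 1) <= tol:
        return "neutral"
    return "bistable"


def equilibrium(
    scheme: FitnessScheme,
    tol: float = 1e-12,
    max_iter: int = 10_000_000,
    p0: float = 0.5,
) -> float:
    """Stable equilibrium allele frequency reached from an interior start.

    Boundary outcomes are resolved analytically from the invasion analysis
    (fixation returns 1.0, loss returns 0.0; a neutral scheme leaves every
    frequency fixed, so ``p0`` is returned).  Interior equilibria are found
    by iterating the recursion from ``p_m = p_f = p0`` until
    ``|dp_m| + |dp_f| < tol``.
    """
    if tol <= 0:
        raise SelectionModelError("tol must be positive")
    outcome = classify_outcome(scheme)
    if outcome == "fixation_of_plus":
        return 1.0
    if outcome == "loss_of_plus":
        return 0.0
    if outcome == "neutral":
        return float(p0)

    # extended precision keeps the rounding floor far below tol, so the
    # geometric error bound (distance ~ delta * r / (1 - r)) stays reachable
    # even under weak selection where the convergence rate approaches 1
    ld = np.longdouble
    wm = tuple(ld(w) for w in scheme.male_fitnesses())
    wf = tuple(ld(w) for w in scheme.female_fitnesses())
    p_m = p_f = ld(p0)
    prev_delta = math.inf
    for it in range(max_iter):
        new_m, new_f = _step(p_m, p_f, wm, wf)
        delta = abs(new_m - p_m) + abs(new_f - p_f)
        p_m, p_f = new_m, new_f
        if delta == 0.0:
            return float(0.5 * (p_m + p_f))
        # only trust the rate estimate once the iteration is near the fixed point
        rate = delta / prev_delta
        if math.isfinite(prev_delta) and delta < math.sqrt(tol):
            if rate < 1 and delta * rate / (1 - rate) < 0.1 * tol:
                return float(0.5 * (p_m + p_f))
        if delta < tol and delta >= prev_delta:
            # step size has hit the rounding floor
            return float(0.5 * (p_m + p_f))
        prev_delta = delta
    raise EquilibriumError(
        f"no convergence within {max_iter} iterations (tol={tol})",
        PopulationState(p_m, p_f, max_iter),
    )


def sweep(
    s_m_values: Sequence[float],
    s_f_values: Sequence[float],
    h_m: float = 1.0,
    h_f: float = 0.0,
    events: EventSchedule | None = None,
    n_generations: int = 10_000,
    p0: float = 0.01,
    near_fixation: float = 0.999,
) -> pd.DataFrame:
    """Grid sweep over (s_m, s_f): outcome, equilibrium and time to fixation.

    One row per grid point.  ``outcome`` and ``equilibrium`` describe the
    base scheme (before any scheduled events); ``generations_to_near_fixation``
    is measured on a trajectory from ``p0`` with the events applied, and is
    NaN when overall p never reaches ``near_fixation`` within the horizon.
    Deterministic given the grid.
    """
    rows = []
    for s_m in s_m_values:
        for s_f in s_f_values:
            scheme = FitnessScheme(s_m=float(s_m), s_f=float(s_f), h_m=h_m, h_f=h_f)
            outcome = classify_outcome(scheme)
            eq = equilibrium(scheme, tol=1e-10) if outcome != "bistable" else math.nan
            gens, final_p = _run_fast(p0, scheme, n_generations, events, near_fixation)
            rows.append(
                {
                    "s_m": float(s_m),
                    "s_f": float(s_f),
                    "h_m": float(h_m),
                    "h_f": float(h_f),
                    "outcome": outcome,
                    "equilibrium": eq,
                    "generations_to_near_fixation": math.nan if gens is None else gens,
                    "final_p": final_p,
                }
            )
    columns = [
        "s_m",
        "s_f",
        "h_m",
        "h_f",
        "outcome",
        "equilibrium",
        "generations_to_near_fixation",
        "final_p",
    ]
    return pd.DataFrame(rows, columns=columns)


def _run_fast(
    p0: float,
    scheme: FitnessScheme,
    n_generations: int,
    events: EventSchedule | None,
    threshold: float | None,
):
    """Iterate without recording.

    Returns ``(first generation with overall p >= threshold or None, final p)``.
    One full pass over the horizon; used by :func:`sweep` where recording
    every generation of a 10^5-10^6 generation run would be wasteful.
    """
    pending = [e for e in events if e[0] <= n_generations] if events else []
    p_m = p_f = float(p0)
    current = scheme
    wm = current.male_fitnesses()
    wf = current.female_fitnesses()
    hit = None
    if threshold is not None and 0.5 * (p_m + p_f) >= threshold:
        hit = 0
    for gen in range(1, n_generations + 1):
        if pending and pending[0][0] == gen - 1:
            while pending and pending[0][0] == gen - 1:
                _, name, value = pending.pop(0)
                current = current.with_parameter(name, value)
            wm = current.male_fitnesses()
            wf = current.female_fitnesses()
        p_m, p_f = _step(p_m, p_f, wm, wf)
        if hit is None and threshold is not None and 0.5 * (p_m + p_f) >= threshold:
            hit = gen
    return hit, 0.5 * (p_m + p_f)
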