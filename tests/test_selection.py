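"""Unit and property tests for the sexually antagonistic selection model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soadc.selection import (
    EventSchedule,
    FitnessScheme,
    PopulationState,
    SelectionModelError,
    classify_outcome,
    equilibrium,
    invasion_growth_rate,
    next_generation,
    simulate_trajectory,
    sweep,
    zygote_genotype_frequencies,
)

NEUTRAL = FitnessScheme(0.0, 0.0)
DEFAULT = FitnessScheme(0.0177, 0.02, h_m=1.0, h_f=0.0)

schemes = st.builds(
    FitnessScheme,
    s_m=st.floats(0, 0.2),
    s_f=st.floats(0, 0.2),
    h_m=st.floats(0, 1),
    h_f=st.floats(0, 1),
)


class TestZygoteFrequencies:
    @pytest.mark.parametrize(
        "p_m,p_f,expected",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0)),
            (1.0, 0.5, (0.0, 0.5, 0.5)),
            (0.1, 0.1, (0.81, 0.18, 0.01)),
        ],
    )
    def test_examples(self, p_m, p_f, expected):
        result = zygote_genotype_frequencies(p_m, p_f)
        assert result == pytest.approx(expected, abs=1e-12)

    @given(p_m=st.floats(0, 1), p_f=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one_and_symmetric(self, p_m, p_f):
        aa, het, AA = zygote_genotype_frequencies(p_m, p_f)
        assert aa + het + AA == pytest.approx(1.0, abs=1e-12)
        assert zygote_genotype_frequencies(p_f, p_m) == pytest.approx((aa, het, AA))

    def test_out_of_range_rejected(self):
        with pytest.raises(SelectionModelError):
            zygote_genotype_frequencies(-0.1, 0.5)


class TestRecursion:
    def test_hand_arithmetic_oracle(self):
        """Single step from p=0.1 under the default antagonistic scheme.

        Expected values from explicit arithmetic: zygotes (0.81, 0.18, 0.01);
        mean fitness 1.003363 (males) and 0.9998 (females);
        p_m' = 0.10177/1.003363, p_f' = 0.0998/0.9998.
        """
        state = next_generation(PopulationState(0.1, 0.1), DEFAULT)
        assert state.p_m == pytest.approx(0.10177 / 1.003363, abs=1e-9)
        assert state.p_f == pytest.approx(0.0998 / 0.9998, abs=1e-9)
        assert state.p_m == pytest.approx(0.101429, abs=1e-6)
        assert state.p_f == pytest.approx(0.099820, abs=1e-6)
        assert state.generation == 1

    def test_neutral_scheme_is_identity(self):
        state = next_generation(PopulationState(0.5, 0.5), NEUTRAL)
        assert (state.p_m, state.p_f) == (0.5, 0.5)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_boundaries_absorbing(self, p0):
        state = next_generation(PopulationState(p0, p0), DEFAULT)
        assert (state.p_m, state.p_f) == (p0, p0)

    @given(scheme=schemes, p_m=st.floats(0, 1), p_f=st.floats(0, 1))
    @settings(max_examples=150, deadline=None)
    def test_frequencies_stay_in_unit_interval(self, scheme, p_m, p_f):
        state = next_generation(PopulationState(p_m, p_f), scheme)
        assert 0 <= state.p_m <= 1
        assert 0 <= state.p_f <= 1

    @given(scheme=schemes, p_m=st.floats(0.05, 0.95), p_f=st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_sex_swap_symmetry(self, scheme, p_m, p_f):
        """Exchanging the sexes' roles together with the allele labels maps
        the model to itself.

        Relabelling the allele turns the male benefit (1, 1+h s, 1+s) into a
        male cost with s' = s/(1+s) and dominance 1-h, and the female cost
        into a benefit with s' = s/(1-s), so the mirrored scheme is
        (s_m' = s_f/(1-s_f), s_f' = s_m/(1+s_m), h_m' = 1-h_f, h_f' = 1-h_m)
        with both sexes' frequencies complemented and swapped.
        """
        mirrored = FitnessScheme(
            s_m=scheme.s_f / (1 - scheme.s_f),
            s_f=scheme.s_m / (1 + scheme.s_m),
            h_m=1 - scheme.h_f,
            h_f=1 - scheme.h_m,
        )
        fwd = next_generation(PopulationState(p_m, p_f), scheme)
        mir = next_generation(PopulationState(1 - p_m, 1 - p_f), mirrored)
        assert mir.p_m == pytest.approx(1 - fwd.p_f, abs=1e-9)
        assert mir.p_f == pytest.approx(1 - fwd.p_m, abs=1e-9)


class TestTrajectory:
    def test_neutral_trajectory_constant(self):
        traj = simulate_trajectory(0.3, NEUTRAL, 50)
        assert np.allclose(traj.p, 0.3)
        assert np.array_equal(traj.generation, np.arange(51))

    def test_fixation_without_female_cost(self):
        """A male-beneficial allele with no female cost sweeps to fixation."""
        traj = simulate_trajectory(0.01, FitnessScheme(0.0177, 0.0), 150_000)
        assert traj.p[-1] > 0.999
        assert np.all(np.diff(traj.p) >= -1e-15)  # non-decreasing

    def test_plateau_then_fixation_after_splicing_event(self):
        """Antagonism holds the allele at an interior plateau; removing the
        female cost at generation 5,000 releases it towards fixation."""
        events = EventSchedule.from_triples([[5000, "s_f", 0.0]])
        traj = simulate_trajectory(0.01, DEFAULT, 150_000, events)
        eq = equilibrium(DEFAULT, tol=1e-10)
        assert traj.p[4999] == pytest.approx(eq, abs=1e-3)  # plateaued pre-event
        assert 0 < eq < 1
        assert traj.p[-1] > 0.999
        # the recorded scheme history shows the event
        assert traj.s_f[4999] == pytest.approx(0.02)
        assert traj.s_f[5000] == 0.0

    def test_event_beyond_horizon_warns(self):
        events = EventSchedule.from_triples([[100, "s_f", 0.0]])
        with pytest.warns(UserWarning, match="never applied"):
            simulate_trajectory(0.1, DEFAULT, 50, events)

    def test_event_schedule_validation(self):
        with pytest.raises(SelectionModelError):
            EventSchedule.from_triples([[10, "s_f", 0.0], [5, "s_m", 0.01]])
        with pytest.raises(SelectionModelError):
            EventSchedule.from_triples([[10, "nope", 0.0]])

    @given(scheme=schemes, p0=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_frequencies_bounded_along_trajectory(self, scheme, p0):
        traj = simulate_trajectory(p0, scheme, 200)
        assert np.all(traj.p_m >= 0) and np.all(traj.p_m <= 1)
        assert np.all(traj.p_f >= 0) and np.all(traj.p_f <= 1)


class TestInvasion:
    def test_growth_rate_formulas(self):
        assert invasion_growth_rate(FitnessScheme(0.0177, 0.03), "plus_rare") == pytest.approx(1.00885)
        assert invasion_growth_rate(NEUTRAL, "plus_rare") == 1.0
        assert invasion_growth_rate(NEUTRAL, "minus_rare") == 1.0
        assert invasion_growth_rate(DEFAULT, "minus_rare") > 1  # protected

    @pytest.mark.parametrize(
        "scheme,boundary",
        [
            (DEFAULT, "plus_rare"),
            (DEFAULT, "minus_rare"),
            (FitnessScheme(0.05, 0.05, h_m=0.3, h_f=0.6), "plus_rare"),
            (FitnessScheme(0.05, 0.05, h_m=0.3, h_f=0.6), "minus_rare"),
        ],
    )
    def test_matches_simulated_growth_of_rare_allele(self, scheme, boundary):
        """The analytic growth factor equals the measured one-generation
        growth of an allele at frequency 1e-6 to relative error < 1e-4."""
        eps = 1e-6
        if boundary == "plus_rare":
            state = next_generation(PopulationState(eps, eps), scheme)
            measured = state.p / eps
        else:
            state = next_generation(PopulationState(1 - eps, 1 - eps), scheme)
            measured = (1 - state.p) / eps
        lam = invasion_growth_rate(scheme, boundary)
        assert measured == pytest.approx(lam, rel=1e-4)

    def test_unknown_boundary_rejected(self):
        with pytest.raises(SelectionModelError):
            invasion_growth_rate(DEFAULT, "sideways")


class TestClassification:
    @pytest.mark.parametrize(
        "scheme,expected",
        [
            (DEFAULT, "protected_polymorphism"),
            (FitnessScheme(0.0177, 0.0), "fixation_of_plus"),
            (NEUTRAL, "neutral"),
            (FitnessScheme(0.0, 0.03, h_f=0.5), "loss_of_plus"),
            (FitnessScheme(0.02, 0.02, h_m=0.0, h_f=1.0), "bistable"),
        ],
    )
    def test_examples(self, scheme, expected):
        assert classify_outcome(scheme) == expected

    def test_agrees_with_boundary_escape_simulation(self):
        """On 120 random schemes away from the neutral margin, the analytic
        classification matches a brute-force escape/decay check simulated
        from near both boundaries."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 120:
            scheme = FitnessScheme(
                s_m=rng.uniform(0, 0.08),
                s_f=rng.uniform(0, 0.08),
                h_m=rng.uniform(0, 1),
                h_f=rng.uniform(0, 1),
            )
            lam_p = invasion_growth_rate(scheme, "plus_rare")
            lam_m = invasion_growth_rate(scheme, "minus_rare")
            if min(abs(lam_p - 1), abs(lam_m - 1)) < 5e-3 and scheme != NEUTRAL:
                continue  # near-marginal schemes need impractically long runs
            plus_invades = _escapes(scheme, start=1e-4, grows=True)
            minus_invades = _escapes(scheme, start=1 - 1e-4, grows=False)
            if plus_invades and minus_invades:
                expected = "protected_polymorphism"
            elif plus_invades:
                expected = "fixation_of_plus"
            elif minus_invades:
                expected = "loss_of_plus"
            else:
                expected = "neutral" if scheme == NEUTRAL else "bistable"
            assert classify_outcome(scheme) == expected, scheme
            checked += 1


def _escapes(scheme, start, grows, horizon=20_000):
    traj = simulate_trajectory(start, scheme, horizon)
    if grows:
        return bool(np.any(traj.p > 10 * start))
    q0 = 1 - start
    return bool(np.any(1 - traj.p > 10 * q0))


class TestEquilibrium:
    def test_boundary_cases(self):
        assert equilibrium(FitnessScheme(0.0177, 0.0)) == 1.0
        assert equilibrium(FitnessScheme(0.0, 0.03, h_f=0.5)) == 0.0
        assert equilibrium(NEUTRAL, p0=0.5) == 0.5

    def test_interior_matches_long_simulation(self):
        scheme = FitnessScheme(0.0177, 0.05)
        eq = equilibrium(scheme, tol=1e-12)
        assert 0 < eq < 1
        traj = simulate_trajectory(0.5, scheme, 100_000)
        assert eq == pytest.approx(traj.p[-1], abs=1e-11)

    def test_monotone_in_selection_coefficients(self):
        """More female cost lowers, more male benefit raises, the equilibrium."""
        s_f_grid = [0.01, 0.02, 0.03, 0.04, 0.05]
        eqs = [equilibrium(FitnessScheme(0.0177, s_f)) for s_f in s_f_grid]
        assert all(a > b for a, b in zip(eqs, eqs[1:]))
        s_m_grid = [0.005, 0.01, 0.02, 0.04]
        eqs_m = [equilibrium(FitnessScheme(s_m, 0.03)) for s_m in s_m_grid]
        assert all(a < b for a, b in zip(eqs_m, eqs_m[1:]))


class TestSweep:
    def test_grid_shape_and_classification(self):
        table = sweep([0.005, 0.0177, 0.05], [0.0, 0.01, 0.05], n_generations=0)
        assert len(table) == 9
        no_cost = table[table.s_f == 0.0]
        assert (no_cost.outcome == "fixation_of_plus").all()
        assert (table[table.s_f > 0].outcome == "protected_polymorphism").all()

    def test_empty_grid(self):
        assert len(sweep([], [0.01])) == 0

    def test_sweep_is_deterministic(self):
        a = sweep([0.01, 0.02], [0.01], n_generations=500)
        b = sweep([0.01, 0.02], [0.01], n_generations=500)
        assert a.equals(b)
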