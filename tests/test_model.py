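import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosemarkov import (
    DegenerateChainError,
    HONG_KONG_2012,
    IllnessDeathModel,
    PopulationState,
    TransitionParameters,
    equilibrium_closed_form,
    iterate_to_equilibrium,
    step_no_replacement,
    step_with_replacement,
)
from .conftest import draw_valid_params

ZERO = TransitionParameters(p21=0, p12=0, p31=0, p32=0, p41=0, p42=0)


@st.composite
def valid_params(draw):
    rows = []
    for _ in range(2):
        a, b, c = (draw(st.floats(0.0, 1.0)) for _ in range(3))
        s = a + b + c
        if s > 1.0:
            scale = s * (1.0 + 1e-12)
            a, b, c = a / scale, b / scale, c / scale
        rows.append((a, b, c))
    (p21, p31, p41), (p12, p32, p42) = rows
    return TransitionParameters(
        p21=p21, p12=p12, p31=p31, p32=p32, p41=p41, p42=p42
    ).validate()


@st.composite
def states(draw):
    counts = [draw(st.floats(0.0, 1e7)) for _ in range(4)]
    return PopulationState(w=counts[0], x=counts[1], y=counts[2], z=counts[3])


class TestStepWithReplacement:
    def test_hand_derived_one_year_flows(self):
        """One step from the Hong Kong initial state, checked against the
        four flow formulas evaluated by hand."""
        state = PopulationState(w=6_850_000, x=150_000)
        nxt = step_with_replacement(state, HONG_KONG_2012)
        assert nxt.x == pytest.approx(157_411.0)          # 19,591 + 137,820
        assert nxt.w == pytest.approx(6_798_742.71)
        assert nxt.y == pytest.approx(42_900.0)           # 41,100 + 1,800
        assert nxt.z == pytest.approx(946.29)             # 571.29 + 375
        assert nxt.total == pytest.approx(7_000_000, rel=1e-12)
        assert nxt.n == 1

    def test_zero_flows_is_identity_on_living(self):
        state = PopulationState(w=100.0, x=50.0)
        nxt = step_with_replacement(state, ZERO)
        assert (nxt.w, nxt.x, nxt.y, nxt.z) == (100.0, 50.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(state=states(), params=valid_params())
    def test_conserves_total_and_nonnegativity(self, state, params):
        nxt = step_with_replacement(state, params)
        assert nxt.total == pytest.approx(state.total, rel=1e-9)
        assert min(nxt.w, nxt.x, nxt.y, nxt.z) >= 0.0

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="negative"):
            PopulationState(w=-1.0, x=0.0)


class TestStepNoReplacement:
    def test_living_population_decays_to_zero(self):
        """In the closed system the living compartments empty exponentially."""
        state = PopulationState(w=6_850_000, x=150_000)
        for _ in range(10_000):
            state = step_no_replacement(state, HONG_KONG_2012)
        assert state.living < 1e-6 * 7_000_000
        assert state.total == pytest.approx(7_000_000, rel=1e-9)

    def test_no_death_flows_keep_dead_constant(self):
        params = TransitionParameters(p21=0.1, p12=0.2, p31=0, p32=0, p41=0, p42=0)
        state = PopulationState(w=900.0, x=100.0, y=5.0, z=7.0)
        for _ in range(100):
            state = step_no_replacement(state, params)
        assert (state.y, state.z) == (5.0, 7.0)

    def test_single_step_from_all_healthy(self):
        state = PopulationState(w=1_000_000, x=0)
        nxt = step_no_replacement(state, HONG_KONG_2012)
        assert nxt.z == pytest.approx(HONG_KONG_2012.p41 * 1_000_000)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(state=states(), params=valid_params())
    def test_monotone_decay_of_living(self, state, params):
        nxt = step_no_replacement(state, params)
        assert nxt.total == pytest.approx(state.total, rel=1e-9)
        assert nxt.living <= state.living * (1.0 + 1e-12)
        death_flow = (params.p31 + params.p41) * state.w + (params.p32 + params.p42) * state.x
        if death_flow > 1e-9 * max(state.living, 1.0):
            assert nxt.living < state.living


class TestClosedFormEquilibrium:
    def test_hong_kong_fractions(self, hk_params, hk_q0):
        eq = equilibrium_closed_form(hk_params, hk_q0)
        assert eq.w_frac == pytest.approx(0.960, abs=5e-4)
        assert eq.x_frac == pytest.approx(0.0338, abs=5e-5)
        assert eq.y_frac == pytest.approx(0.00616, abs=5e-6)
        assert eq.z_frac == pytest.approx(0.000165, abs=5e-7)
        assert sum(eq.fractions) == pytest.approx(1.0, abs=1e-12)
        S = hk_params.ill_exit
        assert eq.R == pytest.approx(
            (1 + hk_params.p31 + hk_params.p41) * S
            + hk_params.p21 * (1 + hk_params.p32 + hk_params.p42)
        )

    def test_equilibrium_is_fixed_point_of_step(self, hk_params, hk_q0):
        eq = equilibrium_closed_form(hk_params, hk_q0)
        state = eq.to_state()
        nxt = step_with_replacement(state, hk_params)
        for a, b in zip((nxt.w, nxt.x, nxt.y, nxt.z), eq.counts):
            assert abs(a - b) < 1e-9 * hk_q0

    def test_no_deaths_reduces_to_two_state_chain(self):
        params = TransitionParameters(p21=0.03, p12=0.1, p31=0, p32=0, p41=0, p42=0)
        eq = equilibrium_closed_form(params, 1000)
        assert eq.y_frac == 0.0 and eq.z_frac == 0.0
        assert eq.w_frac == pytest.approx(0.1 / 0.13)
        assert eq.x_frac == pytest.approx(0.03 / 0.13)

    def test_no_incidence_empties_ill_compartment(self):
        eq = equilibrium_closed_form(HONG_KONG_2012.replace(p21=0.0), 1000)
        assert eq.x_frac == 0.0

    def test_absorbing_ill_state_raises(self):
        params = TransitionParameters(p21=0.01, p12=0, p31=0.001, p32=0, p41=0, p42=0)
        with pytest.raises(DegenerateChainError, match="degenerate"):
            equilibrium_closed_form(params, 1000)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=valid_params())
    def test_fractions_sum_to_one_and_satisfy_fixed_point(self, params):
        if params.ill_exit == 0.0:
            return
        eq = equilibrium_closed_form(params, 1.0)
        assert sum(eq.fractions) == pytest.approx(1.0, abs=1e-12)
        nxt = step_with_replacement(eq.to_state(), params)
        for a, b in zip((nxt.w, nxt.x, nxt.y, nxt.z), eq.counts):
            assert abs(a - b) < 1e-9


class TestPowerIteration:
    def test_hong_kong_ill_share_rises_monotonically(self, hk_params, hk_q0):
        model = IllnessDeathModel(hk_params, hk_q0)
        result = model.iterate()
        frame = result.trajectory_frame()
        share = frame["x"] / hk_q0
        assert share.iloc[0] == pytest.approx(150_000 / 7_000_000)
        assert (share.diff().dropna() >= -1e-15).all()
        assert share.iloc[-1] == pytest.approx(0.033808, abs=1e-5)

    def test_starting_at_equilibrium_converges_immediately(self, hk_params, hk_q0):
        eq = equilibrium_closed_form(hk_params, hk_q0)
        result = iterate_to_equilibrium(eq.to_state(), hk_params)
        assert result.years_to_converge == 1

    def test_matches_closed_form_on_random_parameter_sets(self):
        """Power iteration and the closed form agree on 1,000 random
        valid parameter sets (the closed form is the oracle)."""
        rng = np.random.default_rng(20120101)
        initial = PopulationState(w=0.7, x=0.3)
        for _ in range(1000):
            params = draw_valid_params(rng)
            eq = equilibrium_closed_form(params, 1.0)
            result = iterate_to_equilibrium(
                initial, params, tol=1e-10, keep_trajectory=False
            )
            for a, b in zip(result.fractions, eq.fractions):
                assert abs(a - b) < 1e-8

    def test_reports_no_convergence(self, hk_params):
        with pytest.raises(Exception, match="no convergence"):
            iterate_to_equilibrium(
                PopulationState(w=0.7, x=0.3), hk_params, tol=1e-12, max_years=3
            )

    def test_agreement_with_eigenvector_oracle(self, hk_params):
        """The stationary fractions equal the leading eigenvector of the
        yearly update matrix, computed independently by linear algebra."""
        p = hk_params
        M = np.array(
            [
                [1 - p.p21 - p.p31 - p.p41, p.p12, 1.0, 1.0],
                [p.p21, 1 - p.p12 - p.p32 - p.p42, 0.0, 0.0],
                [p.p31, p.p32, 0.0, 0.0],
                [p.p41, p.p42, 0.0, 0.0],
            ]
        )
        eigvals, eigvecs = np.linalg.eig(M)
        lead = np.argmin(np.abs(eigvals - 1.0))
        vec = np.real(eigvecs[:, lead])
        vec /= vec.sum()
        eq = equilibrium_closed_form(p, 1.0)
        np.testing.assert_allclose(vec, eq.fractions, atol=1e-12)


class TestModelObject:
    def test_default_initial_state_scales_with_q0(self):
        model = IllnessDeathModel(HONG_KONG_2012, 700_000)
        state = model.initial_state()
        assert state.x == pytest.approx(15_000)
        assert state.total == pytest.approx(700_000)

    def test_trajectory_frame_columns(self, hk_params):
        model = IllnessDeathModel(hk_params, 10_000)
        frame = model.trajectory(tol=1e-6)
        assert list(frame.columns) == ["year", "w", "x", "y", "z"]
        assert frame["year"].iloc[0] == 0

    def test_summary_mentions_rates(self, hk_params, hk_q0):
        text = IllnessDeathModel(hk_params, hk_q0).equilibrium().summary()
        assert "16.5 per 100,000" in text
        assert "6.16 per 1,000" in text

    def test_rejects_nonpositive_q0(self):
        with pytest.raises(ValueError):
            IllnessDeathModel(HONG_KONG_2012, 0)

    def test_ill_share_plot_renders(self, hk_params):
        import matplotlib

        matplotlib.use("Agg")
        from rosemarkov.plotting import plot_ill_share

        model = IllnessDeathModel(hk_params, 10_000)
        ax = plot_ill_share(model.trajectory(tol=1e-6),
                            equilibrium_share=model.equilibrium().x_frac)
        assert ax.get_ylabel().startswith("mentally ill")
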