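"""Reaction state machine and explicit integrator."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import calwave as cw
from calwave.dynamics import _Kernel


class TestRateConstant:
    def test_low_concentration_is_intake(self, params):
        k, state = cw.rate_constant(0.1, cw.CellRateState(), params)
        assert k == 0.03
        assert state.regime is cw.RateRegime.INTAKE_LOW

    def test_mid_concentration_is_release(self, params):
        k, state = cw.rate_constant(1.0, cw.CellRateState(), params)
        assert k == -0.025
        assert state.regime is cw.RateRegime.RELEASE

    def test_lock_is_permanent(self, params):
        k, state = cw.rate_constant(3.5, cw.CellRateState(), params)
        assert k == 0.0045 and state.locked
        # back below both thresholds: still k3
        k2, state2 = cw.rate_constant(0.1, state, params)
        assert k2 == 0.0045 and state2.locked
        assert state2.regime is cw.RateRegime.REFRACTORY

    def test_threshold_values_belong_to_release(self, params):
        for c in (params.uc1, params.uc2):
            k, state = cw.rate_constant(c, cw.CellRateState(), params)
            assert k == params.k2 and not state.locked

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            cw.rate_constant(-0.1, cw.CellRateState(), params)


class TestReactionRate:
    @pytest.mark.parametrize(
        "c,k,expected",
        [(0.0, 0.03, 0.0), (0.1, 0.03, -0.003), (1.0, -0.025, 0.025)],
    )
    def test_sign_convention(self, c, k, expected):
        assert cw.reaction_rate(c, k) == pytest.approx(expected)


class TestStep:
    def test_uniform_concentration_kills_diffusion(self, params, settings):
        net = cw.build_chain(7, 0.6)
        state = cw.SimulationState(np.full(7, 0.1), np.zeros(7, bool))
        out = cw.step(state, net, params, settings)
        # every cell updates by the identical reaction term alone
        expected = 0.1 - params.k1 * 0.1
        assert np.allclose(out.concentrations, expected)

    def test_diffusion_conserves_total(self, params, settings):
        rng = np.random.default_rng(7)
        net = cw.build_t_structure(0.6, 0.2)
        state = cw.SimulationState(rng.uniform(0, 3, net.n_cells), np.zeros(net.n_cells, bool))
        total = state.concentrations.sum()
        for _ in range(500):
            state = cw.step(state, net, params, settings, include_reaction=False)
        assert state.concentrations.sum() == pytest.approx(total, rel=1e-12)

    def test_zero_coupling_cells_stay_isolated(self, params, settings):
        net = cw.build_chain(5, 0.0)
        stim = cw.StimulationProtocol(("3",), 2.0)
        result = cw.simulate(net, params, settings, stim)
        for lab in ("1", "2", "4", "5"):
            assert np.all(result.trace(lab) == 0.0)

    def test_state_must_cover_network(self, params, settings):
        net = cw.build_chain(5, 0.6)
        state = cw.SimulationState(np.zeros(3), np.zeros(3, bool))
        with pytest.raises(ValueError):
            cw.step(state, net, params, settings)


class TestClosedForms:
    def test_isolated_cell_piecewise_geometric(self, params, settings):
        """An uncoupled cell follows the scalar recurrence exactly, through
        intake, release and the refractory lock."""
        net = cw.build_chain(2, 0.0)
        stim = cw.StimulationProtocol(("1",), 2.0)
        s = cw.SimulationSettings(n_steps=400)
        result = cw.simulate(net, params, s, stim)

        # independent scalar oracle
        c, locked = 2.0, False
        expected = [c]
        for _ in range(400):
            locked = locked or c > params.uc2
            if locked:
                k = params.k3
            elif c < params.uc1:
                k = params.k1
            else:
                k = params.k2
            c = c - k * c
            expected.append(c)
        assert np.allclose(result.trace("1"), expected, rtol=0, atol=1e-14)

    def test_subthreshold_decay_rate(self, params):
        """Below uc1 the per-step factor is exactly (1 - k1)."""
        net = cw.build_chain(2, 0.0)
        s = cw.SimulationSettings(n_steps=50)
        result = cw.simulate(net, params, s, cw.StimulationProtocol(("1",), 0.2))
        n = np.arange(51)
        assert np.allclose(result.trace("1"), 0.2 * (1 - params.k1) ** n)


class TestSimulate:
    def test_middle_stimulus_propagates_symmetrically(self, chain_single):
        act = chain_single.activated_labels()
        assert "30" in act and "32" in act and "31" in act
        for d in range(1, 25):
            a = chain_single.trace(str(31 - d))
            b = chain_single.trace(str(31 + d))
            assert np.allclose(a, b, atol=1e-10)

    def test_subthreshold_stimulus_never_fires(self, params, settings):
        result = cw.run_chain_single(params, settings, 0.6, c0=0.2)
        assert result.activated_labels() == set()
        totals = result.concentrations.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-12)  # total mass decays
        assert totals[-1] < 0.01

    def test_refractory_regime_is_absorbing(self, chain_single):
        reg = chain_single.regimes
        refr = reg == int(cw.RateRegime.REFRACTORY)
        became = np.maximum.accumulate(refr, axis=0)
        # once refractory, never anything else
        assert np.array_equal(refr, became)

    def test_deterministic_rerun_bitwise(self, params):
        s = cw.SimulationSettings(n_steps=2000)
        a = cw.run_chain_single(params, s, 0.6)
        b = cw.run_chain_single(params, s, 0.6)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_unknown_stimulated_cell_rejected(self, params, settings):
        net = cw.build_chain(5, 0.6)
        with pytest.raises(ValueError):
            cw.simulate(net, params, settings, cw.StimulationProtocol(("99",), 2.0))

    def test_instability_is_reported_with_step_index(self, params):
        s = cw.SimulationSettings(n_steps=8000, diffusion_per_step=True)
        with pytest.raises(cw.IntegrationInstabilityError) as err:
            cw.run_chain_single(params, s, 0.6)
        assert err.value.step_index > 0

    def test_tail_hump_is_confined_to_the_stimulated_cell(self, chain_single):
        """The discrete-diffusion artifact — a secondary rise in the pulse
        tail — appears in the stimulated cell, stays below its main rise
        rate, and never turns the decline of downstream cells positive."""

        def tail_rates(lab):
            rate = np.diff(chain_single.trace(lab))
            i_main = int(np.argmax(rate))
            end = i_main + int(np.nonzero(rate[i_main:] <= 0)[0][0])
            return rate[i_main], rate[end:]

        main, tail = tail_rates("31")
        assert tail.max() > 0  # the hump rises again
        assert tail.max() < 0.5 * main  # but well below the main rise
        for lab in ("35", "40", "25"):
            main, tail = tail_rates(lab)
            assert tail.max() <= 0  # downstream cells only slow their decline


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"uc1": 3.0, "uc2": 0.3},
            {"uc1": -0.1},
            {"k1": -0.03},
            {"k2": 0.025},
            {"k3": 0.0},
        ],
    )
    def test_bad_reaction_parameters(self, kwargs):
        with pytest.raises(ValueError):
            cw.ReactionParameters(**kwargs)

    @pytest.mark.parametrize("kwargs", [{"dt": 0.0}, {"n_steps": 0}, {"record_every": 0}])
    def test_bad_settings(self, kwargs):
        with pytest.raises(ValueError):
            cw.SimulationSettings(**kwargs)


@given(
    c=st.floats(min_value=0, max_value=10, allow_nan=False),
    locked=st.booleans(),
)
@hyp_settings(deadline=None, max_examples=200, derandomize=True)
def test_rate_constant_matches_vector_kernel(c, locked):
    """The scalar state machine and the vectorized kernel agree everywhere."""
    p = cw.ReactionParameters()
    k, state = cw.rate_constant(c, cw.CellRateState(locked=locked), p)
    net = cw.build_chain(2, 0.0)
    kern = _Kernel(net, p, cw.SimulationSettings())
    arr = np.array([c, 0.0])
    lock_arr = np.array([locked, False])
    _, new_locked, regimes, _ = kern.advance(arr, lock_arr)
    assert p.k_table()[regimes[0]] == k
    assert new_locked[0] == state.locked
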