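"""Pathway engine: channel sets, race semantics, trace bookkeeping."""

import dataclasses
import math

import numpy as np
import pytest

import kinrun as kr
from kinrun.dissociation import EscapeModel
from kinrun.engine import (
    ADP,
    ATP,
    CAP,
    DISSOCIATED,
    INT,
    PHI,
    EngineError,
    advance,
    enabled_transitions,
    initial_state,
    simulate_trace,
    trace_rng,
)

CFG = kr.SimulationConfig(n_traces=1, rng_seed=0)
NO_ESCAPE = EscapeModel(attempt_rate=0.0)  # P_I = P_II = 0: immortal dimer


def channels(state, params, config=CFG, **kw):
    return dict(enabled_transitions(state, params, config, **kw))


class TestEnabledTransitions:
    def test_kinesin3_int_atp_before_clock(self, k3_params):
        s = initial_state(k3_params)
        s.mode, s.trailing, s.leading = INT, ATP, ADP
        ch = channels(s, k3_params)
        assert ch["nl_docking"] == 3400.0
        assert "hydrolysis_bound" not in ch  # INT ATPase inhibited before tau
        assert ch["clock_stage"] == pytest.approx(1.7)

    def test_kinesin1_int_atp_races_docking_and_hydrolysis(self, k1_params):
        s = initial_state(k1_params)
        s.mode, s.trailing, s.leading = INT, ATP, ADP
        ch = channels(s, k1_params)
        assert ch == {"nl_docking": 800.0, "hydrolysis_bound": pytest.approx(3.5)}

    def test_two_heads_bound_channels(self, k1_params):
        s = initial_state(k1_params)  # trailing ATP, leading PHI at 2 mM
        ch = channels(s, k1_params)
        assert ch == {
            "hydrolysis_trailing": 140.0,
            "atp_binding_leading": pytest.approx(4000.0),
        }
        s.leading = ADP
        assert channels(s, k1_params) == {
            "hydrolysis_trailing": 140.0,
            "adp_release_leading": 350.0,
        }
        s.leading = ATP
        assert channels(s, k1_params) == {
            "hydrolysis_trailing": 140.0,
            "hydrolysis_leading": pytest.approx(3.5),
        }
        assert channels(s, k1_params, include_futile=False) == {
            "hydrolysis_trailing": 140.0
        }

    def test_dissociated_is_absorbing(self, k1_params):
        s = initial_state(k1_params)
        s.mode = DISSOCIATED
        assert enabled_transitions(s, k1_params, CFG) == []

    def test_unreachable_chemistry_rejected(self, k1_params):
        s = initial_state(k1_params)
        s.trailing = ADP  # trailing head can never hold ADP while bound
        with pytest.raises(EngineError):
            enabled_transitions(s, k1_params, CFG)


class TestAdvance:
    def test_race_winner_proportional_to_rate(self, k1_params, rng):
        # TH(ATP, ADP): hydrolysis 140 vs ADP release 350 -> Period II entry
        # should win with probability 140/490
        wins = 0
        trials = 20_000
        for _ in range(trials):
            s = initial_state(k1_params)
            s.leading = ADP
            _, _, label = advance(s, k1_params, CFG, rng, NO_ESCAPE)
            wins += label == "period_II_entry"
        p = 140.0 / 490.0
        se = math.sqrt(p * (1 - p) / trials)
        assert wins / trials == pytest.approx(p, abs=3 * se)

    def test_forward_step_advances_lattice(self, k1_params, rng):
        s = initial_state(k1_params)
        s.mode, s.trailing, s.leading = INT, ATP, ADP
        s.bound_site = 5
        params = dataclasses.replace(k1_params, rho=1e9)  # docking always wins
        _, _, label = advance(s, params, CFG, rng, NO_ESCAPE)
        assert label == "forward_step"
        assert s.mode == "TWO_HEADS_BOUND"
        assert s.bound_site == 5 and s.n_steps == 1
        assert s.centroid == 5.5  # heads at sites 5 and 6

    def test_period_I_near_certain_dissociation_in_regime(self, escape_model, k3_params):
        # E_w1 = 18 kBT, window t_r: escape is ~certain
        assert escape_model.p_fixed_window(k3_params.E_w1, k3_params.t_r_s) >= 0.99

    def test_advance_on_dissociated_state_rejected(self, k1_params, rng):
        s = initial_state(k1_params)
        s.mode = DISSOCIATED
        with pytest.raises(EngineError):
            advance(s, k1_params, CFG, rng, NO_ESCAPE)


class TestSimulateTrace:
    def test_immortal_dimer_hits_cap(self, k1_params, rng):
        cfg = dataclasses.replace(CFG, max_sim_time=0.2)
        t = simulate_trace(k1_params, cfg, rng, escape_model=NO_ESCAPE)
        assert t.dissociation_period == CAP
        assert t.capped
        assert t.total_time == pytest.approx(0.2, rel=0.05)

    def test_trace_invariants(self, k1_traces, k1_params):
        for t in k1_traces[:100]:
            assert t.velocity == pytest.approx(t.run_length / t.total_time)
            # centroid displacement is the step count up to the half-step
            # offset at detachment
            assert abs(t.run_length - k1_params.step_d * t.n_steps) <= k1_params.step_d

    def test_sequential_stage_dwell_in_rare_period_II_regime(self, rng):
        """With ADP release much faster than trailing hydrolysis the cycle is
        nearly sequential, so at saturating ATP (futile branch off) the mean
        dwell per step approaches 1/k_c + 1/k_NL + 1/k_D."""
        params = dataclasses.replace(
            kr.default_parameters(kr.KINESIN1), k_D=3500.0
        )
        cfg = kr.SimulationConfig(
            atp_concentration=1e6, n_traces=1, rng_seed=0, max_sim_time=0.5
        )
        total_t = total_steps = 0.0
        for i in range(30):
            t = simulate_trace(
                params, cfg, trace_rng(3, i), escape_model=NO_ESCAPE,
                include_futile=False,
            )
            total_t += t.total_time
            total_steps += t.n_steps
        expected = 1 / params.k_c + 1 / params.k_NL + 1 / params.k_D
        assert total_t / total_steps == pytest.approx(expected, rel=0.05)

    def test_geometric_absorption_oracle(self, k1_params, escape_model):
        """Futile branch off: every step carries one Period-I opportunity
        (probability p_I*P_I) and one Period-II opportunity (p_IIocc*P_II),
        so the mean step count must match the geometric absorption mean."""
        q = (
            kr.p_period_I(k1_params) * escape_model.p_period_I(k1_params)
            + kr.p_period_II_occurrence(k1_params) * escape_model.p_period_II(k1_params)
        )
        cfg = kr.SimulationConfig(n_traces=2000, rng_seed=17)
        traces = kr.simulate_traces(
            k1_params, cfg, escape_model=escape_model, include_futile=False
        )
        steps = np.array([t.n_steps for t in traces])
        sem = steps.std() / math.sqrt(steps.size)
        assert steps.mean() == pytest.approx(1.0 / q, abs=3.5 * sem)

    def test_determinism_per_trace_seed(self, k1_params):
        cfg = kr.SimulationConfig(n_traces=5, rng_seed=42)
        a = kr.simulate_traces(k1_params, cfg)
        b = kr.simulate_traces(k1_params, cfg)
        assert [(t.run_length, t.total_time) for t in a] == [
            (t.run_length, t.total_time) for t in b
        ]

    def test_kinesin3_tau_statistics(self, k3_traces, k3_params):
        taus = np.array(
            [t.tau_realized for t in k3_traces if t.tau_realized is not None]
        )
        # clock completes before dissociation in nearly every trace and its
        # realization matches the Gamma mean 1/k_cc
        assert taus.size >= 0.9 * len(k3_traces)
        sem = taus.std() / math.sqrt(taus.size)
        assert taus.mean() == pytest.approx(1.0 / k3_params.k_cc, abs=3.5 * sem)


class TestAnalyticOccurrenceProbabilities:
    def test_period_I_probability(self, k1_params, k3_params):
        assert kr.p_period_I(k1_params) == pytest.approx(3.5 / 803.5)
        assert kr.p_period_I(k3_params) == pytest.approx(13.5 / 3413.5)
        assert kr.p_period_I(k1_params, k_NL_effective=math.inf) == 0.0

    def test_period_II_occurrence(self, k1_params, k3_params):
        assert kr.p_period_II_occurrence(k1_params) == pytest.approx(140 / 490)
        assert kr.p_period_II_occurrence(k3_params) == pytest.approx(270 / 620)
        big = dataclasses.replace(k1_params, k_D=1e12)
        assert kr.p_period_II_occurrence(big) == pytest.approx(0.0, abs=1e-9)
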