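"""Escape model: calibration, regime constraints, monotonicity."""

import pytest
from hypothesis import given, settings, strategies as st

import kinrun as kr
from kinrun.dissociation import (
    CalibrationError,
    EscapeModel,
    calibrate,
    check_regime,
    dissociation_rate,
    escape_probability,
)
from kinrun.params import ParameterError


class TestCalibration:
    def test_p_ii_at_39_matches_fold_change_algebra(self, escape_model, k1_params):
        # (2.3 - 1) * p_I * P_I / p_IIocc with Table-1 kinesin-1 rates
        p_i = kr.p_period_I(k1_params)
        p_ii_occ = kr.p_period_II_occurrence(k1_params)
        expected = 1.3 * p_i * escape_model.p_period_I(k1_params) / p_ii_occ
        assert escape_model.p_period_II(k1_params) == pytest.approx(expected, rel=1e-6)
        assert escape_model.p_period_II(k1_params) == pytest.approx(0.0198, rel=0.01)

    def test_period_II_dominates_kinesin1(self, escape_model, k1_params):
        p_i = kr.p_period_I(k1_params) * escape_model.p_period_I(k1_params)
        p_ii = kr.p_period_II_occurrence(k1_params) * escape_model.p_period_II(k1_params)
        assert p_ii / p_i == pytest.approx(1.3, rel=1e-6)

    def test_regime_constraints_hold(self, escape_model, k1_params):
        assert escape_model.p_fixed_window(18.0, k1_params.t_r_s) >= 0.99
        assert escape_model.p_race(45.0, k1_params.k_D) <= 1e-3

    def test_calibration_requires_kinesin1(self, k3_params):
        with pytest.raises(ParameterError):
            calibrate(k3_params)

    def test_unattainable_fold_change_fails(self, k1_params):
        with pytest.raises(CalibrationError):
            calibrate(k1_params, fold_change=1.0)

    def test_regime_check_rejects_bad_model(self, k1_params):
        # an attempt rate far too small leaves Period-I escape uncertain
        with pytest.raises(CalibrationError):
            check_regime(EscapeModel(attempt_rate=1e6), k1_params)

    def test_round_trip(self, escape_model):
        assert EscapeModel.from_json(escape_model.to_json()) == escape_model


class TestEscapeProbability:
    def test_no_barrier_saturates(self):
        m = EscapeModel(attempt_rate=1e6)
        assert escape_probability(0.0, m, window=1.0) == pytest.approx(1.0)

    def test_infinite_barrier_vanishes(self, escape_model):
        assert escape_probability(500.0, escape_model, window=1.0) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        e=st.floats(0.0, 60.0),
        de=st.floats(0.1, 10.0),
        window=st.floats(1e-6, 1e-2),
    )
    def test_monotone_decreasing_in_depth(self, escape_model, e, de, window):
        p_lo = escape_probability(e, escape_model, window=window)
        p_hi = escape_probability(e + de, escape_model, window=window)
        assert 0.0 <= p_hi <= p_lo <= 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(e=st.floats(20.0, 60.0), f=st.floats(1.5, 10.0))
    def test_monotone_increasing_in_window(self, escape_model, e, f):
        w = 1e-5
        assert escape_probability(e, escape_model, window=w * f) >= escape_probability(
            e, escape_model, window=w
        )

    def test_requires_exactly_one_exposure(self, escape_model):
        with pytest.raises(ParameterError):
            escape_probability(10.0, escape_model)
        with pytest.raises(ParameterError):
            escape_probability(10.0, escape_model, window=1e-5, exit_rate=350.0)


class TestDissociationRate:
    def test_zero_probabilities(self):
        assert dissociation_rate(5.0, 0.0, 7.0, 0.0) == 0.0

    def test_arithmetic(self):
        assert dissociation_rate(2.0, 0.5, 4.0, 0.25) == pytest.approx(2.0)

    def test_rejects_invalid(self):
        with pytest.raises(ParameterError):
            dissociation_rate(-1.0, 0.5, 1.0, 0.5)
        with pytest.raises(ParameterError):
            dissociation_rate(1.0, 1.5, 1.0, 0.5)

    def test_formula_matches_simulated_detachment_rate(self, k1_params, escape_model):
        """epsilon = k_I*P_I + k_II*P_II, with occurrence rates counted from
        the simulation, must reproduce 1/mean detachment time (futile branch
        off so the exposure counts are exact: one INT passage per step plus
        the fatal one, one ADP-release race per step)."""
        cfg = kr.SimulationConfig(n_traces=3000, rng_seed=808)
        traces = kr.simulate_traces(
            k1_params, cfg, escape_model=escape_model, include_futile=False
        )
        total_time = sum(t.total_time for t in traces)
        n_steps = sum(t.n_steps for t in traces)
        n_p1 = sum(t.dissociation_period == "PERIOD_I" for t in traces)
        n_int_passages = n_steps + n_p1
        k_I = n_int_passages * kr.p_period_I(k1_params) / total_time
        k_II = n_steps * kr.p_period_II_occurrence(k1_params) / total_time
        eps = dissociation_rate(
            k_I, escape_model.p_period_I(k1_params),
            k_II, escape_model.p_period_II(k1_params),
        )
        measured = len(traces) / total_time
        assert eps == pytest.approx(measured, rel=0.06)
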