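import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pseshift.observers import (
    CalibrationWarning,
    DoseResponseModel,
    ObserverSpec,
    build_effect_map,
    calibrate_neutral_point,
    make_observers,
    response_probability,
)
from pseshift.design import build_design
from pseshift.simulate import simulate_calibration_block


def obs(**kw):
    defaults = dict(participant_id="P1", lapse_rate=0.0, day_drift_sd=0.0)
    return ObserverSpec(**{**defaults, **kw})


def test_symmetric_observer_is_indifferent_at_zero():
    assert response_probability(obs(), 0.0) == pytest.approx(0.5)


def test_steep_observer_approaches_step_function():
    assert response_probability(obs(slope_scale=1e-4), 0.45) == pytest.approx(1.0)
    assert response_probability(obs(slope_scale=1e-4), -0.45) == pytest.approx(0.0)


def test_logistic_quartile_closed_form():
    # L(ln 3) = 3/4 exactly, so z = s*ln3 gives 0.75
    p = response_probability(obs(slope_scale=0.15), 0.15 * math.log(3.0))
    assert p == pytest.approx(0.75, abs=1e-12)


@given(
    z1=st.floats(-1, 1), z2=st.floats(-1, 1),
    lam=st.floats(0, 0.1), s=st.floats(0.05, 0.4), mu=st.floats(-0.3, 0.3),
)
def test_response_probability_monotone_and_interior(z1, z2, lam, s, mu):
    o = obs(true_neutral=mu, slope_scale=s, lapse_rate=lam)
    p1, p2 = response_probability(o, z1), response_probability(o, z2)
    assert 0.0 < p1 < 1.0
    if z1 < z2:
        assert p1 < p2


def test_positive_effect_is_a_feminine_bias_lowering_male_probability():
    o = obs(effect_map={("VP24", "EST"): 0.05, ("VP24", "control"): 0.0})
    z = np.linspace(-0.45, 0.45, 7)
    p_odor = response_probability(o, z, drug="VP24", odor="EST")
    p_ctrl = response_probability(o, z, drug="VP24", odor="control")
    assert np.all(p_odor < p_ctrl)
    # generative 50% point moved to +delta
    assert response_probability(o, 0.05, drug="VP24", odor="EST") == pytest.approx(0.5)


class TestDoseResponse:
    model = DoseResponseModel()

    def test_gain_peaks_at_optimal_dose_for_high_aq(self):
        g = {d: self.model.gain(aq=30, drug=d) for d in ("none", "OT12", "OT24")}
        assert g["OT12"] == pytest.approx(1.0)
        assert g["OT12"] >= g["none"] and g["OT12"] >= g["OT24"]
        assert g["none"] == 0.0 and g["OT24"] == 0.0  # beyond/below the limbs

    def test_low_aq_sits_near_optimum_and_overshoots_with_oxytocin(self):
        assert self.model.gain(aq=15, drug="none") == pytest.approx(1.0)
        assert self.model.gain(aq=15, drug="OT24") == 0.0
        assert self.model.gain(aq=15, drug="none") > self.model.gain(aq=15, drug="OT12")

    def test_atosiban_blocks_everything(self):
        for aq in (10, 20, 30):
            assert self.model.gain(aq=aq, drug="atosiban60ug") == 0.0

    def test_vasopressin_leaves_tone_unchanged(self):
        for aq in (10, 30):
            assert self.model.gain(aq, "VP12") == self.model.gain(aq, "none")
            assert self.model.gain(aq, "VP24") == self.model.gain(aq, "none")


def test_effect_map_carrier_control_is_zero_by_construction():
    d = build_design("E3")
    m = build_effect_map(
        d, orientation="heterosexual", aq=30, dose_model=DoseResponseModel(),
        peak_and=-0.05, peak_est=0.05,
    )
    assert all(v == 0.0 for (drug, odor), v in m.items() if odor == "control")
    assert m[("OT12", "EST")] > 0.0


@pytest.mark.parametrize(
    "kw", [dict(slope_scale=0.0), dict(lapse_rate=0.2), dict(day_drift_sd=-1.0),
           dict(aq_score=60), dict(kinsey_score=7),
           dict(effect_map={("OT12", "control"): 0.1})],
)
def test_observer_spec_bounds_enforced(kw):
    with pytest.raises(ValueError):
        obs(**kw)


@pytest.mark.parametrize(
    "exp, check",
    [
        ("E3", lambda o: o.aq_score >= 25),
        ("E5", lambda o: o.aq_score < 25),
        ("E2", lambda o: o.kinsey_score >= 4),
        ("E1", lambda o: o.kinsey_score <= 1),
    ],
)
def test_cohort_sampling_matches_inclusion_criteria(exp, check):
    observers = make_observers(build_design(exp), 5)
    assert all(check(o) for o in observers)


def test_effect_override_injects_truth_verbatim():
    d = build_design("E1")
    observers = make_observers(d, 3, effect_override={("VP24", "EST"): 0.05,
                                                      ("VP24", "control"): 0.0,
                                                      ("OT24", "EST"): 0.0})
    deltas = np.array([o.effect_map[("VP24", "EST")] for o in observers])
    assert abs(deltas.mean() - 0.05) < 0.03
    assert all(o.effect_map[("OT24", "EST")] == 0.0 for o in observers)


class TestCalibration:
    def test_recovers_miscalibrated_neutral_point(self):
        o = obs(true_neutral=0.1, slope_scale=0.15)
        trials = simulate_calibration_block(o, np.linspace(-0.45, 0.45, 7), 400, seed=2)
        assert abs(calibrate_neutral_point(trials) - 0.1) < 0.02

    def test_well_calibrated_observer_yields_near_zero_offset(self):
        o = obs(slope_scale=0.15)
        trials = simulate_calibration_block(o, np.linspace(-0.45, 0.45, 7), 400, seed=3)
        assert abs(calibrate_neutral_point(trials)) < 0.02

    def test_degenerate_all_one_response_warns_and_returns_zero(self):
        o = obs(true_neutral=-5.0, slope_scale=0.05)  # always answers male
        trials = simulate_calibration_block(o, np.linspace(-0.45, 0.45, 7), 20, seed=4)
        assert set(trials["response"]) == {"male"}
        with pytest.warns(CalibrationWarning):
            assert calibrate_neutral_point(trials) == 0.0
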