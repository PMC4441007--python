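import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregscreen import (
    ImpulseParams,
    ModelKind,
    SigmoidParams,
    classify_specific_enhancer,
    compute_therapeutic_index,
    fit_dose_response,
    impulse_response,
    reverse_query_half_peak,
    sigmoid_response,
)
from tregscreen.doseresponse import (
    HalfPeakDose,
    curve_from_params,
    invert_sigmoid,
)

from oracles import bisect_sigmoid_crossing

DOSES = np.geomspace(0.01, 10, 8)
LOG_DOSES = np.log10(DOSES)


class TestSigmoid:
    def test_midpoint_value(self):
        p = SigmoidParams(dm=0.5, ri=0.1, rf=0.9, alpha=2.0)
        assert float(sigmoid_response(0.5, p)) == pytest.approx(0.5)

    def test_zero_slope_gives_constant_mean(self):
        p = SigmoidParams(dm=0.0, ri=0.2, rf=0.8, alpha=0.0)
        vals = sigmoid_response(np.linspace(-3, 3, 7), p)
        np.testing.assert_allclose(vals, 0.5)

    def test_direct_evaluation(self):
        p = SigmoidParams(dm=1.0, ri=0.2, rf=1.0, alpha=1.0)
        assert float(sigmoid_response(2.0, p)) == pytest.approx(
            0.2 + 0.8 / (1 + math.exp(-4)), abs=1e-6
        )
        assert float(sigmoid_response(2.0, p)) == pytest.approx(0.9856, abs=2e-4)

    @given(
        st.floats(-2, 2), st.floats(-2, 2),
        st.floats(0.05, 0.95), st.floats(1.0, 2.0), st.floats(0.1, 5.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_for_positive_slope(self, d_lo, dm, ri, rf, alpha):
        p = SigmoidParams(dm=dm, ri=ri, rf=rf, alpha=alpha)  # rf > ri here
        d = np.linspace(d_lo, d_lo + 4, 50)
        vals = np.asarray(sigmoid_response(d, p))
        assert np.all(np.diff(vals) >= -1e-12)


class TestImpulse:
    def test_constant_impulse(self):
        p = ImpulseParams(d1=-1, d2=1, rl=0.7, rp=0.7, rh=0.7, alpha1=1, alpha2=1)
        vals = impulse_response(np.linspace(-4, 4, 9), p)
        np.testing.assert_allclose(vals, 0.7)

    def test_plateau_value(self):
        p = ImpulseParams(d1=-2, d2=1, rl=0, rp=1, rh=0.5, alpha1=3, alpha2=3)
        assert float(impulse_response(-0.5, p)) == pytest.approx(1.0, abs=1e-6)

    def test_tail_limits(self):
        p = ImpulseParams(d1=-1, d2=1, rl=0.1, rp=1.0, rh=0.3, alpha1=2, alpha2=2)
        assert float(impulse_response(-50.0, p)) == pytest.approx(0.1, abs=1e-9)
        assert float(impulse_response(50.0, p)) == pytest.approx(0.3, abs=1e-9)

    def test_reduces_to_onset_sigmoid_when_offset_disabled(self, rng):
        for _ in range(20):
            rl, rp = rng.uniform(0, 0.3), rng.uniform(0.5, 1.5)
            d1, a1 = rng.uniform(-1, 1), rng.uniform(0.3, 3)
            imp = ImpulseParams(d1=d1, d2=1e6, rl=rl, rp=rp, rh=rp,
                                alpha1=a1, alpha2=1.0)
            sig = SigmoidParams(dm=d1, ri=rl, rf=rp, alpha=a1)
            d = np.linspace(-2, 2, 25)
            np.testing.assert_allclose(
                impulse_response(d, imp), sigmoid_response(d, sig), atol=1e-10
            )

    def test_alternative_normalizer(self):
        p = ImpulseParams(d1=-1, d2=1, rl=0.5, rp=1.0, rh=0.2, alpha1=1, alpha2=1)
        peak_norm = impulse_response(0.0, p, normalizer="peak")
        init_norm = impulse_response(0.0, p, normalizer="initial")
        assert float(init_norm) == pytest.approx(float(peak_norm) * p.rp / p.rl)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ImpulseParams(d1=2, d2=1, rl=0, rp=1, rh=0, alpha1=1, alpha2=1)
        with pytest.raises(ValueError):
            ImpulseParams(d1=0, d2=1, rl=0, rp=0, rh=0, alpha1=1, alpha2=1)


class TestReverseQuery:
    def test_midpoint_target(self):
        p = SigmoidParams(dm=0.0, ri=0.0, rf=1.0, alpha=0.5)
        assert invert_sigmoid(p, 0.5) == pytest.approx(0.0)

    def test_analytic_quarter_point(self):
        p = SigmoidParams(dm=0.0, ri=0.0, rf=1.0, alpha=0.5)
        assert invert_sigmoid(p, 0.25) == pytest.approx(0.5 * math.log(1 / 3), abs=1e-9)

    def test_flat_fit_censored(self):
        flat = curve_from_params(
            SigmoidParams(dm=0.0, ri=0.4, rf=0.4, alpha=1.0), (-2.0, 1.0)
        )
        res = reverse_query_half_peak(flat)
        assert res.censored and res.dose_uM == pytest.approx(10.0)

    def test_target_above_curve_censored(self):
        # curve saturates below half its (extrapolated) peak inside the range
        fit = curve_from_params(
            SigmoidParams(dm=5.0, ri=0.0, rf=1.0, alpha=1.0), (-2.0, 1.0)
        )
        res = reverse_query_half_peak(fit)
        assert res.censored

    def test_analytic_matches_bisection(self, rng):
        for _ in range(200):
            ri = rng.uniform(0, 0.3)
            rf = rng.uniform(ri + 0.2, 1.5)
            p = SigmoidParams(
                dm=rng.uniform(-1.5, 0.5), ri=ri, rf=rf, alpha=rng.uniform(0.3, 3)
            )
            target = 0.5 * rf
            if target <= ri:
                continue
            analytic = invert_sigmoid(p, target)
            numeric = bisect_sigmoid_crossing(p, target, analytic - 3, analytic + 3)
            assert analytic == pytest.approx(numeric, abs=1e-6)

    def test_impulse_first_crossing_from_left(self):
        p = ImpulseParams(d1=-1.0, d2=0.5, rl=0.0, rp=1.0, rh=0.0, alpha1=1, alpha2=1)
        fit = curve_from_params(p, (-2.0, 1.0))
        res = reverse_query_half_peak(fit)
        assert not res.censored
        d = math.log10(res.dose_uM)
        assert d < p.d2  # onset-side crossing, not the declining side
        assert float(impulse_response(d, p)) == pytest.approx(0.5, abs=1e-6)


class TestFitting:
    def test_noiseless_single_sigmoid_recovery(self):
        p = SigmoidParams(dm=-0.3, ri=0.05, rf=0.95, alpha=1.2)
        y = sigmoid_response(LOG_DOSES, p)
        fit = fit_dose_response(DOSES, y, seed=3)
        assert fit.model is ModelKind.SINGLE
        np.testing.assert_allclose(fit.params.as_array(), p.as_array(), atol=1e-4)

    def test_noiseless_impulse_selected_and_recovered(self):
        p = ImpulseParams(d1=-1.2, d2=0.4, rl=0.02, rp=0.9, rh=0.2,
                          alpha1=1.3, alpha2=1.0)
        y = impulse_response(LOG_DOSES, p)
        fit = fit_dose_response(DOSES, y, seed=5)
        assert fit.model is ModelKind.IMPULSE
        np.testing.assert_allclose(fit.params.as_array(), p.as_array(), atol=1e-4)

    def test_monotone_noiseless_data_never_prefers_impulse(self, rng):
        for i in range(5):
            p = SigmoidParams(
                dm=rng.uniform(-1, 0.5), ri=rng.uniform(0, 0.2),
                rf=rng.uniform(0.5, 1.2), alpha=rng.uniform(0.5, 2),
            )
            y = sigmoid_response(LOG_DOSES, p)
            fit = fit_dose_response(DOSES, y, seed=i)
            assert fit.model is ModelKind.SINGLE

    def test_flat_responses_give_censored_ec50(self):
        fit = fit_dose_response(DOSES, np.full(8, 0.4), seed=1)
        assert fit.half_peak().censored

    def test_too_few_distinct_doses_rejected(self):
        from tregscreen.doseresponse import FitError

        with pytest.raises(FitError):
            fit_dose_response([1, 1, 2, 2], [0, 0, 1, 1])

    def test_fit_reproducible_given_seed(self):
        p = ImpulseParams(d1=-1, d2=0.5, rl=0, rp=1, rh=0.3, alpha1=1, alpha2=1)
        y = impulse_response(LOG_DOSES, p) + np.linspace(-0.02, 0.02, 8)
        f1 = fit_dose_response(DOSES, y, seed=11)
        f2 = fit_dose_response(DOSES, y, seed=11)
        np.testing.assert_array_equal(f1.params.as_array(), f2.params.as_array())


class TestPrioritization:
    def test_therapeutic_index_ratio(self):
        ti = compute_therapeutic_index(HalfPeakDose(1.0), HalfPeakDose(10.0))
        assert ti.value == pytest.approx(10.0) and not ti.is_lower_bound

    def test_censored_ld50_gives_lower_bound(self):
        ti = compute_therapeutic_index(
            HalfPeakDose(1.0), HalfPeakDose(10.0, censored=True)
        )
        assert ti.value == pytest.approx(10.0) and ti.is_lower_bound
        assert str(ti) == ">=10"

    def test_equal_doses_mark_cytotoxic_regime(self):
        ti = compute_therapeutic_index(HalfPeakDose(2.0), HalfPeakDose(2.0))
        assert ti.value == pytest.approx(1.0)

    def test_censored_ec50_rejected(self):
        with pytest.raises(ValueError):
            compute_therapeutic_index(HalfPeakDose(10.0, censored=True),
                                      HalfPeakDose(10.0))

    @pytest.mark.parametrize(
        "enh, expected",
        [
            ({"TREG": 0.6, "TH1": 0.1, "TH17": 0.05}, (True, True)),
            ({"TREG": 0.6, "TH1": 0.5, "TH17": 0.05}, (True, False)),
            ({"TREG": 0.2, "TH1": 0.1, "TH17": 0.05}, (False, False)),
        ],
    )
    def test_specificity_rule(self, enh, expected):
        call = classify_specific_enhancer("c", enh, threshold=0.3)
        assert (call.is_enhancer, call.is_specific) == expected

    def test_missing_lineage_rejected(self):
        with pytest.raises(ValueError, match="TH17"):
            classify_specific_enhancer("c", {"TREG": 0.5, "TH1": 0.1})
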