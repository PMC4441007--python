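import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregscreen import (
    Assay,
    PlateGrid,
    ScreenModel,
    ScreenParams,
    Well,
    WellRole,
    call_hits,
    correct_cellularity,
    fractional_enhancement,
    fractional_inhibition,
    generate_screen,
    median_center_plate,
    robust_sd,
)
from tregscreen.hitcalling import (
    BatchControlStats,
    CalibrationError,
    Calibration,
    HitCallConfig,
    ProcessingError,
    calibrate_to_positive,
    qc_plate,
    select_negative_reference,
    zscore_wells,
)


def _plate(values_by_role, plate_id="P0"):
    """Build a plate from {role: [pct values]}; wells get distinct positions."""
    wells = []
    pos = [(r, c) for c in range(1, 13) for r in "ABCDEFGH"]
    i = 0
    for role, values in values_by_role.items():
        for v in values:
            r, c = pos[i]
            wells.append(Well(plate_id, r, c, role, float(v), 5e4,
                              compound_id="X" if role is WellRole.COMPOUND else None))
            i += 1
    return PlateGrid(plate_id, "B0", Assay.TREG_LOW, wells)


class TestMedianCentering:
    def test_center_excludes_positive_controls(self):
        plate = _plate({
            WellRole.NEG_CTRL: [10, 20],
            WellRole.COMPOUND: [30],
            WellRole.POS_CTRL: [90],
        })
        centered = median_center_plate(plate)
        # median of non-positive wells {10,20,30} is 20; POS well -> 70
        assert centered[-1] == pytest.approx(70)
        non_pos = centered[:-1]
        assert np.median(non_pos) == pytest.approx(0)

    def test_identical_wells_center_to_zero(self):
        plate = _plate({WellRole.NEG_CTRL: [42] * 8, WellRole.COMPOUND: [42] * 4})
        assert np.allclose(median_center_plate(plate), 0)

    def test_all_positive_plate_rejected(self):
        plate = _plate({WellRole.POS_CTRL: [90] * 8})
        with pytest.raises(ProcessingError):
            median_center_plate(plate)


class TestRobustSd:
    def test_outlier_resistant_hand_value(self):
        assert robust_sd([1, 2, 3, 4, 100]) == pytest.approx(1.4826)

    def test_degenerate_cases(self):
        assert robust_sd([5, 5, 5]) == 0
        with pytest.raises(ProcessingError):
            robust_sd([1.0])

    def test_gaussian_consistency(self, rng):
        x = rng.normal(0, 2.5, size=100_000)
        assert robust_sd(x) == pytest.approx(2.5, rel=0.02)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_shift_and_scale_equivariance(self, values, shift, scale):
        base = robust_sd(values)
        assert robust_sd(np.asarray(values) * scale + shift) == pytest.approx(
            abs(scale) * base, abs=1e-9, rel=1e-9
        )


def _qc_frame(n_out_of_range, n_ctrl=16, separation=10.0):
    """Plate control frame with the requested number of out-of-range controls."""
    half = n_ctrl // 2
    neg = np.zeros(half)
    pos = np.full(half, separation)
    for i in range(n_out_of_range):
        if i % 2 == 0:
            neg[i // 2] = 20.0  # far above the negative class median
        else:
            pos[i // 2] = -20.0
    return pd.DataFrame(
        {
            "plate_id": "P0",
            "role": [WellRole.NEG_CTRL.value] * half + [WellRole.POS_CTRL.value] * half,
            "centered": np.concatenate([neg, pos]),
        }
    )


STATS = BatchControlStats(neg_median=0, neg_rsd=1.0, pos_median=10.0, pos_rsd=1.0,
                          pooled_rsd=1.0)


class TestPlateQC:
    def test_exactly_75_percent_in_range_is_excluded(self):
        report = qc_plate(_qc_frame(4), STATS)
        assert report.pct_in_range == pytest.approx(75.0)
        assert not report.passed

    def test_one_outlier_retained(self):
        report = qc_plate(_qc_frame(1), STATS)
        assert report.pct_in_range == pytest.approx(93.75)
        assert report.passed and report.dynamic_range_ok

    def test_zero_control_separation_fails_dynamic_range(self):
        report = qc_plate(_qc_frame(0, separation=0.0), STATS)
        assert not report.dynamic_range_ok and not report.passed


class TestZScoring:
    def test_reference_retains_bulk_of_null_wells(self, rng):
        centered = rng.normal(0, 1, size=2000)
        mask = select_negative_reference(centered, k=2.0)
        assert mask.mean() >= 0.90  # ~95.4% of a Gaussian lies within 2 SD

    def test_extreme_enhancer_excluded_from_reference(self, rng):
        centered = np.append(rng.normal(0, 1, size=200), 20.0)
        mask = select_negative_reference(centered, k=2.0)
        assert not mask[-1]

    def test_zscore_examples_and_zero_scale(self):
        assert zscore_wells([5.0], 5.0, 2.0)[0] == 0
        assert zscore_wells([9.0], 5.0, 2.0)[0] == pytest.approx(2.0)
        with pytest.raises(ProcessingError):
            zscore_wells([1.0], 0.0, 0.0)

    def test_null_tail_fraction_matches_gaussian(self, rng):
        centered = rng.normal(0, 3.0, size=200_000)
        mask = select_negative_reference(centered, k=2.0)
        z = zscore_wells(centered, centered[mask].mean(), robust_sd(centered))
        assert np.mean(np.abs(z) > 3) == pytest.approx(0.0027, abs=0.0006)


class TestCalibration:
    def test_linear_interpolation(self):
        calib = calibrate_to_positive(
            np.array([0.0] * 8 + [10.0] * 8), np.array([0] * 8 + [1] * 8)
        )
        assert calib.frac_of_pos(3.0) == pytest.approx(0.3)
        assert calib.frac_of_pos(10.0) == pytest.approx(1.0)
        assert calib.frac_of_pos(0.0) == pytest.approx(0.0)

    def test_inverted_controls_raise(self):
        with pytest.raises(CalibrationError, match="inverted"):
            calibrate_to_positive(
                np.array([10.0] * 4 + [0.0] * 4), np.array([0] * 4 + [1] * 4)
            )

    def test_glm_fit_recovers_class_means(self, rng):
        z = np.concatenate([rng.normal(0, 1, 50), rng.normal(8, 1, 50)])
        ind = np.array([0] * 50 + [1] * 50)
        calib = calibrate_to_positive(z, ind)
        assert calib.z_neg == pytest.approx(z[:50].mean())
        assert calib.z_pos == pytest.approx(z[50:].mean())


class TestCellularityCorrection:
    def test_recovers_planted_slope(self, rng):
        n = 500
        log_cells = rng.normal(np.log(5e4), 0.4, n)
        centered = -8.0 * log_cells + rng.normal(0, 3, n) + 90
        roles = np.array([WellRole.COMPOUND.value] * (n - 50)
                         + [WellRole.NEG_CTRL.value] * 50)
        corrected, fit = correct_cellularity(centered, np.exp(log_cells), roles)
        lo, hi = fit.slope_conf_int
        assert lo < -8.0 < hi
        # corrected values no longer depend on cellularity
        r = np.corrcoef(log_cells, corrected)[0, 1]
        assert abs(r) < 0.1

    def test_no_confound_leaves_values_nearly_unchanged(self, rng):
        n = 400
        cells = np.exp(rng.normal(np.log(5e4), 0.4, n))
        centered = rng.normal(0, 3, n)
        roles = np.array([WellRole.COMPOUND.value] * n)
        corrected, fit = correct_cellularity(centered, cells, roles)
        assert np.max(np.abs(corrected - centered)) < 1.5  # slope ~ 0

    def test_zero_cell_variance_passes_through(self, caplog):
        centered = np.arange(12, dtype=float)
        cells = np.full(12, 5e4)
        roles = np.array([WellRole.COMPOUND.value] * 12)
        with caplog.at_level("WARNING"):
            corrected, fit = correct_cellularity(centered, cells, roles)
        assert fit.skipped
        np.testing.assert_array_equal(corrected, centered)

    def test_too_few_wells_rejected(self):
        with pytest.raises(ProcessingError):
            correct_cellularity(
                np.zeros(5), np.full(5, 1e4), np.array([WellRole.COMPOUND.value] * 5)
            )


class TestFractions:
    def test_fractional_enhancement(self):
        assert fractional_enhancement(95, 30, 95) == pytest.approx(1.0)
        assert fractional_enhancement(30, 30, 95) == pytest.approx(0.0)
        assert fractional_enhancement(49.5, 30, 95) == pytest.approx(0.3)
        with pytest.raises(ProcessingError):
            fractional_enhancement(50, 95, 30)

    def test_fractional_inhibition(self):
        assert fractional_inhibition(50, 50) == 0
        assert fractional_inhibition(0, 50) == 1
        assert fractional_inhibition(20, 50) == pytest.approx(0.6)
        with pytest.raises(ProcessingError):
            fractional_inhibition(10, 0)


class TestHitCalling:
    def test_threshold_boundary_is_inclusive(self):
        table = pd.DataFrame(
            {
                "compound_id": ["a", "b"],
                "corrected_frac_of_pos": [0.30, 0.299],
                "excluded": [False, False],
            }
        )
        out = call_hits(table, threshold=0.3)
        assert out.set_index("compound_id")["is_hit"].tolist() == [True, False]

    def test_pipeline_invariant_to_plate_constant_shift(self):
        batches, _ = generate_screen(
            160, frac_enhancers=0.05, seed=21,
            params=ScreenParams(plates_per_batch=2),
        )
        res_a = ScreenModel(batches).fit()

        shifted, _ = generate_screen(
            160, frac_enhancers=0.05, seed=21,
            params=ScreenParams(plates_per_batch=2),
        )
        plate0 = shifted[0].plates[0]
        # shift every well of one plate by a constant (kept inside [0, 100])
        plate0.wells = [
            Well(w.plate_id, w.row, w.col, w.role, w.pct_positive - 4.0,
                 w.live_cells, w.compound_id, w.dose_uM)
            for w in plate0.wells
        ]
        res_b = ScreenModel(shifted).fit()
        # the centered track (z -> frac-of-positive -> hit call) is invariant;
        # raw-percent columns are not expected to be
        cols = ["compound_id", "frac_of_pos", "corrected_frac_of_pos", "is_hit"]
        pd.testing.assert_frame_equal(res_a.hits[cols], res_b.hits[cols])

    def test_qc_failed_plates_flagged_never_dropped(self):
        batches, truth = generate_screen(400, seed=13, n_qc_fail_plates=2)
        res = ScreenModel(batches).fit()
        failed = set(res.qc.loc[~res.qc["passed"], "plate_id"])
        assert failed == truth.qc_fail_plates
        # wells of failed plates are retained with an exclusion reason
        wells_failed = res.wells[res.wells["plate_id"].isin(failed)]
        assert len(wells_failed) > 0
        assert (wells_failed["exclusion_reason"] == "plate_qc_failed").all()

    def test_correction_only_touches_submaximal_regulatory_assay(self):
        batches, _ = generate_screen(
            160, seed=31, assay=Assay.TH1_LOW,
            params=ScreenParams(plates_per_batch=2),
        )
        res = ScreenModel(batches).fit()
        exp = res.wells[~res.wells["is_control_plate"]]
        np.testing.assert_allclose(exp["corrected"], exp["centered"])

    def test_strong_enhancers_called_and_summary_reports_counts(self):
        batches, truth = generate_screen(800, frac_enhancers=0.03, seed=17)
        res = ScreenModel(batches).fit()
        strong = {c for c, f in truth.enhancer_compounds.items() if f >= 0.6}
        hits = set(res.hit_compounds)
        assert strong and strong <= hits
        assert "hits" in res.summary()
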