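import numpy as np
import pytest

from fusact import (
    ActivationMap,
    HRFParams,
    ROISpec,
    extract_roi_timeseries,
    make_default_protocol,
    roi_percent_timecourse,
    select_rois,
    simulate_roi_timecourse,
    stim_response_stats,
    zscore_timecourse,
)
from fusact.preprocess import NormalizedSeries


def _norm_series(values, spacing=1e-4, conditioned=None):
    n = values.shape[0]
    meta = {}
    if conditioned is not None:
        meta["conditioned_pd"] = conditioned
    return NormalizedSeries(
        values=values,
        block_rate=2.0,
        block_timestamps=(np.arange(n) + 0.5) / 2.0,
        normalization_mode="percent_change",
        reference_window=(0, max(1, n // 4)),
        valid_mask=np.ones(values.shape[1:], dtype=bool),
        pixel_spacing_z=spacing,
        pixel_spacing_x=spacing,
        meta=meta,
    )


def _amap(t_map):
    shape = t_map.shape
    return ActivationMap(
        beta=np.zeros(shape), t_score=t_map, p_value=np.ones(shape),
        q_value=np.ones(shape), mask=np.zeros(shape, bool),
        mask_uncorrected=np.zeros(shape, bool), dof=100.0, threshold={},
    )


class TestROISpec:
    def test_one_pixel_roi_returns_voxel_series(self):
        values = np.random.default_rng(0).standard_normal((8, 5, 5))
        roi = ROISpec.from_pixels(2, 3, 1, 1, 1e-4, 1e-4)
        assert np.allclose(extract_roi_timeseries(_norm_series(values), roi), values[:, 2, 3])

    def test_uniform_frame_value(self):
        values = np.full((4, 6, 6), 3.3)
        roi = ROISpec.from_pixels(1, 1, 3, 3, 1e-4, 1e-4)
        assert np.allclose(extract_roi_timeseries(_norm_series(values), roi), 3.3)

    def test_2x2_mean(self):
        # plain arrays are interpreted with unit pixel spacing
        values = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        roi = ROISpec.from_pixels(0, 0, 2, 2, 1.0, 1.0)
        assert extract_roi_timeseries(values, roi)[0] == pytest.approx(2.5)

    def test_physical_to_pixel_bounds(self):
        roi = ROISpec(z0=2e-3, x0=1e-3, height=2e-3, width=2e-3)
        assert roi.pixel_bounds(1e-4, 1e-4, (64, 64)) == (20, 40, 10, 30)

    def test_out_of_grid_rejected(self):
        roi = ROISpec(z0=6e-3, x0=0, height=2e-3, width=2e-3)
        with pytest.raises(ValueError, match="grid"):
            roi.pixel_bounds(1e-4, 1e-4, (64, 64))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ROISpec(z0=0, x0=0, height=0, width=1e-3)


class TestZscore:
    def test_hand_computed_example(self):
        tc = np.array([0.0, 2.0, 3.0])
        z = zscore_timecourse(tc, (0, 2))
        # baseline mean 1, sample std sqrt(2): z(3) = sqrt(2)
        assert z[2] == pytest.approx(np.sqrt(2))

    def test_baseline_window_standardized(self):
        rng = np.random.default_rng(1)
        tc = rng.standard_normal(50) * 3 + 7
        z = zscore_timecourse(tc, (0, 20))
        assert z[:20].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[:20].std(ddof=1) == pytest.approx(1.0)

    def test_flat_outside_baseline_zero(self):
        tc = np.array([1.0, 3.0, 2.0, 2.0, 2.0])
        z = zscore_timecourse(tc, (0, 2))
        assert np.allclose(z[2:], 0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_timecourse(np.ones(10), (0, 5))


class TestStimResponseStats:
    def test_zero_noise_step_recovered_exactly(self, default_protocol):
        _, tc = simulate_roi_timecourse(
            default_protocol, 2.0, effect_percent=5.0, noise_sd_percent=0.0, seed=0
        )
        res = stim_response_stats(tc, default_protocol, 2.0)
        assert res.mean_diff_percent == pytest.approx(5.0, abs=1e-12)
        assert res.n_stim == 30
        assert len(res.per_stimulus_means) == 3
        assert all(m == pytest.approx(5.0) for m in res.per_stimulus_means)

    def test_reported_scale_effect_detected(self, default_protocol):
        _, tc = simulate_roi_timecourse(
            default_protocol, 2.0, effect_percent=11.95, seed=1
        )
        res = stim_response_stats(tc, default_protocol, 2.0)
        assert res.mean_diff_percent == pytest.approx(11.95, abs=0.5)
        assert res.p_value < 1e-3
        assert res.significant_p001 and res.significant_p1e5

    def test_null_type_i_error_calibrated(self, default_protocol):
        hits = 0
        n_sim = 400
        for seed in range(n_sim):
            _, tc = simulate_roi_timecourse(
                default_protocol, 2.0, effect_percent=0.0, seed=seed
            )
            res = stim_response_stats(tc, default_protocol, 2.0)
            hits += res.p_value < 0.05
        assert hits / n_sim == pytest.approx(0.05, abs=0.025)

    def test_default_lag_is_hrf_peak(self, default_protocol):
        _, tc = simulate_roi_timecourse(default_protocol, 2.0, 8.0, 0.0, seed=0)
        res = stim_response_stats(tc, default_protocol, 2.0)
        assert res.meta["lag_s"] == pytest.approx(HRFParams().peak_time)

    def test_baseline_rest_mode(self, default_protocol):
        _, tc = simulate_roi_timecourse(default_protocol, 2.0, 6.0, 0.0, seed=0)
        res = stim_response_stats(tc, default_protocol, 2.0, rest_mode="baseline")
        assert res.n_pre == 40
        assert res.mean_diff_percent == pytest.approx(6.0)

    def test_window_underflow_rejected(self, default_protocol):
        with pytest.raises(ValueError):
            stim_response_stats(np.ones(4), default_protocol, 0.05)


class TestEffectRecovery:
    @pytest.mark.parametrize("effect", [3.19, 3.69, 11.95])
    def test_mean_bias_below_half_point_over_100_seeds(self, default_protocol, effect):
        # reported reactive-ROI magnitudes recovered at default ROI noise
        diffs = []
        for seed in range(100):
            _, tc = simulate_roi_timecourse(
                default_protocol, 2.0, effect_percent=effect, seed=seed
            )
            res = stim_response_stats(tc, default_protocol, 2.0)
            diffs.append(res.mean_diff_percent)
        assert abs(np.mean(diffs) - effect) < 0.5

    def test_null_rois_centered_at_zero(self, default_protocol):
        diffs = [
            stim_response_stats(
                simulate_roi_timecourse(default_protocol, 2.0, 0.0, seed=s)[1],
                default_protocol, 2.0,
            ).mean_diff_percent
            for s in range(100)
        ]
        assert abs(np.mean(diffs)) < 0.1


class TestRoiPercentTimecourse:
    def test_affine_invariance_of_percent_change(self):
        rng = np.random.default_rng(2)
        conditioned = 100 + rng.random((40, 8, 8))
        roi = ROISpec.from_pixels(2, 2, 4, 4, 1e-4, 1e-4)
        tc1 = roi_percent_timecourse(_norm_series(np.zeros_like(conditioned), conditioned=conditioned), roi)
        tc2 = roi_percent_timecourse(_norm_series(np.zeros_like(conditioned), conditioned=conditioned * 7.5), roi)
        assert np.allclose(tc1, tc2)

    def test_baseline_window_mean_zero(self):
        rng = np.random.default_rng(3)
        conditioned = 50 + rng.random((40, 8, 8))
        roi = ROISpec.from_pixels(0, 0, 8, 8, 1e-4, 1e-4)
        tc = roi_percent_timecourse(_norm_series(np.zeros_like(conditioned), conditioned=conditioned), roi)
        assert tc[:10].mean() == pytest.approx(0.0, abs=1e-10)


class TestSelectRois:
    def test_single_hot_block_found(self):
        t = np.zeros((32, 32))
        t[10:12, 20:22] = 50.0
        pd_mean = np.ones((32, 32))
        rois = select_rois(_amap(t), pd_mean, 1e-4, 1e-4, roi_size_mm=0.2, n_each=1)
        reactive = rois[0]
        iz0, iz1, ix0, ix1 = reactive.pixel_bounds(1e-4, 1e-4, (32, 32))
        assert t[iz0:iz1, ix0:ix1].max() == 50.0
        assert reactive.label == "reactive"

    def test_zero_t_map_falls_back_to_vascularity(self, caplog):
        pd_mean = np.ones((32, 32))
        pd_mean[5:9, 5:9] = 10.0
        rois = select_rois(_amap(np.zeros((32, 32))), pd_mean, 1e-4, 1e-4,
                           roi_size_mm=0.4, n_each=1)
        iz0, iz1, ix0, ix1 = rois[0].pixel_bounds(1e-4, 1e-4, (32, 32))
        assert pd_mean[iz0:iz1, ix0:ix1].mean() > 1.0

    def test_selected_windows_do_not_overlap(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal((32, 32))
        pd_mean = rng.random((32, 32)) + 0.5
        rois = select_rois(_amap(t), pd_mean, 1e-4, 1e-4, roi_size_mm=0.6, n_each=2)
        boxes = [r.pixel_bounds(1e-4, 1e-4, (32, 32)) for r in rois]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                overlap = (max(a[0], b[0]) < min(a[1], b[1])) and (
                    max(a[2], b[2]) < min(a[3], b[3])
                )
                assert not overlap

    def test_matches_exhaustive_oracle(self):
        # brute-force scan over every candidate window on a small grid,
        # using the same vascularity-weighted score definitions
        rng = np.random.default_rng(5)
        t = rng.standard_normal((32, 32))
        pd_mean = rng.random((32, 32)) + 0.1
        h = w = 6
        rois = select_rois(_amap(t), pd_mean, 1e-4, 1e-4, roi_size_mm=0.6, n_each=1)
        vasc = np.array([
            [pd_mean[i:i+h, j:j+w].mean() for j in range(33 - w)]
            for i in range(33 - h)
        ])
        score = np.array([
            [(t[i:i+h, j:j+w] * pd_mean[i:i+h, j:j+w]).mean() / pd_mean[i:i+h, j:j+w].mean()
             for j in range(33 - w)]
            for i in range(33 - h)
        ])
        thresh = np.percentile(vasc, 70.0)
        score[vasc < thresh] = -np.inf
        best = np.unravel_index(np.argmax(score), score.shape)
        iz0, _, ix0, _ = rois[0].pixel_bounds(1e-4, 1e-4, (32, 32))
        assert (iz0, ix0) == best

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="align"):
            select_rois(_amap(np.zeros((8, 8))), np.ones((9, 9)), 1e-4, 1e-4)
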