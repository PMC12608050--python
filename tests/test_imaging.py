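"""Binned-pixel microscopy pipeline: denoising, binning, phase dispersion."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaquant import (
    ImageStack,
    OscillatorParams,
    StackParams,
    bin_pixels,
    compare_dispersion_slopes,
    frame_mean_trace,
    gen_image_stack,
    make_mask,
    phase_dispersion,
    pixel_peak_table,
    trim_frames,
    two_frame_min,
)
from circaquant.pipeline import analyze_stack

from conftest import raw_mad


def _stack(arr, dt=1.0, **kw):
    return ImageStack(np.asarray(arr, float), dt, **kw)


class TestTrimAndDenoise:
    def test_trim_keeps_first_frames(self):
        s = _stack(np.arange(200)[:, None, None] * np.ones((1, 4, 4)))
        out = trim_frames(s, 190)
        assert out.n_frames == 190
        assert np.array_equal(out.intensity[0], s.intensity[0])

    def test_trim_short_stack_passes_through_with_warning(self):
        s = _stack(np.ones((150, 4, 4)))
        with pytest.warns(UserWarning, match="fewer"):
            out = trim_frames(s, 190)
        assert out.n_frames == 150

    def test_trim_below_two_rejected(self):
        with pytest.raises(ValueError):
            trim_frames(_stack(np.ones((10, 4, 4))), 1)

    def test_two_frame_min_constant_stack(self):
        s = _stack(np.full((5, 3, 3), 7.0))
        out = two_frame_min(s)
        assert out.n_frames == 4
        assert np.all(out.intensity == 7.0)

    def test_two_frame_min_removes_every_hot_pixel(self):
        params = StackParams(
            n_frames=60, height=16, width=16, pixel_phase_mad_h=0.3,
            hot_pixel_rate=0.005,
            oscillator=OscillatorParams(
                noise_sd=5.0, spike_rate=0.0, duration_h=60.0, dt_h=1.0
            ),
            seed=2,
        )
        stack, truth = gen_image_stack(params, return_truth=True)
        assert len(truth.hot_events) > 0
        hot_value = stack.intensity.max()
        out = two_frame_min(stack)
        for f, r, c in truth.hot_events:
            series = out.intensity[:, r, c]
            assert np.all(series < hot_value * 0.5)

    def test_two_frame_min_pointwise_bound_and_monotone_case(self):
        rng = np.random.default_rng(0)
        arr = rng.random((6, 4, 4))
        out = two_frame_min(_stack(arr))
        assert np.all(out.intensity <= arr[:-1] + 1e-15)
        mono = np.cumsum(np.ones((6, 2, 2)), axis=0)
        out2 = two_frame_min(_stack(mono))
        assert np.array_equal(out2.intensity, mono[:-1])


class TestMaskAndBinning:
    def test_threshold_mask_covers_generated_source(self):
        params = StackParams(
            n_frames=50, height=32, width=32, mask_spec="ellipse",
            pixel_phase_mad_h=0.3,
            oscillator=OscillatorParams(
                noise_sd=2.0, spike_rate=0.0, duration_h=50.0, dt_h=1.0
            ),
            seed=4,
        )
        stack, truth = gen_image_stack(params, return_truth=True)
        mask = make_mask(stack, threshold=100.0)
        coverage = (mask & truth.mask).sum() / truth.mask.sum()
        assert coverage >= 0.95

    def test_threshold_above_max_is_empty(self):
        s = _stack(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            make_mask(s, threshold=10.0)

    def test_full_frame_polygon(self):
        s = _stack(np.ones((4, 8, 8)))
        poly = [(-1, -1), (-1, 9), (9, 9), (9, -1)]
        assert make_mask(s, roi_polygon=poly).all()

    def test_binning_sums_blocks(self):
        s = _stack(np.ones((3, 8, 8)))
        binned, keep = bin_pixels(s, 4)
        assert binned.intensity.shape == (3, 2, 2)
        assert np.all(binned.intensity == 16.0)
        assert keep.all()

    def test_binning_drops_partial_edges(self):
        s = _stack(np.ones((2, 10, 10)))
        binned, _ = bin_pixels(s, 4)
        assert binned.intensity.shape == (2, 2, 2)

    def test_binning_conserves_in_mask_counts(self):
        rng = np.random.default_rng(1)
        arr = rng.random((2, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[:4, :4] = True  # aligned with the 4x4 block grid
        binned, keep = bin_pixels(_stack(arr), 4, mask=mask)
        assert keep.sum() == 1
        assert binned.intensity[:, 0, 0] == pytest.approx(
            arr[:, :4, :4].sum(axis=(1, 2))
        )

    def test_factor_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            bin_pixels(_stack(np.ones((2, 4, 4))), 8)


class TestFrameMeanTrace:
    def test_constant_stack(self):
        tr = frame_mean_trace(_stack(np.full((5, 3, 3), 5.0)))
        assert np.all(tr.value == 5.0)
        assert np.array_equal(tr.time_h, np.arange(5.0))

    def test_masked_equals_unmasked_up_to_scale_with_zero_background(self):
        arr = np.zeros((4, 6, 6))
        arr[:, 2:4, 2:4] = np.arange(1, 5)[:, None, None]
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        a = frame_mean_trace(_stack(arr))
        b = frame_mean_trace(_stack(arr), mask=mask)
        ratio = b.value / a.value
        assert np.allclose(ratio, ratio[0])

    def test_period_recovery_through_stack(self):
        params = StackParams(
            n_frames=110, height=16, width=16, pixel_phase_mad_h=0.3,
            oscillator=OscillatorParams(
                period_h=23.0, noise_sd=5.0, spike_rate=0.0,
                duration_h=110.0, dt_h=1.0,
            ),
            seed=5,
        )
        stack = gen_image_stack(params)
        from circaquant import detrend, lomb_scargle
        tr = frame_mean_trace(stack)
        res = lomb_scargle(detrend(tr), window=(0, 109))
        assert res.best_period_h == pytest.approx(23.0, abs=0.1)


class TestPixelPeakTable:
    @staticmethod
    def _run(mad, seed, growth=0.0, size=64, noise_sd=20.0):
        params = StackParams(
            n_frames=110, height=size, width=size, pixel_phase_mad_h=mad,
            dispersion_growth_h_per_cycle=growth,
            oscillator=OscillatorParams(
                period_h=23.5, noise_sd=noise_sd, spike_rate=0.0,
                duration_h=110.0, dt_h=1.0,
            ),
            seed=seed,
        )
        stack, truth = gen_image_stack(params, return_truth=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = analyze_stack(stack, cycles=[1, 2, 3, 4])
        return result, truth

    def test_zero_dispersion_noise_free_gives_exactly_zero_mad(self):
        result, _ = self._run(0.0, seed=1, size=32, noise_sd=0.0)
        disp = result["phase_dispersion"]
        assert np.all(disp.mad_h == 0.0)

    def test_zero_dispersion_noisy_mad_stays_small(self):
        # read noise alone jitters binned-pixel peak times by well under
        # the dispersion scales of interest
        result, _ = self._run(0.0, seed=1, size=32)
        assert np.all(result["phase_dispersion"].mad_h < 0.1)

    def test_rel_peak_times_mean_centered_per_cycle(self):
        result, _ = self._run(0.5, seed=2, size=32)
        table = result["pixel_peak_table"]
        means = table.groupby("cycle_index")["rel_peak_time_h"].mean()
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-12)

    def test_mad_recovers_generator_dispersion(self):
        result, truth = self._run(0.5, seed=3, size=180)
        offs = truth.offsets_of_covered_blocks()
        assert len(offs) == 2025
        assert raw_mad(offs) == pytest.approx(0.5, abs=0.05)
        disp = result["phase_dispersion"]
        assert disp.cycle_mean_mad_h == pytest.approx(0.5, abs=0.1)

    def test_two_pixel_centering_example(self):
        # two pixels peaking +-1 h around the slice mean -> rel times -1, +1
        df = pd.DataFrame(
            {"pixel_id": [0, 1], "bin_row": [0, 0], "bin_col": [0, 1],
             "cycle_index": [1, 1], "peak_time_h": [11.0, 13.0]}
        )
        df["rel_peak_time_h"] = df["peak_time_h"] - df.groupby("cycle_index")[
            "peak_time_h"
        ].transform("mean")
        assert list(df["rel_peak_time_h"]) == [-1.0, 1.0]


class TestPhaseDispersion:
    def test_hand_computed_mad(self):
        table = pd.DataFrame(
            {"cycle_index": [1] * 5,
             "rel_peak_time_h": [-1.0, -0.5, 0.0, 0.5, 1.0]}
        )
        disp = phase_dispersion(table)
        assert disp.mad_h[0] == 0.5

    def test_all_equal_gives_zero(self):
        table = pd.DataFrame({"cycle_index": [1] * 4, "rel_peak_time_h": [2.0] * 4})
        assert phase_dispersion(table).mad_h[0] == 0.0

    def test_outlier_robustness(self):
        base = [-0.6, -0.3, -0.1, 0.0, 0.1, 0.3]
        with_outlier = base + [50.0]
        t1 = pd.DataFrame({"cycle_index": 1, "rel_peak_time_h": base + [0.6]})
        t2 = pd.DataFrame({"cycle_index": 1, "rel_peak_time_h": with_outlier})
        m1 = phase_dispersion(t1).mad_h[0]
        m2 = phase_dispersion(t2).mad_h[0]
        assert abs(m2 - m1) < 50.0 / 7

    def test_translation_and_scale(self):
        rng = np.random.default_rng(0)
        rel = rng.normal(0, 1, 50)
        t1 = pd.DataFrame({"cycle_index": 1, "rel_peak_time_h": rel})
        t2 = pd.DataFrame({"cycle_index": 1, "rel_peak_time_h": rel + 5.0})
        t3 = pd.DataFrame({"cycle_index": 1, "rel_peak_time_h": rel * 3.0})
        m = phase_dispersion(t1).mad_h[0]
        assert phase_dispersion(t2).mad_h[0] == pytest.approx(m)
        assert phase_dispersion(t3).mad_h[0] == pytest.approx(3 * m)

    def test_sparse_cycle_skipped(self):
        table = pd.DataFrame(
            {"cycle_index": [1, 1, 1, 2], "rel_peak_time_h": [-1, 0, 1, 0.0]}
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            disp = phase_dispersion(table)
        assert list(disp.cycle_index) == [1]


def _mad_frame(slopes, intercept=0.5, noise=0.05, n_slices=4, cycles=4, rng=None):
    rows = []
    for s in range(n_slices):
        for c in range(1, cycles + 1):
            rows.append(
                {"cycle_index": c,
                 "mad_h": intercept + slopes * c + rng.normal(0, noise)}
            )
    return pd.DataFrame(rows)


class TestSlopeComparison:
    def test_tiny_dataset_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        a = pd.DataFrame({"cycle_index": [1, 2, 3], "mad_h": [0.5, 0.8, 1.0]})
        b = pd.DataFrame({"cycle_index": [1, 2, 3], "mad_h": [0.6, 1.2, 1.9]})
        res = compare_dispersion_slopes(a, b)

        data = pd.concat(
            [a.assign(g="A"), b.assign(g="B")], ignore_index=True
        )
        full = smf.ols("mad_h ~ g + cycle_index + g:cycle_index", data).fit()
        red = smf.ols("mad_h ~ g + cycle_index", data).fit()
        table = anova_lm(red, full)
        assert res.f_stat == pytest.approx(float(table["F"][1]), rel=1e-8)
        assert res.p_value == pytest.approx(float(table["Pr(>F)"][1]), rel=1e-8)
        assert res.rss_shared >= res.rss_separate
        assert res.f_stat >= 0

    def test_type_I_rate_near_alpha(self):
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            a = _mad_frame(0.1, rng=rng)
            b = _mad_frame(0.1, rng=rng)
            hits += compare_dispersion_slopes(a, b).p_value < 0.05
        # binomial 99% interval around 0.05 with n=200: [0.01, 0.095]
        assert 0.01 <= hits / n_sim <= 0.095

    def test_power_against_distinct_slopes(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            a = _mad_frame(0.0, rng=rng)
            b = _mad_frame(0.3, rng=rng)
            hits += compare_dispersion_slopes(a, b).p_value < 0.05
        assert hits / n_sim >= 0.9

    def test_too_few_points_rejected(self):
        a = pd.DataFrame({"cycle_index": [1, 2], "mad_h": [0.5, 0.6]})
        b = pd.DataFrame({"cycle_index": [1, 2, 3], "mad_h": [0.5, 0.6, 0.7]})
        with pytest.raises(ValueError):
            compare_dispersion_slopes(a, b)
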