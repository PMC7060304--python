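"""Signal-conditioning checks against analytically known inputs."""

import numpy as np
import pytest

from hfoveit import preprocess
from hfoveit.core import AnalysisError, BaselineMap

from conftest import make_series, run_pipeline, short_config
from hfoveit import phantom

F0 = 9.0


class TestBaseline:
    def test_constant_series_recovers_constant(self):
        series = make_series(lambda t: 5.0, duration=10.0)
        base = preprocess.compute_baseline(series, (0.0, 10.0))
        np.testing.assert_allclose(base.values, 5.0, atol=1e-9)

    def test_picks_minimum_of_slow_signal(self):
        # slow triangular dip to 1.0 well inside the low-pass band
        def fn(t):
            return 3.0 - 2.0 * np.exp(-((t - 5.0) ** 2) / 8.0)

        series = make_series(fn, duration=10.0)
        base = preprocess.compute_baseline(series, (0.0, 10.0))
        np.testing.assert_allclose(base.values, 1.0, rtol=0.02)

    def test_oscillation_troughs_do_not_bias_minimum(self):
        # min of raw signal would be 5 - 1; the filtered minimum stays ~5
        series = make_series(lambda t: 5.0 + np.sin(2 * np.pi * F0 * t), 10.0)
        base = preprocess.compute_baseline(series, (0.0, 10.0))
        np.testing.assert_allclose(base.values, 5.0, rtol=0.01)

    def test_window_outside_recording_rejected(self):
        series = make_series(lambda t: 1.0, duration=8.0)
        with pytest.raises(AnalysisError, match="outside"):
            preprocess.compute_baseline(series, (2.0, 12.0))

    def test_phantom_floor_recovered(self):
        cfg = short_config(noise_sd=0.0, seed=11)
        trial = phantom.simulate_trial(cfg)
        base = preprocess.compute_baseline(
            trial.series, (0.0, cfg.baseline_duration_s)
        )
        np.testing.assert_allclose(
            base.values, trial.truth.baseline_map, atol=0.01
        )


class TestOscillationAmplitude:
    def test_pure_sine_reports_peak_to_peak(self):
        amp = 0.7
        series = make_series(lambda t: amp * np.sin(2 * np.pi * F0 * t), 12.0)
        vent = preprocess.oscillation_amplitude(series, (0.0, 12.0))
        np.testing.assert_allclose(vent.values, 2 * amp, rtol=0.01)

    def test_zero_signal_reports_zero(self):
        series = make_series(lambda t: 0.0, duration=12.0)
        vent = preprocess.oscillation_amplitude(series, (0.0, 12.0))
        np.testing.assert_allclose(vent.values, 0.0, atol=1e-12)

    def test_linear_drift_is_rejected_by_band_pass(self):
        amp = 0.5
        series = make_series(
            lambda t: amp * np.sin(2 * np.pi * F0 * t) + 0.1 * t, 12.0
        )
        vent = preprocess.oscillation_amplitude(series, (0.0, 12.0))
        np.testing.assert_allclose(vent.values, 2 * amp, rtol=0.02)

    def test_window_shorter_than_block_rejected(self):
        series = make_series(lambda t: 1.0, duration=6.0)
        with pytest.raises(AnalysisError, match="block"):
            preprocess.oscillation_amplitude(series, (0.0, 4.0))


class TestAeration:
    def test_constant_minus_baseline(self):
        series = make_series(lambda t: 7.5, duration=8.0)
        base = BaselineMap(np.full((32, 32), 3.0))
        aer = preprocess.aeration(series, base, (0.0, 8.0))
        np.testing.assert_allclose(aer.values, 4.5, atol=1e-9)

    def test_self_referenced_baseline_gives_zero(self):
        series = make_series(lambda t: 7.5, duration=8.0)
        base = preprocess.compute_baseline(series, (0.0, 8.0))
        aer = preprocess.aeration(series, base, (0.0, 8.0))
        np.testing.assert_allclose(aer.values, 0.0, atol=1e-9)

    def test_phantom_levels_recovered(self):
        cfg = short_config(noise_sd=0.0, seed=11)
        trial = phantom.simulate_trial(cfg)
        steps = run_pipeline(trial)
        for k in (0, len(steps) - 1):
            np.testing.assert_allclose(
                steps[k].aeration.values,
                trial.truth.aeration_maps[k],
                atol=0.01 * max(1.0, trial.truth.aeration_maps[k].max()),
            )


class TestExtractStepMaps:
    def test_one_pair_per_step_ordered_by_pressure(self, compact_trial, compact_steps):
        assert len(compact_steps) == len(compact_trial.annotations)
        mpaws = [s.mpaw for s in compact_steps]
        assert mpaws == sorted(mpaws, reverse=True)

    def test_step_exactly_analysis_length_is_accepted(self):
        cfg = short_config(step_duration_s=10.0, analysis_len_s=10.0, seed=0)
        trial = phantom.simulate_trial(cfg)
        steps = run_pipeline(trial)
        assert len(steps) == len(cfg.ladder)

    def test_too_short_step_names_step(self, compact_trial):
        base = BaselineMap(np.zeros((32, 32)))
        with pytest.raises(AnalysisError, match="step 0"):
            preprocess.extract_step_maps(
                compact_trial.series, compact_trial.annotations, base,
                analysis_len=30.0,
            )


class TestInvariances:
    """Linearity contracts of the map extraction."""

    def _series_pair(self):
        rng = np.random.default_rng(3)
        slow = rng.normal(1.0, 0.2, size=(32, 32))
        amp = rng.uniform(0.1, 0.5, size=(32, 32))

        def fn(t):
            return slow + amp * np.sin(2 * np.pi * F0 * t)

        return make_series(fn, duration=12.0)

    def test_offset_invariance(self):
        series = self._series_pair()
        shifted = type(series)(
            times=series.times,
            frames=series.frames + 10.0,
            frame_rate=series.frame_rate,
            oscillation_hz=series.oscillation_hz,
        )
        w = (0.0, 12.0)
        v1 = preprocess.oscillation_amplitude(series, w).values
        v2 = preprocess.oscillation_amplitude(shifted, w).values
        np.testing.assert_allclose(v1, v2, atol=1e-9)
        b1 = preprocess.compute_baseline(series, w).values
        b2 = preprocess.compute_baseline(shifted, w).values
        np.testing.assert_allclose(b2 - b1, 10.0, atol=1e-9)
        a1 = preprocess.aeration(series, BaselineMap(b1), w).values
        a2 = preprocess.aeration(shifted, BaselineMap(b2), w).values
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_homogeneity_of_degree_one(self):
        series = self._series_pair()
        doubled = type(series)(
            times=series.times,
            frames=2.0 * series.frames,
            frame_rate=series.frame_rate,
            oscillation_hz=series.oscillation_hz,
        )
        w = (0.0, 12.0)
        np.testing.assert_allclose(
            preprocess.oscillation_amplitude(doubled, w).values,
            2.0 * preprocess.oscillation_amplitude(series, w).values,
            atol=1e-9,
        )
        zero = BaselineMap(np.zeros((32, 32)))
        np.testing.assert_allclose(
            preprocess.aeration(doubled, zero, w).values,
            2.0 * preprocess.aeration(series, zero, w).values,
            atol=1e-9,
        )

    def test_ventilation_map_is_nonnegative(self, compact_steps):
        for s in compact_steps:
            assert np.all(s.ventilation.values >= 0)
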