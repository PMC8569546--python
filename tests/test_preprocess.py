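"""Preprocessing tests: filtering, segmentation, averaging, resizing."""

import numpy as np
import pytest

from pulse_dssn.core import FIXED_LENGTH, PulseRecord, SingleCycle
from pulse_dssn.preprocess import (
    SegmentationError,
    average_cycle,
    denoise,
    segment_cycles,
    to_fixed_length,
)
from pulse_dssn.simulate import ShapeDraw, SimulationConfig, make_cycle, make_record


def _record(profiles, cid, seed, **kw):
    cfg = SimulationConfig(record_seconds=kw.pop("record_seconds", 20.0), **kw)
    return make_record(profiles[cid], cfg, np.random.default_rng(seed)), cfg


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        rec = PulseRecord(np.zeros(2000), fs_hz=720.0)
        assert np.allclose(denoise(rec).samples, 0.0)

    def test_noiseless_train_nearly_unchanged(self, profiles):
        """Pulse energy sits below 10 Hz, so the band-pass leaves a clean
        cycle train intact (correlation > 0.99 away from the record edges)."""
        rec, _ = _record(profiles, 2, 0, noise_sd=0.0, baseline_amp=0.0)
        out = denoise(rec)
        sl = slice(2000, -2000)
        r = np.corrcoef(rec.samples[sl], out.samples[sl])[0, 1]
        assert r > 0.99

    def test_baseline_wander_removed(self, profiles):
        """A 0.3 Hz sinusoid of amplitude 50 leaves a residual below 5 after
        zero-phase high-pass filtering (least-squares fit of the residual)."""
        rec, cfg = _record(profiles, 2, 1, noise_sd=0.0, baseline_amp=50.0,
                           record_seconds=30.0)
        out = denoise(rec).samples[2000:-2000]
        t = (np.arange(rec.samples.size) / cfg.fs_hz)[2000:-2000]
        design = np.column_stack(
            [np.sin(2 * np.pi * 0.3 * t), np.cos(2 * np.pi * 0.3 * t), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(design, out, rcond=None)
        assert np.hypot(coef[0], coef[1]) < 5.0

    def test_idempotent_within_tolerance(self, profiles):
        rec, _ = _record(profiles, 1, 2, noise_sd=5.0, baseline_amp=50.0)
        once = denoise(rec)
        twice = denoise(once)
        sl = slice(2000, -2000)
        rms = np.sqrt(np.mean((twice.samples[sl] - once.samples[sl]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once.samples[sl] ** 2))

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            denoise(PulseRecord(np.ones(10), fs_hz=720.0))


class TestSegmentation:
    def test_cycle_count_matches_generator(self, profiles):
        """A noiseless record of known periods yields the true cycle count
        within one (partial edge cycles are dropped)."""
        rec, _ = _record(profiles, 2, 3, noise_sd=0.0, baseline_amp=0.0,
                         record_seconds=60.0)
        cycles = segment_cycles(rec)
        # regenerate the true mean period of this record's shape draw
        rng = np.random.default_rng(3)
        shape = profiles[2].draw_shape(rng)
        expected = 60.0 / shape.period_s
        assert abs(len(cycles) - expected) <= 2
        for c in cycles:
            assert np.argmax(c.samples) < c.samples.size / 2

    def test_detected_period_tracks_generator(self, profiles):
        rec, _ = _record(profiles, 5, 4, noise_sd=5.0, baseline_amp=50.0,
                         record_seconds=60.0)
        cycles = segment_cycles(denoise(rec))
        rng = np.random.default_rng(4)
        shape = profiles[5].draw_shape(rng)
        mean_T = np.mean([c.T for c in cycles])
        assert abs(mean_T - shape.period_s) / shape.period_s < 0.02

    def test_constant_signal_has_no_onsets(self):
        with pytest.raises(SegmentationError):
            segment_cycles(PulseRecord(np.full(5000, 3.0), fs_hz=720.0))


class TestAverageCycle:
    def test_single_cycle_round_trip(self, mean_cycle):
        cyc = mean_cycle(1)
        avg = average_cycle([cyc])
        assert np.max(np.abs(avg.samples - cyc.samples)) < 1e-6

    def test_identical_cycles_average_to_one(self, mean_cycle):
        cyc = mean_cycle(4)
        avg = average_cycle([cyc, cyc, cyc])
        np.testing.assert_allclose(avg.samples, cyc.samples, atol=1e-9)

    def test_noise_suppression_scales_with_sqrt_n(self, mean_cycle):
        """Averaging N noisy copies reduces the residual SD below 2 sigma/sqrt(N)."""
        truth = mean_cycle(2)
        sigma, n_copies = 8.0, 25
        rng = np.random.default_rng(6)
        noisy = [
            SingleCycle(truth.samples + rng.normal(0, sigma, truth.samples.size), 720.0)
            for _ in range(n_copies)
        ]
        avg = average_cycle(noisy)
        resid_sd = np.std(avg.samples - truth.samples)
        assert resid_sd < 2 * sigma / np.sqrt(n_copies)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_cycle([])

    def test_output_period_is_median(self, profiles):
        prof = profiles[3]
        rng = np.random.default_rng(7)
        cycles = [make_cycle(prof, rng) for _ in range(9)]
        avg = average_cycle(cycles)
        assert avg.samples.size == int(np.median([c.samples.size for c in cycles]))


class TestFixedLength:
    def test_length_and_range(self, mean_cycle):
        out = to_fixed_length(mean_cycle(6))
        assert out.samples.shape == (FIXED_LENGTH,)
        assert out.samples.min() >= 0.0 and out.samples.max() <= 1.0
        assert np.isclose(out.samples.max(), 1.0)

    def test_constant_cycle_maps_to_zeros(self):
        cyc = SingleCycle(np.full(500, 7.0), fs_hz=720.0)
        assert np.array_equal(to_fixed_length(cyc).samples, np.zeros(FIXED_LENGTH))

    def test_already_normalised_800_cycle_unchanged(self):
        rng = np.random.default_rng(8)
        x = rng.random(FIXED_LENGTH)
        x[0], x[1] = 0.0, 1.0  # pin the min-max range
        cyc = SingleCycle(x, fs_hz=720.0)
        np.testing.assert_allclose(to_fixed_length(cyc).samples, x, atol=1e-9)


class TestPipelineProperty:
    def test_noiseless_record_recovers_generator_h1_and_T(self, profiles):
        """segment -> average -> extract on a clean record reproduces the
        generator cycle's amplitude within 1% and period within 2%."""
        from pulse_dssn.features_time import detect_fiducials, extract_time_features

        rec, _ = _record(profiles, 2, 12, noise_sd=0.0, baseline_amp=0.0,
                         record_seconds=30.0)
        avg = average_cycle(segment_cycles(rec))
        f = extract_time_features(avg, detect_fiducials(avg))
        rng = np.random.default_rng(12)
        shape = profiles[2].draw_shape(rng)
        truth_cycle = make_cycle(profiles[2], rng, shape=shape)
        # the shape draw fixes this record's true amplitude; the onset A is
        # the pulse foot, i.e. the waveform minimum
        u = np.arange(2000) / 2000
        wave = profiles[2].waveform(u, shape)
        true_h1 = wave.max() - wave.min()
        assert abs(f.h1 - true_h1) / true_h1 < 0.01
        assert abs(f.T - shape.period_s) / shape.period_s < 0.02

    def test_denoised_noisy_average_matches_clean_average(self, profiles):
        """Denoising + averaging recovers the same representative cycle that
        a noise-free run of the same record would produce (r > 0.95)."""
        cfg_noisy = SimulationConfig(record_seconds=20.0, noise_sd=5.0,
                                     baseline_amp=50.0, baseline_freq_hz=0.3)
        cfg_clean = SimulationConfig(record_seconds=20.0, noise_sd=0.0, baseline_amp=0.0)
        noisy = make_record(profiles[1], cfg_noisy, np.random.default_rng(13))
        clean = make_record(profiles[1], cfg_clean, np.random.default_rng(13))
        a = average_cycle(segment_cycles(denoise(noisy)))
        b = average_cycle(segment_cycles(clean))
        grid = np.linspace(0, 1, 500, endpoint=False)
        ra = np.interp(grid, np.linspace(0, 1, a.samples.size, endpoint=False), a.samples)
        rb = np.interp(grid, np.linspace(0, 1, b.samples.size, endpoint=False), b.samples)
        assert np.corrcoef(ra, rb)[0, 1] > 0.95
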