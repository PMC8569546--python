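"""Simulator tests: waveform model, determinism, cohort assembly."""

import numpy as np
import pytest

from pulse_dssn.features_time import detect_fiducials, extract_time_features
from pulse_dssn.simulate import (
    ClassProfile,
    ComponentWave,
    ShapeDraw,
    SimulationConfig,
    TABLE_COUNTS,
    class_profiles,
    make_cohort,
    make_cycle,
    make_record,
    read_cohort,
    write_cohort,
)


class TestClassProfiles:
    def test_exactly_seven_calibrated_profiles(self, profiles):
        assert sorted(profiles) == list(range(1, 8))
        for cid, prof in profiles.items():
            assert prof.class_id == cid
            centers = [c.center for c in prof.component_params]
            assert centers == sorted(centers)
            main = prof.component_params[0]
            assert all(main.amp > c.amp for c in prof.component_params[1:])

    def test_invalid_profiles_rejected(self):
        comp = ComponentWave(amp=100.0, center=0.2, width_left=0.05, width_right=0.1)
        tidal = ComponentWave(amp=40.0, center=0.45, width_left=0.05, width_right=0.05)
        dic = ComponentWave(amp=30.0, center=0.65, width_left=0.06, width_right=0.06)
        with pytest.raises(ValueError, match="centers"):
            ClassProfile(1, "slippery", (tidal, comp, dic), 0.8, 0.03)
        with pytest.raises(ValueError, match="greatest"):
            big_tidal = ComponentWave(amp=150.0, center=0.45, width_left=0.05, width_right=0.05)
            ClassProfile(1, "slippery", (comp, big_tidal, dic), 0.8, 0.03)
        with pytest.raises(ValueError, match="period"):
            ClassProfile(1, "slippery", (comp, tidal, dic), -1.0, 0.03)


class TestMakeCycle:
    def test_sample_count_and_closed_form(self, profiles):
        """A noiseless cycle is the closed-form component sum on the sample
        grid; its maximum equals the analytic maximum on that grid."""
        prof = profiles[1]
        rng = np.random.default_rng(0)
        shape = ShapeDraw()
        cyc = make_cycle(prof, rng, shape=shape)
        assert cyc.samples.size == int(round(cyc.T * cyc.fs_hz))
        u = np.arange(cyc.samples.size) / cyc.samples.size
        analytic = prof.waveform(u, shape)
        np.testing.assert_allclose(cyc.samples, analytic, atol=1e-9)
        assert abs(cyc.samples.max() - analytic.max()) < 1e-6

    def test_main_peak_is_global_max_near_main_center(self, profiles):
        for cid, prof in profiles.items():
            cyc = make_cycle(prof, np.random.default_rng(cid), shape=ShapeDraw())
            b = np.argmax(cyc.samples) / cyc.samples.size
            assert abs(b - prof.component_params[0].center) < 0.02

    def test_h1_monotone_in_main_amplitude(self, profiles):
        """Raising the main-wave amplitude strictly raises extracted h1."""
        import dataclasses

        prof = profiles[2]
        h1s = []
        for scale in (0.8, 1.0, 1.2, 1.5):
            main = dataclasses.replace(
                prof.component_params[0], amp=prof.component_params[0].amp * scale
            )
            p2 = dataclasses.replace(prof, component_params=(main,) + prof.component_params[1:])
            cyc = make_cycle(p2, np.random.default_rng(0), shape=ShapeDraw())
            f = extract_time_features(cyc, detect_fiducials(cyc))
            h1s.append(f.h1)
        assert all(a < b for a, b in zip(h1s, h1s[1:]))

    def test_rejects_non_profile(self):
        with pytest.raises(TypeError):
            make_cycle("nope", np.random.default_rng(0))


class TestMakeRecord:
    def test_noiseless_record_is_cycle_tiling(self, profiles):
        """With zero noise and no wander, the record is a boundary-trimmed
        concatenation of noiseless cycles."""
        cfg = SimulationConfig(noise_sd=0.0, baseline_amp=0.0, record_seconds=10.0)
        rec = make_record(profiles[3], cfg, np.random.default_rng(4))
        assert rec.samples.size == int(round(10.0 * cfg.fs_hz))
        # regenerate with the same seed and reassemble manually
        rng = np.random.default_rng(4)
        shape = profiles[3].draw_shape(rng)
        parts = []
        total = 0
        while total < rec.samples.size:
            cyc = make_cycle(profiles[3], rng, cfg.fs_hz, shape=shape)
            parts.append(cyc.samples)
            total += cyc.samples.size
        np.testing.assert_array_equal(rec.samples, np.concatenate(parts)[: rec.samples.size])

    def test_seed_determinism(self, profiles):
        cfg = SimulationConfig(record_seconds=5.0)
        a = make_record(profiles[1], cfg, np.random.default_rng(9))
        b = make_record(profiles[1], cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_too_short_record_rejected(self, profiles):
        cfg = SimulationConfig(record_seconds=0.5)
        with pytest.raises(ValueError, match="shorter than one mean period"):
            make_record(profiles[1], cfg, np.random.default_rng(0))


class TestMakeCohort:
    def test_empty_cohort(self):
        cfg = SimulationConfig(n_per_class={c: 0 for c in range(1, 8)})
        assert make_cohort(cfg) == []

    def test_reference_counts_give_1812_records(self):
        assert sum(TABLE_COUNTS.values()) == 1812

    def test_counts_and_labels(self):
        cfg = SimulationConfig(
            n_per_class={1: 3, 2: 0, 3: 2, 4: 1, 5: 0, 6: 0, 7: 2},
            record_seconds=3.0,
        )
        cohort = make_cohort(cfg)
        labels = [r.label for r in cohort]
        assert len(cohort) == 8
        assert labels.count(1) == 3 and labels.count(3) == 2 and labels.count(4) == 1

    def test_two_seeds_differ_in_values_not_counts(self):
        counts = {c: (2 if c < 3 else 0) for c in range(1, 8)}
        a = make_cohort(SimulationConfig(n_per_class=counts, record_seconds=3.0, seed=1))
        b = make_cohort(SimulationConfig(n_per_class=counts, record_seconds=3.0, seed=2))
        assert len(a) == len(b)
        assert [r.label for r in a] == [r.label for r in b]
        assert not np.array_equal(a[0].samples, b[0].samples)

    def test_cohort_bit_determinism(self):
        counts = {c: (1 if c in (1, 4) else 0) for c in range(1, 8)}
        cfg = dict(n_per_class=counts, record_seconds=3.0, seed=11)
        a = make_cohort(SimulationConfig(**cfg))
        b = make_cohort(SimulationConfig(**cfg))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(fs_hz=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_per_class={1: -1})
        with pytest.raises(ValueError):
            SimulationConfig(n_per_class={9: 1})


class TestCohortIO:
    def test_round_trip(self, tmp_path, profiles):
        counts = {c: (1 if c in (2, 5) else 0) for c in range(1, 8)}
        cohort = make_cohort(SimulationConfig(n_per_class=counts, record_seconds=3.0, seed=3))
        write_cohort(cohort, tmp_path, seed=3)
        back = read_cohort(tmp_path)
        assert [r.id for r in back] == [r.id for r in cohort]
        assert [r.label for r in back] == [r.label for r in cohort]
        for ra, rb in zip(cohort, back):
            np.testing.assert_allclose(ra.samples, rb.samples, atol=1e-9)
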