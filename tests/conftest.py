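"""Shared fixtures: calibrated profiles, deterministic cycles and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pulse_dssn.core import SingleCycle
from pulse_dssn.simulate import ShapeDraw, SimulationConfig, class_profiles, make_cohort


@pytest.fixture(scope="session")
def profiles():
    return class_profiles()


@pytest.fixture(scope="session")
def mean_cycle(profiles):
    """Noiseless mean-parameter cycle factory: mean_cycle(class_id)."""

    def build(cid: int, fs_hz: float = 720.0) -> SingleCycle:
        prof = profiles[cid]
        n = int(round(prof.period_mean_s * fs_hz))
        u = np.arange(n) / n
        return SingleCycle(samples=prof.waveform(u, ShapeDraw()), fs_hz=fs_hz, label=cid)

    return build


@pytest.fixture(scope="session")
def micro_cohort():
    """Small noisy cohort (10 records/class, 8 s each), fixed seed."""
    cfg = SimulationConfig(
        n_per_class={c: 10 for c in range(1, 8)},
        record_seconds=8.0,
        noise_sd=5.0,
        baseline_amp=50.0,
        seed=0,
    )
    return make_cohort(cfg)


@pytest.fixture(scope="session")
def micro_reps(micro_cohort):
    from pulse_dssn.stacking import RepresentationSet

    return RepresentationSet.from_records(micro_cohort, on_error="skip")
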