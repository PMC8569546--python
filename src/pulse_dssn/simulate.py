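"""Synthetic radial-pulse waveform generator for the seven pulse types.

Each pulse cycle is modelled as the sum of three positive unimodal component
waves on a zero baseline — the standard arterial-pulse decomposition:

* the **main (percussion) wave**, an asymmetric Gaussian bump (fast upstroke,
  slower descent) whose peak is fiducial B,
* the **tidal (pre-dicrotic) wave**, a smaller Gaussian on the descending
  limb (fiducials C/D),
* the **dicrotic wave**, a late Gaussian separated from the tidal wave by the
  dicrotic notch (fiducials E/F).

Component amplitudes are in the acquisition device's arbitrary pressure
units; centres and widths are fractions of the cycle so the morphology is
period-invariant.  Per-cycle and per-record parameter jitter (amplitude
scale, main-wave width, tidal/dicrotic prominence and position, period)
reproduces the population spread of the reference per-class feature
statistics (h1, k, w, w/T) while keeping their means on target; the numeric
class profiles in :mod:`pulse_dssn._profiles` are calibrated offline against
this package's own feature extractor by ``scripts/calibrate_profiles.py``.

Randomness is consumed from a single seeded generator per cohort in a fixed
documented order (see :meth:`ClassProfile.draw_shape` and
:func:`make_record`), so a cohort is byte-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASS_NAMES, PulseRecord, SingleCycle

__all__ = [
    "ComponentWave",
    "ClassProfile",
    "SimulationConfig",
    "ShapeDraw",
    "class_profiles",
    "make_cycle",
    "make_record",
    "make_cohort",
    "write_cohort",
    "read_cohort",
    "TABLE_COUNTS",
]

#: Per-class sample sizes of the reference clinical cohort (1812 records).
TABLE_COUNTS: dict[int, int] = {1: 221, 2: 96, 3: 92, 4: 657, 5: 202, 6: 325, 7: 219}


@dataclass(frozen=True)
class ComponentWave:
    """One Gaussian-shaped component wave.

    ``center`` and the two widths are fractions of the cycle; ``width_left``
    and ``width_right`` are the standard deviations of the rising and falling
    flanks (equal for a symmetric bump).  ``amp`` is the peak height in
    signal units.
    """

    amp: float
    center: float
    width_left: float
    width_right: float

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        d = u - self.center
        sd = np.where(d < 0, self.width_left, self.width_right)
        return self.amp * np.exp(-0.5 * (d / sd) ** 2)


@dataclass(frozen=True)
class ShapeDraw:
    """Record-level morphology draw applied on top of a class profile."""

    amp_scale: float = 1.0
    width_scale: float = 1.0
    tidal_scale: float = 1.0
    dicrotic_scale: float = 1.0
    tidal_shift: float = 0.0
    dicrotic_shift: float = 0.0
    period_s: float | None = None


@dataclass(frozen=True)
class ClassProfile:
    """Waveform model parameters for one pulse type.

    ``component_params`` holds exactly three waves (main, tidal, dicrotic)
    with strictly increasing centres in (0, 1); the main wave is strictly
    the tallest.  ``target_stats`` stores the reference per-class
    mean/SD of (h1, k, w, w/T) the profile was calibrated to.
    """

    class_id: int
    class_name: str
    component_params: tuple[ComponentWave, ComponentWave, ComponentWave]
    period_mean_s: float
    period_sd_s: float
    target_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    # population jitter (coefficients of variation / positional SDs)
    amp_rel_sd: float = 0.30
    width_rel_sd: float = 0.13
    tidal_rel_sd: float = 0.12
    dicrotic_rel_sd: float = 0.15
    center_shift_sd: float = 0.02
    record_period_rel_sd: float = 0.06

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_NAMES:
            raise ValueError(f"class_id must be 1-7, got {self.class_id}")
        if len(self.component_params) != 3:
            raise ValueError("a profile needs exactly 3 component waves")
        main, tidal, dicrotic = self.component_params
        centers = [c.center for c in self.component_params]
        if not (0 < centers[0] < centers[1] < centers[2] < 1):
            raise ValueError(
                f"component centers must be strictly increasing in (0,1), got {centers}"
            )
        for c in self.component_params:
            if c.amp <= 0 or c.width_left <= 0 or c.width_right <= 0:
                raise ValueError(f"component amplitudes and widths must be positive: {c}")
        if not (main.amp > tidal.amp and main.amp > dicrotic.amp):
            raise ValueError("main-wave amplitude must be strictly greatest")
        if not (self.period_mean_s > 0 and self.period_sd_s >= 0):
            raise ValueError("period_mean_s must be > 0 and period_sd_s >= 0")

    # -- waveform -----------------------------------------------------------

    def components(self, shape: ShapeDraw | None = None) -> tuple[ComponentWave, ...]:
        """Component waves after applying a record-level shape draw."""
        if shape is None:
            return self.component_params
        main, tidal, dicrotic = self.component_params
        main = replace(
            main,
            amp=main.amp * shape.amp_scale,
            width_left=main.width_left * shape.width_scale,
            width_right=main.width_right * shape.width_scale,
        )
        tidal = replace(
            tidal,
            amp=tidal.amp * shape.amp_scale * shape.tidal_scale,
            center=tidal.center + shape.tidal_shift,
        )
        dicrotic = replace(
            dicrotic,
            amp=dicrotic.amp * shape.amp_scale * shape.dicrotic_scale,
            center=dicrotic.center + shape.dicrotic_shift,
        )
        return (main, tidal, dicrotic)

    def waveform(self, u: np.ndarray, shape: ShapeDraw | None = None) -> np.ndarray:
        """Closed-form noiseless waveform at cycle fractions ``u``."""
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        for comp in self.components(shape):
            out += comp(u)
        return out

    # -- random draws -------------------------------------------------------

    def draw_shape(self, rng: np.random.Generator) -> ShapeDraw:
        """Draw record-level morphology jitter.

        Consumes exactly seven variates in a fixed order: amplitude scale,
        main-width scale, tidal scale, dicrotic scale, tidal shift, dicrotic
        shift, record period.  All scales are truncated normals (+/- 3 SD);
        centre shifts are clipped so the centre ordering is preserved.
        """
        amp = _truncated_normal(rng, 1.0, self.amp_rel_sd)
        width = _truncated_normal(rng, 1.0, self.width_rel_sd, n_sd=2.5)
        tidal = _truncated_normal(rng, 1.0, self.tidal_rel_sd)
        dicrotic = _truncated_normal(rng, 1.0, self.dicrotic_rel_sd)
        main, tid, dic = self.component_params
        gap_lo = tid.center - main.center
        gap_hi = dic.center - tid.center
        max_shift = min(3 * self.center_shift_sd, 0.4 * min(gap_lo, gap_hi))
        t_shift = float(np.clip(rng.normal(0.0, self.center_shift_sd), -max_shift, max_shift))
        d_shift = float(np.clip(rng.normal(0.0, self.center_shift_sd), -max_shift, max_shift))
        period = _truncated_normal(
            rng, self.period_mean_s, self.record_period_rel_sd * self.period_mean_s
        )
        return ShapeDraw(amp, width, tidal, dicrotic, t_shift, d_shift, period)

    def draw_period(self, rng: np.random.Generator, mean_s: float | None = None) -> float:
        """Draw one cycle period (truncated normal, +/- 3 SD)."""
        mean = self.period_mean_s if mean_s is None else mean_s
        return _truncated_normal(rng, mean, self.period_sd_s)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n_sd: float = 3.0
) -> float:
    """Normal(mean, sd) clipped to mean +/- n_sd * sd (and strictly positive)."""
    if sd == 0:
        return float(mean)
    x = float(np.clip(rng.normal(mean, sd), mean - n_sd * sd, mean + n_sd * sd))
    return max(x, 1e-9)


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults mirror the reference acquisition protocol: 720 Hz sampling,
    60 s records, and the clinical per-class counts (1812 records in total).
    ``noise_sd`` is additive white noise in signal units; baseline wander is
    a single sinusoid (amplitude in signal units, default 0.3 Hz).
    """

    n_per_class: dict[int, int] = field(default_factory=lambda: dict(TABLE_COUNTS))
    fs_hz: float = 720.0
    record_seconds: float = 60.0
    noise_sd: float = 5.0
    baseline_amp: float = 50.0
    baseline_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if not self.record_seconds > 0:
            raise ValueError(f"record_seconds must be positive, got {self.record_seconds}")
        if self.noise_sd < 0 or self.baseline_amp < 0 or self.baseline_freq_hz < 0:
            raise ValueError("noise_sd, baseline_amp and baseline_freq_hz must be >= 0")
        for cid, n in self.n_per_class.items():
            if cid not in CLASS_NAMES:
                raise ValueError(f"unknown class id {cid}")
            if n < 0:
                raise ValueError(f"negative count for class {cid}")


def class_profiles() -> dict[int, ClassProfile]:
    """The seven calibrated class profiles, keyed by class code."""
    from ._profiles import PROFILES

    return dict(PROFILES)


def make_cycle(
    profile: ClassProfile,
    rng: np.random.Generator,
    fs_hz: float = 720.0,
    shape: ShapeDraw | None = None,
) -> SingleCycle:
    """Generate one noiseless pulse cycle.

    When ``shape`` is None a fresh record-level morphology draw is consumed,
    so standalone cycles carry the full population variance.  The cycle has
    ``round(T * fs)`` samples evaluated from the closed-form component sum.
    """
    if not isinstance(profile, ClassProfile):
        raise TypeError("profile must be a ClassProfile")
    if shape is None:
        shape = profile.draw_shape(rng)
    T = profile.draw_period(rng, shape.period_s)
    n = int(round(T * fs_hz))
    if n < 2:
        raise ValueError(f"period {T} s too short for sampling rate {fs_hz} Hz")
    u = np.arange(n) / n
    samples = profile.waveform(u, shape)
    return SingleCycle(samples=samples, fs_hz=fs_hz, label=profile.class_id)


def make_record(
    profile: ClassProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    record_id: str = "",
) -> PulseRecord:
    """Generate one multi-cycle record with noise and baseline wander.

    Randomness order: record shape draw (7 variates), then one period per
    cycle, then the baseline phase, then the white-noise array.
    """
    if config.record_seconds < profile.period_mean_s:
        raise ValueError(
            f"record_seconds={config.record_seconds} is shorter than one mean "
            f"period ({profile.period_mean_s} s) of class {profile.class_id}"
        )
    n_total = int(round(config.record_seconds * config.fs_hz))
    shape = profile.draw_shape(rng)
    parts: list[np.ndarray] = []
    total = 0
    while total < n_total:
        cyc = make_cycle(profile, rng, config.fs_hz, shape=shape)
        parts.append(cyc.samples)
        total += cyc.samples.size
    samples = np.concatenate(parts)[:n_total]
    phase = rng.uniform(0, 2 * np.pi)
    if config.baseline_amp > 0:
        t = np.arange(n_total) / config.fs_hz
        samples = samples + config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq_hz * t + phase
        )
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=n_total)
    return PulseRecord(
        samples=samples, fs_hz=config.fs_hz, label=profile.class_id, id=record_id
    )


def make_cohort(
    config: SimulationConfig, profiles: dict[int, ClassProfile] | None = None
) -> list[PulseRecord]:
    """Generate a labelled cohort, deterministic under ``config.seed``.

    Records are generated class by class in ascending class-code order from
    one seeded generator, so the full cohort is reproducible bit for bit.
    """
    if profiles is None:
        profiles = class_profiles()
    rng = np.random.default_rng(config.seed)
    cohort: list[PulseRecord] = []
    for cid in sorted(config.n_per_class):
        prof = profiles[cid]
        for i in range(config.n_per_class[cid]):
            rec = make_record(prof, config, rng, record_id=f"c{cid}_r{i:04d}")
            cohort.append(rec)
    return cohort


# -- on-disk format ---------------------------------------------------------


def write_cohort(cohort: list[PulseRecord], out_dir: str | Path, seed: int | None = None) -> Path:
    """Write one two-column CSV (time_s, amplitude) + JSON sidecar per record,
    plus a manifest CSV (path, class_id).  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        stem = rec.id or f"record_{len(rows):05d}"
        csv_path = out / f"{stem}.csv"
        t = np.arange(rec.samples.size) / rec.fs_hz
        pd.DataFrame({"time_s": t, "amplitude": rec.samples}).to_csv(csv_path, index=False)
        sidecar = {
            "fs_hz": rec.fs_hz,
            "label": rec.label,
            "seed": seed,
            "profile": CLASS_NAMES.get(rec.label) if rec.label else None,
            "id": stem,
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        rows.append({"path": csv_path.name, "class_id": rec.label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(in_dir: str | Path) -> list[PulseRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    cohort = []
    for path in manifest["path"]:
        df = pd.read_csv(in_dir / path)
        meta = json.loads((in_dir / path).with_suffix(".json").read_text())
        cohort.append(
            PulseRecord(
                samples=df["amplitude"].to_numpy(),
                fs_hz=float(meta["fs_hz"]),
                label=meta.get("label"),
                id=meta.get("id", Path(path).stem),
            )
        )
    return cohort
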