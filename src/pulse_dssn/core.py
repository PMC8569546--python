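"""Core containers for pulse signals.

A *pulse record* is a raw multi-cycle pressure trace from one acquisition
(typically ~60 s at 720 Hz).  Preprocessing reduces a record to one
representative *single cycle* (segment, then average), and finally to a
*fixed-length cycle* of 800 min-max-normalised samples, which is the input
representation shared by the wavelet-energy extractor and the 1D CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Pulse-type taxonomy: code -> name.  Four single pulses and three
#: compound pulses (a compound pulse blends the morphology of two types).
CLASS_NAMES: dict[int, str] = {
    1: "slippery",
    2: "flat",
    3: "thready",
    4: "stringy",
    5: "thready-slippery",
    6: "thready-stringy",
    7: "stringy-slippery",
}

N_CLASSES = 7

#: Common length every cycle is resampled to before the CNN / wavelet stage.
FIXED_LENGTH = 800


@dataclass
class PulseRecord:
    """Raw single-channel pulse trace with sampling rate and optional label."""

    samples: np.ndarray
    fs_hz: float
    label: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("PulseRecord.samples must be a 1-D array of length >= 2")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValueError(f"label must be a class code 1-7 or None, got {self.label}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class SingleCycle:
    """One pulse cycle starting at the onset (fiducial A).

    ``T`` is the cycle period in seconds and always equals
    ``len(samples) / fs_hz``.
    """

    samples: np.ndarray
    fs_hz: float
    label: int | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("SingleCycle.samples must be a 1-D array of length >= 2")
        if not self.fs_hz > 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")

    @property
    def T(self) -> float:
        """Cycle period in seconds."""
        return self.samples.size / self.fs_hz

    @property
    def onset_value(self) -> float:
        """Amplitude at the onset point A (first sample)."""
        return float(self.samples[0])

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0 at onset."""
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class FixedLengthCycle:
    """A cycle resampled to exactly 800 samples, min-max scaled to [0, 1]."""

    samples: np.ndarray
    source_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (FIXED_LENGTH,):
            raise ValueError(
                f"FixedLengthCycle must hold exactly {FIXED_LENGTH} samples, "
                f"got shape {self.samples.shape}"
            )
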