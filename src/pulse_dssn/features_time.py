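"""Fiducial-point detection and the 23 time-domain pulse features.

A physiological pulse cycle carries seven landmark points:

====  =============================================
A     onset (start of the systolic upstroke)
B     main (percussion) wave crest
C     main wave gorge (dip before the tidal wave)
D     tidal / pre-dicrotic wave crest
E     dicrotic notch (descending middle gorge)
F     dicrotic wave crest
G     cycle end
====  =============================================

From these, 23 features are computed: 1 slope (k), 2 areas (A_s, A_d),
6 magnitudes (h1-h5, w), 6 times (t1-t5, T) and 8 ratios.  Amplitudes are
baseline-relative (minus the amplitude at A); times are measured from A.

Conventions (the clinical literature states the symbols but not always the
formulas):

* ``k`` — mean upstroke slope, h1 divided by t1 expressed in *sample
  intervals* at the native sampling rate (i.e. ``h1 / (t1 * fs)``).  This
  per-sample convention matches the numeric scale of the reference
  per-class statistics at 720 Hz.
* ``w`` — one-third pulse width: the width of the main wave at 2/3 of h1
  above baseline (one third down from the crest), in seconds, with linear
  interpolation at the two crossings.
* ``A_s``/``A_d`` — trapezoidal integrals of the baseline-relative waveform
  over [A, E] and [E, G]: the dicrotic notch E is the systole/diastole
  boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import SingleCycle

__all__ = [
    "FiducialError",
    "FiducialPoint",
    "FiducialSet",
    "TimeFeatures",
    "FEATURE_NAMES",
    "detect_fiducials",
    "extract_time_features",
]

POINT_NAMES = ("A", "B", "C", "D", "E", "F", "G")

#: The 23 features in fixed output order.
FEATURE_NAMES = (
    "k",
    "A_s",
    "A_d",
    "h1",
    "h2",
    "h3",
    "h4",
    "h5",
    "w",
    "t1",
    "t2",
    "t3",
    "t4",
    "t5",
    "T",
    "t1_over_T",
    "t1_over_t4",
    "t5_over_t4",
    "w_over_T",
    "h2_over_h1",
    "h4_over_h1",
    "h5_over_h1",
    "As_over_Ad",
)


class FiducialError(RuntimeError):
    """Raised when the landmark structure of a cycle cannot be resolved."""


@dataclass(frozen=True)
class FiducialPoint:
    index: int
    time_s: float  # measured from A
    amplitude: float  # baseline-relative (minus amplitude at A)


@dataclass(frozen=True)
class FiducialSet:
    """The seven landmarks of one cycle, A through G."""

    points: dict[str, FiducialPoint]

    def __post_init__(self) -> None:
        if tuple(self.points) != POINT_NAMES:
            raise ValueError(f"expected points {POINT_NAMES}, got {tuple(self.points)}")
        idx = [p.index for p in self.points.values()]
        if any(b <= a for a, b in zip(idx[:-1], idx[1:])):
            raise FiducialError(f"fiducial indices not strictly increasing: {idx}")

    def __getitem__(self, name: str) -> FiducialPoint:
        return self.points[name]

    @property
    def indices(self) -> list[int]:
        return [p.index for p in self.points.values()]


def detect_fiducials(cycle: SingleCycle, prominence_frac: float = 0.02) -> FiducialSet:
    """Locate landmarks A-G on a single (smooth, denoised) cycle.

    B is the global maximum; F is the last local maximum after B whose
    prominence exceeds ``prominence_frac`` of h1 (the dicrotic wave); E is
    the deepest sample between F and the prominent maximum preceding it
    (the dicrotic notch — also the most prominent post-B minimum for
    well-formed cycles).  C/D are the extremum pair between B and E when
    the tidal wave produces one, else inflection points of the descending
    limb (zero crossings of the second derivative), else placed at thirds
    of the B-E span as a last resort.
    """
    x = np.asarray(cycle.samples, dtype=float)
    n = x.size
    if n < 50:
        raise FiducialError(f"cycle too short for fiducial detection ({n} samples)")
    b = int(np.argmax(x))
    if b == 0 or b >= n // 2:
        raise FiducialError(
            f"main-wave crest at sample {b} is not inside the first half of the cycle"
        )
    base = x[0]
    h1 = x[b] - base
    if h1 <= 0:
        raise FiducialError("non-positive main-wave amplitude")

    post = x[b:]
    maxima = np.array([], dtype=int)
    for prom in (prominence_frac, prominence_frac / 4, prominence_frac / 20):
        maxima, _ = signal.find_peaks(post, prominence=prom * h1)
        maxima = maxima[(maxima > 0) & (maxima < post.size - 1)] + b
        if maxima.size:
            break
    if maxima.size == 0:
        raise FiducialError("no dicrotic notch: no local maximum follows the main crest")
    f = int(maxima[-1])
    prev = int(maxima[-2]) if maxima.size >= 2 else b
    e = prev + int(np.argmin(x[prev : f + 1]))
    if not b < e < f:
        raise FiducialError("no dicrotic notch: notch search collapsed")

    c, d = _tidal_pair(x, b, e, prominence_frac * h1)

    fs = cycle.fs_hz
    order = [0, b, c, d, e, f, n - 1]
    pts = {
        name: FiducialPoint(index=i, time_s=i / fs, amplitude=float(x[i] - base))
        for name, i in zip(POINT_NAMES, order)
    }
    return FiducialSet(points=pts)


def _tidal_pair(x: np.ndarray, b: int, e: int, prom: float) -> tuple[int, int]:
    """C (gorge) and D (tidal crest) between B and E."""
    seg = x[b : e + 1]
    if seg.size >= 5:
        d_peaks, _ = signal.find_peaks(seg, prominence=prom)
        c_peaks, _ = signal.find_peaks(-seg, prominence=prom)
        for dp in d_peaks:
            cands = c_peaks[c_peaks < dp]
            if cands.size:
                return b + int(cands[-1]), b + int(dp)
    # fallback: inflections of the descending limb
    if seg.size >= 9:
        win = min(seg.size - (1 - seg.size % 2), 9)
        sm = signal.savgol_filter(seg, window_length=win, polyorder=3)
        d2 = np.gradient(np.gradient(sm))
        crossings = np.nonzero(np.diff(np.signbit(d2)))[0]
        crossings = crossings[(crossings > 0) & (crossings < seg.size - 2)]
        if crossings.size >= 2:
            c, d = b + int(crossings[0]), b + int(crossings[1])
            if b < c < d < e:
                return c, d
    # last resort: thirds of the span (degenerate morphology, documented)
    c = b + max(1, (e - b) // 3)
    d = b + max(2, 2 * (e - b) // 3)
    if not b < c < d < e:
        raise FiducialError("cycle too short to place tidal landmarks")
    return c, d


def _third_width(x: np.ndarray, b: int, base: float, h1: float, fs: float) -> float:
    """Width (s) of the main wave at 2/3 h1 above baseline, interpolated."""
    level = base + (2.0 / 3.0) * h1
    # walk left from the crest
    i = b
    while i > 0 and x[i - 1] >= level:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        left = (i - 1) + (level - x[i - 1]) / (x[i] - x[i - 1])
    # walk right from the crest
    j = b
    while j < x.size - 1 and x[j + 1] >= level:
        j += 1
    if j == x.size - 1:
        right = float(j)
    else:
        right = j + (x[j] - level) / (x[j] - x[j + 1])
    return (right - left) / fs


@dataclass(frozen=True)
class TimeFeatures:
    """The 23 time-domain features of one cycle, in Table-order."""

    k: float
    A_s: float
    A_d: float
    h1: float
    h2: float
    h3: float
    h4: float
    h5: float
    w: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    T: float
    t1_over_T: float
    t1_over_t4: float
    t5_over_t4: float
    w_over_T: float
    h2_over_h1: float
    h4_over_h1: float
    h5_over_h1: float
    As_over_Ad: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


def extract_time_features(cycle: SingleCycle, fid: FiducialSet) -> TimeFeatures:
    """Compute the 23 time-domain features from a cycle and its landmarks."""
    x = np.asarray(cycle.samples, dtype=float)
    fs = cycle.fs_hz
    base = float(x[0])
    B, C, D, E, F, G = (fid[p] for p in ("B", "C", "D", "E", "F", "G"))
    h1, h2, h3, h4, h5 = (p.amplitude for p in (B, C, D, E, F))
    t1, t2, t3, t4, t5 = (p.time_s for p in (B, C, D, E, F))
    T = cycle.T
    if h1 <= 0 or t1 <= 0:
        raise FiducialError("degenerate cycle: non-positive h1 or t1")

    # mean upstroke slope, per sample interval at the native rate
    k = h1 / (t1 * fs)
    w = _third_width(x, B.index, base, h1, fs)
    rel = x - base
    A_s = float(np.trapezoid(rel[: E.index + 1], dx=1.0 / fs))
    A_d = float(np.trapezoid(rel[E.index :], dx=1.0 / fs))

    return TimeFeatures(
        k=k,
        A_s=A_s,
        A_d=A_d,
        h1=h1,
        h2=h2,
        h3=h3,
        h4=h4,
        h5=h5,
        w=w,
        t1=t1,
        t2=t2,
        t3=t3,
        t4=t4,
        t5=t5,
        T=T,
        t1_over_T=t1 / T,
        t1_over_t4=t1 / t4,
        t5_over_t4=t5 / t4,
        w_over_T=w / T,
        h2_over_h1=h2 / h1,
        h4_over_h1=h4 / h1,
        h5_over_h1=h5 / h1,
        As_over_Ad=A_s / A_d if A_d != 0 else np.inf,
    )
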