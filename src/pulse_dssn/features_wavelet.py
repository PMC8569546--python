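"""Wavelet-packet energy features.

An 8-level wavelet-packet decomposition with the sym8 wavelet splits the
signal into 2^8 = 256 terminal frequency bands; the feature for band j is
its energy E_j = sum_k c_{j,k}^2 over that node's coefficients.  Pulse
energy concentrates below 10 Hz, so at 720 Hz sampling the informative
bands are the lowest few; the full 256-dimensional vector is kept as the
classifier input.

The input is zero-padded to the next multiple of 2^levels before the
transform (800 -> 1024 at defaults): zero padding leaves the signal energy
unchanged, and with periodic boundary extension every level then halves
evenly, keeping the decomposition orthogonal so that Parseval's identity
(sum of node energies = signal energy) holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import FixedLengthCycle

__all__ = ["WaveletConfig", "EnergyFeatures", "wpd_energy", "total_energy"]


@dataclass(frozen=True)
class WaveletConfig:
    wavelet_name: str = "sym8"
    levels: int = 8
    boundary_mode: str = "periodization"
    node_order: str = "freq"  # "freq" (ascending frequency) or "natural"
    relative: bool = False  # E_j / sum(E) when True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.node_order not in ("freq", "natural"):
            raise ValueError(f"node_order must be 'freq' or 'natural', got {self.node_order}")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}")


@dataclass(frozen=True)
class EnergyFeatures:
    """Terminal-node energies, one per frequency band (2^levels entries)."""

    energies: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size != len(self.node_labels):
            raise ValueError("energies and node_labels must have matching length")
        if np.any(e < -1e-12):
            raise ValueError("energies must be non-negative")
        object.__setattr__(self, "energies", e)


def wpd_energy(
    cycle: FixedLengthCycle | np.ndarray, config: WaveletConfig = WaveletConfig()
) -> EnergyFeatures:
    """Full wavelet-packet tree to depth ``levels``; energy per terminal node.

    Accepts a :class:`FixedLengthCycle` or any 1-D signal of length
    >= 2^levels.  Nodes are ordered by ascending frequency band by default
    so that band index maps monotonically to Hz.
    """
    x = cycle.samples if isinstance(cycle, FixedLengthCycle) else np.asarray(cycle, dtype=float)
    n_nodes = 2**config.levels
    if x.ndim != 1 or x.size < n_nodes:
        raise ValueError(f"signal of length {x.size} too short for {config.levels} levels")
    block = n_nodes
    if x.size % block:
        x = np.concatenate([x, np.zeros(block - x.size % block)])
    wp = pywt.WaveletPacket(
        data=x,
        wavelet=config.wavelet_name,
        mode=config.boundary_mode,
        maxlevel=config.levels,
    )
    nodes = wp.get_level(config.levels, order=config.node_order)
    energies = np.array([float(np.sum(np.square(node.data))) for node in nodes])
    if config.relative:
        tot = energies.sum()
        if tot > 0:
            energies = energies / tot
    labels = tuple(node.path for node in nodes)
    return EnergyFeatures(energies=energies, node_labels=labels)


def total_energy(features: EnergyFeatures) -> float:
    """Sum of all terminal-node energies (equals signal energy under an
    orthogonal wavelet with periodic extension)."""
    return float(np.sum(features.energies))
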