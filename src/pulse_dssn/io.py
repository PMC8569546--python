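"""Tabular on-disk formats: feature tables, predictions, metrics.

Feature tables are plain CSV, one row per record: an ``id`` column, a
``label`` column (empty when unlabelled), then the named feature columns —
the 23 time-domain symbols, or the 256 wavelet bands labelled by band index
and approximate frequency range.  Augmented tables carry a ``synthetic``
flag column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import N_CLASSES
from .features_time import FEATURE_NAMES

__all__ = [
    "time_features_frame",
    "wavelet_features_frame",
    "predictions_frame",
    "write_metrics",
    "sha256_of",
    "write_manifest",
]


def time_features_frame(
    ids: np.ndarray, labels: np.ndarray, features: np.ndarray,
    synthetic: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per cycle, the 23 named time-domain columns."""
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) features, got {feats.shape}")
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "label", labels)
    df.insert(0, "id", ids)
    if synthetic is not None:
        df["synthetic"] = np.asarray(synthetic, dtype=bool)
    return df


def wavelet_band_labels(n_bands: int = 256, fs_hz: float = 720.0) -> list[str]:
    """Column names: band index plus approximate frequency range in Hz."""
    width = fs_hz / 2 / n_bands
    return [f"E{j:03d}_{j * width:.2f}-{(j + 1) * width:.2f}Hz" for j in range(n_bands)]


def wavelet_features_frame(
    ids: np.ndarray, labels: np.ndarray, energies: np.ndarray,
    fs_hz: float = 720.0, synthetic: np.ndarray | None = None,
) -> pd.DataFrame:
    e = np.asarray(energies, dtype=float)
    df = pd.DataFrame(e, columns=wavelet_band_labels(e.shape[1], fs_hz))
    df.insert(0, "label", labels)
    df.insert(0, "id", ids)
    if synthetic is not None:
        df["synthetic"] = np.asarray(synthetic, dtype=bool)
    return df


def predictions_frame(
    ids: np.ndarray, true_labels: np.ndarray | None, predicted: np.ndarray,
    probabilities: np.ndarray,
) -> pd.DataFrame:
    """id, true_label (if known), predicted_label, p_class1..p_class7."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[1] != N_CLASSES:
        raise ValueError(f"probabilities must be (n, {N_CLASSES})")
    df = pd.DataFrame({"id": ids})
    if true_labels is not None:
        df["true_label"] = true_labels
    df["predicted_label"] = predicted
    for c in range(N_CLASSES):
        df[f"p_class{c + 1}"] = p[:, c]
    return df


def write_metrics(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=1, sort_keys=True))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: list[Path], out_path: str | Path) -> None:
    """JSON manifest mapping artifact name -> sha256 of its bytes."""
    manifest = {p.name: sha256_of(p) for p in sorted(paths)}
    Path(out_path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
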