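"""SMOTE oversampling for the imbalanced pulse-type cohort.

For each original sample x of a class with multiplicity N, N synthetic
samples are generated as ``x + u * (x_nn - x)`` with u ~ Uniform(0, 1) and
x_nn one of x's k nearest same-class neighbours (Euclidean), so every
synthetic point lies on a segment between two original same-class points.
Originals are always retained; a class of size m with multiplicity N grows
to exactly m * (N + 1).

Reference multiplicities for the clinical class proportions: N = 7 for the
flat and thready pulses, N = 3 for slippery / thready-slippery /
stringy-slippery, N = 2 for thready-stringy, N = 0 for stringy.  Balancing
belongs inside the training split only; validation and test folds are never
augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote", "DEFAULT_MULTIPLICITY"]

#: Reference per-class synthetic-sample multiplicities (class code -> N).
DEFAULT_MULTIPLICITY: dict[int, int] = {1: 3, 2: 7, 3: 7, 4: 0, 5: 3, 6: 2, 7: 3}


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    multiplicity: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MULTIPLICITY))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        for cid, n in self.multiplicity.items():
            if n < 0:
                raise ValueError(f"multiplicity for class {cid} must be >= 0, got {n}")


def smote(
    features: np.ndarray, labels: np.ndarray, config: SmoteConfig = SmoteConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample minority classes.

    Returns ``(features_out, labels_out, synthetic_flag)`` with originals
    first (in input order) and synthetic rows appended class by class.
    Deterministic under ``config.seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one label per row")
    rng = np.random.default_rng(config.seed)
    new_X: list[np.ndarray] = []
    new_y: list[np.ndarray] = []
    for cid in sorted(config.multiplicity):
        n_syn = config.multiplicity[cid]
        if n_syn == 0:
            continue
        mask = y == cid
        m = int(mask.sum())
        if m == 0:
            continue
        if m <= config.k_neighbors:
            raise ValueError(
                f"class {cid} has {m} samples, not enough for k={config.k_neighbors} "
                "SMOTE neighbours"
            )
        Xc = X[mask]
        nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(Xc)
        # first neighbour is the point itself
        idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        for i in range(m):
            picks = rng.integers(0, config.k_neighbors, size=n_syn)
            u = rng.uniform(0.0, 1.0, size=n_syn)
            neigh = Xc[idx[i, picks]]
            new_X.append(Xc[i] + u[:, None] * (neigh - Xc[i]))
            new_y.append(np.full(n_syn, cid, dtype=y.dtype))
    if new_X:
        X_out = np.vstack([X] + new_X)
        y_out = np.concatenate([y] + new_y)
    else:
        X_out, y_out = X.copy(), y.copy()
    flag = np.zeros(X_out.shape[0], dtype=bool)
    flag[X.shape[0] :] = True
    return X_out, y_out, flag
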