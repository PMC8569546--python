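"""DSSN orchestration: split, base learners, meta-features, meta-learner.

The stacked model (DSSN: DCNN- and SVM-based stacking network) fuses three
base learners — an SVM on time-domain features, an SVM on wavelet-packet
band energies, and a 1D CNN on the fixed-length cycle — through a fully
connected meta-learner that consumes the concatenated 7-class probability
vectors (3 x 7 = 21 meta-features, fixed order: svm_time, svm_wavelet,
dcnn).

Leakage control: the data are split 6:2:2 (train/validation/test,
stratified).  The meta-learner's training inputs are out-of-fold
predictions from a stratified K-fold (K = 5) *within the training split*:
no base learner ever predicts a sample it was fitted on.  Base learners
are refit on the full training split for inference; neural learners use
the validation split only for early stopping.  SMOTE augmentation, when
enabled, is applied once upstream on the training split's cycle
representation, and the three feature representations of each synthetic
sample are derived from its synthetic cycle — never on validation or test
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .balance import SmoteConfig, smote
from .core import FIXED_LENGTH, N_CLASSES, PulseRecord, SingleCycle
from .evaluate import MetricsReport, confusion, macro_metrics
from .features_time import FiducialError, detect_fiducials, extract_time_features
from .features_wavelet import WaveletConfig, wpd_energy
from .models import (
    DcnnConfig,
    FcnnConfig,
    SvmConfig,
    fit_dcnn,
    fit_fcnn,
    fit_svm,
)
from .preprocess import preprocess_record, to_fixed_length

__all__ = [
    "SplitSpec",
    "RepresentationSet",
    "StackedModel",
    "split",
    "build_meta_features",
    "fit_dssn",
    "predict_dssn",
]

META_ORDER = ("svm_time", "svm_wavelet", "dcnn")


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.train + self.val + self.test}"
            )
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("all split fractions must be positive")


def split(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, stratified train/val/test index sets."""
    y = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    groups = [np.nonzero(y == c)[0] for c in np.unique(y)] if spec.stratified else [
        np.arange(y.size)
    ]
    for idx in groups:
        if idx.size < 5:
            raise ValueError(f"class with {idx.size} samples is too small to split 6:2:2")
        perm = rng.permutation(idx)
        n_tr = int(round(spec.train * idx.size))
        n_va = int(round(spec.val * idx.size))
        n_tr = min(n_tr, idx.size - 2)  # keep val and test non-empty
        n_va = max(1, min(n_va, idx.size - n_tr - 1))
        train_idx.append(perm[:n_tr])
        val_idx.append(perm[n_tr : n_tr + n_va])
        test_idx.append(perm[n_tr + n_va :])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
    )


@dataclass
class RepresentationSet:
    """Per-sample feature representations derived from one cycle each.

    ``raw_cycles`` holds the representative cycle of each record resampled
    to 800 points *without* normalisation, together with its period ``T``;
    this pair is lossless enough to re-derive all three classifier inputs,
    which is what makes upstream SMOTE (interpolation in cycle space)
    consistent across branches.
    """

    ids: np.ndarray
    labels: np.ndarray
    raw_cycles: np.ndarray  # (n, 800), signal units
    periods: np.ndarray  # (n,), seconds
    time_features: np.ndarray  # (n, 23)
    wavelet_features: np.ndarray  # (n, 256)
    cycles: np.ndarray  # (n, 800), min-max normalised

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, idx: np.ndarray) -> "RepresentationSet":
        return RepresentationSet(
            self.ids[idx],
            self.labels[idx],
            self.raw_cycles[idx],
            self.periods[idx],
            self.time_features[idx],
            self.wavelet_features[idx],
            self.cycles[idx],
        )

    @staticmethod
    def derive_one(
        raw800: np.ndarray, period_s: float, fs_hz: float = 720.0,
        wavelet: WaveletConfig = WaveletConfig(),
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time 23, wavelet 256, normalised 800) from one raw cycle."""
        n = max(100, int(round(period_s * fs_hz)))
        src = np.linspace(0.0, 1.0, raw800.size, endpoint=False)
        native = np.interp(np.linspace(0.0, 1.0, n, endpoint=False), src, raw800)
        cyc = SingleCycle(samples=native, fs_hz=fs_hz)
        tfe = extract_time_features(cyc, detect_fiducials(cyc)).to_array()
        fixed = to_fixed_length(cyc)
        wfe = wpd_energy(fixed, wavelet).energies
        return tfe, wfe, fixed.samples

    @classmethod
    def from_records(
        cls,
        cohort: list[PulseRecord],
        wavelet: WaveletConfig = WaveletConfig(),
        on_error: str = "raise",
    ) -> "RepresentationSet":
        """Preprocess every record and derive all three representations.

        ``on_error='skip'`` drops records whose landmark structure cannot be
        resolved instead of raising.
        """
        ids, labels, raws, periods, tf, wf, cy = [], [], [], [], [], [], []
        for rec in cohort:
            try:
                avg = preprocess_record(rec)
                raw800 = np.interp(
                    np.linspace(0.0, 1.0, FIXED_LENGTH, endpoint=False),
                    np.linspace(0.0, 1.0, avg.samples.size, endpoint=False),
                    avg.samples,
                )
                t, w, c = cls.derive_one(raw800, avg.T, rec.fs_hz, wavelet)
            except (FiducialError, RuntimeError) as err:
                if on_error == "skip":
                    continue
                raise RuntimeError(f"record {rec.id!r}: {err}") from err
            ids.append(rec.id)
            labels.append(rec.label if rec.label is not None else -1)
            raws.append(raw800)
            periods.append(avg.T)
            tf.append(t)
            wf.append(w)
            cy.append(c)
        return cls(
            np.array(ids),
            np.array(labels),
            np.array(raws),
            np.array(periods),
            np.array(tf),
            np.array(wf),
            np.array(cy),
        )


def build_meta_features(
    p_svm_time: np.ndarray,
    p_svm_wavelet: np.ndarray,
    p_dcnn: np.ndarray,
    ids: tuple[np.ndarray, ...] | None = None,
) -> np.ndarray:
    """Concatenate the three 7-class probability blocks into 21-dim rows.

    When per-learner ``ids`` are given they must match exactly (same
    samples, same order).
    """
    blocks = (p_svm_time, p_svm_wavelet, p_dcnn)
    if ids is not None:
        first = np.asarray(ids[0])
        for other in ids[1:]:
            if not np.array_equal(first, np.asarray(other)):
                raise ValueError("base-learner outputs cover different sample ids")
    shapes = {b.shape for b in blocks}
    if len(shapes) != 1 or next(iter(shapes))[1] != N_CLASSES:
        raise ValueError(f"expected matching (n, {N_CLASSES}) blocks, got {shapes}")
    return np.hstack(blocks)


@dataclass
class StackedModel:
    """Fitted DSSN: three base learners + FCNN meta-learner + metadata."""

    svm_time: object
    svm_wavelet: object
    dcnn: object
    fcnn: object
    split_indices: dict[str, np.ndarray]
    split_ids: dict[str, np.ndarray]
    oof_folds: dict[str, np.ndarray] = field(default_factory=dict)
    configs: dict = field(default_factory=dict)
    seed: int = 0

    def base_probas(self, reps: RepresentationSet) -> dict[str, np.ndarray]:
        return {
            "svm_time": self.svm_time.predict_proba(reps.time_features),
            "svm_wavelet": self.svm_wavelet.predict_proba(reps.wavelet_features),
            "dcnn": self.dcnn.predict_proba(reps.cycles),
        }

    def save(self, out_dir: str | Path) -> Path:
        import joblib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, out / "dssn_model.joblib")
        import json

        (out / "config.json").write_text(
            json.dumps({k: repr(v) for k, v in self.configs.items()}, indent=1)
        )
        for name in ("dcnn", "fcnn"):
            learner = getattr(self, name)
            if hasattr(learner, "log"):
                import pandas as pd

                pd.DataFrame(
                    {
                        "epoch": range(len(learner.log.val_loss)),
                        "train_loss": learner.log.train_loss,
                        "val_loss": learner.log.val_loss,
                    }
                ).to_csv(out / f"{name}_training_log.csv", index=False)
        return out / "dssn_model.joblib"

    @staticmethod
    def load(model_dir: str | Path) -> "StackedModel":
        import joblib

        return joblib.load(Path(model_dir) / "dssn_model.joblib")


def _seed_for(seed: int, tag: int) -> int:
    return int((seed * 1000003 + tag) % (2**31 - 1))


def fit_dssn(
    reps: RepresentationSet,
    split_spec: SplitSpec | None = None,
    svm_config: SvmConfig = SvmConfig(),
    dcnn_config: DcnnConfig = DcnnConfig(),
    fcnn_config: FcnnConfig = FcnnConfig(),
    smote_config: SmoteConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    grid_search: bool = False,
) -> StackedModel:
    """Train the full stacking network on a preprocessed cohort."""
    if split_spec is None:
        split_spec = SplitSpec(seed=seed)
    idx_tr, idx_va, idx_te = split(reps.labels, split_spec)
    train = reps.subset(idx_tr)
    val = reps.subset(idx_va)

    if smote_config is not None:
        train = _augment_train(train, smote_config)

    y_tr = train.labels
    y_va = val.labels

    # out-of-fold meta-features within the training split
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=_seed_for(seed, 17))
    oof = {name: np.zeros((len(train), N_CLASSES)) for name in META_ORDER}
    fold_of = np.full(len(train), -1)
    for fold, (fit_idx, out_idx) in enumerate(skf.split(train.time_features, y_tr)):
        fold_of[out_idx] = fold
        svm_t = fit_svm(
            train.time_features[fit_idx], y_tr[fit_idx], svm_config,
            seed=_seed_for(seed, 100 + fold),
        )
        svm_w = fit_svm(
            train.wavelet_features[fit_idx], y_tr[fit_idx], svm_config,
            seed=_seed_for(seed, 200 + fold),
        )
        dcnn = fit_dcnn(
            train.cycles[fit_idx], y_tr[fit_idx], (val.cycles, y_va),
            dcnn_config, seed=_seed_for(seed, 300 + fold),
        )
        oof["svm_time"][out_idx] = svm_t.predict_proba(train.time_features[out_idx])
        oof["svm_wavelet"][out_idx] = svm_w.predict_proba(train.wavelet_features[out_idx])
        oof["dcnn"][out_idx] = dcnn.predict_proba(train.cycles[out_idx])

    # final base learners on the full training split (used for inference)
    val_pair = (val.time_features, y_va)
    svm_time = fit_svm(
        train.time_features, y_tr, svm_config, grid_search=grid_search,
        validation=val_pair if grid_search else None, seed=_seed_for(seed, 1),
    )
    svm_wavelet = fit_svm(
        train.wavelet_features, y_tr, svm_config, grid_search=grid_search,
        validation=(val.wavelet_features, y_va) if grid_search else None,
        seed=_seed_for(seed, 2),
    )
    dcnn = fit_dcnn(
        train.cycles, y_tr, (val.cycles, y_va), dcnn_config, seed=_seed_for(seed, 3)
    )

    meta_train = build_meta_features(oof["svm_time"], oof["svm_wavelet"], oof["dcnn"])
    meta_val = build_meta_features(
        svm_time.predict_proba(val.time_features),
        svm_wavelet.predict_proba(val.wavelet_features),
        dcnn.predict_proba(val.cycles),
    )
    fcnn = fit_fcnn(
        meta_train, y_tr, (meta_val, y_va), fcnn_config, seed=_seed_for(seed, 4)
    )

    return StackedModel(
        svm_time=svm_time,
        svm_wavelet=svm_wavelet,
        dcnn=dcnn,
        fcnn=fcnn,
        split_indices={"train": idx_tr, "val": idx_va, "test": idx_te},
        split_ids={
            "train": reps.ids[idx_tr],
            "val": reps.ids[idx_va],
            "test": reps.ids[idx_te],
        },
        oof_folds={"train_fold": fold_of, "train_ids": train.ids},
        configs={
            "svm": svm_config,
            "dcnn": dcnn_config,
            "fcnn": fcnn_config,
            "split": split_spec,
            "smote": smote_config,
            "n_folds": n_folds,
        },
        seed=seed,
    )


def _augment_train(train: RepresentationSet, cfg: SmoteConfig) -> RepresentationSet:
    """Upstream SMOTE: interpolate in (raw cycle, period) space, then derive
    every representation of each synthetic sample from its synthetic cycle."""
    base = np.hstack([train.raw_cycles, train.periods[:, None]])
    aug, labels, flag = smote(base, train.labels, cfg)
    syn = aug[flag]
    syn_labels = labels[flag]
    tf, wf, cy = [], [], []
    keep = []
    for i, row in enumerate(syn):
        try:
            t, w, c = RepresentationSet.derive_one(row[:-1], float(row[-1]))
        except (FiducialError, RuntimeError):
            continue  # rare degenerate interpolation; drop it
        keep.append(i)
        tf.append(t)
        wf.append(w)
        cy.append(c)
    keep = np.array(keep, dtype=int)
    if keep.size == 0:
        return train
    syn_ids = np.array([f"syn_{i:05d}" for i in range(keep.size)])
    return RepresentationSet(
        ids=np.concatenate([train.ids, syn_ids]),
        labels=np.concatenate([train.labels, syn_labels[keep]]),
        raw_cycles=np.vstack([train.raw_cycles, syn[keep, :-1]]),
        periods=np.concatenate([train.periods, syn[keep, -1]]),
        time_features=np.vstack([train.time_features, np.array(tf)]),
        wavelet_features=np.vstack([train.wavelet_features, np.array(wf)]),
        cycles=np.vstack([train.cycles, np.array(cy)]),
    )


def predict_dssn(
    model: StackedModel, reps: RepresentationSet
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted class codes, 7-class probabilities) for a cohort."""
    if len(reps) == 0:
        return np.array([], dtype=int), np.empty((0, N_CLASSES))
    base = model.base_probas(reps)
    meta = build_meta_features(base["svm_time"], base["svm_wavelet"], base["dcnn"])
    proba = model.fcnn.predict_proba(meta)
    return proba.argmax(axis=1) + 1, proba


def evaluate_split(
    model: StackedModel, reps: RepresentationSet, which: str = "test"
) -> dict[str, MetricsReport]:
    """Metrics for the three base learners and the DSSN on one split."""
    sub = reps.subset(model.split_indices[which])
    out: dict[str, MetricsReport] = {}
    base = model.base_probas(sub)
    for name in META_ORDER:
        pred = base[name].argmax(axis=1) + 1
        out[name] = macro_metrics(confusion(sub.labels, pred))
    pred, _ = predict_dssn(model, sub)
    out["dssn"] = macro_metrics(confusion(sub.labels, pred))
    return out
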