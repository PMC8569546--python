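"""End-to-end pipeline: simulate -> preprocess -> features -> train -> report.

``run_pipeline`` executes every stage from one :class:`PipelineConfig`,
writes the feature tables, predictions, metrics and a hash manifest to the
output directory, and returns the test-split metrics of the stacked model.
All artifacts are deterministic functions of the configuration (including
its seed), so rerunning the same configuration reproduces identical
manifest hashes.  Per-stage timing and seeds are logged to stderr.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from .balance import SmoteConfig
from .config import PipelineConfig
from .evaluate import MetricsReport
from .io import (
    predictions_frame,
    time_features_frame,
    wavelet_features_frame,
    write_manifest,
    write_metrics,
)
from .models import DcnnConfig, FcnnConfig, SvmConfig
from .simulate import SimulationConfig, make_cohort
from .stacking import (
    RepresentationSet,
    SplitSpec,
    StackedModel,
    evaluate_split,
    fit_dssn,
    predict_dssn,
)

__all__ = ["run_pipeline", "make_fixtures"]

log = logging.getLogger("pulse_dssn")


def _stage(name: str, t0: float) -> None:
    log.info("stage %-12s %6.1f s", name, time.time() - t0)


def run_pipeline(config: PipelineConfig) -> MetricsReport:
    """Run every stage and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    log.info("pipeline seed %d", config.seed)

    t0 = time.time()
    sim = SimulationConfig(
        n_per_class=dict(config.simulate.n_per_class),
        fs_hz=config.simulate.fs_hz,
        record_seconds=config.simulate.record_seconds,
        noise_sd=config.simulate.noise_sd,
        baseline_amp=config.simulate.baseline_amp,
        baseline_freq_hz=config.simulate.baseline_freq_hz,
        seed=config.seed,
    )
    cohort = make_cohort(sim)
    _stage("simulate", t0)

    t0 = time.time()
    try:
        reps = RepresentationSet.from_records(cohort, on_error="skip")
    except RuntimeError as err:
        raise RuntimeError(f"preprocessing failed: {err}") from err
    log.info("preprocessed %d of %d records", len(reps), len(cohort))
    _stage("preprocess", t0)

    t0 = time.time()
    tf = time_features_frame(reps.ids, reps.labels, reps.time_features)
    wf = wavelet_features_frame(reps.ids, reps.labels, reps.wavelet_features)
    tf.to_csv(out / "time_features.csv", index=False)
    wf.to_csv(out / "wavelet_features.csv", index=False)
    artifacts += [out / "time_features.csv", out / "wavelet_features.csv"]
    _stage("features", t0)

    t0 = time.time()
    smote_cfg = (
        SmoteConfig(
            k_neighbors=config.smote.k_neighbors,
            multiplicity=dict(config.smote.multiplicity),
            seed=config.seed,
        )
        if config.smote.enabled
        else None
    )
    model = fit_dssn(
        reps,
        split_spec=SplitSpec(
            train=config.split.train,
            val=config.split.val,
            test=config.split.test,
            stratified=config.split.stratified,
            seed=config.seed,
        ),
        svm_config=SvmConfig(C=config.svm.C, gamma=config.svm.gamma),
        dcnn_config=DcnnConfig(
            batch_size=config.dcnn.batch_size,
            max_epochs=config.dcnn.max_epochs,
            patience=config.dcnn.patience,
        ),
        fcnn_config=FcnnConfig(
            batch_size=config.fcnn.batch_size,
            max_epochs=config.fcnn.max_epochs,
            patience=config.fcnn.patience,
        ),
        smote_config=smote_cfg,
        n_folds=config.stacking.n_folds,
        seed=config.seed,
        grid_search=config.svm.grid_search,
    )
    _stage("train", t0)

    t0 = time.time()
    pred, proba = predict_dssn(model, reps)
    predictions_frame(reps.ids, reps.labels, pred, proba).to_csv(
        out / "predictions.csv", index=False
    )
    artifacts.append(out / "predictions.csv")
    results = evaluate_split(model, reps, "test")
    for name, report in results.items():
        write_metrics(report, out / f"metrics_{name}.json")
        artifacts.append(out / f"metrics_{name}.json")
    (out / "config.json").write_text(config.model_dump_json(indent=1))
    artifacts.append(out / "config.json")
    write_manifest(artifacts, out / "manifest.json")
    _stage("evaluate", t0)

    return results["dssn"]


def make_fixtures(seed: int = 0, n_per_class: int = 10):
    """Deterministic micro-cohort for tests: 10 records per class, 8 s each.

    Candidate records are screened through preprocessing so every fixture is
    usable downstream (the simulator occasionally draws a morphology whose
    dicrotic notch cannot be resolved, as clinical acquisitions do).
    """
    from .features_time import FiducialError
    from .preprocess import preprocess_record
    from .simulate import class_profiles, make_record

    profiles = class_profiles()
    sim = SimulationConfig(
        n_per_class={},
        record_seconds=8.0,
        noise_sd=5.0,
        baseline_amp=50.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    cohort = []
    for cid in range(1, 8):
        kept = 0
        attempt = 0
        while kept < n_per_class and attempt < 4 * n_per_class:
            rec = make_record(profiles[cid], sim, rng, record_id=f"c{cid}_f{kept:03d}")
            attempt += 1
            try:
                avg = preprocess_record(rec)
                from .stacking import RepresentationSet

                RepresentationSet.derive_one(
                    np.interp(
                        np.linspace(0, 1, 800, endpoint=False),
                        np.linspace(0, 1, avg.samples.size, endpoint=False),
                        avg.samples,
                    ),
                    avg.T,
                    rec.fs_hz,
                )
            except (FiducialError, RuntimeError):
                continue
            cohort.append(rec)
            kept += 1
        if kept < n_per_class:
            raise RuntimeError(f"could not generate {n_per_class} fixtures for class {cid}")
    return cohort
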