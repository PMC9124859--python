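"""End-to-end orchestration: simulate -> filter -> invert -> scouts -> classify.

`run_subject_level` trains and scores one classifier per simulated subject on
a stratified 90/10 split of that subject's 84 trials; `run_group_level`
pools all subjects with the 10-part group split and trains a single model.
Every stage writes its artifacts (metrics JSON, learning-curve CSV, model
checkpoint, provenance log) under the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .dualcnn import DualCNNClassifier
from .evaluate import (AblationSpec, MetricsReport, compute_metrics,
                       group_split, run_ablation, subject_split)
from .inverse import WMNEInverse
from .preprocess import FilterSpec, bandpass, baseline_segments
from .scouts import assemble_input, extract_scout_series
from .simulate import (SimConfig, generate_dataset,
                       simulation_forward_model, to_raw_recording)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_subject_level", "run_group_level"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; a pure function of (config, seed)."""

    sim: SimConfig = field(default_factory=SimConfig)
    band_low: float = 8.0
    band_high: float = 30.0
    filter_order: int = 4
    lam: float | str = "auto"
    gamma: float = 0.5
    loading: float = 0.1
    weight_sharing: str = "independent"
    dropout_rate: float = 0.3
    use_spatial_dropout: bool = True
    use_batchnorm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 32
    iterations: int = 600
    train_fraction: float = 0.9
    folds: int = 10
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed drives every stochastic stage
        if self.sim.seed != self.seed:
            self.sim = replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim.pop("class_templates", None)
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _filter_segments(segments, fs, cfg: PipelineConfig):
    sos = sp_signal.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                           btype="bandpass", fs=fs, output="sos")
    return [sp_signal.sosfiltfilt(sos, s, axis=-1) for s in segments]


def _prepare_assembled(cfg: PipelineConfig):
    """Shared front half of both pipelines: simulate through scout assembly."""
    t0 = time.perf_counter()
    dataset = generate_dataset(cfg.sim)
    logger.info("simulated %d trials in %.1fs", dataset.epochs.n_trials,
                time.perf_counter() - t0)

    spec = FilterSpec(low=cfg.band_low, high=cfg.band_high,
                      order=cfg.filter_order)
    filtered = bandpass(dataset.epochs, spec)

    montage, _, leadfield, scouts, pairing = simulation_forward_model(cfg.sim)
    baseline = []
    for subject in range(cfg.sim.n_subjects):
        raw = to_raw_recording(dataset, subject)
        baseline.extend(baseline_segments(raw, policy="rest"))
    baseline = _filter_segments(baseline, cfg.sim.fs, cfg)

    imager = WMNEInverse(leadfield=leadfield, lam=cfg.lam, gamma=cfg.gamma,
                         loading=cfg.loading)
    imager.fit(baseline)
    logger.info("WMNE lambda = %.4g", imager.lambda_)
    source_epochs = imager.transform(filtered)
    series = extract_scout_series(source_epochs, scouts)
    assembled = assemble_input(series, pairing)
    return dataset, assembled, imager


def _classifier(cfg: PipelineConfig) -> DualCNNClassifier:
    return DualCNNClassifier(
        weight_sharing=cfg.weight_sharing,
        dropout_rate=cfg.dropout_rate,
        use_spatial_dropout=cfg.use_spatial_dropout,
        use_batchnorm=cfg.use_batchnorm,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        n_iter=cfg.iterations,
        random_state=cfg.seed,
    )


def _write_artifacts(out: Path, cfg: PipelineConfig, clf, report: MetricsReport,
                     lam: float) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.save(out / "metrics.json")
    report.confusion_frame().to_csv(out / "confusion.csv")
    import pandas as pd
    frame = pd.DataFrame(clf.history_)
    frame.insert(0, "iteration", np.arange(1, len(frame) + 1))
    frame.to_csv(out / "history.csv", index=False)
    params = {f"param_{i}_{name}": p
              for i, (name, p, _) in enumerate(clf.model_.parameters())}
    np.savez(out / "checkpoint.npz", **params)
    (out / "architecture.json").write_text(
        json.dumps(asdict(clf.architecture_), indent=2, default=str))
    import scipy
    import sklearn
    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "lambda": lam,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "sklearn": sklearn.__version__},
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))


def run_subject_level(cfg: PipelineConfig) -> list[MetricsReport]:
    """Per-subject 90/10 experiment; returns one report per subject."""
    dataset, assembled, imager = _prepare_assembled(cfg)
    labels = dataset.epochs.labels
    reports = []
    for subject in range(cfg.sim.n_subjects):
        mask = dataset.subject_ids == subject
        idx = np.flatnonzero(mask)
        split = subject_split(labels[idx], fraction=cfg.train_fraction,
                              seed=cfg.seed + subject)
        tr, te = idx[split.train_indices], idx[split.test_indices]
        clf = _classifier(cfg)
        t0 = time.perf_counter()
        clf.fit(assembled[tr], labels[tr],
                eval_set=(assembled[te], labels[te]))
        logger.info("subject %d: trained %d iterations in %.1fs", subject,
                    cfg.iterations, time.perf_counter() - t0)
        from .evaluate import _full_probs
        report = compute_metrics(_full_probs(clf, assembled[te]), labels[te])
        reports.append(report)
        if cfg.out_dir is not None:
            _write_artifacts(Path(cfg.out_dir) / f"subject_{subject:02d}",
                             cfg, clf, report, imager.lambda_)
    return reports


def run_group_level(
    cfg: PipelineConfig,
    ablation: bool = False,
) -> MetricsReport | dict[str, MetricsReport]:
    """Pooled experiment across subjects with the 10-part group split."""
    if cfg.sim.n_subjects < 2:
        raise ValueError("group-level run needs at least 2 subjects")
    dataset, assembled, imager = _prepare_assembled(cfg)
    labels = dataset.epochs.labels
    split = group_split(dataset.subject_ids, folds=cfg.folds, seed=cfg.seed)
    if ablation:
        params = dict(weight_sharing=cfg.weight_sharing,
                      dropout_rate=cfg.dropout_rate,
                      learning_rate=cfg.learning_rate,
                      batch_size=cfg.batch_size, n_iter=cfg.iterations,
                      random_state=cfg.seed)
        reports = run_ablation(assembled, labels, split, base_params=params,
                               spec=AblationSpec())
        if cfg.out_dir is not None:
            out = Path(cfg.out_dir) / "group_ablation"
            out.mkdir(parents=True, exist_ok=True)
            for name, rep in reports.items():
                rep.save(out / f"metrics_{name}.json")
        return reports
    tr, te = split.train_indices, split.test_indices
    clf = _classifier(cfg)
    clf.fit(assembled[tr], labels[tr], eval_set=(assembled[te], labels[te]))
    from .evaluate import _full_probs
    report = compute_metrics(_full_probs(clf, assembled[te]), labels[te])
    if cfg.out_dir is not None:
        _write_artifacts(Path(cfg.out_dir) / "group", cfg, clf, report,
                         imager.lambda_)
    return report
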