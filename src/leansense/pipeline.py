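"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
encode -> train -> evaluate, as one reproducible, logged run.

Every run is fully determined by its :class:`RunConfig` (including one
cohort seed and one soft-sensor seed); the run report JSON embeds the
config, a config hash and per-stage cardinalities so the dataset
bookkeeping (subjects, segments, images) is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import connectivity as conn
from . import softsensor as ss
from .encoder import build_image_dataset
from .io import write_cohort
from .preprocess import PreprocessConfig, preprocess
from .recording import Recording
from .synth import make_cohort
from .task import ANALYSIS_SUBTASKS

log = logging.getLogger("leansense")


@dataclass
class RunConfig:
    """Fully specified pipeline run."""

    n_subjects: int = 24
    fs: float = 128.0
    cohort_seed: int = 7
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_lag: int = 0
    analysis_subtasks: tuple[str, ...] = ANALYSIS_SUBTASKS
    soft_sensor: ss.SoftSensorConfig = field(default_factory=ss.SoftSensorConfig)
    output_dir: str = "leansense_run"
    write_recordings: bool = False
    write_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "soft_sensor" in kwargs:
            sc = dict(kwargs["soft_sensor"])
            if "conv_blocks" in sc:
                sc["conv_blocks"] = [
                    (f, tuple(k), tuple(p)) for f, k, p in sc["conv_blocks"]
                ]
            if "shallow_features" in sc:
                sc["shallow_features"] = tuple(sc["shallow_features"])
            kwargs["soft_sensor"] = ss.SoftSensorConfig(**sc)
        if "analysis_subtasks" in kwargs:
            kwargs["analysis_subtasks"] = tuple(kwargs["analysis_subtasks"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def subject_connectivity(kata: Recording, cpdna: Recording,
                         max_lag: int = 0) -> tuple[dict, list]:
    """Correlation matrices on the 250-s analysis windows + hypothesis verdicts."""
    mats = {
        "KATA": conn.correlation_matrix(kata.subtask_window("KATA-III"),
                                        max_lag=max_lag),
        "CPDnA": conn.correlation_matrix(cpdna.subtask_window("Plan"),
                                         max_lag=max_lag),
    }
    reports = conn.evaluate_hypotheses(mats["KATA"], mats["CPDnA"])
    return mats, reports


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        log.info("stage %s ...", name)
        return name

    try:
        name = stage("simulate")
        cohort = make_cohort(config.n_subjects, config.fs, config.cohort_seed)
        report["stages"][name] = {"recordings": len(cohort),
                                  "subjects": config.n_subjects}
        if config.write_recordings:
            write_cohort(cohort, out / "cohort", seed=config.cohort_seed)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        name = stage("preprocess")
        pre = [preprocess(r, config.preprocess) for r in cohort]
        for raw, clean in zip(cohort, pre):
            log.info("  %s/%s: raw range [%.2f, %.2f] -> [%.2f, %.2f]",
                     raw.subject_id, raw.task, raw.data.min(), raw.data.max(),
                     clean.data.min(), clean.data.max())
        report["stages"][name] = {"recordings": len(pre)}
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    try:
        name = stage("connectivity")
        by_subject: dict[str, dict[str, Recording]] = {}
        for r in pre:
            by_subject.setdefault(r.subject_id, {})[r.task] = r
        verdicts: dict[str, dict[str, str]] = {}
        supported_counts = {h.id: 0 for h in conn.default_hypotheses()}
        first_mats = None
        for sid in sorted(by_subject):
            mats, reports = subject_connectivity(
                by_subject[sid]["KATA"], by_subject[sid]["CPDnA"],
                max_lag=config.max_lag)
            if first_mats is None:
                first_mats = (mats, reports)
            verdicts[sid] = {r.spec.id: r.verdict for r in reports}
            for r in reports:
                supported_counts[r.spec.id] += r.verdict == "supported"
        (out / "connectivity.json").write_text(conn.report_to_json(
            first_mats[1], first_mats[0]))
        report["stages"][name] = {
            "per_subject_verdicts": verdicts,
            "supported_counts": supported_counts,
            "n_subjects": len(by_subject),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("connectivity", e) from e

    try:
        name = stage("encode")
        img_dir = out / "images" if config.write_images else None
        dataset = build_image_dataset(pre, config.analysis_subtasks, img_dir)
        dataset.entries.to_csv(out / "image_manifest.csv", index=False)
        report["stages"][name] = {
            "images": len(dataset.images),
            "class_counts": dataset.class_counts,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("encode", e) from e

    try:
        name = stage("train")
        split = ss.split_by_subject(dataset, seed=config.soft_sensor.seed)
        sensor = ss.build_model(config.soft_sensor, montage=cohort[0].channel_names,
                                fs=config.fs)
        sensor, history = ss.train(sensor, dataset, split)
        history.to_csv(out / "history.csv", index=False)
        sensor.save(out / "model")
        report["stages"][name] = {
            "train_subjects": len(split.train_subjects),
            "validation_subjects": len(split.validation_subjects),
            "test_subjects": len(split.test_subjects),
            "n_parameters": sensor.net.n_params,
            "best_val_acc": float(history["val_acc"].max()),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e

    try:
        name = stage("evaluate")
        metrics = ss.evaluate(sensor, dataset, split)
        (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
        from .viz import plot_confusion, plot_history
        plot_confusion(metrics, out / "confusion.png")
        plot_history(history, out / "training_curves.png")
        report["stages"][name] = metrics.to_dict()
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    report["elapsed_s"] = round(time.time() - t0, 1)
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
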