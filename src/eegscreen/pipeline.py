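"""End-to-end orchestration: simulate or load, preprocess, denoise,
extract features, test, and classify — one configuration, one seed policy.

A single master seed deterministically derives per-stage and per-subject
seeds through ``numpy.random.SeedSequence``, so re-running with the same
inputs and configuration reproduces every intermediate artifact and the
final report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .artifacts import denoise
from .classify import ClassificationReport, cross_validate
from .features import FEATURE_COLUMNS, feature_table, relative_power
from .group_stats import FeatureTestResult, results_frame, select_features
from .io import Recording, RunConfig, read_manifest, read_recording
from .preprocess import preprocess
from .synth import CohortSpec, generate_cohort

__all__ = ["RunReport", "run_pipeline", "load_cohort"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject ID."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject_id!r}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


@dataclass
class RunReport:
    """Everything a pipeline run produced, fully determined by
    (input data, RunConfig, seeds)."""

    config: Dict
    n_subjects: int
    group_counts: Dict[str, int]
    stage_log: List[str]
    feature_tests: List[FeatureTestResult]
    selected_features: List[str]
    relative_power_by_group: pd.DataFrame
    classification: Optional[ClassificationReport]
    feature_matrix: pd.DataFrame

    def to_dict(self) -> Dict:
        return {
            "config": self.config,
            "n_subjects": self.n_subjects,
            "group_counts": self.group_counts,
            "stage_log": self.stage_log,
            "feature_tests": [dataclasses.asdict(r) for r in self.feature_tests],
            "selected_features": self.selected_features,
            "relative_power_by_group": json.loads(
                self.relative_power_by_group.to_json(orient="index", double_precision=12)
            ),
            "classification": (
                self.classification.to_dict() if self.classification else None
            ),
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_cohort(manifest_path: str | Path, fs: float) -> List[Recording]:
    """Load every recording referenced by a cohort manifest."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    recs = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        recs.append(
            read_recording(
                p,
                fs_hint=fs,
                subject_id=str(row["subject_id"]),
                mmse=int(row["mmse"]),
            )
        )
    return recs


def run_pipeline(
    source: CohortSpec | str | Path | Sequence[Recording],
    config: Optional[RunConfig] = None,
    out_dir: Optional[str | Path] = None,
    fs: float = 512.0,
) -> RunReport:
    """Execute the full analysis over a cohort.

    ``source`` may be a :class:`CohortSpec` (simulate), a manifest path
    (load), or an in-memory list of recordings.  Stages: preprocess ->
    denoise (optional) -> STFT features -> control-referenced relative
    power -> Kruskal-Wallis/Bonferroni selection -> SMOTE + RBF-SVM
    cross-validation (optional).  Intermediate tables are written under
    ``out_dir`` when given.
    """
    config = config or RunConfig()
    log: List[str] = []

    if isinstance(source, CohortSpec):
        spec = dataclasses.replace(source, seed=config.seed)
        recordings, manifest, _ = generate_cohort(spec)
        log.append(f"simulate: generated {len(recordings)} recordings")
    elif isinstance(source, (str, Path)):
        recordings = load_cohort(source, fs=fs)
        log.append(f"load: read {len(recordings)} recordings from {source}")
    else:
        recordings = list(source)
        log.append(f"load: received {len(recordings)} in-memory recordings")
    if not recordings:
        raise ValueError("empty cohort")

    processed: List[Recording] = []
    for rec in recordings:
        try:
            pre = preprocess(rec, config)
        except Exception as exc:
            raise StageError("preprocess", rec.subject_id, exc) from exc
        if config.run_denoise:
            try:
                sub_cfg = dataclasses.replace(config)
                pre, mask = denoise(pre, sub_cfg)
                if len(mask):
                    log.append(
                        f"denoise: {rec.subject_id} cleaned {len(mask)} interval(s)"
                    )
            except Exception as exc:
                raise StageError("denoise", rec.subject_id, exc) from exc
        processed.append(pre)
    log.append(f"preprocess: {len(processed)} recordings band-limited + z-normalized")

    try:
        table = feature_table(
            processed, window_s=config.stft_window_s, taper=config.stft_taper
        )
    except Exception as exc:
        raise StageError("features", "(cohort)", exc) from exc
    log.append(f"features: {len(FEATURE_COLUMNS)} candidates per subject")

    try:
        rel = relative_power(table, reference_group=config.reference_group)
    except Exception as exc:
        raise StageError("relative_power", "(cohort)", exc) from exc
    by_group = rel.groupby("group")[FEATURE_COLUMNS].mean()

    try:
        selected, tests = select_features(
            rel, alpha=config.alpha, method=config.p_adjust_method
        )
    except Exception as exc:
        raise StageError("stats", "(cohort)", exc) from exc
    log.append(
        f"stats: {len(selected)} of {len(tests)} features significant at "
        f"alpha={config.alpha} ({config.p_adjust_method})"
    )

    report_cls: Optional[ClassificationReport] = None
    if config.run_classification:
        try:
            report_cls = cross_validate(
                rel,
                folds=config.cv_folds,
                seed=config.seed,
                leakage_mode=config.leakage_mode,
                alpha=config.alpha,
                p_adjust_method=config.p_adjust_method,
                smote_k_neighbors=config.smote_k_neighbors,
                C=config.svm_C,
                gamma=config.svm_gamma,
            )
        except Exception as exc:
            raise StageError("classify", "(cohort)", exc) from exc
        log.append(
            f"classify: {config.cv_folds}-fold test accuracy "
            f"{report_cls.test_accuracy:.3f}"
        )

    counts = pd.Series([r.group for r in recordings]).value_counts().to_dict()
    report = RunReport(
        config=json.loads(config.to_json()),
        n_subjects=len(recordings),
        group_counts={k: int(v) for k, v in counts.items()},
        stage_log=log,
        feature_tests=tests,
        selected_features=selected,
        relative_power_by_group=by_group,
        classification=report_cls,
        feature_matrix=rel,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rel.to_csv(out / "features_relative.csv")
        results_frame(tests).to_csv(out / "feature_tests.csv", index=False)
        by_group.to_csv(out / "relative_power_by_group.csv")
        if report_cls is not None:
            report_cls.to_json(out / "classification.json")
            report_cls.metrics_frame().to_csv(out / "metrics.csv", index=False)
        report.to_json(out / "run_report.json")
    return report
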