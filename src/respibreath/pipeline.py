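"""End-to-end orchestration: simulate -> detect -> featurize -> classify -> evaluate.

``run_experiment`` mirrors the study's intra-subject, per-activity design:
for every simulated participant and every activity, one recording is
generated, breaths are detected and featurized, a model is trained and
evaluated by stratified cross-validation on that participant-activity
subset, and per-breath plus segment-level metrics are accumulated into a
single summary table.  All stage randomness derives deterministically
from the global seed, so a rerun with the same config reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import breathing, classify, evaluate, features, signal_io, synthetic_data

log = logging.getLogger("respibreath")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, independent across stages."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_participants: int = 3
    activities: tuple[str, ...] = ("sitting", "standing", "walking")
    simulation: synthetic_data.SimulationConfig = synthetic_data.SimulationConfig()
    filter: breathing.FilterConfig = breathing.FilterConfig()
    detector: breathing.DetectorConfig = breathing.DetectorConfig()
    features: features.FeatureConfig = features.FeatureConfig()
    classifier: classify.ClassifierSpec = classify.ClassifierSpec()
    n_folds: int = 15
    select_top_fraction: float | None = 0.10  # None disables selection
    out_dir: Path | None = None


@dataclass
class ExperimentResult:
    results: pd.DataFrame      # one row per participant x activity
    summary: pd.DataFrame      # per-activity mean (SD) + overall
    text_report: str
    rocs: dict[tuple[str, str], classify.RocResult]


def process_recording(
    rec: signal_io.RawRecording,
    cfg: PipelineConfig,
) -> tuple[list[breathing.BreathEvent], pd.DataFrame]:
    """Voltage -> resistance -> filtered peaks -> labelled feature matrix."""
    res = signal_io.voltage_to_resistance(rec)
    events = breathing.detect_all(res, cfg.filter, cfg.detector)
    matrix = features.feature_matrix(events, res, cfg.features)
    return events, matrix


def evaluate_subset(
    events: list[breathing.BreathEvent],
    matrix: pd.DataFrame,
    rec: signal_io.RawRecording,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[evaluate.EvaluationReport, classify.RocResult]:
    """Cross-validate on one participant-activity subset; out-of-fold
    predictions feed both the per-breath and the segment-level metrics."""
    y = matrix["label"].to_numpy()
    X = matrix.drop(columns="label")
    groups = breathing.group_breath_events(events, rec.sample_rate)
    if cfg.select_top_fraction is not None:
        selected = features.select_features(
            X, y, n_folds=cfg.n_folds,
            top_fraction=cfg.select_top_fraction,
            seed=stage_seed(seed, "select"),
        )
        X = X[selected]
    spec = replace(cfg.classifier, seed=stage_seed(seed, "train"))
    roc, _, oof = classify.cross_validate(
        X, y, spec, n_folds=cfg.n_folds, seed=stage_seed(seed, "cv"),
        groups=groups,
    )
    pred = (oof >= 0.5).astype(int)
    counts = evaluate.confusion(pred, y)
    acc, tpr, fpr = evaluate.sample_metrics(counts)
    peak_times = np.array([e.peak_time(rec.sample_rate) for e in events])
    segments = evaluate.build_segments(rec.talk_intervals, peak_times, pred)
    acc_seg = evaluate.segment_accuracy(segments)
    rep = evaluate.EvaluationReport(
        confusion=counts, acc=acc, tpr=tpr, fpr=fpr,
        acc_seg=acc_seg, auc=roc.auc,
        meta={"n_events": len(events)},
    )
    return rep, roc


def run_experiment(cfg: PipelineConfig) -> ExperimentResult:
    """Run the full chain for every simulated participant and activity."""
    log.info("pipeline config: %s", dataclasses.asdict(cfg))
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    rocs: dict[tuple[str, str], classify.RocResult] = {}
    for p in range(1, cfg.n_participants + 1):
        participant = f"P{p:02d}"
        for activity in cfg.activities:
            cell = f"{participant}:{activity}"
            sim_cfg = replace(
                cfg.simulation,
                activity=activity,
                seed=stage_seed(cfg.seed, f"simulate:{cell}"),
            )
            rec = synthetic_data.simulate_recording(sim_cfg)
            rec.participant_id = participant
            events, matrix = process_recording(rec, cfg)
            log.info("%s: %d breath events", cell, len(events))
            rep, roc = evaluate_subset(
                events, matrix, rec, cfg, stage_seed(cfg.seed, cell)
            )
            rocs[(participant, activity)] = roc
            rows.append({
                "participant": participant, "activity": activity,
                "acc": rep.acc, "tpr": rep.tpr, "fpr": rep.fpr,
                "acc_seg": rep.acc_seg, "auc": rep.auc,
                "n_events": len(events),
            })
            if out_dir is not None:
                stem = out_dir / f"{participant}_{activity}"
                signal_io.write_recording(rec, stem.with_suffix(".csv"))
                matrix.to_csv(f"{stem}_features.csv", index=False)

    results = pd.DataFrame(rows)
    summary, text = evaluate.report(results)
    if out_dir is not None:
        results.to_csv(out_dir / "results.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        (out_dir / "report.txt").write_text(text + "\n")
    return ExperimentResult(results=results, summary=summary,
                            text_report=text, rocs=rocs)
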