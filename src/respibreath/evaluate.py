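"""Per-breath metrics, segment-level majority-vote accuracy, report tables.

Per-breath (sample) metrics over the detected breath events, with
*talking* as the positive class:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    TPR = TP / (TP + FN)
    FPR = FP / (FP + TN)

all reported as percentages.  A zero denominator makes the metric
explicitly undefined (``None``), never silently zero.

Segment accuracy scores whole talking intervals: a true talking segment
is correct iff *strictly more than half* of the breath predictions whose
peaks fall in it say talking (an exact tie counts as incorrect; a talking
segment containing no detected breaths is a miss and counts incorrect).

    ACC_seg = correctly classified talking segments / total talking segments
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SegmentOutcome:
    interval: tuple[float, float]
    true_label: int
    member_predictions: list[int]

    @property
    def majority_talking(self) -> bool:
        """Strict majority of member predictions are talking."""
        preds = self.member_predictions
        return len(preds) > 0 and sum(preds) * 2 > len(preds)


@dataclass
class EvaluationReport:
    confusion: ConfusionCounts
    acc: float | None       # percent
    tpr: float | None
    fpr: float | None
    acc_seg: float | None = None
    auc: float | None = None
    meta: dict = field(default_factory=dict)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def sample_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(ACC, TPR, FPR) as percentages; ``None`` where the denominator is zero."""
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total > 0 else None
    tpr = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    fpr = 100.0 * c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else None
    return acc, tpr, fpr


def build_segments(
    talk_intervals: list[tuple[float, float]],
    peak_times: np.ndarray,
    predictions: np.ndarray,
) -> list[SegmentOutcome]:
    """Group per-breath predictions into the true talking segments."""
    peak_times = np.asarray(peak_times, dtype=float)
    predictions = np.asarray(predictions).astype(int)
    segments = []
    for start, end in talk_intervals:
        inside = (peak_times >= start) & (peak_times < end)
        segments.append(
            SegmentOutcome(
                interval=(start, end),
                true_label=1,
                member_predictions=predictions[inside].tolist(),
            )
        )
    return segments


def segment_accuracy(segments: list[SegmentOutcome]) -> float:
    """ACC_seg (%) over true talking segments, strict-majority rule."""
    talking = [s for s in segments if s.true_label == 1]
    if not talking:
        raise ValueError("no talking segments to evaluate")
    correct = sum(s.majority_talking for s in talking)
    return 100.0 * correct / len(talking)


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.1f}"


def report(results: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Summarize per-participant, per-activity results.

    ``results`` needs columns ``participant, activity, acc, tpr, fpr`` (and
    optionally ``acc_seg, auc``).  Returns the per-activity mean (SD)
    summary frame (an ``Average`` row last) and a rendered text table.
    Missing participant-activity cells are simply absent and excluded
    from the means.
    """
    required = {"participant", "activity", "acc", "tpr", "fpr"}
    if missing := required - set(results.columns):
        raise ValueError(f"results missing columns: {sorted(missing)}")
    metrics = [c for c in ("acc", "tpr", "fpr", "acc_seg", "auc") if c in results.columns]

    rows = []
    order = [a for a in ("sitting", "standing", "walking")
             if a in set(results["activity"])]
    for activity in order + ["Average"]:
        sub = results if activity == "Average" else results[results["activity"] == activity]
        row = {"activity": activity}
        for m in metrics:
            vals = sub[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    summary = pd.DataFrame(rows)

    lines = ["activity    " + "".join(f"{m.upper():>16}" for m in metrics)]
    for row in rows:
        cells = []
        for m in metrics:
            mean, sd = row[f"{m}_mean"], row[f"{m}_sd"]
            cells.append(f"{_fmt(mean)} ({sd:.1f})" if mean is not None else "NA")
        lines.append(f"{row['activity']:<12}" + "".join(f"{c:>16}" for c in cells))

    lines.append("")
    lines.append("per participant:")
    per_part = results.sort_values(["participant", "activity"])
    for _, r in per_part.iterrows():
        cells = "".join(f"{_fmt(r[m]):>10}" for m in metrics)
        lines.append(f"  {r['participant']:<8}{r['activity']:<10}{cells}")
    return summary, "\n".join(lines)
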