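"""Phase-3 evaluation: confusion matrix, derived metrics, AUC, m ± d summaries.

Metrics are computed directly from the four confusion-matrix counts:
accuracy, precision, recall, F1 and the Matthews correlation coefficient
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Degenerate
denominators return 0 with a warning.  AUC is the Mann–Whitney rank
statistic on scores — the probability that a random positive outscores a
random negative, with ties counted one half.  Repeated experiments are
summarised as mean ± (population) standard deviation, printed to two
decimals as in comparison tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "SummaryReport",
    "confusion_matrix",
    "derive_metrics",
    "compute_auc",
    "evaluate_predictions",
    "summarize_repeats",
    "format_m_pm_d",
    "render_comparison_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Four-cell counts with class 1 as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty prediction vectors")
    if not (np.isin(y_true, [0, 1]).all() and np.isin(y_pred, [0, 1]).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", what)
        return 0.0
    return num / den


def derive_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision, recall, F1 and MCC from the four counts."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    accuracy = (tp + tn) / cm.total
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "F1")
    denom2 = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = float(_safe_div(tp * tn - fp * fn, np.sqrt(denom2), "MCC"))
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1, mcc=mcc)


def compute_auc(y_true, scores) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) with ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricReport:
    """Full report from scores: threshold for the counts, ranks for AUC."""
    y_pred = (np.asarray(scores) >= threshold).astype(int)
    report = derive_metrics(confusion_matrix(y_true, y_pred))
    report.auc = compute_auc(y_true, scores)
    return report


@dataclass
class SummaryReport:
    """Per-metric mean m and (population) standard deviation d over repeats."""

    means: dict[str, float]
    stds: dict[str, float]
    n_repeats: int

    def formatted(self) -> dict[str, str]:
        return {k: format_m_pm_d(self.means[k], self.stds[k]) for k in self.means}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"metric": list(self.means), "mean": list(self.means.values()), "std": list(self.stds.values())})


def summarize_repeats(reports: list[MetricReport]) -> SummaryReport:
    """Aggregate repeated experiments into m ± d per metric."""
    if len(reports) < 1:
        raise ValueError("need at least one report")
    keys = [k for k, v in reports[0].as_dict().items() if v is not None]
    for r in reports[1:]:
        if [k for k, v in r.as_dict().items() if v is not None] != keys:
            raise ValueError("inconsistent metric sets across repeats")
    means = {}
    stds = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        means[k] = float(vals.mean())
        stds[k] = float(vals.std())  # population sd
    return SummaryReport(means=means, stds=stds, n_repeats=len(reports))


def format_m_pm_d(m: float, d: float) -> str:
    """Render ``m ± d`` to two decimals, round-half-even."""

    def r2(x: float) -> str:
        return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))

    return f"{r2(m)} ± {r2(d)}"


def render_comparison_table(rows: dict[str, SummaryReport], group_rows: dict[str, dict[str, float]] | None = None) -> str:
    """Text grid of models × metrics in ``m ± d`` form, with optional
    plain-mean group-average rows appended."""
    if not rows:
        raise ValueError("no rows to render")
    metrics = list(next(iter(rows.values())).means)
    width = max(len(name) for name in list(rows) + list(group_rows or {})) + 2
    header = "Model".ljust(width) + "".join(m.capitalize().ljust(14) for m in metrics)
    lines = [header, "-" * len(header)]
    for name, summary in rows.items():
        cells = summary.formatted()
        lines.append(name.ljust(width) + "".join(cells[m].ljust(14) for m in metrics))
    for name, means in (group_rows or {}).items():
        lines.append(name.ljust(width) + "".join(f"{means[m]:.2f}".ljust(14) for m in metrics))
    return "\n".join(lines)
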