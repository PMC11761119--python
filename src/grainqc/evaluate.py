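"""Classification metrics and paired significance testing.

Confusion matrices use rows = actual, columns = predicted.  Per-class
precision/recall/F1 come from one-vs-rest reductions (TP_i, FP_i, FN_i,
TN_i); the headline figures are macro averages (unweighted class means),
with micro accuracy = trace / total.  Model comparisons use the paired
t-test on per-epoch accuracy series with a 95% confidence interval on the
mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix", "MetricsReport", "PairedTestResult",
    "confusion", "metrics", "paired_ttest", "report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K int, rows = actual
    labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> {precision, recall, f1, support}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_f1: float
    zero_division_classes: list[str]


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    mean_difference: float
    n: int


def confusion(y_true, y_pred, num_classes: int,
              labels: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels out of range [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    if labels is None:
        labels = [str(i) for i in range(num_classes)]
    return ConfusionMatrix(counts=counts, labels=list(labels))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy + per-class and macro precision/recall/F1.

    Zero-division (a class never predicted, or with zero support) yields 0
    for the affected metric and flags the class, keeping macro averages
    finite.
    """
    c = cm.counts
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(c) / total)
    per_class: dict[str, dict[str, float]] = {}
    flagged: list[str] = []
    precs, recs, f1s = [], [], []
    tp_all = fp_all = fn_all = 0
    for i, lab in enumerate(cm.labels):
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - tp)
        fn = int(c[i, :].sum() - tp)
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        if tp + fp == 0 or tp + fn == 0:
            flagged.append(lab)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[lab] = {"precision": prec, "recall": rec, "f1": f1,
                          "support": float(tp + fn)}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    micro_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    micro_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    return MetricsReport(
        accuracy=accuracy, per_class=per_class,
        macro_precision=float(np.mean(precs)), macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)), micro_f1=float(micro_f1),
        zero_division_classes=flagged,
    )


def paired_ttest(acc_a, acc_b, confidence: float = 0.95) -> PairedTestResult:
    """Paired t-test on matched accuracy series; positive t favours series a.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 sample standard deviation;
    two-sided p from Student's t with n-1 df; the CI is
    mean(d) +- t_{(1+conf)/2, n-1} * sd(d)/sqrt(n).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("series must be 1-D, equal length, n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t-test is degenerate")
    se = sd / np.sqrt(n)
    t = float(d.mean() / se)
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    tcrit = float(stats.t.ppf((1 + confidence) / 2, df=n - 1))
    return PairedTestResult(
        t_statistic=t, p_value=p,
        ci_low=float(d.mean() - tcrit * se), ci_high=float(d.mean() + tcrit * se),
        mean_difference=float(d.mean()), n=n,
    )


def report(results: dict[str, MetricsReport],
           histories: dict[str, "np.ndarray | list[float]"] | None = None,
           out_dir=None):
    """Evaluation bundle: metrics table, pairwise significance table and
    (optionally) confusion-matrix heatmaps written under out_dir."""
    import pandas as pd

    rows = []
    for name, rep in results.items():
        rows.append({
            "model": name,
            "accuracy": rep.accuracy,
            "precision": rep.macro_precision,
            "recall": rep.macro_recall,
            "f1": rep.macro_f1,
        })
    metrics_df = pd.DataFrame(rows)

    sig_rows = []
    if histories:
        names = list(histories)
        master = names[0]
        for other in names[1:]:
            r = paired_ttest(histories[master], histories[other])
            sig_rows.append({
                "master_model": master, "contrast_model": other,
                "t_value": r.t_statistic, "p_value": r.p_value,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
            })
    sig_df = pd.DataFrame(sig_rows)

    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6g")
        if not sig_df.empty:
            sig_df.to_csv(out_dir / "significance.csv", index=False, float_format="%.6g")
    return metrics_df, sig_df


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Heatmap of the confusion matrix (counts annotated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=45)
    ax.set_yticks(range(len(cm.labels)), cm.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    for i in range(len(cm.labels)):
        for j in range(len(cm.labels)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="white" if cm.counts[i, j] > cm.counts.max() / 2 else "black")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
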