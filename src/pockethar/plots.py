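"""Figure generation for sweep reports.

Three analogue figures: the accuracy-vs-window-length box plot with the
mean curve, per-participant accuracy curves, and per-activity
precision/recall/F1 curves.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import SweepReport

__all__ = [
    "plot_accuracy_by_window",
    "plot_participant_curves",
    "plot_activity_metrics",
    "plot_all",
]


def plot_accuracy_by_window(report: SweepReport, path: str | Path) -> Path:
    """Box plot of per-participant accuracies per window length + mean curve."""
    ws = sorted(report.accuracy["window_length"].unique())
    data = [
        report.accuracy.loc[report.accuracy["window_length"] == w, "accuracy"]
        for w in ws
    ]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.boxplot(data, positions=range(len(ws)), widths=0.6)
    means = [d.mean() for d in data]
    ax.plot(range(len(ws)), means, "r-o", label="mean accuracy")
    ax.set_xticks(range(len(ws)), [str(w) for w in ws])
    ax.set_xlabel("window length (samples)")
    ax.set_ylabel("LOSO accuracy")
    ax.legend()
    fig.tight_layout()
    return _save(fig, path)


def plot_participant_curves(report: SweepReport, path: str | Path) -> Path:
    """Accuracy against window length, one curve per participant."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for pid, grp in report.accuracy.groupby("participant"):
        grp = grp.sort_values("window_length")
        ax.plot(grp["window_length"], grp["accuracy"], marker="o", label=f"P{pid}")
    ax.set_xlabel("window length (samples)")
    ax.set_ylabel("LOSO accuracy")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return _save(fig, path)


def plot_activity_metrics(report: SweepReport, path: str | Path) -> Path:
    """Precision, recall and F1 per activity across window lengths."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, metric in zip(axes, ("precision", "recall", "f1")):
        for activity, grp in report.activity.groupby("activity"):
            grp = grp.sort_values("window_length")
            ax.plot(grp["window_length"], grp[metric], marker="o", label=activity)
        ax.set_title(metric)
        ax.set_xlabel("window length (samples)")
    axes[0].set_ylabel("score")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    return _save(fig, path)


def plot_all(report: SweepReport, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        plot_accuracy_by_window(report, out_dir / "accuracy_by_window.png"),
        plot_participant_curves(report, out_dir / "participant_curves.png"),
        plot_activity_metrics(report, out_dir / "activity_metrics.png"),
    ]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
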