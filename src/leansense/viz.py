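"""Small plotting helpers (PNG outputs for run reports)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .connectivity import CorrelationMatrix  # noqa: E402
from .softsensor import CLASSES, Metrics  # noqa: E402


def plot_correlation_heatmap(matrix: CorrelationMatrix, path: str | Path,
                             title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.channel_names)),
                  matrix.channel_names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.channel_names)), matrix.channel_names, fontsize=7)
    ax.set_title(title or "Channel cross-correlation")
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_confusion(metrics: Metrics, path: str | Path) -> Path:
    conf = metrics.confusion
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(conf, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(conf[i, j]), ha="center", va="center")
    ax.set_xticks([0, 1], [f"pred {c}" for c in CLASSES])
    ax.set_yticks([0, 1], [f"true {c}" for c in CLASSES])
    ax.set_title(f"ACC = {metrics.ACC:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_history(history: pd.DataFrame, path: str | Path) -> Path:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].plot(history["epoch"], history["train_acc"], label="train")
    axes[0].plot(history["epoch"], history["val_acc"], label="validation")
    axes[0].set_xlabel("epoch"); axes[0].set_ylabel("accuracy"); axes[0].legend()
    axes[1].plot(history["epoch"], history["train_loss"], label="train")
    axes[1].plot(history["epoch"], history["val_loss"], label="validation")
    axes[1].set_xlabel("epoch"); axes[1].set_ylabel("loss"); axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_paired_sensors(matrix: CorrelationMatrix, pairs: list[tuple[str, str]],
                        path: str | Path, title: str = "") -> Path:
    """Bar chart of selected channel-pair coefficients."""
    labels = [f"{a}-{b}" for a, b in pairs]
    values = [matrix.pair(a, b) for a, b in pairs]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(pairs)), 3))
    ax.bar(labels, values, color="steelblue")
    ax.set_ylim(0, 1)
    ax.set_ylabel("correlation")
    ax.set_title(title or "Selected sensor pairs")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
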