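"""Figure rendering: ROC comparison, calibration curves, Kaplan-Meier
risk-group curves and nomogram point scales (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import models as riskmodels  # noqa: E402

__all__ = ["plot_roc", "plot_calibration", "plot_km", "plot_nomogram_scales"]


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores)
    labels = labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    tpr = np.concatenate([[0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps / max(fps[-1], 1)])
    return fpr, tpr


def plot_roc(predictions: dict[str, tuple[np.ndarray, np.ndarray]],
             path: str | Path, title: str = "5-year OS discrimination") -> Path:
    """One ROC curve per risk model; ``predictions`` maps model name to
    (predicted probability, binary outcome)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (pred, y) in predictions.items():
        fpr, tpr = _roc_points(np.asarray(pred, float), np.asarray(y, int))
        auc = riskmodels.c_index(pred, y)
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:0.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_calibration(table: pd.DataFrame, path: str | Path,
                     title: str = "Calibration") -> Path:
    """Mean predicted vs observed event rate per risk group."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k:", lw=0.8, label="perfect")
    ax.plot(table["mean_pred"], table["observed_rate"], "o-", label="model")
    ax.set_xlabel("predicted 5-year OS probability")
    ax.set_ylabel("observed rate")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_km(km_result: dict, path: str | Path,
            title: str = "Kaplan-Meier by risk group") -> Path:
    """Survival curves of the Youden-split risk groups."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for name, km in km_result["curves"].items():
        km.plot_survival_function(ax=ax)
    p = km_result.get("logrank_p")
    note = "log-rank n/a" if p is None else f"log-rank p = {p:0.2g}"
    ax.set_title(f"{title} ({note})")
    ax.set_xlabel("months since resection")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_nomogram_scales(nomogram: dict, path: str | Path) -> Path:
    """Horizontal point-range bars, one per predictor, largest on top."""
    preds = sorted(nomogram["predictors"].items(),
                   key=lambda kv: -kv[1]["max_points"])
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(preds) + 1.5))
    names = [k for k, _ in preds]
    spans = [v["max_points"] for _, v in preds]
    ax.barh(range(len(preds)), spans, height=0.5, color="#4477aa")
    ax.set_yticks(range(len(preds)), names, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("points")
    ax.set_title("Nomogram predictor point ranges")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
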