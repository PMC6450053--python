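"""Plain-text and figure reporting for a trained cascade run."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .variant_loh import VariantSet, loh_profile_table  # noqa: E402

logger = logging.getLogger(__name__)


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    return fpr, tpr


def plot_score_distributions(out_path, results: pd.DataFrame, labels: pd.DataFrame) -> None:
    """Index-score boxplots split by the relevant truth label."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    panels = [
        ("H", labels["hurthle"].astype(bool), ("H-", "H+")),
        ("N", labels["neoplasm"].astype(bool), ("N-", "N+")),
        ("BS", labels["histology"] == "malignant", ("benign", "malignant")),
    ]
    for ax, (col, mask, names) in zip(axes, panels):
        vals = results[col]
        groups = [vals[~mask.to_numpy()].dropna(), vals[mask.to_numpy()].dropna()]
        ax.boxplot(groups, tick_labels=list(names))
        ax.set_title(f"{col} score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def plot_roc(out_path, trained, results: pd.DataFrame, labels: pd.DataFrame) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for name, scores, truth in [
        ("HI (CV)", trained.cv_reports["hi"].scores, trained.cv_reports["hi"].labels),
        ("NI (CV)", trained.cv_reports["ni"].scores, trained.cv_reports["ni"].labels),
        ("BS (train)", results["BS"].to_numpy(),
         (labels["histology"] == "malignant").to_numpy()),
    ]:
        fpr, tpr = _roc_points(np.asarray(scores), np.asarray(truth))
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def plot_loh_heatmap(out_path, variant_sets: Mapping[str, VariantSet],
                     labels: pd.DataFrame) -> None:
    """Samples x chromosomes LOH heatmap, Hurthle-positive samples on top."""
    table = loh_profile_table(variant_sets.values())
    order = labels["hurthle"].astype(bool).sort_values(ascending=False).index
    table = table.reindex(order)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="Reds", vmin=0, vmax=1)
    ax.axhline(int(labels["hurthle"].sum()) - 0.5, color="black", ls="--", lw=0.8)
    ax.set_xticks(range(table.shape[1]))
    ax.set_xticklabels(table.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("samples (H+ above dashed line)")
    fig.colorbar(im, ax=ax, label="LOH")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def write_report(
    out_dir,
    trained,
    results: pd.DataFrame,
    labels: pd.DataFrame,
    variant_sets: Mapping[str, VariantSet] | None = None,
    figures: bool = True,
) -> Path:
    """Write a text summary (and optional figures) of a trained cascade run."""
    out_dir = Path(out_dir)
    labels = labels.loc[results.index]
    malignant = (labels["histology"] == "malignant").to_numpy()
    suspicious = (results["call"] == "Suspicious").to_numpy()
    sens = float(suspicious[malignant].mean())
    spec = float((~suspicious)[~malignant].mean())
    lines = [
        "cascade training report",
        "=======================",
        f"samples: {len(results)} "
        f"({int(labels['hurthle'].sum())} H+ / {int((~labels['hurthle'].astype(bool)).sum())} H-)",
        f"HI: {len(trained.hi_genes)} genes, cost {trained.hi_model.cost:g}, "
        f"CV AUC {trained.cv_reports['hi'].auc:.3f}",
        f"NI: {len(trained.ni_genes)} genes + {len(trained.loh_feature_names)} LOH features, "
        f"cost {trained.ni_model.cost:g}, CV AUC {trained.cv_reports['ni'].auc:.3f}",
        f"BS stand-in: {len(trained.bs_scorer.feature_names)} genes, "
        f"{len(trained.bs_scorer.models)} bagged models, cost {trained.bs_scorer.cost:g}",
        "thresholds: "
        + ", ".join(f"{k}={v:.4f}" for k, v in trained.config.thresholds_dict().items()),
        f"training sensitivity {sens:.3f}, specificity {spec:.3f}, "
        f"rescued {int(results['rescue_flag'].sum())} sample(s)",
        f"calls: {int((~suspicious).sum())} Benign / {int(suspicious.sum())} Suspicious",
    ]
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    if figures:
        plot_score_distributions(out_dir / "score_distributions.png", results, labels)
        plot_roc(out_dir / "roc.png", trained, results, labels)
        if variant_sets:
            plot_loh_heatmap(out_dir / "loh_heatmap.png", variant_sets, labels)
    logger.info("report written to %s", report_path)
    return report_path
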