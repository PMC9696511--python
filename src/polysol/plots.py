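"""Static figures: relevancy bars, residual histogram, parity, trends, Williams plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import ResidualReport, ValidityReport
from .relevancy import RelevancyReport


def relevancy_bars(report: RelevancyReport, path: str | Path) -> None:
    df = report.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    features = df["feature"].unique()
    x = np.arange(len(features))
    for i, method in enumerate(("spearman", "pearson")):
        vals = [report.coefficient(f, method) for f in features]
        ax.bar(x + (i - 0.5) * width, vals, width, label=method)
    ax.set_xticks(x, features, rotation=20)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("relevancy coefficient")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def residual_histogram(report: ResidualReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (report.bin_edges[:-1] + report.bin_edges[1:]) / 2.0
    ax.bar(centers, report.counts, width=np.diff(report.bin_edges) * 0.9)
    ax.set_xlabel("actual difference AD (degC)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def parity_plot(y_true, y_pred, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y_true, y_pred, s=12, alpha=0.7)
    lims = [min(np.min(y_true), np.min(y_pred)), max(np.max(y_true), np.max(y_pred))]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("experimental T_sol (degC)")
    ax.set_ylabel("predicted T_sol (degC)")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def trend_plot(profiles: dict, dataset, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for (drug, polymer), df in profiles.items():
        line, = ax.plot(df["drug_load_wt"], df["t_sol_pred"], label=f"{drug}/{polymer}")
        sub = dataset.subset_system(drug, polymer)
        ax.scatter([r.drug_load for r in sub], sub.t_sol, color=line.get_color(), s=18)
    ax.set_xlabel("drug load (wt%)")
    ax.set_ylabel("T_sol (degC)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def williams_plot(report: ValidityReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    outlier = report.flags == "outlier"
    ax.scatter(report.hat[~outlier], report.sr[~outlier], s=12, label="valid")
    if outlier.any():
        ax.scatter(report.hat[outlier], report.sr[outlier], s=16, color="r", label="outlier")
    ax.axvline(report.cl, color="k", ls="--", lw=1, label=f"CL={report.cl:.4f}")
    for y in (-3, 3):
        ax.axhline(y, color="gray", ls=":", lw=1)
    ax.set_xlabel("Hat index (leverage)")
    ax.set_ylabel("standard residual SR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
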