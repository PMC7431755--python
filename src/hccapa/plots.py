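"""Report figures: dose-response curves, toxicity curve, per-cell scatter."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import four_pl

__all__ = ["plot_report"]

_COLORS = {"organelle": "#e6a817", "whole_cell": "#3b7dbf"}


def plot_report(run_dir: str | Path, config=None) -> list[Path]:
    run_dir = Path(run_dir)
    out = []
    results_path = run_dir / "results.json"
    if results_path.exists():
        with open(results_path) as fh:
            results = json.load(fh)
        out.append(_plot_dose_response(run_dir, results))
        out.append(_plot_scatter(run_dir))
    tox_path = run_dir / "toxicity.csv"
    if tox_path.exists():
        out.append(_plot_toxicity(run_dir))
    return [p for p in out if p is not None]


def _plot_dose_response(run_dir: Path, results: dict) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    for mask_name, res in results.items():
        table_path = run_dir / f"responses_{mask_name}.csv"
        if not table_path.exists():
            continue
        table = pd.read_csv(table_path)
        color = _COLORS.get(mask_name, "k")
        ax.scatter(
            np.maximum(table["concentration_um"], _floor(table)),
            table["response"],
            s=18, alpha=0.7, color=color,
            label=f"{mask_name}: CP50 = {res['cp50']:.2g} ± {res['se_cp50']:.2g} µM",
        )
        if res.get("converged"):
            cs = np.geomspace(_floor(table), table["concentration_um"].max(), 200)
            ax.plot(cs, four_pl(cs, res["cp50"], res["hill"], res["top"], res["bottom"]),
                    color=color, lw=1.2)
    ax.set_xscale("log")
    ax.set_xlabel("transporter concentration (µM)")
    ax.set_ylabel("reporter response (counts)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = run_dir / "dose_response.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _floor(table: pd.DataFrame) -> float:
    pos = table.loc[table["concentration_um"] > 0, "concentration_um"]
    return float(pos.min()) / 3.0 if len(pos) else 0.1


def _plot_toxicity(run_dir: Path) -> Path:
    tox = pd.read_csv(run_dir / "toxicity.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(tox["concentration_um"], tox["percent_selected"], yerr=tox["sem"],
                fmt="o-", color="k", capsize=3)
    ax.axhline(100, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("transporter concentration (µM)")
    ax.set_ylabel("selected cells (% of control)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    path = run_dir / "toxicity.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _plot_scatter(run_dir: Path) -> Path | None:
    cells_path = run_dir / "cells.csv"
    if not cells_path.exists():
        return None
    cells = pd.read_csv(cells_path)
    sel = cells[cells["selected"]]
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, (name, gcol, rcol) in zip(
        axes,
        [
            ("whole cell", "gfp_mean_body", "rep_mean_body"),
            ("organelle", "gfp_mean_organelle", "rep_mean_organelle"),
        ],
    ):
        ax.scatter(sel[gcol], sel[rcol], s=4, alpha=0.3,
                   color=_COLORS["whole_cell" if name == "whole cell" else "organelle"])
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("GFP (counts)")
    axes[0].set_ylabel("reporter (counts)")
    fig.tight_layout()
    path = run_dir / "correlation_scatter.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
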