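"""End-to-end orchestration: simulate -> segment -> quantify -> fit -> report.

Each stage reads and writes plain files inside the run directory, so stages
can be re-run individually; a manifest records the configuration hash, seed
and every output file, which is sufficient to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .io import read_plate, write_json, write_masks
from .quantify import (
    apply_qc,
    calibrate_damage_thresholds,
    extract_features,
    qc_summary,
)
from .segmentation import segment_field
from .stats import (
    aggregate_responses,
    compare_masks,
    fit_dose_response,
    regression_r2,
    toxicity_curve,
)
from .synthgen import build_plate

log = logging.getLogger("hccapa")

STAGES = ("simulate", "segment", "quantify", "fit", "report")

RESPONSE_COLS = {"organelle": "rep_mean_organelle", "whole_cell": "rep_mean_body"}


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    stages: list = dfield(default_factory=list)
    outputs: list = dfield(default_factory=list)
    timestamps: dict = dfield(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _stamp() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int,
    stages=STAGES,
    noise: bool = True,
    write_mask_images: bool = False,
) -> RunManifest:
    """Execute the requested stages in order inside ``out_dir``.

    simulate  - build the synthetic plate (TIFFs + ground truth)
    segment   - masks for every field
    quantify  - per-cell CSV + QC summary JSON (damage filter always on;
                the transfection gate only in transient mode)
    fit       - dose-response fits for both masks + toxicity table +
                per-cell regression r² per mask
    report    - results JSON, mask comparison, plots

    Later stages require the artifacts of earlier ones on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    manifest = RunManifest(
        config_hash=config_hash(config), master_seed=int(seed), version=__version__
    )

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            manifest.timestamps[stage + "_start"] = _stamp()
            try:
                _STAGE_FNS[stage](config, out_dir, seed, noise, write_mask_images, manifest)
            except Exception as exc:
                log.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            manifest.stages.append(stage)
            manifest.timestamps[stage + "_end"] = _stamp()
        write_json(manifest.to_dict(), out_dir / "manifest.json")
        manifest.outputs.append(str(out_dir / "manifest.json"))
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _simulate(config, out_dir, seed, noise, _write_masks, manifest):
    plate_dir = out_dir / "plate"
    build_plate(config.layout, config.simulation, config.mode, seed, plate_dir, noise=noise)
    n_wells = len(config.layout.wells)
    log.info("simulate: %d wells written to %s", n_wells, plate_dir)
    manifest.outputs.append(str(plate_dir))


def _segment_and_quantify(config, out_dir, noise, write_mask_images, manifest):
    """Shared worker: segmentation feeds straight into feature extraction."""
    plate_dir = out_dir / "plate"
    layout, fields = read_plate(plate_dir, config.simulation.pixel_size_um)
    frames = []
    gfp_sds = []
    n_border = 0
    for f in fields:
        masks = segment_field(f, config.segmentation)
        n_border += masks.n_border_discarded
        if write_mask_images:
            p = write_masks(masks, out_dir / "masks", f.well_id, f.field_index)
            manifest.outputs.append(str(p))
        conc = layout.well(f.well_id).concentration_um
        rec = extract_features(
            f, masks, f.well_id, f.field_index, conc, config.segmentation
        )
        gfp_sds.append(masks.background["gfp"][1])
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    log.info("segment: %d cells across %d fields", len(records), len(fields))

    controls = records[records["concentration_um"] == 0.0]
    thresholds = calibrate_damage_thresholds(controls, config.qc)
    records = apply_qc(
        records, thresholds, float(np.median(gfp_sds)), config.mode, config.qc
    )
    records.to_csv(out_dir / "cells.csv", index=False)
    summary = qc_summary(records)
    summary.to_csv(out_dir / "qc_summary.csv", index=False)
    write_json(
        {
            "per_well": summary.to_dict(orient="records"),
            "totals": {
                "n_total": int(len(records)),
                "n_border_discarded": int(n_border),
                "n_damaged": int(records["qc_damaged"].sum()),
                "n_gated_out": int(records["qc_gated_out"].sum()),
                "n_selected": int(records["selected"].sum()),
            },
            "damage_thresholds": thresholds.__dict__,
        },
        out_dir / "qc_summary.json",
    )
    log.info(
        "quantify: %d/%d cells selected (%.1f%% damaged, %.1f%% gated out)",
        int(records["selected"].sum()),
        len(records),
        100 * records["qc_damaged"].mean(),
        100 * records["qc_gated_out"].mean(),
    )
    manifest.outputs += [
        str(out_dir / "cells.csv"),
        str(out_dir / "qc_summary.csv"),
        str(out_dir / "qc_summary.json"),
    ]


def _segment(config, out_dir, seed, noise, write_mask_images, manifest):
    _segment_and_quantify(config, out_dir, noise, write_mask_images, manifest)


def _quantify(config, out_dir, seed, noise, write_mask_images, manifest):
    if not (out_dir / "cells.csv").exists():
        _segment_and_quantify(config, out_dir, noise, write_mask_images, manifest)


def _fit(config, out_dir, seed, noise, _write_masks, manifest):
    cells_path = out_dir / "cells.csv"
    if not cells_path.exists():
        raise FileNotFoundError(f"quantify stage output missing: {cells_path}")
    records = pd.read_csv(cells_path)
    layout = config.layout
    results = {}
    fits = {}
    for mask_name, col in RESPONSE_COLS.items():
        table = aggregate_responses(records, layout, col)
        table.to_csv(out_dir / f"responses_{mask_name}.csv", index=False)
        fit = fit_dose_response(
            table["concentration_um"],
            table["response"],
            table["replicate"],
            config.fit,
            mask=mask_name,
        )
        fits[mask_name] = fit
        # mask-accuracy metric: GFP-vs-reporter correlation of selected cells
        # in the untreated controls, where reporter ∝ free HaloTags ∝ GFP
        sel = records[records["selected"] & (records["concentration_um"] == 0.0)]
        gfp_col = "gfp_mean_organelle" if mask_name == "organelle" else "gfp_mean_body"
        reg = regression_r2(sel[gfp_col], sel[col])
        results[mask_name] = {**fit.to_dict(), "r_squared": reg.r_squared, "n_cells": reg.n_cells}
        log.info(
            "fit[%s]: cp50=%.3g ± %.2g µM, hill=%.3g, r²=%.4f",
            mask_name, fit.cp50, fit.se_cp50, fit.hill, reg.r_squared,
        )
    tox = toxicity_curve(pd.read_csv(out_dir / "qc_summary.csv"), layout)
    tox.table.to_csv(out_dir / "toxicity.csv", index=False)
    write_json(results, out_dir / "results.json")
    manifest.outputs += [
        str(out_dir / "results.json"),
        str(out_dir / "toxicity.csv"),
    ]
    _fit.cache = fits  # reused by report stage within the same run


def _report(config, out_dir, seed, noise, _write_masks, manifest):
    import json

    results_path = out_dir / "results.json"
    if not results_path.exists():
        raise FileNotFoundError(f"fit stage output missing: {results_path}")
    with open(results_path) as fh:
        results = json.load(fh)
    fit_w = _rebuild_fit(results["whole_cell"])
    fit_o = _rebuild_fit(results["organelle"])
    try:
        comparison = compare_masks(fit_w, fit_o).to_dict()
    except ValueError as exc:
        comparison = {"error": str(exc)}
    write_json(comparison, out_dir / "mask_comparison.json")
    manifest.outputs.append(str(out_dir / "mask_comparison.json"))

    from .plots import plot_report

    plot_paths = plot_report(out_dir, config)
    manifest.outputs += [str(p) for p in plot_paths]
    if "p_value" in comparison:
        log.info(
            "report: whole-cell cp50 %.3g vs organelle %.3g µM (p=%.3g)",
            comparison["cp50_whole_cell"], comparison["cp50_organelle"], comparison["p_value"],
        )


def _rebuild_fit(d: dict):
    from .stats import DoseResponseFit

    return DoseResponseFit(
        cp50=d["cp50"], hill=d["hill"], top=d["top"], bottom=d["bottom"],
        se_cp50=d["se_cp50"], n_replicates=d["n_replicates"], converged=d["converged"],
        residual_sd=d["residual_sd"], replicate_cp50s=tuple(d.get("replicate_cp50s", ())),
        se_cp50_covariance=d.get("se_cp50_covariance", float("nan")), mask=d.get("mask", ""),
    )


_STAGE_FNS = {
    "simulate": _simulate,
    "segment": _segment,
    "quantify": _quantify,
    "fit": _fit,
    "report": _report,
}
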