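"""Self-contained benchmark experiments on the synthetic generator.

Each function generates its own data, runs the relevant pipeline stages in
memory and returns the headline quantity: the discard rate of the
damaged-cell filter, the removal rate of the transfection gate, the
recovery of an analytically prescribed per-cell correlation, and full-plate
CP50 recovery.  They are the package's reference workloads for validating
the analysis chain against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, PlateLayout, QCParams, SegmentationParams, SimulationConfig
from .quantify import apply_qc, calibrate_damage_thresholds, extract_features
from .segmentation import segment_field
from .stats import RegressionResult, regression_r2
from .synthgen import field_rng, render_field, sample_population

__all__ = [
    "segment_population",
    "damaged_fraction_experiment",
    "gate_removal_experiment",
    "linear_gaussian_pairs",
    "r2_recovery_experiment",
    "cp50_recovery_experiment",
    "DOSE_LADDER_UM",
]

# geometric ladder bracketing the default CP50 (7.3 µM) plus untreated controls
DOSE_LADDER_UM = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


def segment_population(
    config: SimulationConfig,
    mode: str,
    n_cells: int,
    seed: int,
    concentration: float = 0.0,
    seg: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Render and segment enough fields to cover ``n_cells``; return features.

    Fields are independent (per-field RNG streams); the returned frame also
    carries the per-field GFP background SD in ``bg_sd``.
    """
    seg = seg or SegmentationParams()
    n_fields = int(np.ceil(n_cells / config.n_cells_per_field))
    frames = []
    for i in range(1, n_fields + 1):
        rng = field_rng(seed, "X", i)
        cells = sample_population(config, mode, concentration, rng)
        field = render_field(cells, config, rng, well_id="X", field_index=i)
        masks = segment_field(field, seg)
        rec = extract_features(field, masks, "X", i, concentration, seg)
        rec["bg_sd"] = masks.background["gfp"][1]
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def damaged_fraction_experiment(
    seed: int,
    n_cells: int = 10_000,
    p_damaged: float = 0.15,
    qc: QCParams | None = None,
) -> dict:
    """Percentage of cells flagged by the damaged-cell exclusion filter.

    Stable-mode, untreated population with the configured damage
    probability; thresholds are calibrated on the population itself (all
    wells untreated, i.e. all are controls).
    """
    config = SimulationConfig(p_damaged=p_damaged)
    records = segment_population(config, "stable", n_cells, seed)
    thresholds = calibrate_damage_thresholds(records, qc)
    out = apply_qc(records, thresholds, float(records["bg_sd"].median()), "stable", qc)
    return {
        "percent_flagged": 100.0 * float(out["qc_damaged"].mean()),
        "n_cells": int(len(out)),
    }


def gate_removal_experiment(
    seed: int,
    n_cells: int = 10_000,
    transient_mix: tuple[float, float, float] = (0.20, 0.20, 0.60),
    qc: QCParams | None = None,
) -> dict:
    """Percentage of cells removed by the transient-transfection gate.

    The mixture's non- plus over-expresser share is the expected removal
    rate; damage is switched off to isolate the gate.
    """
    config = SimulationConfig(p_damaged=0.0, transient_mix=transient_mix)
    records = segment_population(config, "transient", n_cells, seed)
    thresholds = calibrate_damage_thresholds(records, qc)
    out = apply_qc(records, thresholds, float(records["bg_sd"].median()), "transient", qc)
    return {
        "percent_removed": 100.0 * float(out["qc_gated_out"].mean()),
        "n_cells": int(len(out)),
    }


def linear_gaussian_pairs(
    rho: float, n: int, rng: np.random.Generator, config: SimulationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (GFP, reporter) pairs with population r² set analytically.

    R = a·G + eps with var(eps) = a²·var(G)·(1−rho)/rho, so the population
    coefficient of determination of the OLS of R on G equals rho exactly.
    G follows the generator's log-normal expression distribution scaled by
    the GFP gain.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly between 0 and 1")
    config = config or SimulationConfig()
    sigma = np.sqrt(np.log1p(config.expression_cv**2))
    g = config.gfp_gain * rng.lognormal(np.log(config.expression_median), sigma, n)
    a = config.reporter_gain / config.gfp_gain
    eps_sd = np.sqrt(a**2 * np.var(g) * (1.0 - rho) / rho)
    r = a * g + rng.normal(0.0, eps_sd, n)
    return g, r


def r2_recovery_experiment(rho: float, seed: int, n: int = 5000) -> RegressionResult:
    """Fit the per-cell regression on pairs with known population r²."""
    g, r = linear_gaussian_pairs(rho, n, np.random.default_rng(seed))
    return regression_r2(g, r)


def cp50_recovery_experiment(
    seed: int,
    out_dir: str | Path,
    offtarget_amplitude: float | None = None,
    n_replicates: int = 3,
    n_fields: int = 1,
) -> dict:
    """Full stable-mode screen: plate -> masks -> QC -> dose-response fits.

    Returns the organelle- and whole-cell-mask fits (cp50, se_cp50, ...)
    from ``results.json`` of a complete pipeline run.
    """
    import json

    from .pipeline import run_pipeline

    cfg = PipelineConfig(
        layout=PlateLayout.dose_ladder(DOSE_LADDER_UM, n_replicates, n_fields)
    )
    if offtarget_amplitude is not None:
        cfg = dataclasses.replace(
            cfg, simulation=cfg.simulation.replace(offtarget_amplitude=offtarget_amplitude)
        )
    run_pipeline(cfg, out_dir, seed, stages=("simulate", "segment", "quantify", "fit"))
    with open(Path(out_dir) / "results.json") as fh:
        return json.load(fh)
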