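"""Per-cell feature extraction and the two cell-selection filters.

Features are background-subtracted channel means under the cell-body and
organelle masks plus nuclear/organelle morphology.  Two filters mirror the
assay's selection process:

* damaged-cell exclusion - condensed (small, bright) nuclei or fragmented
  organelle networks, with thresholds calibrated on untreated control wells;
* transient-transfection gate - removes over-expressers (no dark region in
  the cell body) and non/under-expressers (no organelle-localised GFP).

A cell is ``selected`` iff it passes both filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import QCParams, SegmentationParams
from .segmentation import MaskSet, dark_region_fraction

__all__ = [
    "CELL_COLUMNS",
    "DamageThresholds",
    "extract_features",
    "calibrate_damage_thresholds",
    "flag_damaged",
    "transfection_gate",
    "offtarget_index",
    "apply_qc",
    "qc_summary",
]

CELL_COLUMNS = [
    "cell_id",
    "well",
    "field",
    "concentration_um",
    "gfp_mean_body",
    "gfp_mean_organelle",
    "rep_mean_body",
    "rep_mean_organelle",
    "nuc_area",
    "nuc_mean_intensity",
    "organelle_n_components",
    "organelle_area",
    "dark_fraction",
    "offtarget_index",
    "qc_damaged",
    "qc_gated_out",
    "selected",
]

_S4 = ndi.generate_binary_structure(2, 1)


def _label_means(img: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return ndi.mean(np.asarray(img, float), labels=labels, index=ids)


def _label_sums(img: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return ndi.sum_labels(np.asarray(img, float), labels=labels, index=ids)


def extract_features(
    images,
    masks: MaskSet,
    well_id: str = "",
    field_index: int = 0,
    concentration_um: float = np.nan,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """One row of measured features per segmented cell.

    Intensity means are background-subtracted with the per-channel robust
    background stored in the mask set.  Cells whose organelle mask is empty
    get missing organelle intensities (NaN) and are excluded from
    organelle-mask statistics downstream but retained for whole-body ones.
    """
    params = params or SegmentationParams()
    ids = masks.cell_ids
    if ids.size == 0:
        return pd.DataFrame(columns=CELL_COLUMNS)

    gfp_bg, gfp_sd = masks.background.get("gfp", (0.0, 0.0))
    rep_bg, _ = masks.background.get("reporter", (0.0, 0.0))
    nuc_bg, _ = masks.background.get("nuclear", (0.0, 0.0))

    cell_labels = masks.cell_labels
    org_labels = np.where(masks.organelle_mask, cell_labels, 0)

    gfp_body = _label_means(images.gfp, cell_labels, ids) - gfp_bg
    rep_body = _label_means(images.reporter, cell_labels, ids) - rep_bg
    org_area = _label_sums(np.ones_like(cell_labels, dtype=float), org_labels, ids)
    with np.errstate(invalid="ignore"):
        gfp_org = np.where(
            org_area > 0, _label_means(images.gfp, org_labels, ids) - gfp_bg, np.nan
        )
        rep_org = np.where(
            org_area > 0, _label_means(images.reporter, org_labels, ids) - rep_bg, np.nan
        )

    nuc_area = _label_sums(np.ones_like(cell_labels, dtype=float), masks.nuclei_labels, ids)
    nuc_mean = _label_means(images.nuclear, masks.nuclei_labels, ids) - nuc_bg

    # organelle fragmentation: connected components of the mask per cell
    comp_labels, _ = ndi.label(masks.organelle_mask, structure=_S4)
    n_comp = np.zeros(ids.size)
    for i, lab in enumerate(ids):
        comps = comp_labels[(cell_labels == lab) & masks.organelle_mask]
        n_comp[i] = np.unique(comps[comps > 0]).size

    dark = dark_region_fraction(images.gfp, cell_labels, gfp_bg, gfp_sd, params)

    # off-target index: reporter signal in the body but outside the organelle
    rep_body_sum = _label_sums(np.asarray(images.reporter, float) - rep_bg, cell_labels, ids)
    rep_org_sum = _label_sums(np.asarray(images.reporter, float) - rep_bg, org_labels, ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        ot_index = np.where(
            rep_body_sum > 0,
            np.clip((rep_body_sum - rep_org_sum) / rep_body_sum, 0.0, 1.0),
            np.nan,
        )

    return pd.DataFrame(
        {
            "cell_id": ids,
            "well": well_id,
            "field": field_index,
            "concentration_um": concentration_um,
            "gfp_mean_body": gfp_body,
            "gfp_mean_organelle": gfp_org,
            "rep_mean_body": rep_body,
            "rep_mean_organelle": rep_org,
            "nuc_area": nuc_area,
            "nuc_mean_intensity": nuc_mean,
            "organelle_n_components": n_comp,
            "organelle_area": org_area,
            "dark_fraction": [dark.get(int(lab), np.nan) for lab in ids],
            "offtarget_index": ot_index,
        }
    )


def offtarget_index(records: pd.DataFrame) -> pd.Series:
    """Per-cell fraction of body reporter signal lying outside the organelle."""
    return records["offtarget_index"]


@dataclass(frozen=True)
class DamageThresholds:
    """Control-calibrated cut-offs for the damaged-cell filter."""

    nuc_area_min: float
    nuc_intensity_max: float
    fragmentation_max: float


def _fragmentation_index(records: pd.DataFrame) -> pd.Series:
    with np.errstate(divide="ignore", invalid="ignore"):
        return records["organelle_n_components"] / records["organelle_area"].replace(0, np.nan)


def calibrate_damage_thresholds(
    control_records: pd.DataFrame, qc: QCParams | None = None
) -> DamageThresholds:
    """Robust thresholds from untreated control wells.

    The healthy population dominates the controls, so median +/- k robust
    SDs (1.4826*MAD) of each morphology feature bounds it even though the
    controls themselves contain damaged cells; anything beyond the bound in
    the damage direction (smaller/brighter nuclei, more fragmented
    organelles) is flagged.
    """
    qc = qc or QCParams()
    if control_records.empty:
        raise ValueError("no control cells available for threshold calibration")

    def robust(s: pd.Series) -> tuple[float, float]:
        v = s.dropna().to_numpy(float)
        med = float(np.median(v))
        sd = 1.4826 * float(np.median(np.abs(v - med)))
        return med, max(sd, np.finfo(float).eps)

    a_med, a_sd = robust(control_records["nuc_area"])
    i_med, i_sd = robust(control_records["nuc_mean_intensity"])
    f_med, f_sd = robust(_fragmentation_index(control_records))
    k = qc.damage_k_mad
    return DamageThresholds(
        nuc_area_min=a_med - k * a_sd,
        nuc_intensity_max=i_med + k * i_sd,
        fragmentation_max=f_med + k * f_sd,
    )


def flag_damaged(records: pd.DataFrame, thresholds: DamageThresholds) -> pd.Series:
    """Damaged if the nucleus is condensed (small OR bright) or the
    organelle network is fragmented (high components-per-area)."""
    frag = _fragmentation_index(records)
    flags = (
        (records["nuc_area"] < thresholds.nuc_area_min)
        | (records["nuc_mean_intensity"] > thresholds.nuc_intensity_max)
        | (frag > thresholds.fragmentation_max)
    )
    return flags.fillna(False)


def transfection_gate(
    records: pd.DataFrame,
    gfp_background_sd: float,
    qc: QCParams | None = None,
) -> pd.Series:
    """Gate for transient transfection: keep properly localised expressers.

    A cell is gated out when its body has (almost) no dark region - GFP
    everywhere, the over-expresser signature - or when its organelle GFP does
    not clear the background - a non/under-expresser.  Cells with an empty
    organelle mask count as non-expressers.
    """
    qc = qc or QCParams()
    g_min = qc.gate_gfp_k * gfp_background_sd
    over = records["dark_fraction"] < qc.gate_dark_min
    under = records["gfp_mean_organelle"].fillna(-np.inf) < g_min
    return (over | under).fillna(False)


def apply_qc(
    records: pd.DataFrame,
    thresholds: DamageThresholds,
    gfp_background_sd: float,
    mode: str = "stable",
    qc: QCParams | None = None,
) -> pd.DataFrame:
    """Attach qc_damaged / qc_gated_out / selected flags to the records."""
    out = records.copy()
    out["qc_damaged"] = flag_damaged(out, thresholds)
    if mode == "transient":
        out["qc_gated_out"] = transfection_gate(out, gfp_background_sd, qc)
    else:
        out["qc_gated_out"] = False
    out["selected"] = ~out["qc_damaged"] & ~out["qc_gated_out"]
    return out


def qc_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-well counts: total, damaged, gated, selected cells."""
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "concentration_um": g["concentration_um"].iloc[0],
                "n_total": len(g),
                "n_damaged": int(g["qc_damaged"].sum()),
                "n_gated_out": int(g["qc_gated_out"].sum()),
                "n_selected": int(g["selected"].sum()),
            }
        )

    return records.groupby("well", sort=True).apply(agg, include_groups=False).reset_index()
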