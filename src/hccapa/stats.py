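"""Quantitative layer: per-cell regression r², 4PL dose-response (CP50),
toxicity curve, and the paired one-tailed mask comparison.

CP50 is the transporter concentration producing half-maximal cell
penetration: the midpoint of the reporter-signal dose-response

    S(c) = bottom + (top - bottom) / (1 + (c / cp50)**hill),

fitted by nonlinear least squares with cp50 and hill optimised in log
space.  The c = 0 wells enter as exact top-asymptote observations.  The
reported ``se_cp50`` is the SEM of the per-replicate CP50 estimates (the
single-fit covariance is kept as a diagnostic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .config import FitParams

__all__ = [
    "RegressionResult",
    "DoseResponseFit",
    "ToxicityCurve",
    "MaskComparison",
    "regression_r2",
    "four_pl",
    "fit_dose_response",
    "aggregate_responses",
    "toxicity_curve",
    "paired_one_tailed_t",
    "compare_masks",
]


# ---------------------------------------------------------------------------
# per-cell regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_cells: int


def regression_r2(gfp, reporter) -> RegressionResult:
    """OLS of reporter on GFP across cells; r² = 1 − SS_res/SS_tot.

    The r² of this per-cell correlation is the assay's mask-accuracy metric:
    reporter signal is proportional to free HaloTags, GFP to total HaloTags,
    so under a clean mask the two are collinear up to biological noise.
    """
    x = np.asarray(gfp, dtype=float)
    y = np.asarray(reporter, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"regression needs at least 3 finite cell pairs, got {x.size}")
    if np.var(x) == 0:
        raise ValueError("regression undefined: zero predictor variance")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_cells=int(x.size),
    )


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    cp50: float
    hill: float
    top: float
    bottom: float
    se_cp50: float
    n_replicates: int
    converged: bool
    residual_sd: float
    replicate_cp50s: tuple = ()
    se_cp50_covariance: float = float("nan")  # single-fit diagnostic
    mask: str = ""

    def to_dict(self) -> dict:
        return {
            "cp50": self.cp50,
            "hill": self.hill,
            "top": self.top,
            "bottom": self.bottom,
            "se_cp50": self.se_cp50,
            "n_replicates": self.n_replicates,
            "converged": self.converged,
            "residual_sd": self.residual_sd,
            "replicate_cp50s": list(self.replicate_cp50s),
            "se_cp50_covariance": self.se_cp50_covariance,
            "mask": self.mask,
        }


def four_pl(c, cp50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic; S(0) = top, S(inf) = bottom for hill > 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / cp50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def _fit_single(conc: np.ndarray, resp: np.ndarray, params: FitParams):
    """One 4PL least-squares fit; returns (cp50, hill, top, bottom, cov_se, resid_sd)."""
    top0 = float(resp.max())
    bot0 = float(resp.min())
    pos = conc[conc > 0]
    cp0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0

    def residuals(p):
        log_cp50, log_hill, top, bottom = p
        return four_pl(conc, np.exp(log_cp50), np.exp(log_hill), top, bottom) - resp

    x0 = np.array([np.log(cp0), 0.0, top0, bot0])
    sol = optimize.least_squares(
        residuals, x0, xtol=params.xtol, ftol=params.xtol, gtol=params.xtol,
        max_nfev=params.max_nfev, method="lm" if conc.size >= 4 else "trf",
    )
    log_cp50, log_hill, top, bottom = sol.x
    dof = max(conc.size - 4, 1)
    resid_sd = float(np.sqrt(np.sum(sol.fun**2) / dof))
    cov_se = np.nan
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * resid_sd**2
        cov_se = float(np.sqrt(cov[0, 0]) * np.exp(log_cp50))  # delta method, log scale
    except np.linalg.LinAlgError:
        pass
    return float(np.exp(log_cp50)), float(np.exp(log_hill)), float(top), float(bottom), cov_se, resid_sd


def fit_dose_response(
    concentrations,
    responses,
    replicate_ids=None,
    params: FitParams | None = None,
    mask: str = "",
) -> DoseResponseFit:
    """Fit the 4PL dose-response and estimate CP50 with its replicate SEM.

    ``concentrations``/``responses`` are per-well aggregated values (one
    entry per well).  With replicate ids, each replicate is fitted
    separately and ``se_cp50`` is the SEM of the per-replicate CP50s; the
    headline parameters come from a pooled fit of all wells.  A flat
    response (span below ``flat_response_k`` x residual noise) is flagged
    non-convergent and no CP50 is reported.
    """
    params = params or FitParams()
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    ok = np.isfinite(conc) & np.isfinite(resp)
    conc, resp = conc[ok], resp[ok]
    reps = np.asarray(replicate_ids)[ok] if replicate_ids is not None else None
    if np.unique(conc).size < 5 or 0.0 not in conc:
        raise ValueError("need at least 5 distinct concentrations including 0")

    cp50, hill, top, bottom, cov_se, resid_sd = _fit_single(conc, resp, params)

    span = float(resp.max() - resp.min())
    if span < params.flat_response_k * max(resid_sd, np.finfo(float).eps) or span == 0.0:
        return DoseResponseFit(
            cp50=np.nan, hill=np.nan, top=top, bottom=bottom, se_cp50=np.nan,
            n_replicates=0 if reps is None else int(np.unique(reps).size),
            converged=False, residual_sd=resid_sd, mask=mask,
        )

    rep_cp50s: list[float] = []
    if reps is not None:
        for r in np.unique(reps):
            sel = reps == r
            if np.unique(conc[sel]).size >= 5 and 0.0 in conc[sel]:
                rcp, *_ = _fit_single(conc[sel], resp[sel], params)
                rep_cp50s.append(rcp)
    if len(rep_cp50s) >= 2:
        se = float(np.std(rep_cp50s, ddof=1) / np.sqrt(len(rep_cp50s)))
    else:
        se = cov_se
    return DoseResponseFit(
        cp50=cp50, hill=hill, top=top, bottom=bottom, se_cp50=se,
        n_replicates=len(rep_cp50s), converged=True, residual_sd=resid_sd,
        replicate_cp50s=tuple(rep_cp50s), se_cp50_covariance=cov_se, mask=mask,
    )


def aggregate_responses(
    records: pd.DataFrame, layout, response_col: str = "rep_mean_organelle"
) -> pd.DataFrame:
    """Per-well response for dose-response fitting.

    The response is the median over selected cells of the per-cell
    reporter/GFP intensity ratio under the chosen mask
    (``rep_mean_organelle`` or ``rep_mean_body`` divided by the matching GFP
    mean).  Normalising each cell's reporter signal by its GFP cancels the
    broad expression distribution - reporter and GFP are both proportional
    to the HaloTag count, so the ratio tracks the free-HaloTag fraction -
    and medians resist residual off-target outliers.  Returns columns well,
    concentration_um, replicate, response, n_cells.
    """
    gfp_col = {
        "rep_mean_organelle": "gfp_mean_organelle",
        "rep_mean_body": "gfp_mean_body",
    }[response_col]
    sel = records[records["selected"]].copy()
    denom = sel[gfp_col].where(sel[gfp_col] > 0)
    sel["_ratio"] = sel[response_col] / denom
    rows = []
    for well, g in sel.groupby("well"):
        spec = layout.well(well)
        vals = g["_ratio"].dropna()
        rows.append(
            {
                "well": well,
                "concentration_um": spec.concentration_um,
                "replicate": spec.replicate,
                "response": float(vals.median()) if len(vals) else np.nan,
                "n_cells": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toxicity
# ---------------------------------------------------------------------------


@dataclass
class ToxicityCurve:
    """Percent of damage-free selected cells relative to untreated controls."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: concentration_um, percent_selected, sem, n_wells


def toxicity_curve(summary: pd.DataFrame, layout) -> ToxicityCurve:
    """Toxicity readout of the screen.

    percent_selected(c) = 100 * mean selected-cell count at c / mean
    selected-cell count in the 0 µM controls, with the SEM over replicate
    wells.  A non-toxic transporter gives a flat curve at 100%.
    """
    df = summary.copy()
    df["concentration_um"] = [layout.well(w).concentration_um for w in df["well"]]
    control = df[df["concentration_um"] == 0.0]["n_selected"]
    if control.empty or control.mean() == 0:
        raise ValueError("control wells missing or contain no selected cells")
    c0 = float(control.mean())
    rows = []
    for conc, g in df.groupby("concentration_um"):
        counts = g["n_selected"].to_numpy(float)
        pct = 100.0 * counts / c0
        rows.append(
            {
                "concentration_um": float(conc),
                "percent_selected": float(pct.mean()),
                "sem": float(pct.std(ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else 0.0,
                "n_wells": int(len(pct)),
            }
        )
    return ToxicityCurve(pd.DataFrame(rows).sort_values("concentration_um").reset_index(drop=True))


# ---------------------------------------------------------------------------
# mask comparison
# ---------------------------------------------------------------------------


def paired_one_tailed_t(x, y) -> tuple[float, int, float]:
    """One-tailed paired Student's t-test of H1: mean(x - y) > 0.

    Returns (t, df, p) with t = mean(d) / (sd(d)/sqrt(n)), df = n - 1 and p
    the upper-tail probability.  Zero-variance differences resolve to
    t = +/-inf (p = 0 or 1) unless the mean is also 0, which resolves to
    t = 0, p = 0.5 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired test needs two equal-length vectors of n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0.0:
        if m == 0.0:
            return 0.0, n - 1, 0.5
        warnings.warn("zero-variance differences; p reported at machine floor")
        return float(np.sign(m) * np.inf), n - 1, 0.0 if m > 0 else 1.0
    t = m / (sd / np.sqrt(n))
    p = float(sps.t.sf(t, df=n - 1))
    return float(t), n - 1, p


@dataclass
class MaskComparison:
    cp50_whole_cell: float
    cp50_organelle: float
    difference_um: float
    percent_difference: float
    se_ratio: float
    t: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def compare_masks(fit_whole: DoseResponseFit, fit_organelle: DoseResponseFit) -> MaskComparison:
    """Whole-cell vs organelle mask: CP50 difference and its significance.

    The one-tailed alternative is fixed a priori as whole-cell CP50 >
    organelle CP50 (off-target reporter outside the organelle right-shifts
    the whole-cell curve).  Pairing is by replicate.
    """
    xw = np.asarray(fit_whole.replicate_cp50s, float)
    xo = np.asarray(fit_organelle.replicate_cp50s, float)
    if xw.size != xo.size or xw.size < 2:
        raise ValueError("mask comparison needs matched per-replicate CP50s (n >= 2)")
    t, df, p = paired_one_tailed_t(xw, xo)
    diff = fit_whole.cp50 - fit_organelle.cp50
    return MaskComparison(
        cp50_whole_cell=fit_whole.cp50,
        cp50_organelle=fit_organelle.cp50,
        difference_um=diff,
        percent_difference=100.0 * diff / fit_organelle.cp50,
        se_ratio=fit_whole.se_cp50 / fit_organelle.se_cp50
        if fit_organelle.se_cp50 > 0
        else np.nan,
        t=t,
        df=df,
        p_value=p,
    )
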