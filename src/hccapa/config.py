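"""Configuration objects for simulation, segmentation, QC and fitting.

Every numeric default of the pipeline lives here (or in the YAML file that
mirrors these dataclasses field-for-field); nothing downstream hard-codes a
threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "CameraModel",
    "SimulationConfig",
    "PlateLayout",
    "WellSpec",
    "SegmentationParams",
    "QCParams",
    "FitParams",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class CameraModel:
    """Poisson-Gaussian detector model (sCMOS approximation).

    Recorded counts = offset + poisson_scale * Poisson(signal / poisson_scale)
    + N(0, read_noise_sd), clipped to the 16-bit range.  ``poisson_scale`` is
    the conversion gain in counts per photoelectron; setting it to 0 disables
    shot noise, and read_noise_sd = 0 disables read noise.
    """

    read_noise_sd: float = 3.0
    poisson_scale: float = 0.5
    offset: float = 100.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.poisson_scale < 0 or self.offset < 0:
            raise ValueError("camera parameters must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic HC CAPA plate generator.

    The generator emulates cells expressing a HaloTag-GFP fusion on an
    organelle (mitochondrial network or Golgi apparatus).  Per-cell HaloTag
    expression is log-normal; a transporter at concentration ``c`` blocks a
    Hill-type fraction ``theta(c) = c**h / (c**h + cp50_true**h)`` of the
    HaloTags; the reporter dye then labels the free remainder, so its specific
    signal is proportional to ``expression * (1 - theta)``.

    Off-target reporter staining is modelled as saturable puncta driven by
    the dye excess: when HaloTags are blocked, unreacted dye accumulates at
    non-specific sites inside the cell body but outside the organelle.  The
    integrated off-target signal per cell is
    ``offtarget_amplitude * (reporter_gain * expression * organelle area) *
    theta / (theta + offtarget_saturation)``, i.e. ``offtarget_amplitude``
    is the fraction of the cell's maximal integrated specific signal that
    ends up off-target at full dye excess.  The saturable form keeps the
    whole-cell dose-response monotone (guaranteed for amplitude <=
    saturation constant) while shifting its apparent midpoint above the
    true CP50 - the bias that organelle masking removes.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    n_cells_per_field: int = 60
    expression_median: float = 1.0
    expression_cv: float = 0.35
    gfp_gain: float = 2500.0
    reporter_gain: float = 2500.0
    cp50_true: float = 7.3
    hill_true: float = 1.0
    # per-cell CV of reporter labeling efficiency: biological noise that
    # decorrelates reporter from GFP beyond what the camera contributes
    reporter_cv: float = 0.05
    offtarget_amplitude: float = 0.15
    offtarget_saturation: float = 0.4
    offtarget_puncta_per_cell: int = 4
    # well-to-well CV of the off-target amplitude (staining/wash batch
    # effects); the extra well-level noise afflicts only the whole-cell
    # readout, which is why the organelle mask is the more precise one
    offtarget_well_cv: float = 0.5
    p_damaged: float = 0.15
    p_damaged_slope: float = 0.0  # extra damage probability per µM (toxic transporter)
    transient_mix: tuple[float, float, float] = (0.20, 0.20, 0.60)  # (non, normal, over)
    nucleus_sigma_px: float = 5.0
    cell_radius_px: float = 28.0
    nuclear_amp: float = 3000.0
    camera: CameraModel = field(default_factory=CameraModel)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 128 or w < 128:
            raise ValueError("field dimensions must be at least 128 px")
        if self.cp50_true <= 0:
            raise ValueError("cp50_true must be positive")
        if self.hill_true <= 0:
            raise ValueError("hill_true must be positive")
        for name in ("p_damaged",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.transient_mix) - 1.0) > _PROB_TOL:
            raise ValueError("transient_mix must sum to 1")
        if any(p < 0 or p > 1 for p in self.transient_mix):
            raise ValueError("transient_mix entries must lie in [0, 1]")
        if self.offtarget_amplitude < 0:
            raise ValueError("offtarget_amplitude must be non-negative")
        if self.offtarget_saturation <= 0:
            raise ValueError("offtarget_saturation must be positive")
        if self.expression_median <= 0 or self.expression_cv < 0:
            raise ValueError("invalid expression distribution parameters")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    concentration_um: float
    replicate: int
    n_fields: int = 1

    def __post_init__(self) -> None:
        if self.concentration_um < 0:
            raise ValueError(f"negative concentration for well {self.well_id}")
        if self.n_fields < 1:
            raise ValueError(f"well {self.well_id} needs at least one field")


@dataclass(frozen=True)
class PlateLayout:
    """Maps wells to transporter concentration and replicate index."""

    wells: tuple[WellSpec, ...]

    def __post_init__(self) -> None:
        if not self.control_wells:
            raise ValueError("layout must contain at least one control (0 µM) well")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids in layout")
        reps = sorted({w.replicate for w in self.wells})
        if reps != list(range(1, len(reps) + 1)):
            raise ValueError("replicate indices must be contiguous from 1")

    @property
    def control_wells(self) -> tuple[str, ...]:
        return tuple(w.well_id for w in self.wells if w.concentration_um == 0.0)

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(sorted({w.replicate for w in self.wells}))

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(f"well {well_id!r} not in layout")

    @classmethod
    def dose_ladder(
        cls,
        concentrations_um: Sequence[float],
        n_replicates: int = 3,
        n_fields: int = 1,
    ) -> "PlateLayout":
        """Standard screen: one well per (concentration, replicate).

        Concentration 0 must be present; those wells are the controls.
        Well ids follow row = replicate (A, B, ...), column = concentration
        rank, e.g. ``A01`` is replicate 1 at the lowest concentration.
        """
        concs = sorted(set(float(c) for c in concentrations_um))
        if not concs or concs[0] != 0.0:
            raise ValueError("dose ladder must include concentration 0 (control)")
        wells = []
        for r in range(1, n_replicates + 1):
            row = chr(ord("A") + r - 1)
            for j, c in enumerate(concs, start=1):
                wells.append(WellSpec(f"{row}{j:02d}", c, r, n_fields))
        return cls(tuple(wells))

    def to_dict(self) -> dict:
        return {
            "wells": [
                {
                    "well_id": w.well_id,
                    "concentration_um": w.concentration_um,
                    "replicate": w.replicate,
                    "n_fields": w.n_fields,
                }
                for w in self.wells
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        return cls(tuple(WellSpec(**w) for w in d["wells"]))


@dataclass(frozen=True)
class SegmentationParams:
    """Mask-construction parameters (all lengths in pixels)."""

    nuclei_smooth_sigma: float = 2.0
    nuclei_min_area: int = 30
    nuclei_max_area: int = 2500
    nuclei_min_distance: int = 8
    # minimum Otsu-threshold elevation over robust background, in background SDs;
    # guards against spurious nuclei on blank fields
    nuclei_min_snr: float = 5.0
    body_smooth_sigma: float = 4.0
    body_foreground_k: float = 4.0
    body_max_radius: float = 42.0
    organelle_tophat_radius: int = 4
    organelle_k_mad: float = 3.0
    organelle_min_component_px: int = 4
    dark_k: float = 3.0  # GFP <= background + dark_k * background_sd counts as dark
    discard_border: bool = True


@dataclass(frozen=True)
class QCParams:
    """Damaged-cell exclusion and transient-transfection gate settings.

    Damage thresholds are control-relative: on untreated wells the per-cell
    nuclear area, nuclear intensity and organelle fragmentation index are
    summarised by median and MAD, and cells beyond ``damage_k_mad`` robust
    SDs in the damage direction are flagged.
    """

    damage_k_mad: float = 4.0
    gate_dark_min: float = 0.25  # minimum dark-region fraction (else over-expresser)
    # minimum organelle GFP in background SDs (else non/under-expresser); must sit
    # well above the upper-tail selection bias that a threshold-derived mask
    # acquires on a non-expressing cell, and well below genuine expression
    gate_gfp_k: float = 15.0


@dataclass(frozen=True)
class FitParams:
    """4PL dose-response fitting controls."""

    xtol: float = 1e-8
    max_nfev: int = 10000
    flat_response_k: float = 3.0  # span < k * residual noise ⇒ flagged non-convergent


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    layout: PlateLayout = field(
        default_factory=lambda: PlateLayout.dose_ladder(
            (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0), n_replicates=3, n_fields=1
        )
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCParams = field(default_factory=QCParams)
    fit: FitParams = field(default_factory=FitParams)
    mode: str = "stable"  # {"stable", "transient"}

    def __post_init__(self) -> None:
        if self.mode not in ("stable", "transient"):
            raise ValueError("mode must be 'stable' or 'transient'")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, PlateLayout):
            return obj.to_dict()
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    return obj


def _tupled(d: dict, keys: Sequence[str]) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(d: dict) -> PipelineConfig:
    sim = d.get("simulation", {})
    sim = _tupled(sim, ["field_size_px", "transient_mix"])
    cam = sim.pop("camera", None)
    sim_cfg = SimulationConfig(
        **sim, **({"camera": CameraModel(**cam)} if cam is not None else {})
    )
    layout = (
        PlateLayout.from_dict(d["layout"]) if "layout" in d else PipelineConfig().layout
    )
    return PipelineConfig(
        simulation=sim_cfg,
        layout=layout,
        segmentation=SegmentationParams(**d.get("segmentation", {})),
        qc=QCParams(**d.get("qc", {})),
        fit=FitParams(**d.get("fit", {})),
        mode=d.get("mode", "stable"),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the configuration."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()
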