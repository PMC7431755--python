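"""Synthetic HC CAPA plate generator.

Produces multiwell fluorescence fields (nuclear stain / GFP / reporter) and
the latent per-cell ground truth that the rest of the pipeline is tested
against.  Two cellular scenarios are emulated:

``stable``
    A clonal line expressing HaloTag-GFP on the outer mitochondrial
    membrane: uniform log-normal expression, filamentous organelle texture.
``transient``
    Transiently transfected cells with the fusion protein on the Golgi
    apparatus: a mixture of non-expressers, normally expressing cells with a
    peri-nuclear punctate Golgi, and over-expressers whose GFP floods the
    entire cell body (no dark region).

The chloroalkane penetration mechanism enters through the per-cell HaloTag
occupancy: a transporter at concentration ``c`` blocks the fraction
``theta = c**h / (c**h + cp50**h)`` of HaloTags, and the reporter dye labels
only the free remainder, so the specific reporter amplitude is
``reporter_gain * expression * (1 - theta)`` on the organelle texture.
Dye excess additionally produces saturable off-target puncta outside the
organelle (see :class:`~hccapa.config.SimulationConfig`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import PlateLayout, SimulationConfig

__all__ = [
    "GroundTruthCell",
    "FieldImageSet",
    "occupancy_response",
    "offtarget_response",
    "sample_population",
    "render_field",
    "build_plate",
    "field_rng",
    "GROUND_TRUTH_COLUMNS",
    "CHANNEL_ORDER",
]

CHANNEL_ORDER = ("nuclear", "gfp", "reporter")

GROUND_TRUTH_COLUMNS = [
    "cell_id",
    "well",
    "field",
    "x_px",
    "y_px",
    "expression",
    "occupancy",
    "damaged",
    "expr_class",
]


@dataclass(frozen=True)
class GroundTruthCell:
    """Latent state of one simulated cell."""

    cell_id: int
    centroid_px: tuple[float, float]  # (row, col)
    expression: float
    occupancy: float
    damaged: bool
    expr_class: str  # {"non", "normal", "over"}
    organelle_kind: str  # {"mitochondria", "golgi"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class FieldImageSet:
    """Three co-registered 16-bit channels for one field."""

    nuclear: np.ndarray
    gfp: np.ndarray
    reporter: np.ndarray
    pixel_size_um: float
    well_id: str = ""
    field_index: int = 0

    def stack(self) -> np.ndarray:
        return np.stack([self.nuclear, self.gfp, self.reporter])


def occupancy_response(c, cp50: float, h: float):
    """Hill-type fraction of HaloTags blocked at transporter concentration c.

    theta(c) = c**h / (c**h + cp50**h); theta(cp50) = 1/2 defines the CP50
    (half-maximal cell penetration).  Accepts scalars or arrays; c >= 0.
    """
    if cp50 <= 0:
        raise ValueError("cp50 must be positive")
    if h <= 0:
        raise ValueError("Hill slope h must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / cp50) ** h, 0.0)
    theta = ratio / (1.0 + ratio)
    return float(theta) if theta.ndim == 0 else theta


def offtarget_response(theta, saturation: float):
    """Saturable off-target factor in [0, 1): theta / (theta + saturation).

    The dye excess grows with HaloTag occupancy theta, and off-target sites
    saturate with Michaelis-type constant ``saturation``.
    """
    theta = np.asarray(theta, dtype=float)
    out = theta / (theta + saturation)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


def field_rng(master_seed: int, well_id: str, field_index: int) -> np.random.Generator:
    """Deterministic per-field RNG stream derived from (seed, well, field)."""
    well_key = zlib.crc32(str(well_id).encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, well_key, int(field_index)])
    return np.random.default_rng(ss)


def _place_centroids(
    n: int, shape: tuple[int, int], cell_radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid placement with a margin that keeps whole cells in-field."""
    h, w = shape
    # keep whole cells clear of the border: segmented bodies (clipped at the
    # body_max_radius default, plus jitter) must never touch the field edge
    margin = cell_radius + 22.0
    n_side = int(np.ceil(np.sqrt(n)))
    if n_side < 2:
        n_side = 2
    ys = np.linspace(margin, h - margin, n_side)
    xs = np.linspace(margin, w - margin, n_side)
    spacing = min(ys[1] - ys[0], xs[1] - xs[0])
    if spacing < 1.2 * cell_radius:
        raise ValueError(
            f"cannot place {n} cells of radius {cell_radius} in a {h}x{w} field"
        )
    grid = np.array([(y, x) for y in ys for x in xs])
    idx = rng.choice(len(grid), size=n, replace=False)
    jitter = rng.uniform(-0.1 * spacing, 0.1 * spacing, size=(n, 2))
    return grid[idx] + jitter


def sample_population(
    config: SimulationConfig,
    mode: str,
    concentration: float,
    seed: int | np.random.Generator,
    n_cells: int | None = None,
    with_centroids: bool = True,
) -> list[GroundTruthCell]:
    """Draw the latent per-cell state for one field.

    Expression is log-normal with the configured median and CV; undamaged and
    damaged cells alike carry occupancy theta(concentration).  In transient
    mode each cell is assigned an expression class from ``transient_mix``:
    non-expressers get ~zero expression, over-expressers at least 10x the
    median.  The damage probability may ramp with concentration via
    ``p_damaged_slope`` (toxic transporter scenario).
    """
    if mode not in ("stable", "transient"):
        raise ValueError("mode must be 'stable' or 'transient'")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_cells_per_field if n_cells is None else int(n_cells)

    sigma = np.sqrt(np.log1p(config.expression_cv**2))
    mu = np.log(config.expression_median)
    expression = rng.lognormal(mean=mu, sigma=sigma, size=n)

    if mode == "transient":
        classes = rng.choice(
            np.array(["non", "normal", "over"]), size=n, p=list(config.transient_mix)
        )
        non = classes == "non"
        over = classes == "over"
        expression[non] *= 0.002  # untransfected: trace autofluorescence only
        expression[over] = np.maximum(expression[over] * 12.0, 10.0 * config.expression_median)
        kind = "golgi"
    else:
        classes = np.full(n, "normal")
        kind = "mitochondria"

    p_dam = min(1.0, config.p_damaged + config.p_damaged_slope * concentration)
    damaged = rng.random(n) < p_dam
    theta = occupancy_response(concentration, config.cp50_true, config.hill_true)

    if with_centroids:
        centroids = _place_centroids(n, config.field_size_px, config.cell_radius_px, rng)
    else:
        centroids = np.zeros((n, 2))

    return [
        GroundTruthCell(
            cell_id=i + 1,
            centroid_px=(float(centroids[i, 0]), float(centroids[i, 1])),
            expression=float(expression[i]),
            occupancy=float(theta),
            damaged=bool(damaged[i]),
            expr_class=str(classes[i]),
            organelle_kind=kind,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with unit median and the given CV."""
    return float(np.sqrt(np.log1p(cv**2)))


def _gaussian_blob(img: np.ndarray, center: tuple[float, float], sigma: float, amp: float) -> None:
    """Accumulate a 2-D Gaussian into ``img`` (in place), truncated at 4 sigma."""
    h, w = img.shape
    cy, cx = center
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def _disk_coords(center, radius, shape):
    h, w = shape
    cy, cx = center
    r = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return yy[inside], xx[inside]


_SOFT_EDGE_SIGMA = 4.0  # px; GFP fades over ~4 px at the membrane of a filled cell


def _soft_disk(center, radius, shape):
    """Filled disk with a Gaussian-fading rim (whole-body over-expresser fill).

    Returns (ys, xs, weight); weight is 1 inside ``radius`` and decays as a
    Gaussian beyond it, so the rendered cell edge fades the way a real
    cytosolic fill does instead of dropping to background in one pixel.
    """
    h, w = shape
    cy, cx = center
    r = int(np.ceil(radius + 3 * _SOFT_EDGE_SIGMA))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    keep = d <= radius + 3 * _SOFT_EDGE_SIGMA
    excess = np.maximum(d[keep] - radius, 0.0)
    weight = np.exp(-(excess**2) / (2 * _SOFT_EDGE_SIGMA**2))
    return yy[keep], xx[keep], weight


def _filament_texture(
    cell: GroundTruthCell,
    shape: tuple[int, int],
    cell_radius: float,
    nucleus_sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mitochondrial network: short random walks radiating across the body."""
    cy, cx = cell.centroid_px
    n_fil = 6
    steps = 45
    ang0 = rng.uniform(0, 2 * np.pi, size=(n_fil, 1))
    ang = ang0 + np.cumsum(rng.normal(0, 0.45, size=(n_fil, steps)), axis=1)
    r0 = nucleus_sigma * 1.6
    ys = cy + r0 * np.sin(ang0) + np.cumsum(1.1 * np.sin(ang), axis=1)
    xs = cx + r0 * np.cos(ang0) + np.cumsum(1.1 * np.cos(ang), axis=1)
    inside = (ys - cy) ** 2 + (xs - cx) ** 2 <= (cell_radius - 2) ** 2
    return _rasterise(ys[inside], xs[inside], shape, dilate=1)


def _speck_texture(cell, shape, cell_radius, rng):
    """Fragmented organelle of a damaged cell: many isolated small specks."""
    cy, cx = cell.centroid_px
    n_specks = 18
    r = rng.uniform(3, cell_radius - 3, n_specks)
    ang = rng.uniform(0, 2 * np.pi, n_specks)
    ys = cy + r * np.sin(ang)
    xs = cx + r * np.cos(ang)
    return _rasterise(ys, xs, shape, dilate=1)


def _golgi_texture(cell, shape, nucleus_sigma, rng):
    """Peri-nuclear punctate cluster on one side of the nucleus."""
    cy, cx = cell.centroid_px
    side = rng.uniform(0, 2 * np.pi)
    oy = cy + 2.4 * nucleus_sigma * np.sin(side)
    ox = cx + 2.4 * nucleus_sigma * np.cos(side)
    n_puncta = 10
    ys = oy + rng.normal(0, 4.0, n_puncta)
    xs = ox + rng.normal(0, 4.0, n_puncta)
    return _rasterise(ys, xs, shape, dilate=2)


def _rasterise(ys, xs, shape, dilate: int = 1):
    """Round float points to pixels and thicken by a square structuring element."""
    h, w = shape
    ys = np.clip(np.round(np.asarray(ys)).astype(int), 0, h - 1)
    xs = np.clip(np.round(np.asarray(xs)).astype(int), 0, w - 1)
    if dilate > 0:
        offs = np.arange(-dilate, dilate + 1)
        dy, dx = np.meshgrid(offs, offs, indexing="ij")
        ys = np.clip((ys[:, None] + dy.ravel()[None, :]).ravel(), 0, h - 1)
        xs = np.clip((xs[:, None] + dx.ravel()[None, :]).ravel(), 0, w - 1)
    return ys, xs


def _apply_camera(signal: np.ndarray, cam, rng: np.random.Generator) -> np.ndarray:
    out = signal.astype(float)
    if cam.poisson_scale > 0:
        out = cam.poisson_scale * rng.poisson(np.maximum(out, 0) / cam.poisson_scale)
    if cam.read_noise_sd > 0:
        out = out + rng.normal(0, cam.read_noise_sd, out.shape)
    out = out + cam.offset
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def render_field(
    cells: list[GroundTruthCell],
    config: SimulationConfig,
    seed: int | np.random.Generator,
    noise: bool = True,
    well_id: str = "",
    field_index: int = 0,
    offtarget_scale: float = 1.0,
) -> FieldImageSet:
    """Render the three channels for one field of simulated cells.

    Channel semantics: nuclear stain = Gaussian blobs at the centroids
    (condensed and brighter for damaged cells); GFP = organelle texture at
    amplitude ``gfp_gain * expression`` (whole-body fill for over-expressers,
    fragmented specks for damaged cells); reporter = specific amplitude
    ``reporter_gain * expression * (1 - occupancy)`` on the same texture plus
    off-target puncta strictly outside it.  With ``noise=False`` the camera
    model reduces to adding the constant offset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # off-target placement draws from its own substream so that the rendered
    # cell textures are bit-identical across offtarget_amplitude settings
    ot_rng = np.random.default_rng(rng.integers(2**63))
    shape = tuple(config.field_size_px)
    h, w = shape
    nuclear = np.zeros(shape)
    gfp = np.zeros(shape)
    reporter = np.zeros(shape)
    # off-target spots are rendered separately and clipped to zero on every
    # organelle texture pixel, so the specific signal on organelles is exact
    offtarget = np.zeros(shape)
    texture_union = np.zeros(shape, dtype=bool)

    for cell in cells:
        cy, cx = cell.centroid_px
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"cell {cell.cell_id} centroid outside the field")

        # nuclear channel: condensed + brighter when damaged
        nuc_amp = config.nuclear_amp * rng.lognormal(0.0, 0.12)
        if cell.damaged:
            _gaussian_blob(nuclear, (cy, cx), 0.55 * config.nucleus_sigma_px, 1.8 * nuc_amp)
        else:
            _gaussian_blob(nuclear, (cy, cx), config.nucleus_sigma_px, nuc_amp)

        # organelle texture
        weight = None
        if cell.expr_class == "over":
            ys, xs, weight = _soft_disk((cy, cx), config.cell_radius_px, shape)
        elif cell.damaged:
            ys, xs = _speck_texture(cell, shape, config.cell_radius_px, rng)
        elif cell.organelle_kind == "golgi":
            ys, xs = _golgi_texture(cell, shape, config.nucleus_sigma_px, rng)
        else:
            ys, xs = _filament_texture(
                cell, shape, config.cell_radius_px, config.nucleus_sigma_px, rng
            )

        gfp_amp = config.gfp_gain * cell.expression
        labeling = rng.lognormal(0.0, _lognormal_sigma(config.reporter_cv)) if noise else 1.0
        rep_amp = config.reporter_gain * cell.expression * (1.0 - cell.occupancy) * labeling
        if weight is None:
            gfp[ys, xs] = np.maximum(gfp[ys, xs], gfp_amp)
            reporter[ys, xs] = np.maximum(reporter[ys, xs], rep_amp)
        else:
            gfp[ys, xs] = np.maximum(gfp[ys, xs], gfp_amp * weight)
            reporter[ys, xs] = np.maximum(reporter[ys, xs], rep_amp * weight)
        texture_union[ys, xs] = True

        # off-target puncta: inside the body, strictly outside the organelle.
        # offtarget_amplitude is the fraction of the cell's maximal integrated
        # specific signal (reporter_gain * expression * organelle area) that
        # accumulates off-target at full dye excess; it is split over the
        # puncta as Gaussian spots.
        if config.offtarget_amplitude > 0 and config.offtarget_puncta_per_cell > 0:
            texture = set(zip(ys.tolist(), xs.tolist()))
            punct_sigma = 2.0
            ot_amp = (
                config.offtarget_amplitude
                * offtarget_scale
                * config.reporter_gain
                * cell.expression
                * len(texture)
                * offtarget_response(cell.occupancy, config.offtarget_saturation)
                / (config.offtarget_puncta_per_cell * 2 * np.pi * punct_sigma**2)
            )
            if ot_amp > 0:
                placed = 0
                attempts = 0
                while placed < config.offtarget_puncta_per_cell and attempts < 200:
                    attempts += 1
                    r = ot_rng.uniform(2, config.cell_radius_px - 2)
                    ang = ot_rng.uniform(0, 2 * np.pi)
                    py, px = cy + r * np.sin(ang), cx + r * np.cos(ang)
                    iy, ix = int(round(py)), int(round(px))
                    if not (0 <= iy < h and 0 <= ix < w):
                        continue
                    near = any(
                        (iy + dy, ix + dx) in texture
                        for dy in (-2, -1, 0, 1, 2)
                        for dx in (-2, -1, 0, 1, 2)
                    )
                    if near:
                        continue
                    _gaussian_blob(offtarget, (py, px), punct_sigma, ot_amp)
                    placed += 1

    offtarget[texture_union] = 0.0
    reporter += offtarget

    cam = config.camera
    if noise:
        channels = [_apply_camera(ch, cam, rng) for ch in (nuclear, gfp, reporter)]
    else:
        channels = [
            np.clip(np.round(ch + cam.offset), 0, 65535).astype(np.uint16)
            for ch in (nuclear, gfp, reporter)
        ]
    return FieldImageSet(
        nuclear=channels[0],
        gfp=channels[1],
        reporter=channels[2],
        pixel_size_um=config.pixel_size_um,
        well_id=well_id,
        field_index=field_index,
    )


# ---------------------------------------------------------------------------
# plate assembly
# ---------------------------------------------------------------------------


def cells_to_frame(cells: list[GroundTruthCell], well_id: str, field_index: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "well": well_id,
            "field": field_index,
            "x_px": [c.centroid_px[1] for c in cells],
            "y_px": [c.centroid_px[0] for c in cells],
            "expression": [c.expression for c in cells],
            "occupancy": [c.occupancy for c in cells],
            "damaged": [c.damaged for c in cells],
            "expr_class": [c.expr_class for c in cells],
        }
    )[GROUND_TRUTH_COLUMNS]


def build_plate(
    layout: PlateLayout,
    config: SimulationConfig,
    mode: str,
    seed: int,
    out_dir: str | Path,
    noise: bool = True,
) -> Path:
    """Simulate and write a full plate: one TIFF per field plus ground truth.

    Each field gets its own RNG stream derived from (master seed, well id,
    field index), so the plate is bit-reproducible and wells are independent
    of generation order.  Files: ``<well>_f<field>.tif`` (pages in the order
    nuclear, GFP, reporter), ``ground_truth.csv``, ``layout.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for well in layout.wells:
        # well-level staining variability (field index 0 is reserved for
        # per-well draws; real fields count from 1)
        well_rng = field_rng(seed, well.well_id, 0)
        ot_scale = (
            well_rng.lognormal(0.0, _lognormal_sigma(config.offtarget_well_cv))
            if (noise and config.offtarget_well_cv > 0)
            else 1.0
        )
        for f_idx in range(1, well.n_fields + 1):
            rng = field_rng(seed, well.well_id, f_idx)
            cells = sample_population(config, mode, well.concentration_um, rng)
            field = render_field(
                cells, config, rng, noise=noise, well_id=well.well_id,
                field_index=f_idx, offtarget_scale=ot_scale,
            )
            path = out_dir / f"{well.well_id}_f{f_idx}.tif"
            try:
                tifffile.imwrite(path, field.stack(), photometric="minisblack")
            except OSError as exc:
                raise OSError(f"failed writing field image {path}: {exc}") from exc
            frames.append(cells_to_frame(cells, well.well_id, f_idx))
    truth = pd.concat(frames, ignore_index=True)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    import yaml

    with open(out_dir / "layout.yaml", "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=True)
    return out_dir
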