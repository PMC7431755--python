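"""Plate-directory reading/writing and result round-trips.

A plate directory contains one multi-page 16-bit TIFF per field named
``<well>_f<field>.tif`` with pages in the fixed order (nuclear, GFP,
reporter), a ``layout.yaml`` describing wells, and optionally the
generator's ``ground_truth.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import PlateLayout
from .synthgen import CHANNEL_ORDER, FieldImageSet

__all__ = ["read_field", "read_plate", "write_masks", "write_json", "read_ground_truth"]


def read_field(path: str | Path, pixel_size_um: float = float("nan")) -> FieldImageSet:
    """Read one field TIFF, validating page count and bit depth."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(CHANNEL_ORDER):
        raise ValueError(
            f"{path}: expected {len(CHANNEL_ORDER)} pages "
            f"({', '.join(CHANNEL_ORDER)}), found {stack.shape[0]}"
        )
    if stack.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit pages, found dtype {stack.dtype}")
    well, _, fidx = path.stem.rpartition("_f")
    return FieldImageSet(
        nuclear=stack[0],
        gfp=stack[1],
        reporter=stack[2],
        pixel_size_um=pixel_size_um,
        well_id=well,
        field_index=int(fidx) if fidx.isdigit() else 0,
    )


def read_plate(path: str | Path, pixel_size_um: float = float("nan")):
    """Load a plate directory -> (layout, list of FieldImageSet).

    Every well in the layout must have all its field images on disk; errors
    name the offending well or file.
    """
    path = Path(path)
    layout_file = path / "layout.yaml"
    if not layout_file.exists():
        raise FileNotFoundError(f"layout file missing: {layout_file}")
    with open(layout_file) as fh:
        layout = PlateLayout.from_dict(yaml.safe_load(fh))
    fields = []
    for well in layout.wells:
        for f_idx in range(1, well.n_fields + 1):
            f_path = path / f"{well.well_id}_f{f_idx}.tif"
            if not f_path.exists():
                raise FileNotFoundError(
                    f"layout references well {well.well_id} field {f_idx} "
                    f"but {f_path} does not exist"
                )
            fields.append(read_field(f_path, pixel_size_um))
    return layout, fields


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    p = Path(path) / "ground_truth.csv" if Path(path).is_dir() else Path(path)
    return pd.read_csv(p)


def write_masks(masks, out_dir: str | Path, well_id: str, field_index: int) -> Path:
    """Write the label/boolean masks of one field as a 16-bit label TIFF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{well_id}_f{field_index}_masks.tif"
    stack = np.stack(
        [
            masks.nuclei_labels.astype(np.uint16),
            masks.cell_labels.astype(np.uint16),
            masks.organelle_mask.astype(np.uint16),
            masks.dark_mask.astype(np.uint16),
        ]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
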