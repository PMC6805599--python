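"""NIfTI, JSON and CSV plumbing.

Image stacks and label maps are stored as NIfTI-1 with a JSON sidecar next
to the file (same name, ``.json`` extension).  The sidecar is authoritative
for the grid (it carries the interslice gap and the LPS convention, which a
plain affine cannot); the affine encodes voxel spacing with the
center-to-center slice spacing as the axial step, in RAS+ world coordinates
(the in-plane axes are therefore negated relative to the package's LPS
voxel axes).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .image import Grid, ImageStack, LabelMap, Landmarks

__all__ = [
    "write_image", "read_image", "write_labelmap", "read_labelmap",
    "write_ground_truth", "read_ground_truth", "save_json", "load_json",
]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag([-grid.dx, -grid.dy, grid.slice_spacing, 1.0])
    aff[0, 3] = -grid.x0
    aff[1, 3] = -grid.y0
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, default=_json_default, allow_nan=True)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_image(stack: ImageStack, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data, _affine(stack.grid)), path)
    sidecar = {"grid": stack.grid.to_dict(), "kind": "image"}
    if stack.landmarks is not None:
        sidecar["landmarks"] = {"upper": stack.landmarks.upper,
                                "lower": stack.landmarks.lower,
                                "umbilicus": stack.landmarks.umbilicus}
    save_json(sidecar, _sidecar_path(path))
    return path


def read_image(path) -> ImageStack:
    path = Path(path)
    sidecar = load_json(_sidecar_path(path))
    grid = Grid.from_dict(sidecar["grid"])
    lm = sidecar.get("landmarks")
    landmarks = Landmarks(**lm) if lm else None
    data = np.asanyarray(nib.load(path).dataobj, dtype=np.float32)
    return ImageStack(data=data, grid=grid, landmarks=landmarks)


def write_labelmap(label_map: LabelMap, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(label_map.data.astype(np.uint8), _affine(label_map.grid)),
             path)
    save_json({"grid": label_map.grid.to_dict(), "kind": "labels",
               "provenance": label_map.provenance}, _sidecar_path(path))
    return path


def read_labelmap(path, expected_grid: Grid | None = None,
                  provenance: str | None = None) -> LabelMap:
    """Load a label map; validates grid agreement when ``expected_grid`` is
    given (import path for externally supplied masks)."""
    path = Path(path)
    sidecar = load_json(_sidecar_path(path))
    grid = Grid.from_dict(sidecar["grid"])
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(
            f"label-map grid {grid.to_dict()} does not match the image grid "
            f"{expected_grid.to_dict()}")
    data = np.asanyarray(nib.load(path).dataobj).astype(np.uint8)
    return LabelMap(data=data, grid=grid,
                    provenance=provenance or sidecar.get("provenance", "imported"))


def write_ground_truth(truth, path) -> Path:
    """Ground-truth volumes, median line and anchors as a JSON sidecar
    (the label volume itself is written separately as NIfTI)."""
    path = Path(path)
    save_json({
        "volumes": truth.volumes_dict(),
        "asat_left_frac": truth.asat_left_frac,
        "vat_left_frac": truth.vat_left_frac,
        "median_line_mm": truth.median_line_mm,
        "anchor_slice": truth.anchor_slice,
        "anchor_posterior_mm": list(truth.anchor_posterior_mm),
        "anchor_vertebra_mm": list(truth.anchor_vertebra_mm),
    }, path)
    return path


def read_ground_truth(path) -> dict:
    d = load_json(path)
    d["median_line_mm"] = np.asarray(d["median_line_mm"], dtype=float)
    return d
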