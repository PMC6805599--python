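"""Median-line construction and left/right splitting of label maps.

The median line is a straight sagittal plane per slice.  Its base lateral
position is the midpoint between two near-midline anatomical anchors (the
dorsal tip of the spinous process and the center of the corresponding
vertebral body, at the L4/L5 level); per-slice lateral offsets allow
correction for scoliotic deformation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import LabelMap

__all__ = ["MedianLine", "define_median_line", "split_mask", "median_line_from_truth"]


@dataclass
class MedianLine:
    """Per-slice sagittal split position.

    ``x0`` is the base lateral position (mm, patient coordinates);
    ``offsets`` holds one lateral correction per slice (mm, default 0);
    ``anchor`` is free text recording the anatomical rule used.
    """

    x0: float
    offsets: np.ndarray
    anchor: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.x0):
            raise ValueError("x0 must be finite")
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 1:
            raise ValueError("offsets must be one per slice")

    @property
    def n_slices(self) -> int:
        return self.offsets.size

    @property
    def positions(self) -> np.ndarray:
        """Lateral line position per slice (mm)."""
        return self.x0 + self.offsets

    def to_dict(self) -> dict:
        return {"x0": self.x0, "offsets": self.offsets.tolist(), "anchor": self.anchor}

    @classmethod
    def from_dict(cls, d: dict) -> "MedianLine":
        return cls(x0=d["x0"], offsets=np.asarray(d["offsets"], float),
                   anchor=d.get("anchor", ""))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MedianLine":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def define_median_line(posterior_point: tuple[float, float],
                       vertebra_center: tuple[float, float],
                       n_slices: int,
                       offsets: np.ndarray | None = None,
                       lateral_tolerance: float = 5.0,
                       anchor: str = "midpoint of spinous process and vertebral center (L4/L5 analog)",
                       ) -> MedianLine:
    """Median line anchored between the spinous process and vertebral center.

    Both anchor points are (x, y) positions in mm on the same slice.  The
    base position is the lateral midpoint of the two anchors; a warning is
    issued when they are laterally further apart than ``lateral_tolerance``
    (the rule expects near-midline anchors).
    """
    px, vx = float(posterior_point[0]), float(vertebra_center[0])
    if abs(px - vx) > lateral_tolerance:
        warnings.warn(
            f"median-line anchors are {abs(px - vx):.1f} mm apart laterally "
            f"(tolerance {lateral_tolerance} mm); expected near-midline anchors",
            UserWarning, stacklevel=2)
    if offsets is None:
        offsets = np.zeros(n_slices)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (n_slices,):
        raise ValueError(f"offsets must have length {n_slices}")
    return MedianLine(x0=(px + vx) / 2.0, offsets=offsets, anchor=anchor)


def median_line_from_truth(truth) -> MedianLine:
    """Median line from phantom ground truth via its stored anchor points."""
    return define_median_line(truth.anchor_posterior_mm, truth.anchor_vertebra_mm,
                              n_slices=truth.median_line_mm.size,
                              offsets=truth.median_offsets_mm,
                              anchor="phantom ground truth")


def split_mask(label_map: LabelMap, line: MedianLine) -> tuple[LabelMap, LabelMap]:
    """Split a label map into left and right halves at the median line.

    A voxel belongs to the left half iff its center's lateral coordinate is
    greater than the line position on its slice; centers exactly on the line
    go left (fixed tie-break).  Left and right counts sum exactly to the
    input counts for every label.
    """
    grid = label_map.grid
    if line.n_slices != grid.shape[2]:
        raise ValueError(
            f"line defines {line.n_slices} slices, label map has {grid.shape[2]}")
    x = grid.x_coords
    left_side = x[:, None, None] >= line.positions[None, None, :]
    left = np.where(left_side, label_map.data, 0).astype(np.uint8)
    right = np.where(left_side, 0, label_map.data).astype(np.uint8)
    return (LabelMap(data=left, grid=grid, provenance=label_map.provenance),
            LabelMap(data=right, grid=grid, provenance=label_map.provenance))
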