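"""Fat segmentation and SAT/VAT compartmentalisation on transverse slices.

The operators reconstruct, deterministically, the compartment logic of
interactive outer/inner-contour reading: fat voxels geodesically connected
to the body boundary form the subcutaneous ring, everything inside the
remaining abdominal-cavity region is visceral fat.  All morphology is
slice-wise 2-D with 4-connectivity in-plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .image import SAT, VAT, Grid, ImageStack, LabelMap

__all__ = [
    "ThresholdMethod",
    "segment_fat",
    "otsu_threshold",
    "compute_body_mask",
    "separate_sat_vat",
    "side_completeness",
    "SideCompleteness",
]

#: 4-connected in-plane structuring element
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class ThresholdMethod:
    """Fat-threshold choice: global Otsu (default) or a fixed intensity."""

    mode: str = "otsu"
    value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "otsu"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed":
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("fixed threshold requires a finite value")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of the stack histogram (``nbins`` bins over the
    observed intensity range), maximising between-class variance.

    The returned threshold is the upper edge of the last bin of the lower
    class, so ``intensity >= threshold`` selects exactly the upper class.
    When several splits tie (the between-class variance is flat across empty
    bins between well-separated intensity levels), the middle split is taken,
    placing the threshold mid-gap rather than against one of the peaks.
    """
    values = np.asarray(values)
    if values.min() == values.max():
        raise ValueError("degenerate histogram: image is constant")
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float) / hist.sum()
    omega0 = np.cumsum(w)[:-1]
    mu0 = np.cumsum(w * centers)[:-1]
    mu_total = float(np.sum(w * centers))
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_total * omega0 - mu0) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    best = sigma_b.max()
    ties = np.flatnonzero(np.isclose(sigma_b, best, rtol=1e-12, atol=0.0))
    split = int(ties[len(ties) // 2])
    return float(edges[split + 1])


def segment_fat(stack: ImageStack, method: ThresholdMethod = ThresholdMethod()) -> np.ndarray:
    """Binary fat mask: true exactly where intensity >= threshold."""
    if method.mode == "fixed":
        thr = method.value
    else:
        thr = otsu_threshold(stack.data)
    return stack.data >= thr


def compute_body_mask(stack: ImageStack, background_threshold: float | None = None) -> np.ndarray:
    """Per slice: largest 4-connected component of above-background voxels,
    with interior holes filled.

    When no background threshold is given, the lower threshold of a
    three-class Otsu split (background / lean / fat) is used; a two-class
    Otsu is the fallback for two-level images.  Empty slices stay empty.
    """
    if background_threshold is None:
        data = stack.data
        if data.min() == data.max():
            return np.zeros(stack.grid.shape, dtype=bool)
        try:
            background_threshold = float(filters.threshold_multiotsu(data, classes=3)[0])
        except ValueError:  # fewer than 3 distinguishable levels
            background_threshold = otsu_threshold(data)
    body = np.zeros(stack.grid.shape, dtype=bool)
    for z in range(stack.grid.shape[2]):
        above = stack.data[:, :, z] >= background_threshold
        if not above.any():
            continue
        lab = measure.label(above, connectivity=1)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        body[:, :, z] = ndimage.binary_fill_holes(lab == largest)
    return body


def separate_sat_vat(fat_mask: np.ndarray, body_mask: np.ndarray, grid: Grid,
                     closing_radius: int = 3,
                     provenance: str = "automatic") -> LabelMap:
    """Assign fat voxels to SAT vs VAT slice-by-slice.

    Per slice: fat components (4-connected) touching the body boundary are
    the subcutaneous candidates; the abdominal cavity is the body region
    left after removing them, morphologically closed (disk of
    ``closing_radius`` voxels, bridging thin muscle-wall gaps in noisy
    images) and hole-filled.  VAT is fat inside the cavity, SAT is all other
    fat, so the two labels are disjoint and exhaust the fat mask.
    """
    fat_mask = np.asarray(fat_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if fat_mask.shape != body_mask.shape or fat_mask.shape != grid.shape:
        raise ValueError("fat mask, body mask and grid shapes must agree")
    n_outside = int(np.count_nonzero(fat_mask & ~body_mask))
    if n_outside:
        raise ValueError(
            f"fat mask not contained in body mask: {n_outside} voxels outside")
    labels = np.zeros(grid.shape, dtype=np.uint8)
    disk = morphology.disk(closing_radius) if closing_radius > 0 else None
    for z in range(grid.shape[2]):
        fat = fat_mask[:, :, z]
        body = body_mask[:, :, z]
        if not fat.any():
            continue
        boundary = body & ~ndimage.binary_erosion(body, structure=_CROSS,
                                                  border_value=0)
        comp = measure.label(fat, connectivity=1)
        touching = np.unique(comp[boundary & fat])
        sat_conn = np.isin(comp, touching[touching > 0])
        cavity = body & ~sat_conn
        if disk is not None and cavity.any():
            cavity = ndimage.binary_closing(cavity, structure=disk)
        cavity = ndimage.binary_fill_holes(cavity) & ~sat_conn
        vat = fat & cavity
        sat = fat & ~cavity
        labels[:, :, z][sat] = SAT
        labels[:, :, z][vat] = VAT
    return LabelMap(data=labels, grid=grid, provenance=provenance)


class SideCompleteness(NamedTuple):
    left_complete: bool
    right_complete: bool


def side_completeness(label_map: LabelMap) -> SideCompleteness:
    """Flag body sides whose subcutaneous fat may be cut by the lateral FOV.

    A side is incomplete iff any SAT voxel lies on that side's lateral grid
    border on any slice.  With LPS orientation the last lateral index is the
    patient's left.
    """
    sat = label_map.mask(SAT)
    left_border_hit = bool(sat[-1, :, :].any())
    right_border_hit = bool(sat[0, :, :].any())
    return SideCompleteness(left_complete=not left_border_hit,
                            right_complete=not right_border_hit)
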