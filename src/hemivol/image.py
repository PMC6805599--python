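"""In-memory containers for fat-selective MR image stacks and label maps.

Conventions
-----------
Arrays are indexed ``[x, y, z]``:

* axis 0 — lateral, in patient-based LPS coordinates (increasing index =
  increasing x = patient's **left**),
* axis 1 — antero-posterior (increasing index = posterior),
* axis 2 — transverse slice (axial position).

Physical in-plane coordinates are voxel-center coordinates in millimetres.
Axial positions are slice centers separated by the center-to-center slice
spacing (slice thickness + interslice gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label values used throughout the package.
BACKGROUND = 0
SAT = 1  # (abdominal) subcutaneous adipose tissue
VAT = 2  # visceral adipose tissue

VALID_LABELS = frozenset({BACKGROUND, SAT, VAT})


@dataclass(frozen=True)
class Grid:
    """Voxel geometry shared by an image stack and any label map derived from it.

    Parameters
    ----------
    shape : (nx, ny, nz)
        Matrix size in voxels.
    dx, dy : float
        In-plane voxel spacing in mm.
    slice_thickness : float
        Acquired slice thickness in mm.
    slice_gap : float
        Unimaged interslice gap in mm; center-to-center spacing is
        ``slice_thickness + slice_gap``.
    x0, y0 : float, optional
        Physical coordinate (mm) of the center of voxel (0, 0).  Defaults
        place the grid symmetrically around the isocenter.
    orientation : str
        Patient-based axis convention; only ``"LPS"`` is supported.
    """

    shape: tuple[int, int, int]
    dx: float
    dy: float
    slice_thickness: float = 10.0
    slice_gap: float = 0.5
    x0: float | None = None
    y0: float | None = None
    orientation: str = "LPS"

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if min(nx, ny, nz) < 1:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("in-plane spacings must be strictly positive")
        if self.slice_thickness <= 0 or self.slice_gap < 0:
            raise ValueError("slice thickness must be > 0 and gap >= 0")
        if self.orientation != "LPS":
            raise ValueError(f"unsupported orientation {self.orientation!r}")
        if self.x0 is None:
            object.__setattr__(self, "x0", -(nx - 1) / 2.0 * self.dx)
        if self.y0 is None:
            object.__setattr__(self, "y0", -(ny - 1) / 2.0 * self.dy)

    @property
    def slice_spacing(self) -> float:
        """Center-to-center axial step in mm (thickness + gap)."""
        return self.slice_thickness + self.slice_gap

    def axial_step(self, spacing_mode: str = "center") -> float:
        """Axial extent attributed to one slice, in mm.

        ``"center"`` uses the center-to-center spacing (default, 10.5 mm for
        10 mm slices with a 0.5 mm gap, i.e. the gap is attributed to the
        adjacent slice); ``"thickness"`` uses the slice thickness only.
        """
        if spacing_mode == "center":
            return self.slice_spacing
        if spacing_mode == "thickness":
            return self.slice_thickness
        raise ValueError(f"unknown spacing mode {spacing_mode!r}")

    def voxel_volume_cm3(self, spacing_mode: str = "center") -> float:
        return self.dx * self.dy * self.axial_step(spacing_mode) / 1000.0

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + np.arange(self.shape[0]) * self.dx

    @property
    def y_coords(self) -> np.ndarray:
        return self.y0 + np.arange(self.shape[1]) * self.dy

    @property
    def z_coords(self) -> np.ndarray:
        return np.arange(self.shape[2]) * self.slice_spacing

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "dx": self.dx,
            "dy": self.dy,
            "slice_thickness": self.slice_thickness,
            "slice_gap": self.slice_gap,
            "x0": self.x0,
            "y0": self.y0,
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(
            shape=tuple(d["shape"]),
            dx=d["dx"],
            dy=d["dy"],
            slice_thickness=d["slice_thickness"],
            slice_gap=d["slice_gap"],
            x0=d.get("x0"),
            y0=d.get("y0"),
            orientation=d.get("orientation", "LPS"),
        )


@dataclass(frozen=True)
class Landmarks:
    """Anatomical slice indices bounding the analysed abdominal region.

    ``upper`` is the fixed cranial landmark (vertebra-T9 analog), ``lower``
    the caudal bound (pelvic-floor analog); ``umbilicus`` anchors relative
    slice numbering in per-slice profiles.  These are metadata, not detected
    anatomy.
    """

    upper: int
    lower: int
    umbilicus: int

    def validate(self, n_slices: int) -> None:
        for name, idx in (("upper", self.upper), ("lower", self.lower),
                          ("umbilicus", self.umbilicus)):
            if not 0 <= idx < n_slices:
                raise ValueError(
                    f"landmark {name}={idx} outside slice range [0, {n_slices})")
        if self.upper > self.lower:
            raise ValueError(
                f"upper landmark {self.upper} below lower landmark {self.lower}")


@dataclass
class ImageStack:
    """A 3-D fat-signal volume (fat appears bright) with voxel geometry."""

    data: np.ndarray
    grid: Grid
    landmarks: Landmarks | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.landmarks is not None:
            self.landmarks.validate(self.grid.shape[2])

    @property
    def n_slices(self) -> int:
        return self.grid.shape[2]


@dataclass
class LabelMap:
    """Per-voxel compartment labels (0 background, 1 SAT, 2 VAT).

    ``provenance`` records how the labels were obtained: ``"automatic"``
    (produced by this package's operators), ``"imported"`` (externally
    supplied masks) or ``"ground-truth"`` (phantom construction).
    """

    data: np.ndarray
    grid: Grid
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"label shape {self.data.shape} != grid shape {self.grid.shape}")
        present = set(np.unique(self.data).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"invalid label values {sorted(present - VALID_LABELS)}")
        if self.provenance not in ("automatic", "imported", "ground-truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def counts(self) -> dict[int, int]:
        binc = np.bincount(self.data.ravel(), minlength=3)
        return {BACKGROUND: int(binc[0]), SAT: int(binc[1]), VAT: int(binc[2])}
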