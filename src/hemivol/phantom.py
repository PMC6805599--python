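"""Synthetic abdominal fat-image phantoms with exactly known compartments.

Each transverse slice is modelled as two nested ellipses: the outer ellipse
is the skin contour, the inner ellipse the abdominal muscle wall.  The ring
between them is subcutaneous fat (SAT); visceral fat (VAT) is a union of
random ellipsoidal blobs placed inside the abdominal cavity with a lean
safety margin to the wall.  Lateral asymmetry of SAT is controlled by a
lateral offset of the inner ellipse, VAT asymmetry by side-specific voxel
budgets.  Ground-truth volumes are exact voxel counts times the voxel
volume, so every downstream stage can be tested without external data.

Two calibrations make the phantom hit requested volumes:

* the outer ellipse is scaled by the smallest factor for which the voxelised
  SAT ring reaches the target ASAT volume (monotone in the target);
* VAT blobs are added per body side until the side's voxel budget is met,
  the last blob being trimmed from its rim inward, so left and right VAT
  ground truth equal their budgets to the voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import refdata
from .image import SAT, VAT, Grid, ImageStack, LabelMap, Landmarks

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "GroupParams",
    "CohortSubject",
    "generate_subject_phantom",
    "generate_cohort",
    "crop_fov",
    "inner_offset_for_left_fraction",
    "cohort_table_from_parameters",
    "study_cohort_spec",
]


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Volume targets are in cm^3; all lengths in mm.  ``asat_target=None``
    uses the ellipse geometry exactly as given (no outer-ellipse scaling),
    which is the mode analytic-geometry oracles rely on.
    """

    nx: int = 128
    ny: int = 128
    dx: float = 3.5
    dy: float = 3.5
    n_slices: int = 50
    slice_thickness: float = 10.0
    slice_gap: float = 0.5
    #: per-slice outer/inner ellipse semi-axes, shape (n_slices, 2) [mm]
    outer_semiaxes: np.ndarray = None
    inner_semiaxes: np.ndarray = None
    #: lateral offset of the inner ellipse (mm, + = patient left);
    #: controls ASAT left/right asymmetry
    inner_offset: float = 0.0
    asat_target: float | None = None
    vat_target: float = 0.0
    vat_left_fraction: float = 0.5
    #: uniform ranges for blob semi-axes [mm]
    vat_blob_inplane: tuple[float, float] = (15.0, 40.0)
    vat_blob_axial: tuple[float, float] = (12.0, 30.0)
    #: lean margin between cavity wall and any VAT blob [mm]
    vat_margin: float = 10.0
    #: per-slice lateral offset of the whole body (scoliosis analog) [mm]
    scoliosis: np.ndarray = None
    fat_level: float = 1000.0
    lean_level: float = 100.0
    #: additive Gaussian noise, default 3% of the default fat-lean gap
    noise_sd: float = 30.0
    seed: int = 0
    landmark_upper: int = 0
    landmark_lower: int | None = None
    umbilicus: int | None = None
    #: slice carrying the median-line anchor points (L4/L5 analog)
    anchor_slice: int | None = None

    def __post_init__(self) -> None:
        n = self.n_slices
        if n < 1 or self.nx < 1 or self.ny < 1:
            raise ValueError("matrix size and slice count must be positive")
        if self.dx <= 0 or self.dy <= 0 or self.slice_thickness <= 0 or self.slice_gap < 0:
            raise ValueError("spacings must be strictly positive (gap >= 0)")
        if self.outer_semiaxes is None or self.inner_semiaxes is None:
            raise ValueError("outer and inner semi-axes are required "
                             "(use PhantomSpec.default to build a profile)")
        self.outer_semiaxes = _as_semiaxes(self.outer_semiaxes, n, "outer")
        self.inner_semiaxes = _as_semiaxes(self.inner_semiaxes, n, "inner")
        if self.scoliosis is None:
            self.scoliosis = np.zeros(n)
        self.scoliosis = np.asarray(self.scoliosis, dtype=float)
        if self.scoliosis.shape != (n,):
            raise ValueError(f"scoliosis offsets must have length {n}")
        if self.fat_level <= self.lean_level:
            raise ValueError("fat intensity must exceed lean intensity")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not 0.0 <= self.vat_left_fraction <= 1.0:
            raise ValueError("vat_left_fraction must lie in [0, 1]")
        if self.vat_target < 0:
            raise ValueError("vat_target must be >= 0")
        if self.landmark_lower is None:
            self.landmark_lower = n - 1
        if self.umbilicus is None:
            self.umbilicus = n // 2
        if self.anchor_slice is None:
            self.anchor_slice = max(0, min(n - 1, self.umbilicus - 3))
        self.landmarks.validate(n)
        if not 0 <= self.anchor_slice < n:
            raise ValueError(f"anchor slice {self.anchor_slice} out of range")

    @property
    def landmarks(self) -> Landmarks:
        return Landmarks(upper=self.landmark_upper, lower=self.landmark_lower,
                         umbilicus=self.umbilicus)

    @property
    def grid(self) -> Grid:
        return Grid(shape=(self.nx, self.ny, self.n_slices), dx=self.dx, dy=self.dy,
                    slice_thickness=self.slice_thickness, slice_gap=self.slice_gap)

    @classmethod
    def default(cls, *, outer: tuple[float, float] = (190.0, 130.0),
                inner: tuple[float, float] = (115.0, 80.0),
                taper: float = 0.10, **overrides) -> "PhantomSpec":
        """Build a spec with a smooth axial taper of the trunk cross-section.

        The semi-axes of both ellipses are scaled per slice by
        ``1 - taper * u**2`` with ``u`` in [-1, 1], peaking at the umbilicus
        slice, which mimics the waist being widest near the umbilicus.
        """
        n = overrides.get("n_slices", cls.n_slices)
        umb = overrides.get("umbilicus") or n // 2
        z = np.arange(n)
        u = 2.0 * (z - umb) / max(n, 2)
        profile = 1.0 - taper * u ** 2
        overrides.setdefault("outer_semiaxes", np.outer(profile, np.asarray(outer, float)))
        overrides.setdefault("inner_semiaxes", np.outer(profile, np.asarray(inner, float)))
        return cls(**overrides)


def _as_semiaxes(arr, n_slices: int, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape == (2,):
        arr = np.tile(arr, (n_slices, 1))
    if arr.shape != (n_slices, 2):
        raise ValueError(f"{name} semi-axes must have shape ({n_slices}, 2)")
    if not np.all(arr > 0):
        raise ValueError(f"{name} semi-axes must be strictly positive")
    return arr


@dataclass
class GroundTruth:
    """Exact labels, volumes and median-line positions of one phantom.

    Volumes are voxel counts times the voxel volume (in-plane spacing times
    center-to-center slice spacing); totals are stored as ``left + right``
    so the conservation identity holds with zero tolerance.
    """

    labels: LabelMap
    asat_left: float
    asat_right: float
    vat_left: float
    vat_right: float
    #: lateral position of the true median line per slice [mm]
    median_line_mm: np.ndarray
    anchor_slice: int
    anchor_posterior_mm: tuple[float, float]
    anchor_vertebra_mm: tuple[float, float]

    def __post_init__(self) -> None:
        for v in (self.asat_left, self.asat_right, self.vat_left, self.vat_right):
            if v < 0:
                raise ValueError("ground-truth volumes must be >= 0")

    @property
    def asat_total(self) -> float:
        return self.asat_left + self.asat_right

    @property
    def vat_total(self) -> float:
        return self.vat_left + self.vat_right

    @property
    def asat_left_frac(self) -> float:
        return self.asat_left / self.asat_total if self.asat_total > 0 else float("nan")

    @property
    def vat_left_frac(self) -> float:
        return self.vat_left / self.vat_total if self.vat_total > 0 else float("nan")

    @property
    def median_offsets_mm(self) -> np.ndarray:
        """Per-slice lateral offsets relative to the anchor slice."""
        return self.median_line_mm - self.median_line_mm[self.anchor_slice]

    def volumes_dict(self) -> dict[str, float]:
        return {
            "asat_total": self.asat_total, "asat_left": self.asat_left,
            "asat_right": self.asat_right, "vat_total": self.vat_total,
            "vat_left": self.vat_left, "vat_right": self.vat_right,
        }


# --------------------------------------------------------------------------
# single-subject generation
# --------------------------------------------------------------------------

def _min_containing_scale(spec: PhantomSpec, n_theta: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Per slice, the smallest outer-ellipse scale containing the offset
    inner ellipse, and the largest scale keeping the body inside the grid."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    ao, bo = spec.outer_semiaxes[:, 0], spec.outer_semiaxes[:, 1]
    ai, bi = spec.inner_semiaxes[:, 0], spec.inner_semiaxes[:, 1]
    # inner boundary points relative to the outer-ellipse center
    x = spec.inner_offset + ai[:, None] * cos_t  # (nz, n_theta)
    y = bi[:, None] * sin_t
    s_min = np.sqrt((x / ao[:, None]) ** 2 + (y / bo[:, None]) ** 2).max(axis=1)
    grid = spec.grid
    x_half = min(-grid.x_coords[0], grid.x_coords[-1]) - spec.dx
    y_half = min(-grid.y_coords[0], grid.y_coords[-1]) - spec.dy
    s_max = np.minimum((x_half - np.abs(spec.scoliosis)) / ao, y_half / bo)
    return s_min, s_max


def _calibrate_outer_scale(r_out2: np.ndarray, inner: np.ndarray,
                           target_mm3: float, vox_mm3: float,
                           s_lo: float, s_hi: float) -> float:
    """Smallest outer scale whose voxelised SAT ring reaches ``target_mm3``.

    The ring voxel count is a non-decreasing step function of the scale, so
    bisection on the scale keeps the realised volume monotone in the target.
    """
    def ring_mm3(s: float) -> float:
        return np.count_nonzero((r_out2 <= s * s) & ~inner) * vox_mm3

    if ring_mm3(s_lo) > target_mm3:
        raise ValueError(
            f"target ASAT {target_mm3 / 1000.0:.0f} cm^3 below the minimum "
            f"feasible ring volume {ring_mm3(s_lo) / 1000.0:.0f} cm^3")
    if ring_mm3(s_hi) < target_mm3:
        raise ValueError(
            f"target ASAT {target_mm3 / 1000.0:.0f} cm^3 exceeds the ring "
            f"capacity {ring_mm3(s_hi) / 1000.0:.0f} cm^3 of the grid")
    lo, hi = s_lo, s_hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if ring_mm3(mid) >= target_mm3:
            hi = mid
        else:
            lo = mid
    return hi


def _fill_vat_side(allowed: np.ndarray, k_target: int, rng: np.random.Generator,
                   spec: PhantomSpec, side: str) -> np.ndarray:
    """Union of random ellipsoidal blobs covering exactly ``k_target`` voxels
    of the ``allowed`` region (one body side of the margin-eroded cavity)."""
    filled = np.zeros(allowed.shape, dtype=bool)
    if k_target == 0:
        return filled
    capacity = int(np.count_nonzero(allowed))
    vox_cm3 = spec.grid.voxel_volume_cm3()
    if k_target > capacity:
        raise ValueError(
            f"target VAT for the {side} side ({k_target * vox_cm3:.0f} cm^3) "
            f"exceeds the cavity capacity ({capacity * vox_cm3:.0f} cm^3)")
    centers = np.flatnonzero(allowed)
    grid = spec.grid
    xs, ys, zs = grid.x_coords, grid.y_coords, grid.z_coords
    step = grid.slice_spacing
    count = 0
    for _ in range(20000):
        if count >= k_target:
            break
        ci = centers[rng.integers(centers.size)]
        cxi, cyi, czi = np.unravel_index(ci, allowed.shape)
        cx, cy, cz = xs[cxi], ys[cyi], zs[czi]
        ax = rng.uniform(*spec.vat_blob_inplane)
        ay = rng.uniform(*spec.vat_blob_inplane)
        az = rng.uniform(*spec.vat_blob_axial)
        ix0 = max(0, int(np.ceil((cx - ax - grid.x0) / spec.dx)))
        ix1 = min(allowed.shape[0], int(np.floor((cx + ax - grid.x0) / spec.dx)) + 1)
        iy0 = max(0, int(np.ceil((cy - ay - grid.y0) / spec.dy)))
        iy1 = min(allowed.shape[1], int(np.floor((cy + ay - grid.y0) / spec.dy)) + 1)
        iz0 = max(0, int(np.ceil((cz - az) / step)))
        iz1 = min(allowed.shape[2], int(np.floor((cz + az) / step)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        rho2 = (((xs[ix0:ix1, None, None] - cx) / ax) ** 2
                + ((ys[None, iy0:iy1, None] - cy) / ay) ** 2
                + ((zs[None, None, iz0:iz1] - cz) / az) ** 2)
        win_filled = filled[ix0:ix1, iy0:iy1, iz0:iz1]
        new = (rho2 <= 1.0) & allowed[ix0:ix1, iy0:iy1, iz0:iz1] & ~win_filled
        n_new = int(np.count_nonzero(new))
        if n_new == 0:
            continue
        if count + n_new > k_target:
            # trim the blob from its rim inward to land exactly on target
            need = k_target - count
            flat = np.flatnonzero(new.ravel())
            order = np.argsort(rho2.ravel()[flat], kind="stable")
            keep = flat[order[:need]]
            trimmed = np.zeros(new.size, dtype=bool)
            trimmed[keep] = True
            new = trimmed.reshape(new.shape)
            n_new = need
        win_filled |= new
        count += n_new
    else:
        raise RuntimeError(
            f"could not place the requested VAT volume on the {side} side "
            f"({count}/{k_target} voxels filled); cavity too fragmented")
    return filled


def generate_subject_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate one phantom image stack and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises ``ValueError`` when the
    geometry is infeasible (inner ellipse not strictly inside the outer one
    on some slice, body exceeding the grid, or volume targets outside the
    feasible range).
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    X = grid.x_coords[:, None, None]
    Y = grid.y_coords[None, :, None]
    cx = spec.scoliosis[None, None, :]
    ao = spec.outer_semiaxes[:, 0][None, None, :]
    bo = spec.outer_semiaxes[:, 1][None, None, :]
    ai = spec.inner_semiaxes[:, 0][None, None, :]
    bi = spec.inner_semiaxes[:, 1][None, None, :]

    r_out2 = ((X - cx) / ao) ** 2 + (Y / bo) ** 2
    inner = ((X - cx - spec.inner_offset) / ai) ** 2 + (Y / bi) ** 2 <= 1.0

    s_min, s_max = _min_containing_scale(spec)
    s_lo = float(s_min.max()) * (1.0 + 1e-9)
    s_hi = float(s_max.min())
    if s_hi <= s_lo:
        z = int(np.argmax(s_min / s_max))
        raise ValueError(
            f"infeasible geometry on slice {z}: the offset inner ellipse "
            f"cannot fit strictly inside an outer ellipse within the grid")
    vox_mm3 = spec.dx * spec.dy * grid.slice_spacing
    if spec.asat_target is None:
        s = 1.0
        bad = np.flatnonzero(s_min >= 1.0)
        if bad.size:
            raise ValueError(
                f"inner ellipse not strictly inside the outer ellipse on "
                f"slice {int(bad[0])}")
        if np.any(s_max < 1.0):
            z = int(np.argmin(s_max))
            raise ValueError(f"body exceeds the image grid on slice {z}")
    else:
        s = _calibrate_outer_scale(r_out2, inner, spec.asat_target * 1000.0,
                                   vox_mm3, s_lo, s_hi)

    body = r_out2 <= s * s
    sat = body & ~inner

    # true median line follows the body center (scoliosis analog)
    left = (X - cx) >= 0.0

    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[sat] = SAT
    if spec.vat_target > 0:
        am = spec.inner_semiaxes[:, 0] - spec.vat_margin
        bm = spec.inner_semiaxes[:, 1] - spec.vat_margin
        if np.any(am <= 0) or np.any(bm <= 0):
            z = int(np.argmin(np.minimum(am, bm)))
            raise ValueError(
                f"VAT margin {spec.vat_margin} mm leaves no cavity on slice {z}")
        allowed = (((X - cx - spec.inner_offset) / am[None, None, :]) ** 2
                   + (Y / bm[None, None, :]) ** 2) <= 1.0
        target_mm3 = spec.vat_target * 1000.0
        k_left = int(round(spec.vat_left_fraction * target_mm3 / vox_mm3))
        k_right = int(round((1.0 - spec.vat_left_fraction) * target_mm3 / vox_mm3))
        vat_l = _fill_vat_side(allowed & left, k_left, rng, spec, "left")
        vat_r = _fill_vat_side(allowed & ~left, k_right, rng, spec, "right")
        labels[vat_l | vat_r] = VAT

    img = np.zeros(grid.shape, dtype=np.float64)
    img[body] = spec.lean_level
    img[labels > 0] = spec.fat_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=grid.shape)

    stack = ImageStack(data=img.astype(np.float32), grid=grid,
                       landmarks=spec.landmarks)

    vox_cm3 = vox_mm3 / 1000.0
    sat_lab = labels == SAT
    vat_lab = labels == VAT
    a = spec.anchor_slice
    bi_a = spec.inner_semiaxes[a, 1]
    bo_a = spec.outer_semiaxes[a, 1] * s
    x_a = float(spec.scoliosis[a])
    truth = GroundTruth(
        labels=LabelMap(data=labels, grid=grid, provenance="ground-truth"),
        asat_left=float(np.count_nonzero(sat_lab & left)) * vox_cm3,
        asat_right=float(np.count_nonzero(sat_lab & ~left)) * vox_cm3,
        vat_left=float(np.count_nonzero(vat_lab & left)) * vox_cm3,
        vat_right=float(np.count_nonzero(vat_lab & ~left)) * vox_cm3,
        median_line_mm=spec.scoliosis.copy(),
        anchor_slice=a,
        # spinous-process analog (dorsal, just inside the skin) and
        # vertebral-center analog, both on the body midline
        anchor_posterior_mm=(x_a, 0.5 * (bi_a + bo_a)),
        anchor_vertebra_mm=(x_a, 0.6 * bi_a),
    )
    return stack, truth


def crop_fov(stack: ImageStack, fov_width: float, lateral_offset: float = 0.0) -> ImageStack:
    """Restrict the stack laterally to a field-of-view window.

    Emulates a scanner whose FOV (typically 50-55 cm) is narrower than the
    patient: voxels whose centers fall outside
    ``[lateral_offset - fov_width/2, lateral_offset + fov_width/2]`` are
    removed and the grid origin is updated so physical coordinates of the
    remaining voxels are preserved.
    """
    if fov_width <= 0:
        raise ValueError("fov_width must be > 0")
    x = stack.grid.x_coords
    keep = (x >= lateral_offset - fov_width / 2.0) & (x <= lateral_offset + fov_width / 2.0)
    if not keep.any():
        raise ValueError("FOV window lies entirely outside the image grid")
    i0 = int(np.argmax(keep))
    i1 = len(keep) - int(np.argmax(keep[::-1]))
    g = stack.grid
    new_grid = Grid(shape=(i1 - i0, g.shape[1], g.shape[2]), dx=g.dx, dy=g.dy,
                    slice_thickness=g.slice_thickness, slice_gap=g.slice_gap,
                    x0=float(x[i0]), y0=g.y0, orientation=g.orientation)
    return ImageStack(data=stack.data[i0:i1].copy(), grid=new_grid,
                      landmarks=stack.landmarks)


# --------------------------------------------------------------------------
# ASAT asymmetry calibration
# --------------------------------------------------------------------------

def _ellipse_tail_fraction(t: np.ndarray) -> np.ndarray:
    """Fraction of an ellipse's area with normalised abscissa >= t."""
    t = np.clip(t, -1.0, 1.0)
    return (np.arccos(t) - t * np.sqrt(1.0 - t * t)) / np.pi


def inner_offset_for_left_fraction(spec: PhantomSpec, target_frac: float) -> float:
    """Inner-ellipse lateral offset producing a requested left-ASAT fraction.

    Uses the closed-form areas of the ellipse ring: the left SAT area on a
    slice is half the outer-ellipse area minus the part of the inner ellipse
    left of the midline.  The outer scale implied by ``asat_target`` is
    accounted for analytically; the voxelised fraction matches to a few
    tenths of a percent at default resolution.
    """
    ao, bo = spec.outer_semiaxes[:, 0], spec.outer_semiaxes[:, 1]
    ai, bi = spec.inner_semiaxes[:, 0], spec.inner_semiaxes[:, 1]
    a_out = np.pi * ao * bo
    a_in = np.pi * ai * bi
    if spec.asat_target is None:
        s2 = 1.0
    else:
        step = spec.slice_thickness + spec.slice_gap
        s2 = (spec.asat_target * 1000.0 / step + a_in.sum()) / a_out.sum()
    ring = s2 * a_out.sum() - a_in.sum()
    if ring <= 0:
        raise ValueError("ring area non-positive; ASAT target infeasible")

    def frac_minus_target(d: float) -> float:
        left = s2 * a_out / 2.0 - a_in * _ellipse_tail_fraction(-d / ai)
        return left.sum() / ring - target_frac

    d_max = 0.8 * float(ai.min())
    lo, hi = -d_max, d_max
    if frac_minus_target(lo) < 0 or frac_minus_target(hi) > 0:
        raise ValueError(
            f"left-ASAT fraction {target_frac} not achievable with this geometry")
    return float(optimize.brentq(frac_minus_target, lo, hi, xtol=1e-10))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Group-specific sampling ranges (e.g. per gender)."""

    label: str
    asat_range: tuple[float, float]
    vat_range: tuple[float, float]
    asat_left_frac: tuple[float, float, float, float] = refdata.ASAT_LEFT_FRACTION
    vat_left_frac: tuple[float, float, float, float] = refdata.VAT_LEFT_FRACTION


@dataclass
class CohortSpec:
    """Sampling distributions for a synthetic cohort.

    Totals are drawn uniformly from ``asat_range``/``vat_range`` (cm^3);
    left-side fractions from truncated normals ``(mean, sd, lower, upper)``.
    Defaults emulate the development cohort (see :mod:`hemivol.refdata`).
    When ``groups`` are given, subjects are split as evenly as possible over
    the groups, each sampled from its own ranges.
    """

    n_subjects: int = 26
    asat_range: tuple[float, float] = refdata.REFERENCE_RANGES["asat"]
    vat_range: tuple[float, float] = refdata.REFERENCE_RANGES["vat"]
    asat_left_frac: tuple[float, float, float, float] = refdata.ASAT_LEFT_FRACTION
    vat_left_frac: tuple[float, float, float, float] = refdata.VAT_LEFT_FRACTION
    groups: tuple[GroupParams, ...] | None = None
    #: uniform range of per-subject scoliosis sinusoid amplitude [mm]
    scoliosis_amplitude: tuple[float, float] = (0.0, 4.0)
    seed: int = 0
    base_spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for name, rng_ in (("asat_range", self.asat_range), ("vat_range", self.vat_range)):
            if not rng_[0] < rng_[1]:
                raise ValueError(f"{name} must satisfy low < high")
        for name, fr in (("asat_left_frac", self.asat_left_frac),
                         ("vat_left_frac", self.vat_left_frac)):
            mean, sd, lo, hi = fr
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(f"{name} truncation bounds must lie in (0, 1)")
            if sd <= 0:
                raise ValueError(f"{name} sd must be > 0")

    def _group_of(self, i: int) -> GroupParams | None:
        if not self.groups:
            return None
        g = len(self.groups)
        base, extra = divmod(self.n_subjects, g)
        bounds = np.cumsum([base + (1 if j < extra else 0) for j in range(g)])
        return self.groups[int(np.searchsorted(bounds, i, side="right"))]

    def sample_parameters(self, seed: int | None = None) -> "pd.DataFrame":
        """Draw per-subject targets (no images) as a data frame.

        Columns: subject_id, group, seed, asat_total, vat_total,
        asat_left_frac, vat_left_frac, scoliosis_amp, scoliosis_phase.
        Per-subject seeds are spawned reproducibly from the master seed.
        """
        import pandas as pd

        master = self.seed if seed is None else seed
        rng = np.random.default_rng(master)
        child = np.random.SeedSequence(master).generate_state(max(self.n_subjects, 1))
        child = (child.astype(np.int64) % (2 ** 31)).astype(np.int64)
        rows = []
        for i in range(self.n_subjects):
            gp = self._group_of(i)
            asat_rng = gp.asat_range if gp else self.asat_range
            vat_rng = gp.vat_range if gp else self.vat_range
            af = gp.asat_left_frac if gp else self.asat_left_frac
            vf = gp.vat_left_frac if gp else self.vat_left_frac
            rows.append({
                "subject_id": f"sub-{i + 1:03d}",
                "group": gp.label if gp else "",
                "seed": int(child[i]),
                "asat_total": rng.uniform(*asat_rng),
                "vat_total": rng.uniform(*vat_rng),
                "asat_left_frac": _truncated_normal(af, rng),
                "vat_left_frac": _truncated_normal(vf, rng),
                "scoliosis_amp": rng.uniform(*self.scoliosis_amplitude),
                "scoliosis_phase": rng.uniform(0.0, 2.0 * np.pi),
            })
        cols = ["subject_id", "group", "seed", "asat_total", "vat_total",
                "asat_left_frac", "vat_left_frac", "scoliosis_amp", "scoliosis_phase"]
        return pd.DataFrame(rows, columns=cols)


def _truncated_normal(params: tuple[float, float, float, float],
                      rng: np.random.Generator) -> float:
    mean, sd, lo, hi = params
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    spec: PhantomSpec
    image: ImageStack
    truth: GroundTruth


def generate_cohort(cohort: CohortSpec) -> list[CohortSubject]:
    """Generate a cohort of phantoms from sampled per-subject targets."""
    params = cohort.sample_parameters()
    base = cohort.base_spec if cohort.base_spec is not None else PhantomSpec.default()
    subjects: list[CohortSubject] = []
    z = np.arange(base.n_slices)
    for row in params.itertuples(index=False):
        scoliosis = row.scoliosis_amp * np.sin(
            2.0 * np.pi * z / max(base.n_slices, 2) + row.scoliosis_phase)
        spec = dataclasses.replace(
            base,
            outer_semiaxes=base.outer_semiaxes.copy(),
            inner_semiaxes=base.inner_semiaxes.copy(),
            asat_target=float(row.asat_total),
            vat_target=float(row.vat_total),
            vat_left_fraction=float(row.vat_left_frac),
            scoliosis=scoliosis,
            seed=int(row.seed),
        )
        spec.inner_offset = inner_offset_for_left_fraction(spec, float(row.asat_left_frac))
        stack, truth = generate_subject_phantom(spec)
        subjects.append(CohortSubject(subject_id=row.subject_id, group=row.group,
                                      spec=spec, image=stack, truth=truth))
    return subjects


def cohort_table_from_parameters(params: "pd.DataFrame") -> "pd.DataFrame":
    """Build a volumes-only cohort table directly from sampled targets.

    ``side = fraction x total`` algebraically, bypassing image synthesis;
    this is the volumes-level route used when the statistics are exercised
    without imaging.
    """
    import pandas as pd

    out = pd.DataFrame({
        "subject_id": params["subject_id"],
        "group": params.get("group", ""),
        "asat_total": params["asat_total"],
        "asat_left": params["asat_left_frac"] * params["asat_total"],
        "vat_total": params["vat_total"],
        "vat_left": params["vat_left_frac"] * params["vat_total"],
    })
    out["asat_right"] = out["asat_total"] - out["asat_left"]
    out["vat_right"] = out["vat_total"] - out["vat_left"]
    cols = ["subject_id", "group", "asat_total", "asat_left", "asat_right",
            "vat_total", "vat_left", "vat_right"]
    return out[cols]


def study_cohort_spec(n_subjects: int = 26, seed: int = 0,
                      base_spec: PhantomSpec | None = None) -> CohortSpec:
    """Cohort spec emulating the development population: equal female/male
    groups with gender-specific reference-volume ranges."""
    gm = refdata.GROUP_MEANS
    groups = (
        GroupParams(label="female", asat_range=(10672.0, 24161.0),
                    vat_range=(1137.0, 4174.0)),
        GroupParams(label="male", asat_range=(7812.0, 16349.0),
                    vat_range=(3282.0, 7513.0)),
    )
    assert set(gm) == {"female", "male"}
    return CohortSpec(n_subjects=n_subjects, groups=groups, seed=seed,
                      base_spec=base_spec)
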