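"""Stage composition: phantom cohort -> segmentation -> split -> volumes -> stats.

Each stage reads the artifacts of the previous one from a pipeline directory
(one subdirectory per subject), so the command-line interface stays a thin
wrapper and every intermediate remains inspectable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .image import ImageStack, LabelMap
from .midline import MedianLine, define_median_line, split_mask
from .phantom import CohortSpec, GroupParams, PhantomSpec, generate_cohort
from .segmentation import (ThresholdMethod, compute_body_mask, segment_fat,
                           separate_sat_vat, side_completeness)
from .stats import run_validation
from .volumetry import compartment_volumes, slice_profiles

__all__ = [
    "cohort_spec_from_config", "load_cohort_config",
    "generate_stage", "segment_stage", "split_stage",
    "volumes_stage", "validate_stage", "process_subject",
]

MANIFEST = "manifest.csv"
VOLUMES_CSV = "volumes.csv"
PROFILES_CSV = "slice_profiles.csv"
REPORT_JSON = "report.json"
PER_SUBJECT_CSV = "per_subject.csv"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def cohort_spec_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain configuration dictionary."""
    cfg = dict(cfg)
    phantom_cfg = dict(cfg.pop("phantom", {}))
    base_spec = None
    if phantom_cfg:
        outer = tuple(phantom_cfg.pop("outer", (190.0, 130.0)))
        inner = tuple(phantom_cfg.pop("inner", (115.0, 80.0)))
        taper = phantom_cfg.pop("taper", 0.10)
        base_spec = PhantomSpec.default(outer=outer, inner=inner, taper=taper,
                                        **phantom_cfg)
    groups = cfg.pop("groups", None)
    if groups is not None:
        groups = tuple(
            GroupParams(label=g["label"],
                        asat_range=tuple(g["asat_range"]),
                        vat_range=tuple(g["vat_range"]),
                        asat_left_frac=tuple(g.get("asat_left_frac",
                                                   CohortSpec.asat_left_frac)),
                        vat_left_frac=tuple(g.get("vat_left_frac",
                                                  CohortSpec.vat_left_frac)))
            for g in groups)
    for key in ("asat_range", "vat_range", "asat_left_frac", "vat_left_frac",
                "scoliosis_amplitude"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    spec = CohortSpec(base_spec=base_spec, groups=groups, **cfg)
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    return spec


def load_cohort_config(path, seed: int | None = None) -> CohortSpec:
    return cohort_spec_from_config(hio.load_json(path), seed=seed)


def demo_config_path() -> Path:
    """Bundled 6-subject demo cohort configuration."""
    from importlib.resources import files

    return Path(str(files("hemivol").joinpath("data/demo_cohort.json")))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _subject_dirs(data_dir: Path) -> list[Path]:
    dirs = sorted(p for p in Path(data_dir).iterdir()
                  if p.is_dir() and p.name.startswith("sub-"))
    if not dirs:
        raise FileNotFoundError(f"no subject directories under {data_dir}")
    return dirs


def generate_stage(cohort: CohortSpec, out_dir) -> pd.DataFrame:
    """Generate a phantom cohort and write images, ground truth and the
    cohort manifest under ``out_dir``. Returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in generate_cohort(cohort):
        sdir = out_dir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        hio.write_image(subj.image, sdir / "image.nii")
        hio.write_labelmap(subj.truth.labels, sdir / "truth_labels.nii")
        hio.write_ground_truth(subj.truth, sdir / "truth.json")
        rows.append({"subject_id": subj.subject_id, "group": subj.group,
                     "seed": subj.spec.seed, **subj.truth.volumes_dict()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / MANIFEST, index=False)
    return manifest


def segment_stage(data_dir, threshold: ThresholdMethod = ThresholdMethod(),
                  closing_radius: int = 3,
                  background_threshold: float | None = None) -> None:
    """Segment every subject image into a SAT/VAT label map (labels.nii).

    Fat voxels are intersected with the body mask before
    compartmentalisation so that rare noise outliers outside the body do not
    abort the run.
    """
    for sdir in _subject_dirs(data_dir):
        stack = hio.read_image(sdir / "image.nii")
        fat = segment_fat(stack, threshold)
        body = compute_body_mask(stack, background_threshold)
        labels = separate_sat_vat(fat & body, body, stack.grid,
                                  closing_radius=closing_radius)
        hio.write_labelmap(labels, sdir / "labels.nii")


def split_stage(data_dir, line: MedianLine | None = None,
                midline_from_ground_truth: bool = True) -> None:
    """Split each subject's label map at the median line (left.nii/right.nii).

    With ``midline_from_ground_truth`` the line is rebuilt per subject from
    the phantom's stored anchor points and scoliosis offsets; otherwise a
    single explicit :class:`MedianLine` is applied to all subjects.
    """
    if line is None and not midline_from_ground_truth:
        raise ValueError("either supply a median line or use the ground truth")
    for sdir in _subject_dirs(data_dir):
        labels = hio.read_labelmap(sdir / "labels.nii")
        if midline_from_ground_truth and line is None:
            truth = hio.read_ground_truth(sdir / "truth.json")
            subj_line = define_median_line(
                truth["anchor_posterior_mm"], truth["anchor_vertebra_mm"],
                n_slices=labels.grid.shape[2],
                offsets=truth["median_line_mm"] - truth["median_line_mm"][truth["anchor_slice"]],
                anchor="phantom ground truth")
        else:
            subj_line = line
        left, right = split_mask(labels, subj_line)
        subj_line.save(sdir / "median_line.json")
        hio.write_labelmap(left, sdir / "left.nii")
        hio.write_labelmap(right, sdir / "right.nii")


def volumes_stage(data_dir, spacing_mode: str = "center",
                  write_profiles: bool = True) -> pd.DataFrame:
    """Landmark-bounded volumes (and slice profiles) for every subject.

    Writes ``volumes.csv`` (one row per subject with all six volumes, left
    fractions and FOV-completeness flags) and a long-format
    ``slice_profiles.csv``.
    """
    data_dir = Path(data_dir)
    rows = []
    profiles = []
    for sdir in _subject_dirs(data_dir):
        stack_meta = hio.load_json(sdir / "image.json")
        lm = stack_meta.get("landmarks") or {}
        labels = hio.read_labelmap(sdir / "labels.nii")
        left = hio.read_labelmap(sdir / "left.nii")
        right = hio.read_labelmap(sdir / "right.nii")
        slice_range = (lm["upper"], lm["lower"]) if lm else None
        vols = compartment_volumes(left, right, slice_range=slice_range,
                                   spacing_mode=spacing_mode)
        complete = side_completeness(labels)
        row = {"subject_id": sdir.name, **vols.to_dict()}
        del row["slice_range"]
        row["slice_upper"], row["slice_lower"] = vols.slice_range
        row["left_complete"] = complete.left_complete
        row["right_complete"] = complete.right_complete
        rows.append(row)
        if write_profiles and lm:
            prof = slice_profiles(left, right, umbilicus_index=lm["umbilicus"],
                                  spacing_mode=spacing_mode)
            prof.insert(0, "subject_id", sdir.name)
            profiles.append(prof)
    volumes = pd.DataFrame(rows)
    volumes.to_csv(data_dir / VOLUMES_CSV, index=False)
    if profiles:
        pd.concat(profiles, ignore_index=True).to_csv(data_dir / PROFILES_CSV,
                                                      index=False)
    return volumes


def validate_stage(volumes: pd.DataFrame, out_dir, group_by: pd.Series | None = None,
                   equal_var: bool = True) -> dict:
    """Run the conversion/agreement statistics on a volumes table and write
    ``report.json`` and ``per_subject.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = volumes.copy()
    if group_by is not None:
        table["group"] = np.asarray(group_by)
    report, per_subject = run_validation(table, equal_var=equal_var)
    hio.save_json(report, out_dir / REPORT_JSON)
    per_subject.to_csv(out_dir / PER_SUBJECT_CSV, index=False)
    return report


def process_subject(stack: ImageStack, line: MedianLine,
                    labels: LabelMap | None = None,
                    threshold: ThresholdMethod = ThresholdMethod(),
                    closing_radius: int = 3,
                    spacing_mode: str = "center"):
    """In-memory single-subject pipeline (segment -> split -> volumes).

    ``labels`` may be supplied (imported or ground-truth masks) to skip the
    automatic segmentation.  Returns (CompartmentVolumes, SideCompleteness,
    LabelMap).
    """
    if labels is None:
        fat = segment_fat(stack, threshold)
        body = compute_body_mask(stack)
        labels = separate_sat_vat(fat & body, body, stack.grid,
                                  closing_radius=closing_radius)
    left, right = split_mask(labels, line)
    slice_range = None
    if stack.landmarks is not None:
        slice_range = (stack.landmarks.upper, stack.landmarks.lower)
    vols = compartment_volumes(left, right, slice_range=slice_range,
                               spacing_mode=spacing_mode)
    return vols, side_completeness(labels), labels
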