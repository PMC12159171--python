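"""File adapters: NIfTI-1 volumes, FSL-dialect gradient tables, cohort CSV.

Gradient files follow the FSL convention: ``bvals`` is one whitespace-
separated row, ``bvecs`` three rows (x, y, z components). Label masks are
written as uint8 NIfTI-1; all volumes share the source affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import IOValidationError
from .tensor import DWIVolume, GradientTable, TensorField

COHORT_REQUIRED_COLUMNS = (
    "subject_id", "group", "age", "sex", "bmi", "ahi", "odi", "plmi",
    "arousal_index", "tst", "sl", "se", "wake", "n1", "n2", "n3", "r",
)
_PERCENT_COLUMNS = ("se", "wake", "n1", "n2", "n3", "r")
_NONNEG_COLUMNS = ("ahi", "odi", "plmi", "arousal_index", "tst", "sl")
_STAGE_COLUMNS = ("wake", "n1", "n2", "n3", "r")


# --------------------------------------------------------------------------
# NIfTI volumes
# --------------------------------------------------------------------------

def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
               dtype=None) -> None:
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path):
    """Returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_tensor_field(field: TensorField, out_dir, affine=None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(field.components, out_dir / "tensor.nii.gz", affine)
    save_nifti(field.s0, out_dir / "s0.nii.gz", affine)
    save_nifti(field.mask, out_dir / "mask.nii.gz", affine)


def load_tensor_field(in_dir) -> TensorField:
    in_dir = Path(in_dir)
    comps, _ = load_nifti(in_dir / "tensor.nii.gz")
    s0, _ = load_nifti(in_dir / "s0.nii.gz")
    mask, _ = load_nifti(in_dir / "mask.nii.gz")
    return TensorField(components=comps, s0=s0, mask=mask.astype(bool))


# --------------------------------------------------------------------------
# gradient tables
# --------------------------------------------------------------------------

def write_bvals_bvecs(gradients: GradientTable, bvals_path, bvecs_path) -> None:
    np.savetxt(str(bvals_path), gradients.b_values[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), gradients.directions.T, fmt="%.10f")


def read_bvals_bvecs(bvals_path, bvecs_path,
                     for_fitting: bool = True) -> GradientTable:
    bvals = np.loadtxt(str(bvals_path)).ravel()
    bvecs = np.atleast_2d(np.loadtxt(str(bvecs_path)))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous; FSL dialect stores axes in rows, assume that
    if bvecs.shape != (bvals.size, 3):
        raise IOValidationError(
            f"bvecs shape {bvecs.shape} incompatible with {bvals.size} b-values")
    dwi = bvals > 0
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
    if bad.size:
        col = int(np.flatnonzero(dwi)[bad[0]])
        raise IOValidationError(
            f"non-unit gradient direction in bvecs column {col}")
    table = GradientTable(b_values=bvals, directions=bvecs)
    table.validate(for_fitting=for_fitting)
    return table


def write_dwi(dwi: DWIVolume, out_dir, stem: str = "dwi") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_nifti(dwi.signal, out_dir / f"{stem}.nii.gz", dwi.affine)
    write_bvals_bvecs(dwi.gradients, out_dir / f"{stem}.bval",
                      out_dir / f"{stem}.bvec")


def load_dwi(nii_path, bvals_path, bvecs_path) -> DWIVolume:
    data, affine = load_nifti(nii_path)
    if data.ndim != 4:
        raise IOValidationError(f"expected 4D DWI, got shape {data.shape}")
    if np.any(data < 0):
        raise IOValidationError("negative signal values in DWI volume")
    table = read_bvals_bvecs(bvals_path, bvecs_path)
    voxel = float(np.abs(affine[0, 0])) or 1.0
    return DWIVolume(signal=data, gradients=table, voxel_size=voxel,
                     affine=affine)


def write_labels(labels: dict, out_dir, affine=None) -> None:
    """Labels dict {hemi: {kind: mask}} -> one uint8 mask file each."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for hemi, kinds in labels.items():
        for kind, mask in kinds.items():
            save_nifti(mask, out_dir / f"label_{hemi}_{kind}.nii.gz",
                       affine, dtype=np.uint8)


def load_labels(in_dir) -> dict:
    in_dir = Path(in_dir)
    out: dict = {}
    for path in sorted(in_dir.glob("label_*_*.nii.gz")):
        _, hemi, kind = path.name.replace(".nii.gz", "").split("_")
        data, _ = load_nifti(path)
        out.setdefault(hemi, {})[kind] = data.astype(bool)
    if not out:
        raise IOValidationError(f"no label_*_*.nii.gz files under {in_dir}")
    return out


# --------------------------------------------------------------------------
# cohort CSV
# --------------------------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path, require_alps: bool = False):
    """Validated cohort read; returns (DataFrame, warnings).

    Hard failures (missing columns, out-of-range percentages, negative
    event indices) raise; stage ratios not summing to 100 produce a warning
    naming the subject.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise IOValidationError(f"cohort CSV missing columns: {missing}")
    if require_alps and "alps" not in df.columns and "alps_true" not in df.columns:
        raise IOValidationError("cohort CSV has neither 'alps' nor 'alps_true'")
    warnings = []
    for col in _PERCENT_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise IOValidationError(f"column {col!r} outside [0, 100]")
    for col in _NONNEG_COLUMNS:
        if (df[col].dropna() < 0).any():
            raise IOValidationError(f"column {col!r} has negative values")
    stage_sum = df[list(_STAGE_COLUMNS)].sum(axis=1)
    off = np.abs(stage_sum - 100.0) > 1e-6
    for sid in df.loc[off, "subject_id"]:
        warnings.append(f"subject {sid}: sleep-stage ratios do not sum to 100")
    if "alps" not in df.columns and "alps_true" in df.columns:
        df["alps"] = df["alps_true"]
    return df, warnings
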