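"""Reading and writing lesion volumes, manifests and feature tables.

Volumes are NIfTI (.nii/.nii.gz) via nibabel; arrays are (z, y, x) with the
voxel spacing on the affine diagonal in the same axis order.  Feature
tables are CSV with mandatory columns ``patient_id, lesion_id, site_label``
followed by feature columns named as in the 107-entry catalog (unknown
names are kept with a warning, so externally extracted extras survive a
round trip).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .catalog import catalog
from .errors import GeometryError, NonBinaryMaskError, SchemaError
from .heterogeneity import META_COLUMNS
from .synthetic import LesionCase, PatientCase

__all__ = [
    "write_volume",
    "read_case",
    "write_cohort",
    "read_manifest",
    "write_feature_table",
    "read_feature_table",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([*[float(s) for s in spacing], 1.0])


def write_volume(path, array, spacing) -> None:
    """Write a scalar or binary volume as NIfTI (masks as uint8 {0,1})."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))


def read_case(image_path, mask_path):
    """Load an image+mask pair, validating geometry and mask binarity.

    Returns ``(image, mask, spacing)`` with the mask as bool.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if not np.allclose(img.affine, msk.affine, atol=1e-4):
        raise GeometryError(
            f"image/mask affines disagree: {image_path} vs {mask_path}"
        )
    image = np.asarray(img.dataobj, dtype=np.float64)
    mask_arr = np.asarray(msk.dataobj)
    values = np.unique(mask_arr)
    if not np.all(np.isin(values, (0, 1))):
        raise NonBinaryMaskError(f"mask {mask_path} has values {values[:10]}")
    if image.shape != mask_arr.shape:
        raise GeometryError("image and mask shapes differ")
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    return image, mask_arr.astype(bool), spacing


def write_cohort(patients: list[PatientCase], out_dir) -> Path:
    """Write every lesion's image+mask as NIfTI plus a manifest CSV.

    Manifest columns: patient_id, lesion_id, site_label, mask_path,
    image_path (paths relative to the manifest).  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        for lesion in patient.lesions:
            img_name = f"{lesion.lesion_id}_image.nii.gz"
            msk_name = f"{lesion.lesion_id}_mask.nii.gz"
            write_volume(out / img_name, lesion.image, lesion.spacing)
            write_volume(out / msk_name, lesion.mask, lesion.spacing)
            rows.append({
                "patient_id": patient.patient_id,
                "lesion_id": lesion.lesion_id,
                "site_label": lesion.site_label,
                "mask_path": msk_name,
                "image_path": img_name,
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path) -> list[PatientCase]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "lesion_id", "site_label", "mask_path", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    patients: dict[str, PatientCase] = {}
    for _, row in df.iterrows():
        image, mask, spacing = read_case(base / row["image_path"],
                                         base / row["mask_path"])
        case = LesionCase(mask=mask, image=image, spacing=spacing,
                          patient_id=row["patient_id"],
                          lesion_id=row["lesion_id"],
                          site_label=row["site_label"])
        patients.setdefault(row["patient_id"],
                            PatientCase(row["patient_id"], [])).lesions.append(case)
    return list(patients.values())


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a lesions x features CSV, validating schema and feature names.

    Feature names outside the 107-entry catalog warn but are retained;
    non-numeric feature cells are a schema error.
    """
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    known = set(catalog().names())
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        if col not in known:
            warnings.warn(f"feature {col!r} not in the 107-feature catalog",
                          stacklevel=2)
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise SchemaError(f"non-numeric values in feature column {col!r}")
        df[col] = coerced
    return df
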