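"""Reading and writing volumes, masks, and cohort manifests.

NIfTI is the native on-disk format (one file per modality per subject, one
binary file per structure mask).  DICOM series import is supported for
clinical CT/MR exports; geometry consistency across the series is checked.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import PairedCase, StructureMaskSet, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "write_case",
    "read_case",
    "write_cohort",
    "read_cohort",
]


def _default_domain(modality: str) -> str:
    return "HU" if modality in ("CT", "SCT") else "arbitrary"


def read_volume(path: os.PathLike, format: str = "NIfTI", modality: str = "MR",
                intensity_domain: Optional[str] = None) -> VoxelVolume:
    """Load a volume from a NIfTI file or a DICOM series directory.

    Spacing is taken from the header.  CT volumes default to the HU
    intensity domain, MR to arbitrary units.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    domain = intensity_domain or _default_domain(modality)
    if format == "NIfTI":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3-D NIfTI, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return VoxelVolume(data, spacing_mm=spacing, modality=modality,
                           intensity_domain=domain)
    if format == "DICOM-series":
        return _read_dicom_series(path, modality=modality, intensity_domain=domain)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_series(directory: Path, modality: str, intensity_domain: str) -> VoxelVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    if not files:
        raise IOError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    try:
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    except AttributeError as exc:
        raise ValueError(f"{directory}: DICOM series lacks ImagePositionPatient") from exc

    rows, cols = slices[0].Rows, slices[0].Columns
    px = [float(v) for v in slices[0].PixelSpacing]
    for d in slices[1:]:
        if (d.Rows, d.Columns) != (rows, cols):
            raise ValueError(f"{directory}: inconsistent in-plane matrix across series")
        if [float(v) for v in d.PixelSpacing] != px:
            raise ValueError(f"{directory}: inconsistent pixel spacing across series")
    zs = [float(d.ImagePositionPatient[2]) for d in slices]
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise ValueError(f"{directory}: non-uniform slice spacing")
    slice_gap = float(abs(dz[0])) if len(dz) else float(
        getattr(slices[0], "SliceThickness", 1.0))

    planes = []
    for d in slices:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is (row, col) = (y, x); our convention is (x, y, z)
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    spacing = (px[1], px[0], slice_gap)
    return VoxelVolume(data, spacing_mm=spacing, modality=modality,
                       intensity_domain=intensity_domain)


def write_volume(v: VoxelVolume, path: os.PathLike) -> Path:
    """Write a volume as NIfTI with a diagonal affine built from its spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(v.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float64), affine), str(path))
    return path


def write_mask(mask: np.ndarray, spacing_mm: Sequence[float], path: os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    return path


def read_mask(path: os.PathLike) -> np.ndarray:
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj)
    if not np.isin(data, (0, 1)).all():
        raise ValueError(f"{path}: mask is not binary")
    return data.astype(bool)


def masks_from_label_volume(labels: np.ndarray,
                            name_map: Dict[int, str]) -> StructureMaskSet:
    """Split an integer label volume into named binary masks.

    ``name_map`` maps label values to structure names; label 0 is
    background unless explicitly named.
    """
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist()) - {0}
    unnamed = present - set(name_map)
    if unnamed:
        raise ValueError(f"label volume contains unnamed labels: {sorted(unnamed)}")
    return StructureMaskSet({name: labels == value
                             for value, name in name_map.items()})


# ---------------------------------------------------------------------------
# whole cases and cohorts
# ---------------------------------------------------------------------------

def write_case(case: PairedCase, out_dir: os.PathLike) -> Dict[str, str]:
    """Persist one paired case; returns the file map used by the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = case.subject_id
    files = {
        "mr": str(write_volume(case.mr, out / f"{sid}_mr.nii.gz")),
        "ct": str(write_volume(case.ct, out / f"{sid}_ct.nii.gz")),
    }
    for name, m in case.masks.masks.items():
        files[f"mask_{name}"] = str(
            write_mask(m, case.mr.spacing_mm, out / f"{sid}_mask_{name}.nii.gz"))
    return files


def read_case(subject_id: str, files: Dict[str, str]) -> PairedCase:
    mr = read_volume(files["mr"], modality="MR")
    ct = read_volume(files["ct"], modality="CT")
    masks = {
        key[len("mask_"):]: read_mask(p)
        for key, p in files.items() if key.startswith("mask_")
    }
    return PairedCase(subject_id=subject_id, mr=mr, ct=ct,
                      masks=StructureMaskSet(masks))


def write_cohort(cases: Iterable[PairedCase], out_dir: os.PathLike) -> Path:
    """Write every case plus a plain-text manifest table; returns its path."""
    out = Path(out_dir)
    rows = []
    for case in cases:
        files = write_case(case, out)
        row = {"subject_id": case.subject_id, "n_slices": case.n_slices}
        row.update(files)
        rows.append(row)
    manifest = out / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: os.PathLike) -> List[PairedCase]:
    df = pd.read_csv(manifest_path)
    cases = []
    for _, row in df.iterrows():
        files = {k: row[k] for k in df.columns if k not in ("subject_id", "n_slices")}
        cases.append(read_case(str(row["subject_id"]), files))
    return cases
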