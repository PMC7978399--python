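"""In-memory containers for image volumes and the preprocessing they undergo.

Conventions used throughout the package:

* volumes are 3-D arrays with axes ``(x, y, z)`` where ``x`` is the
  left-right axis, ``y`` the antero-posterior axis, and ``z`` indexes
  transverse slices;
* indices are 0-based;
* CT intensities are Hounsfield Units (HU), MR intensities are in
  arbitrary scanner units, and network inputs/targets live on a
  ``[0, 1]`` normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "IntensityScale",
    "StructureMaskSet",
    "PairedCase",
    "PairedSlice",
    "STRUCTURE_NAMES",
    "normalize_to_unit",
    "denormalize",
    "compute_air_mask",
    "flip_lr",
    "extract_slices",
    "stack_slices",
]

#: The contoured structures every paired case is expected to carry, plus the
#: body outline.  GTV = gross tumor volume.
STRUCTURE_NAMES = ("GTV", "femur_R", "femur_L", "bladder", "anorectum", "body")

_MODALITIES = ("MR", "CT", "SCT")
_DOMAINS = ("HU", "normalized", "arbitrary")


@dataclass
class VoxelVolume:
    """A scalar image volume with voxel spacing and intensity bookkeeping.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities; must be finite.
    spacing_mm : tuple of float
        Voxel edge lengths in millimetres, strictly positive.
    modality : {"MR", "CT", "SCT"}
        SCT marks a synthetic CT produced by the generator.
    intensity_domain : {"HU", "normalized", "arbitrary"}
        "normalized" asserts all values lie in [0, 1].
    """

    data: np.ndarray
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "MR"
    intensity_domain: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.intensity_domain not in _DOMAINS:
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")
        if self.intensity_domain == "normalized":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"normalized volume has values outside [0, 1]: [{lo}, {hi}]"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **changes) -> "VoxelVolume":
        """Copy of this volume with new voxel data (and optional field changes)."""
        return replace(self, data=data, **changes)


@dataclass(frozen=True)
class IntensityScale:
    """An affine intensity window ``[lo, hi]`` mapped onto ``[0, 1]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError(f"require hi > lo, got ({self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo


class StructureMaskSet:
    """Named binary masks sharing one voxel grid."""

    def __init__(self, masks: Dict[str, np.ndarray]):
        self.masks: Dict[str, np.ndarray] = {}
        shape = None
        for name, m in masks.items():
            m = np.asarray(m)
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"mask {name!r} is not binary")
            m = m.astype(bool)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} != reference grid {shape}"
                )
            self.masks[name] = m
        self.shape = shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> List[str]:
        return list(self.masks)

    def structures(self) -> List[str]:
        """Contoured structures, excluding the body outline."""
        return [n for n in self.masks if n != "body"]


@dataclass
class PairedCase:
    """One subject's co-registered MR and CT with its structure masks.

    ``tissue_labels`` is optional provenance carried by simulated cases: an
    integer volume giving the generating tissue class of every voxel, which
    enables exact ground-truth checks that clinical data cannot offer.
    """

    subject_id: str
    mr: VoxelVolume
    ct: VoxelVolume
    masks: StructureMaskSet
    tissue_labels: Optional[np.ndarray] = None
    tissue_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.mr.shape != self.ct.shape:
            raise ValueError(
                f"MR grid {self.mr.shape} != CT grid {self.ct.shape}"
            )
        if self.mr.spacing_mm != self.ct.spacing_mm:
            raise ValueError("MR and CT spacing differ")
        if self.masks.shape is not None and self.masks.shape != self.mr.shape:
            raise ValueError("mask grid does not match image grid")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mr.shape

    @property
    def n_slices(self) -> int:
        return self.mr.shape[2]


@dataclass
class PairedSlice:
    """A single transverse MR/CT slice pair, the unit the networks consume."""

    subject_id: str
    slice_index: int
    mr_slice: np.ndarray
    ct_slice: np.ndarray

    def __post_init__(self) -> None:
        self.mr_slice = np.asarray(self.mr_slice, dtype=np.float64)
        self.ct_slice = np.asarray(self.ct_slice, dtype=np.float64)
        if self.mr_slice.shape != self.ct_slice.shape:
            raise ValueError("MR and CT slices differ in shape")


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def normalize_to_unit(v: VoxelVolume) -> Tuple[VoxelVolume, IntensityScale]:
    """Min-max rescale a volume to [0, 1], returning the scale used.

    Raises
    ------
    ValueError
        If the volume is constant (the affine map would be degenerate).
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant volume")
    scale = IntensityScale(lo, hi)
    out = v.with_data((v.data - lo) / scale.width, intensity_domain="normalized")
    return out, scale


def denormalize(v: VoxelVolume, scale: IntensityScale, domain: str = "HU") -> VoxelVolume:
    """Invert :func:`normalize_to_unit` with a recorded intensity scale."""
    return v.with_data(v.data * scale.width + scale.lo, intensity_domain=domain)


def compute_air_mask(
    ct: VoxelVolume,
    hu_threshold: float = -400.0,
    closing_radius: int = 2,
) -> np.ndarray:
    """Body mask of a CT volume: everything that is not exterior air.

    Voxels above ``hu_threshold`` seed the body region; the seed is closed
    morphologically, reduced to its largest connected component, and interior
    air pockets (e.g. bowel lumen) are filled slice-by-slice so they stay part
    of the body.  Returns a boolean volume.
    """
    if ct.intensity_domain != "HU":
        raise ValueError("air mask is defined on HU-domain volumes")
    seed = ct.data > hu_threshold
    if not seed.any():
        raise ValueError("no voxel above threshold: volume is all air")
    if closing_radius > 0:
        struct = _disk3d(closing_radius)
        seed = ndimage.binary_closing(seed, structure=struct)
    labels, n = ndimage.label(seed)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        seed = labels == (1 + int(np.argmax(sizes)))
    filled = np.empty_like(seed)
    for k in range(seed.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(seed[:, :, k])
    return filled


def _disk3d(radius: int) -> np.ndarray:
    """In-plane disk structuring element (no coupling across slices)."""
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    disk = (x * x + y * y) <= r * r
    return disk[:, :, None]


def flip_lr(s: PairedSlice) -> PairedSlice:
    """Mirror a paired slice about the left-right axis (axis 0)."""
    return PairedSlice(
        subject_id=s.subject_id,
        slice_index=s.slice_index,
        mr_slice=s.mr_slice[::-1, :].copy(),
        ct_slice=s.ct_slice[::-1, :].copy(),
    )


def extract_slices(case: PairedCase) -> List[PairedSlice]:
    """Split a paired case into its transverse slices, ordered by index."""
    return [
        PairedSlice(
            subject_id=case.subject_id,
            slice_index=k,
            mr_slice=case.mr.data[:, :, k],
            ct_slice=case.ct.data[:, :, k],
        )
        for k in range(case.n_slices)
    ]


def stack_slices(slices: List[PairedSlice]) -> Tuple[np.ndarray, np.ndarray]:
    """Reassemble (mr, ct) volumes from an ordered slice list."""
    mr = np.stack([s.mr_slice for s in slices], axis=2)
    ct = np.stack([s.ct_slice for s in slices], axis=2)
    return mr, ct
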