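"""Seed-reproducible paired pseudo-MR / pseudo-CT pelvis phantoms.

The clinical cohort behind this method is private, so the package ships a
procedural stand-in: an elliptical torso containing two circular femurs with
a dense cortical gradient, a fluid-filled bladder, a tubular anorectum with
an air lumen, and a tumor blob between bladder and anorectum.  The geometry
is deliberately minimal — its job is to exercise every tissue regime (air,
soft tissue, fat, fluid, bone) and all five contour-restricted metrics, not
to look anatomical.

Both modalities are derived from one latent "texture" field per voxel, so a
known, per-tissue monotone map links MR intensity to CT HU exactly when
noise is disabled; :func:`true_forward_map` exposes that ground truth for
recovery tests.  MR contrast is T2-like: fluid brightest, then tumor, soft
tissue, fat, with bone and air dark.

All volumes are synthetic; every file written by this module represents
simulated, not clinical, data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .volumes import PairedCase, StructureMaskSet, VoxelVolume

__all__ = [
    "TissueClass",
    "PhantomConfig",
    "DEFAULT_TISSUE_TABLE",
    "generate_subject",
    "generate_cohort",
    "true_forward_map",
    "table1_slice_counts",
]


@dataclass(frozen=True)
class TissueClass:
    """One tissue regime: an HU range and an MR intensity range.

    Within a tissue, a latent texture value t in [0, 1] maps affinely onto
    both ranges, which makes the MR -> HU relation piecewise affine and
    monotone per tissue.
    """

    name: str
    hu_range: Tuple[float, float]
    mr_range: Tuple[float, float]

    def __post_init__(self) -> None:
        if not self.hu_range[0] < self.hu_range[1]:
            raise ValueError(f"{self.name}: HU range must be ordered lo < hi")
        if not self.mr_range[0] < self.mr_range[1]:
            raise ValueError(f"{self.name}: MR range must be ordered lo < hi")

    @property
    def hu_center(self) -> float:
        return 0.5 * (self.hu_range[0] + self.hu_range[1])

    @property
    def mr_center(self) -> float:
        return 0.5 * (self.mr_range[0] + self.mr_range[1])


#: T2-like intensity ordering: fluid > tumor > soft tissue > fat >= bone ~ air.
#: MR units are arbitrary (scanner-like scale 0-1000).
DEFAULT_TISSUE_TABLE: Tuple[TissueClass, ...] = (
    TissueClass("air", (-1010.0, -990.0), (0.0, 30.0)),
    TissueClass("bone", (200.0, 1300.0), (30.0, 110.0)),
    TissueClass("fat", (-120.0, -80.0), (250.0, 380.0)),
    TissueClass("soft_tissue", (10.0, 60.0), (420.0, 560.0)),
    TissueClass("tumor", (30.0, 80.0), (600.0, 720.0)),
    TissueClass("fluid", (-10.0, 15.0), (820.0, 980.0)),
)


@dataclass
class PhantomConfig:
    """Cohort-level phantom settings.

    Defaults mirror the study cohort: 11 subjects on a 144x144 grid with
    3.2 x 3.2 x 5 mm voxels and per-subject slice counts of 44 or 50.
    """

    n_subjects: int = 11
    grid: Tuple[int, int] = (144, 144)
    slice_count_choices: Tuple[int, ...] = (44, 50)
    spacing_mm: Tuple[float, float, float] = (3.2, 3.2, 5.0)
    tissue_table: Tuple[TissueClass, ...] = DEFAULT_TISSUE_TABLE
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"MR": 8.0, "CT": 15.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if any(g <= 0 for g in self.grid) or len(self.grid) != 2:
            raise ValueError("grid must be two positive integers")
        if any(g % 4 for g in self.grid):
            raise ValueError(
                f"grid {self.grid} not divisible by 4: the generators pool twice")
        if not self.slice_count_choices or any(c <= 0 for c in self.slice_count_choices):
            raise ValueError("slice counts must be positive")
        names = [t.name for t in self.tissue_table]
        if len(names) != len(set(names)):
            raise ValueError("tissue names must be unique")

    def tissue(self, name: str) -> TissueClass:
        for t in self.tissue_table:
            if t.name == name:
                return t
        raise KeyError(f"unknown tissue {name!r}")

    @property
    def tissue_names(self) -> Tuple[str, ...]:
        return tuple(t.name for t in self.tissue_table)


#: slice counts of the emulated cohort, by 1-based subject index: subjects
#: 1, 2, 3 and 5 have 50 slices, the remaining seven have 44.
_LONG_SUBJECTS = (1, 2, 3, 5)


def table1_slice_counts(n_subjects: int = 11,
                        choices: Sequence[int] = (44, 50)) -> List[int]:
    """Per-subject slice counts following the emulated cohort's pattern."""
    lo, hi = min(choices), max(choices)
    return [hi if (i + 1) in _LONG_SUBJECTS else lo for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse(nx: int, ny: int, cx: float, cy: float, ax: float, ay: float):
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _subject_geometry(nx: int, ny: int, rng: np.random.Generator):
    """Randomized per-subject geometry parameters (voxel units)."""
    j = lambda lo, hi: float(rng.uniform(lo, hi))  # noqa: E731
    # centring on (n-1)/2 makes the geometry exactly mirror-symmetric under
    # an index flip along the left-right axis
    mx, my = (nx - 1) / 2.0, (ny - 1) / 2.0
    return {
        "body": (mx, my, nx * j(0.40, 0.44), ny * j(0.31, 0.35)),
        "fat_frac": j(0.82, 0.88),          # interior fraction where fat ring starts
        "femur_dx": nx * j(0.24, 0.27),     # lateral femur offset
        "femur_dy": ny * j(0.02, 0.05),     # posterior shift
        "femur_r": nx * j(0.045, 0.060),
        "bladder": (mx, ny * j(0.38, 0.42), nx * j(0.075, 0.095), ny * j(0.055, 0.075)),
        "tumor": (mx, ny * j(0.54, 0.57), nx * j(0.035, 0.050), ny * j(0.030, 0.042)),
        "ano_cy": ny * j(0.68, 0.72),
        "ano_r": nx * j(0.030, 0.038),
        "ano_lumen": 0.45,                  # lumen radius as fraction of tube radius
    }


def _slice_masks(nx: int, ny: int, geo: dict, zfrac: float) -> Dict[str, np.ndarray]:
    """Binary masks of one transverse slice.

    ``zfrac`` in [0, 1] positions the slice along the cranio-caudal axis;
    bladder and tumor taper away from the central slices while body, femurs
    and anorectum run the whole stack.
    """
    cx, cy, bax, bay = geo["body"]
    body = _ellipse(nx, ny, cx, cy, bax, bay)

    femur_R = _ellipse(nx, ny, cx - geo["femur_dx"], cy + geo["femur_dy"],
                       geo["femur_r"], geo["femur_r"])
    femur_L = _ellipse(nx, ny, cx + geo["femur_dx"], cy + geo["femur_dy"],
                       geo["femur_r"], geo["femur_r"])

    # central taper for bladder and tumor: scale in [0, 1], zero near the ends
    taper = max(0.0, 1.0 - (2.0 * (zfrac - 0.5)) ** 2 * 1.6)
    bcx, bcy, brx, bry = geo["bladder"]
    bladder = (_ellipse(nx, ny, bcx, bcy, brx * taper, bry * taper)
               if taper > 0.05 else np.zeros((nx, ny), dtype=bool))
    tcx, tcy, trx, try_ = geo["tumor"]
    tumor = (_ellipse(nx, ny, tcx, tcy, trx * taper, try_ * taper)
             if taper > 0.05 else np.zeros((nx, ny), dtype=bool))

    ano_tube = _ellipse(nx, ny, cx, geo["ano_cy"], geo["ano_r"], geo["ano_r"])
    lumen = _ellipse(nx, ny, cx, geo["ano_cy"],
                     geo["ano_r"] * geo["ano_lumen"], geo["ano_r"] * geo["ano_lumen"])
    anorectum = ano_tube & ~lumen       # the contour is the wall, not the air lumen

    return {"body": body, "femur_R": femur_R, "femur_L": femur_L,
            "bladder": bladder, "tumor": tumor, "anorectum": anorectum,
            "ano_lumen": lumen}


def _tissue_labels(nx: int, ny: int, geo: dict, zfrac: float,
                   names: Sequence[str]) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Integer tissue-label slice plus the structure masks it was built from."""
    m = _slice_masks(nx, ny, geo, zfrac)
    idx = {name: i for i, name in enumerate(names)}
    lab = np.full((nx, ny), idx["air"], dtype=np.int8)

    body = m["body"]
    lab[body] = idx["soft_tissue"]
    # subcutaneous fat ring: between fat_frac and 1.0 of the body ellipse
    cx, cy, bax, bay = geo["body"]
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = ((x - cx) / bax) ** 2 + ((y - cy) / bay) ** 2
    lab[body & (r2 >= geo["fat_frac"] ** 2)] = idx["fat"]

    lab[m["femur_R"] | m["femur_L"]] = idx["bone"]
    lab[m["bladder"]] = idx["fluid"]
    lab[m["tumor"]] = idx["tumor"]
    lab[m["anorectum"]] = idx["soft_tissue"]
    lab[m["ano_lumen"]] = idx["air"]
    return lab, m


def true_forward_map(mr_value, tissue: TissueClass):
    """Ground-truth MR -> HU map of the phantom, per tissue class.

    The latent texture is recovered as ``t = (mr - mr_lo) / (mr_hi - mr_lo)``
    (clipped to [0, 1]) and re-expressed on the HU range, so the map is
    monotone non-decreasing within the tissue and inverts the noise-free
    phantom construction exactly.
    """
    mr_value = np.asarray(mr_value, dtype=np.float64)
    mlo, mhi = tissue.mr_range
    hlo, hhi = tissue.hu_range
    t = np.clip((mr_value - mlo) / (mhi - mlo), 0.0, 1.0)
    out = hlo + t * (hhi - hlo)
    return float(out) if out.ndim == 0 else out


def generate_subject(config: PhantomConfig, subject_id: str,
                     n_slices: int) -> PairedCase:
    """Generate one paired pseudo-MR/pseudo-CT subject.

    Deterministic in (config, subject_id, n_slices): the subject's random
    stream is seeded from the config seed and a stable hash of the id.
    """
    if n_slices not in config.slice_count_choices:
        raise ValueError(
            f"n_slices={n_slices} not in allowed choices {config.slice_count_choices}")
    nx, ny = config.grid
    rng = np.random.default_rng(
        (int(config.seed) + _stable_id_offset(subject_id)) % (2 ** 63))
    geo = _subject_geometry(nx, ny, rng)
    names = config.tissue_names

    labels = np.empty((nx, ny, n_slices), dtype=np.int8)
    masks = {n: np.zeros((nx, ny, n_slices), dtype=bool)
             for n in ("GTV", "femur_R", "femur_L", "bladder", "anorectum", "body")}
    for k in range(n_slices):
        zfrac = k / max(n_slices - 1, 1)
        lab, m = _tissue_labels(nx, ny, geo, zfrac, names)
        labels[:, :, k] = lab
        masks["body"][:, :, k] = m["body"]
        masks["femur_R"][:, :, k] = m["femur_R"]
        masks["femur_L"][:, :, k] = m["femur_L"]
        masks["bladder"][:, :, k] = m["bladder"]
        masks["GTV"][:, :, k] = m["tumor"]
        masks["anorectum"][:, :, k] = m["anorectum"]

    # latent texture field in [0, 1]; shared by both modalities
    texture = rng.uniform(0.15, 0.85, size=labels.shape)
    # femur cortical gradient: texture rises towards the rim, so HU spans the
    # configured bone range with a dense shell
    bone_idx = names.index("bone")
    in_bone = labels == bone_idx
    if in_bone.any():
        texture[in_bone] = _cortical_texture(masks["femur_R"] | masks["femur_L"],
                                             geo)[in_bone]

    mr = np.empty(labels.shape)
    ct = np.empty(labels.shape)
    for i, t in enumerate(config.tissue_table):
        sel = labels == i
        mr[sel] = t.mr_range[0] + texture[sel] * (t.mr_range[1] - t.mr_range[0])
        ct[sel] = t.hu_range[0] + texture[sel] * (t.hu_range[1] - t.hu_range[0])

    mr_noise = float(config.noise_sd.get("MR", 0.0))
    ct_noise = float(config.noise_sd.get("CT", 0.0))
    if mr_noise > 0:
        mr = mr + rng.normal(0.0, mr_noise, size=mr.shape)
    if ct_noise > 0:
        ct = ct + rng.normal(0.0, ct_noise, size=ct.shape)

    return PairedCase(
        subject_id=subject_id,
        mr=VoxelVolume(mr, spacing_mm=config.spacing_mm, modality="MR",
                       intensity_domain="arbitrary"),
        ct=VoxelVolume(ct, spacing_mm=config.spacing_mm, modality="CT",
                       intensity_domain="HU"),
        masks=StructureMaskSet(masks),
        tissue_labels=labels,
        tissue_names=names,
    )


def _cortical_texture(femur_mask: np.ndarray, geo: dict) -> np.ndarray:
    """Texture in femurs rising with distance from each femur centre."""
    nx, ny, nz = femur_mask.shape
    cx = geo["body"][0]
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cy = geo["body"][1] + geo["femur_dy"]
    r = geo["femur_r"]
    dR = np.sqrt((x - (cx - geo["femur_dx"])) ** 2 + (y - cy) ** 2)
    dL = np.sqrt((x - (cx + geo["femur_dx"])) ** 2 + (y - cy) ** 2)
    frac = np.clip(np.minimum(dR, dL) / r, 0.0, 1.0)
    return np.repeat(frac[:, :, None], nz, axis=2)


def _stable_id_offset(subject_id: str) -> int:
    """Deterministic (non-salted) integer from a subject identifier."""
    h = 0
    for ch in str(subject_id):
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return h


def generate_cohort(config: PhantomConfig) -> List[PairedCase]:
    """Generate the whole phantom cohort.

    Subject ids are ``S01..Snn``; slice counts follow the emulated cohort's
    pattern (subjects 1, 2, 3, 5 long, the rest short) extended cyclically
    for cohorts larger than 11.  Each subject draws from an independent,
    deterministic stream (config seed + subject index).
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects for leave-one-out")
    counts = [
        max(config.slice_count_choices)
        if ((i % 11) + 1) in _LONG_SUBJECTS else min(config.slice_count_choices)
        for i in range(config.n_subjects)
    ]
    cases = []
    for i, n_slices in enumerate(counts):
        sub_cfg = PhantomConfig(
            n_subjects=config.n_subjects, grid=config.grid,
            slice_count_choices=config.slice_count_choices,
            spacing_mm=config.spacing_mm, tissue_table=config.tissue_table,
            noise_sd=dict(config.noise_sd), seed=int(config.seed) + i)
        cases.append(generate_subject(sub_cfg, f"S{i + 1:02d}", n_slices))
    return cases
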