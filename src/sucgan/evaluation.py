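"""Synthetic-CT quality metrics, per-contour reports, and HU histograms.

Four metrics are reported, all computed over a voxel mask:

* MAPE — mean absolute prediction error in HU.  Despite the name (which
  follows the field's usage for this task) it is a mean absolute error, not
  a percentage.
* RMSE — root mean square error in HU.
* PSNR — ``10 log10(MAX^2 / MSE)`` in dB, with MAX the maximum measured CT
  intensity over the mask by default.
* SSIM — the global (non-windowed) structural similarity statistic built
  from masked means, variances, and the covariance, with the standard
  stabilizers ``c1 = (0.01 L)^2`` and ``c2 = (0.03 L)^2``.

Whole-volume metrics exclude air outside the body via the air mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .volumes import PairedCase, VoxelVolume, compute_air_mask

__all__ = [
    "SSIMParams",
    "MetricsReport",
    "HistogramSet",
    "mape",
    "rmse",
    "psnr",
    "ssim_global",
    "contour_metrics",
    "hu_histogram",
    "case_histograms",
    "summarize_cohort",
    "DEFAULT_HISTOGRAM_EDGES",
]

#: default HU histogram binning: 50 uniform bins spanning [-1024, 1600] HU
DEFAULT_HISTOGRAM_EDGES = np.linspace(-1024.0, 1600.0, 51)

METRIC_COLUMNS = ("mape", "rmse", "psnr", "ssim")


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizers for the global SSIM statistic.

    ``dynamic_range`` is the intensity span L from which the stabilizers are
    derived; the default covers the conventional CT HU window.
    """

    dynamic_range: float = 4095.0
    c1: float = field(default=None)  # type: ignore[assignment]
    c2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.c1 is None:
            object.__setattr__(self, "c1", (0.01 * self.dynamic_range) ** 2)
        if self.c2 is None:
            object.__setattr__(self, "c2", (0.03 * self.dynamic_range) ** 2)
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")


@dataclass
class MetricsReport:
    """MAPE/RMSE/PSNR/SSIM for one region of one subject."""

    region: str
    mape: float
    rmse: float
    psnr: float
    ssim: float
    n_voxels: int
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("a metrics report needs a non-empty region")
        if self.mape > self.rmse + 1e-9:
            raise ValueError("MAPE cannot exceed RMSE")


@dataclass
class HistogramSet:
    """Per-structure HU histograms of the measured CT and the synthetic CT."""

    bin_edges: np.ndarray
    ct_counts: Dict[str, np.ndarray]
    sct_counts: Dict[str, np.ndarray]


def _masked(ct, sct, mask) -> Tuple[np.ndarray, np.ndarray]:
    ct, sct, mask = np.asarray(ct), np.asarray(sct), np.asarray(mask, dtype=bool)
    if ct.shape != sct.shape or ct.shape != mask.shape:
        raise ValueError("ct, sct and mask must share one grid")
    if not mask.any():
        raise ValueError("empty mask")
    return ct[mask], sct[mask]


def mape(ct, sct, mask) -> float:
    """Mean absolute error in HU over the masked voxels."""
    a, b = _masked(ct, sct, mask)
    return float(np.mean(np.abs(a - b)))


def rmse(ct, sct, mask) -> float:
    """Root mean square error in HU over the masked voxels."""
    a, b = _masked(ct, sct, mask)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(ct, sct, mask, max_value: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the volumes agree exactly.

    ``max_value`` defaults to the maximum measured CT intensity on the mask.
    """
    a, b = _masked(ct, sct, mask)
    if max_value is None:
        max_value = float(np.max(a))
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value ** 2 / mse))


def ssim_global(ct, sct, mask, params: SSIMParams = SSIMParams()) -> float:
    """Global structural similarity over the masked voxels (single statistic)."""
    a, b = _masked(ct, sct, mask)
    mu_a, mu_b = float(a.mean()), float(b.mean())
    var_a, var_b = float(a.var()), float(b.var())
    cov = float(((a - mu_a) * (b - mu_b)).mean())
    num = (2 * mu_a * mu_b + params.c1) * (2 * cov + params.c2)
    den = (mu_a ** 2 + mu_b ** 2 + params.c1) * (var_a + var_b + params.c2)
    return float(num / den)


def region_metrics(ct, sct, mask, region: str, params: SSIMParams,
                   subject_id: Optional[str] = None,
                   max_value: Optional[float] = None) -> MetricsReport:
    return MetricsReport(
        region=region,
        mape=mape(ct, sct, mask),
        rmse=rmse(ct, sct, mask),
        psnr=psnr(ct, sct, mask, max_value=max_value),
        ssim=ssim_global(ct, sct, mask, params),
        n_voxels=int(np.asarray(mask, dtype=bool).sum()),
        subject_id=subject_id,
    )


def contour_metrics(case: PairedCase, sct: VoxelVolume,
                    params: SSIMParams = SSIMParams(),
                    air_threshold: float = -400.0,
                    structures: Sequence[str] = ("GTV", "femur_R", "femur_L",
                                                 "bladder", "anorectum"),
                    ) -> List[MetricsReport]:
    """Whole-body report (air-masked) plus one report per contoured structure.

    Missing structure masks are skipped with a warning rather than failing
    the evaluation.
    """
    if sct.intensity_domain != "HU":
        raise ValueError("synthetic CT must be in HU for evaluation")
    if sct.shape != case.ct.shape:
        raise ValueError("synthetic CT grid does not match the case grid")
    body = compute_air_mask(case.ct, hu_threshold=air_threshold)
    reports = [region_metrics(case.ct.data, sct.data, body, "whole_body",
                              params, subject_id=case.subject_id)]
    for name in structures:
        if name not in case.masks:
            warnings.warn(f"subject {case.subject_id}: no mask for {name!r}; skipped")
            continue
        reports.append(region_metrics(case.ct.data, sct.data, case.masks[name],
                                      name, params, subject_id=case.subject_id))
    return reports


def hu_histogram(volume, mask, bin_edges=DEFAULT_HISTOGRAM_EDGES) -> np.ndarray:
    """Histogram of masked voxel intensities; outliers land in the end bins."""
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    volume, mask = np.asarray(volume), np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = np.clip(volume[mask], bin_edges[0], bin_edges[-1])
    counts, _ = np.histogram(values, bins=bin_edges)
    return counts


def case_histograms(case: PairedCase, sct: VoxelVolume,
                    bin_edges=DEFAULT_HISTOGRAM_EDGES) -> HistogramSet:
    """CT and sCT histograms for every contoured structure of a case."""
    ct_counts, sct_counts = {}, {}
    for name in case.masks.structures():
        m = case.masks[name]
        if not m.any():
            continue
        ct_counts[name] = hu_histogram(case.ct.data, m, bin_edges)
        sct_counts[name] = hu_histogram(sct.data, m, bin_edges)
    return HistogramSet(np.asarray(bin_edges, dtype=np.float64), ct_counts, sct_counts)


def summarize_cohort(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Per-region mean and sample SD of each metric across subjects.

    Returns a table indexed by region with ``<metric>_mean`` and
    ``<metric>_sd`` columns plus the subject count; a single-subject region
    reports SD 0 and is flagged in the ``single_subject`` column.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    df = pd.DataFrame([{
        "region": r.region, "subject_id": r.subject_id,
        **{m: getattr(r, m) for m in METRIC_COLUMNS},
    } for r in reports])
    rows = []
    for region, grp in df.groupby("region", sort=False):
        row = {"region": region, "n_subjects": len(grp),
               "single_subject": len(grp) == 1}
        for m in METRIC_COLUMNS:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_sd"] = grp[m].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def plot_histogram_overlay(hist: HistogramSet, structure: str, ax=None):
    """Overlay the CT and sCT HU histograms of one structure (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    ax.step(centers, hist.ct_counts[structure], where="mid", label="CT")
    ax.step(centers, hist.sct_counts[structure], where="mid", label="sCT")
    ax.set_xlabel("HU")
    ax.set_ylabel("voxels")
    ax.set_title(structure)
    ax.legend()
    return ax
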