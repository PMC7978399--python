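"""Image-quality metrics, per-contour reports, histograms, summaries."""

import numpy as np
import pandas as pd
import pytest

from sucgan import (SSIMParams, contour_metrics, hu_histogram,
                    mape, psnr, rmse, ssim_global, summarize_cohort)
from sucgan.evaluation import MetricsReport, case_histograms

FULL = np.ones((2, 1, 1), dtype=bool)


def test_mape_examples():
    assert mape(np.zeros((2, 1, 1)), np.zeros((2, 1, 1)), FULL) == 0.0
    ct = np.array([0.0, 100.0]).reshape(2, 1, 1)
    sct = np.array([10.0, 90.0]).reshape(2, 1, 1)
    assert mape(ct, sct, FULL) == pytest.approx(10.0)
    ct = np.array([0.0, 0.0]).reshape(2, 1, 1)
    sct = np.array([3.0, 4.0]).reshape(2, 1, 1)
    assert mape(ct, sct, FULL) == pytest.approx(3.5)


def test_rmse_examples():
    ct = np.array([0.0, 0.0]).reshape(2, 1, 1)
    sct = np.array([3.0, 4.0]).reshape(2, 1, 1)
    assert rmse(ct, ct, FULL) == 0.0
    assert rmse(ct, sct, FULL) == pytest.approx(np.sqrt(12.5))


def test_mape_never_exceeds_rmse():
    rng = np.random.default_rng(0)
    for _ in range(50):
        ct = rng.normal(size=(4, 4, 3))
        sct = rng.normal(size=(4, 4, 3))
        mask = rng.random((4, 4, 3)) < 0.7
        if not mask.any():
            continue
        assert mape(ct, sct, mask) <= rmse(ct, sct, mask) + 1e-12


def test_psnr_examples():
    ct = np.zeros((4, 1, 1))
    sct = np.full((4, 1, 1), 0.1)           # MSE = 0.01
    assert psnr(ct, sct, np.ones_like(ct, bool), max_value=1.0) == pytest.approx(20.0)
    assert psnr(ct, ct, np.ones_like(ct, bool)) == np.inf
    rng = np.random.default_rng(1)
    err = rng.normal(size=(4, 4, 3))
    full = np.ones(err.shape, bool)
    gain = (psnr(np.zeros_like(err), err / 2, full, max_value=5.0)
            - psnr(np.zeros_like(err), err, full, max_value=5.0))
    assert gain == pytest.approx(10 * np.log10(4))


def test_psnr_decreases_with_mse():
    base = np.zeros((4, 4, 3))
    full = np.ones(base.shape, bool)
    scales = [0.1, 0.2, 0.5, 1.0]
    vals = [psnr(base, np.full_like(base, s), full, max_value=1.0) for s in scales]
    assert np.all(np.diff(vals) < 0)


def test_ssim_identity_symmetry_and_constant_example():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(4, 4, 3))
    b = rng.normal(size=(4, 4, 3))
    full = np.ones(a.shape, bool)
    assert ssim_global(a, a, full) == pytest.approx(1.0)
    assert ssim_global(a, b, full) == pytest.approx(ssim_global(b, a, full))
    # constant volumes: second factor is 1, first factor = 16.01/20.01
    p = SSIMParams(dynamic_range=1.0, c1=0.01, c2=0.5)
    v2, v4 = np.full((2, 2, 2), 2.0), np.full((2, 2, 2), 4.0)
    assert ssim_global(v2, v4, np.ones(v2.shape, bool), p) == pytest.approx(16.01 / 20.01)


def test_metrics_are_permutation_invariant():
    rng = np.random.default_rng(3)
    ct = rng.normal(size=(4, 4, 3))
    sct = rng.normal(size=(4, 4, 3))
    mask = rng.random((4, 4, 3)) < 0.8
    perm = rng.permutation(ct.size)
    shuffle = lambda v: v.ravel()[perm].reshape(v.shape)  # noqa: E731
    p = SSIMParams()
    assert mape(ct, sct, mask) == pytest.approx(mape(shuffle(ct), shuffle(sct), shuffle(mask)))
    assert rmse(ct, sct, mask) == pytest.approx(rmse(shuffle(ct), shuffle(sct), shuffle(mask)))
    assert ssim_global(ct, sct, mask, p) == pytest.approx(
        ssim_global(shuffle(ct), shuffle(sct), shuffle(mask), p))


def test_empty_mask_is_rejected():
    z = np.zeros((2, 2, 2))
    with pytest.raises(ValueError, match="empty"):
        mape(z, z, np.zeros_like(z, bool))


def test_metrics_report_orders_mape_below_rmse():
    with pytest.raises(ValueError, match="MAPE"):
        MetricsReport(region="x", mape=5.0, rmse=1.0, psnr=1.0, ssim=0.5, n_voxels=3)


# ---------------------------------------------------------------------------
# contour reports
# ---------------------------------------------------------------------------

def test_perfect_sct_scores_perfectly_per_structure(noise_free_cohort):
    case = noise_free_cohort[0]
    sct = case.ct.with_data(case.ct.data.copy(), modality="SCT")
    reports = contour_metrics(case, sct)
    regions = {r.region for r in reports}
    assert regions == {"whole_body", "GTV", "femur_R", "femur_L", "bladder",
                       "anorectum"}
    for r in reports:
        assert r.mape == 0.0
        assert r.ssim == pytest.approx(1.0)
        assert r.psnr == np.inf


def test_structure_report_matches_direct_masked_metric(noise_free_cohort):
    rng = np.random.default_rng(4)
    case = noise_free_cohort[0]
    sct = case.ct.with_data(case.ct.data + rng.normal(0, 30, case.ct.shape),
                            modality="SCT")
    reports = {r.region: r for r in contour_metrics(case, sct)}
    m = case.masks["bladder"]
    assert reports["bladder"].mape == pytest.approx(mape(case.ct.data, sct.data, m))
    assert reports["bladder"].n_voxels == int(m.sum())
    assert reports["whole_body"].n_voxels == int(case.masks["body"].sum())


def test_missing_structure_is_skipped_with_warning(noise_free_cohort):
    import dataclasses

    from sucgan import StructureMaskSet
    case = noise_free_cohort[0]
    masks = {k: v for k, v in case.masks.masks.items() if k != "GTV"}
    slim = dataclasses.replace(case, masks=StructureMaskSet(masks))
    sct = case.ct.with_data(case.ct.data.copy(), modality="SCT")
    with pytest.warns(UserWarning, match="GTV"):
        reports = contour_metrics(slim, sct)
    assert {r.region for r in reports} == {"whole_body", "femur_R", "femur_L",
                                           "bladder", "anorectum"}


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def test_histogram_counts_are_conserved_and_clip_outliers():
    rng = np.random.default_rng(5)
    vol = rng.normal(0, 2000, size=(6, 6, 4))    # plenty of out-of-range values
    mask = rng.random(vol.shape) < 0.5
    counts = hu_histogram(vol, mask)
    assert counts.sum() == mask.sum()


def test_histogram_of_constant_volume_is_a_spike():
    vol = np.full((3, 3, 3), 42.0)
    counts = hu_histogram(vol, np.ones(vol.shape, bool))
    assert (counts > 0).sum() == 1
    assert counts.sum() == 27


def test_histogram_is_flip_invariant(noise_free_cohort):
    case = noise_free_cohort[0]
    m = case.masks["body"]
    a = hu_histogram(case.ct.data, m)
    b = hu_histogram(case.ct.data[::-1], m[::-1])
    assert np.array_equal(a, b)


def test_case_histograms_cover_structures(noise_free_cohort):
    case = noise_free_cohort[0]
    sct = case.ct.with_data(case.ct.data.copy(), modality="SCT")
    hs = case_histograms(case, sct)
    for name, counts in hs.ct_counts.items():
        assert counts.sum() == case.masks[name].sum()
        assert np.array_equal(counts, hs.sct_counts[name])


def test_bad_bin_edges_rejected():
    with pytest.raises(ValueError, match="increasing"):
        hu_histogram(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), [0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def _report(subject, value):
    return MetricsReport(region="whole_body", mape=value, rmse=value + 1,
                         psnr=30.0, ssim=0.9, n_voxels=10, subject_id=subject)


def test_summary_mean_and_sample_sd():
    df = summarize_cohort([_report("a", 1.0), _report("b", 2.0), _report("c", 3.0)])
    row = df.loc["whole_body"]
    assert row["mape_mean"] == pytest.approx(2.0)
    assert row["mape_sd"] == pytest.approx(1.0)
    assert row["n_subjects"] == 3
    assert not row["single_subject"]


def test_summary_single_subject_flagged():
    df = summarize_cohort([_report("a", 5.0)])
    row = df.loc["whole_body"]
    assert row["mape_mean"] == 5.0
    assert row["mape_sd"] == 0.0
    assert row["single_subject"]


def test_summary_is_order_invariant():
    reports = [_report(s, v) for s, v in zip("abc", (1.0, 2.0, 3.0))]
    a = summarize_cohort(reports)
    b = summarize_cohort(reports[::-1])
    pd.testing.assert_frame_equal(a, b)
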