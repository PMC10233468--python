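"""Evaluation metric chain: stage oracles, full-chain identities,
affine invariance, Tukey box summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imcsr.evalmetrics import (
    LinearTransformParams,
    NormalizationParams,
    SsimConstants,
    evaluate,
    fit_linear_transform,
    nrmse,
    pcc,
    percentile_normalize,
    ssim_global,
    tukey_summary,
)


def _quantile_oracle(sorted_vals, p):
    """Linear interpolation between order statistics (rank p*(n-1))."""
    n = len(sorted_vals)
    pos = p * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def test_percentile_normalize_identity_and_degenerate():
    img = np.linspace(0, 1, 16).reshape(4, 4)
    out = percentile_normalize(img, NormalizationParams(0.0, 1.0))
    np.testing.assert_allclose(out, img, atol=1e-15)
    with pytest.raises(ValueError, match="degenerate"):
        percentile_normalize(np.full((4, 4), 3.0))


def test_percentile_normalize_ramp_oracle():
    img = np.arange(10, dtype=float).reshape(2, 5)
    params = NormalizationParams(0.1, 0.99)
    out = percentile_normalize(img, params)
    vals = np.sort(img.ravel())
    q_lo = _quantile_oracle(vals, 0.1)
    q_hi = _quantile_oracle(vals, 0.99)
    np.testing.assert_allclose(out, (img - q_lo) / (q_hi - q_lo), rtol=1e-12)


def test_linear_transform_identity_and_affine_inverse():
    x = np.random.default_rng(0).random((6, 6))
    lt = fit_linear_transform(x, x)
    assert lt.slope == pytest.approx(1.0) and lt.intercept == pytest.approx(0.0, abs=1e-12)
    lt2 = fit_linear_transform(2 * x + 1, x)
    assert lt2.slope == pytest.approx(0.5)
    assert lt2.intercept == pytest.approx(-0.5)
    with pytest.raises(ValueError, match="constant"):
        fit_linear_transform(np.ones((3, 3)), x[:3, :3])


def test_linear_transform_normal_equations_oracle():
    rng = np.random.default_rng(1)
    p = rng.random((16, 16))
    g = 0.7 * p + 0.1 + 0.05 * rng.standard_normal((16, 16))
    lt = fit_linear_transform(p, g)
    x, y = p.ravel(), g.ravel()
    n = x.size
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    assert lt.slope == pytest.approx(slope, abs=1e-8)
    assert lt.intercept == pytest.approx(intercept, abs=1e-8)


def test_nrmse_closed_forms():
    x = np.random.default_rng(2).random((8, 8))
    assert nrmse(x, x) == 0.0
    assert nrmse(np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]])) == pytest.approx(
        np.sqrt(0.5)
    )
    y = np.random.default_rng(3).random((8, 8))
    assert nrmse(x, y) == pytest.approx(np.sqrt(np.mean((x - y) ** 2)), rel=1e-12)


def test_ssim_forms_on_identical_images():
    x = np.random.default_rng(4).random((8, 8))
    assert ssim_global(x, x) == pytest.approx(1.0, rel=1e-12)
    # literal typeset variant lacks the factor 2 on the covariance
    var = np.mean((x - x.mean()) ** 2)
    expected = (var + 0.03) / (2 * var + 0.03)
    as_printed = ssim_global(x, x, SsimConstants(form="as_printed"))
    assert as_printed == pytest.approx(expected, rel=1e-12)
    assert as_printed < 1.0


def test_ssim_moment_oracle():
    rng = np.random.default_rng(5)
    p, g = rng.random((8, 8)), rng.random((8, 8))
    mu_p, mu_g = p.mean(), g.mean()
    var_p, var_g = ((p - mu_p) ** 2).mean(), ((g - mu_g) ** 2).mean()
    cov = ((p - mu_p) * (g - mu_g)).mean()
    expected = ((2 * mu_p * mu_g + 0.01) * (2 * cov + 0.03)) / (
        (mu_p**2 + mu_g**2 + 0.01) * (var_p + var_g + 0.03)
    )
    assert ssim_global(p, g) == pytest.approx(expected, rel=1e-12)


def test_pcc_limits_and_errors():
    x = np.arange(9, dtype=float).reshape(3, 3)
    assert pcc(x, x) == pytest.approx(1.0)
    assert pcc(x, -x) == pytest.approx(-1.0)
    assert pcc(np.array([[0.0, 1.0, 2.0]]), np.array([[2.0, 1.0, 0.0]])) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="constant"):
        pcc(np.ones((3, 3)), x)


@pytest.mark.parametrize("seed", range(6))
def test_stage_oracles_on_random_grids(seed):
    """Each stage matches an independent brute-force computation."""
    rng = np.random.default_rng(seed)
    h = int(rng.integers(8, 33))
    p = rng.random((h, h))
    g = rng.random((h, h))
    # quantile oracle
    params = NormalizationParams(0.1, 0.99)
    vals = np.sort(p.ravel())
    q_lo, q_hi = _quantile_oracle(vals, 0.1), _quantile_oracle(vals, 0.99)
    np.testing.assert_allclose(
        percentile_normalize(p, params), (p - q_lo) / (q_hi - q_lo), atol=1e-8
    )
    # moments
    assert nrmse(p, g) == pytest.approx(np.sqrt(np.mean((p - g) ** 2)), abs=1e-8)
    cov = np.mean((p - p.mean()) * (g - g.mean()))
    assert pcc(p, g) == pytest.approx(cov / (p.std() * g.std()), abs=1e-8)


def test_evaluate_full_chain_identity():
    x = np.random.default_rng(7).random((3, 12, 12))
    report = evaluate(x, x)
    np.testing.assert_allclose(report.nrmse, 0.0, atol=1e-12)
    np.testing.assert_allclose(report.ssim, 1.0, rtol=1e-12)
    np.testing.assert_allclose(report.pcc, 1.0, rtol=1e-12)


@pytest.mark.parametrize("a,b", [(0.5, -1.0), (2.0, 0.0), (10.0, 3.0)])
def test_evaluate_affine_invariance(a, b):
    x = np.random.default_rng(8).random((16, 16))
    report = evaluate(a * x + b, x)
    assert report.nrmse[0] < 1e-8
    assert report.pcc[0] == pytest.approx(1.0, abs=1e-10)


def test_evaluate_negative_slope_restored_by_transform():
    x = np.random.default_rng(9).random((16, 16))
    assert pcc(-2 * x + 3, x) == pytest.approx(-1.0)
    report = evaluate(-2 * x + 3, x)          # LT absorbs the sign flip
    assert report.pcc[0] == pytest.approx(1.0, abs=1e-8)


def test_evaluate_matches_stagewise_composition():
    rng = np.random.default_rng(10)
    pred = rng.random((2, 10, 10))
    gt = rng.random((2, 10, 10))
    report = evaluate(pred, gt)
    for c in range(2):
        pn = percentile_normalize(pred[c])
        gn = percentile_normalize(gt[c])
        lt = fit_linear_transform(pn, gn)
        pt = lt.apply(pn)
        assert report.nrmse[c] == pytest.approx(nrmse(pt, gn), rel=1e-12)
        assert report.ssim[c] == pytest.approx(ssim_global(pt, gn), rel=1e-12)
        assert report.pcc[c] == pytest.approx(pcc(pt, gn), rel=1e-12)
        assert report.transforms[c].slope == pytest.approx(lt.slope)


def test_evaluate_error_carries_channel_index():
    pred = np.stack([np.random.default_rng(0).random((4, 4)), np.ones((4, 4))])
    gt = np.random.default_rng(1).random((2, 4, 4))
    with pytest.raises(ValueError, match="channel 1"):
        evaluate(pred, gt)


def test_tukey_degenerate_and_symmetric():
    box = tukey_summary([5.0])
    assert (box.median, box.q1, box.q3) == (5.0, 5.0, 5.0)
    assert (box.whisker_low, box.whisker_high) == (5.0, 5.0)
    assert box.outliers == ()
    sym = tukey_summary([1.0, 2.0, 3.0, 4.0, 5.0])
    assert sym.median == pytest.approx(np.mean([1, 2, 3, 4, 5]))
    with pytest.raises(ValueError):
        tukey_summary([])


def test_tukey_outlier_hand_oracle():
    values = list(range(1, 12)) + [100]           # {1..11, 100}
    box = tukey_summary(values)
    q1 = np.percentile(values, 25)                # 3.75
    q3 = np.percentile(values, 75)                # 8.25
    fence = q3 + 1.5 * (q3 - q1)                  # 15.0
    assert box.q1 == pytest.approx(q1) and box.q3 == pytest.approx(q3)
    assert box.whisker_high == 11.0               # largest point inside the fence
    assert box.whisker_low == 1.0
    assert box.outliers == (100.0,)
    assert box.whisker_high < fence


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_tukey_partition_property(values):
    box = tukey_summary(values)
    arr = np.asarray(values)
    assert box.whisker_high <= arr.max() and box.whisker_low >= arr.min()
    inside = ((arr >= box.whisker_low) & (arr <= box.whisker_high)).sum()
    assert inside + len(box.outliers) == len(values)
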