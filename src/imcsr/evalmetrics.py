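"""Evaluation metric chain: percentile normalization, linear transform,
NRMSE, global SSIM, PCC, and Tukey box summaries.

Before any metric is computed, both the prediction and the ground truth
are percentile-normalized,

    Y_N = (Y - perct(Y, p_low)) / (perct(Y, p_high) - perct(Y, p_low)),

with p_low = 0.1 and p_high = 0.99 interpreted as quantile fractions
(10th and 99th percentiles), quantiles by linear interpolation of order
statistics.  The normalized prediction is then mapped onto the
normalized ground truth by an ordinary least-squares affine transform
(slope/intercept fitted over all pixels) — this makes the metrics
invariant to positive affine rescalings of the raw prediction:

    NRMSE = sqrt(mean((pred_T - gt_N)^2))
    SSIM  = (2 mu_p mu_g + c1)(2 cov + c2)
            / ((mu_p^2 + mu_g^2 + c1)(var_p + var_g + c2))
    PCC   = cov / (sd_p * sd_g)

with c1 = 0.01 and c2 = 0.03 used literally as constants.  The SSIM
``corrected`` form carries the conventional factor 2 on the covariance
so SSIM(X, X) = 1 exactly; ``as_printed`` drops it (numerator
(cov + c2)) for literal fidelity to a common typeset variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormalizationParams",
    "LinearTransformParams",
    "SsimConstants",
    "MetricsReport",
    "percentile_normalize",
    "fit_linear_transform",
    "nrmse",
    "ssim_global",
    "pcc",
    "evaluate",
    "tukey_summary",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Low/high quantile fractions of the percentile normalization.

    ``method`` is any quantile interpolation method numpy accepts;
    the default linear interpolation of order statistics is the common
    convention.
    """

    p_low: float = 0.1
    p_high: float = 0.99
    method: str = "linear"

    def __post_init__(self):
        if not (0.0 <= self.p_low < self.p_high <= 1.0):
            raise ValueError(f"require 0 <= p_low < p_high <= 1, got {self}")


@dataclass(frozen=True)
class LinearTransformParams:
    """Slope/intercept of the least-squares affine map onto the ground truth."""

    slope: float
    intercept: float

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("linear transform parameters must be finite")

    def apply(self, image: np.ndarray) -> np.ndarray:
        return self.slope * image + self.intercept


@dataclass(frozen=True)
class SsimConstants:
    """SSIM stabilizing constants and formula variant."""

    c1: float = 0.01
    c2: float = 0.03
    form: str = "corrected"

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be positive")
        if self.form not in ("corrected", "as_printed"):
            raise ValueError(f"unknown SSIM form {self.form!r}")


@dataclass
class MetricsReport:
    """Per-channel and mean NRMSE / SSIM / PCC plus the fitted transforms."""

    nrmse: np.ndarray
    ssim: np.ndarray
    pcc: np.ndarray
    transforms: list[LinearTransformParams]
    channel_names: tuple[str, ...] = ()

    @property
    def mean_nrmse(self) -> float:
        return float(self.nrmse.mean())

    @property
    def mean_ssim(self) -> float:
        return float(self.ssim.mean())

    @property
    def mean_pcc(self) -> float:
        return float(self.pcc.mean())

    def to_frame(self):
        """Tabular report: one row per channel plus a mean row."""
        import pandas as pd

        names = list(self.channel_names) or [f"channel_{i}" for i in range(len(self.nrmse))]
        rows = {
            "channel": names + ["mean"],
            "nrmse": list(self.nrmse) + [self.mean_nrmse],
            "ssim": list(self.ssim) + [self.mean_ssim],
            "pcc": list(self.pcc) + [self.mean_pcc],
        }
        return pd.DataFrame(rows)


def _as2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grid, got shape {arr.shape}")
    return arr


def percentile_normalize(
    image, params: NormalizationParams = NormalizationParams()
) -> np.ndarray:
    """Subtract the low quantile and divide by the inter-quantile range.

    No clipping: values may fall outside [0, 1].  Raises on an image
    whose two quantiles coincide (e.g., a constant image).
    """
    img = _as2d(image, "image")
    lo = float(np.quantile(img, params.p_low, method=params.method))
    hi = float(np.quantile(img, params.p_high, method=params.method))
    if hi <= lo:
        raise ValueError(
            f"degenerate normalization: quantiles p_low={params.p_low} and "
            f"p_high={params.p_high} coincide at {lo}"
        )
    return (img - lo) / (hi - lo)


def fit_linear_transform(pred_n, gt_n) -> LinearTransformParams:
    """Ordinary least-squares slope/intercept mapping pred_n onto gt_n."""
    p = _as2d(pred_n, "pred_n").ravel()
    g = _as2d(gt_n, "gt_n").ravel()
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {pred_n.shape} vs {gt_n.shape}")
    p_mean = p.mean()
    var = np.mean((p - p_mean) ** 2)
    if var == 0:
        raise ValueError("constant prediction: affine fit is rank-deficient")
    cov = np.mean((p - p_mean) * (g - g.mean()))
    slope = cov / var
    intercept = g.mean() - slope * p_mean
    return LinearTransformParams(float(slope), float(intercept))


def nrmse(pred_t, gt_n) -> float:
    """Root of the mean squared pixel difference."""
    p = _as2d(pred_t, "pred_t")
    g = _as2d(gt_n, "gt_n")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(np.sqrt(np.mean((p - g) ** 2)))


def ssim_global(pred_t, gt_n, consts: SsimConstants = SsimConstants()) -> float:
    """Single global SSIM statistic from whole-image moments."""
    p = _as2d(pred_t, "pred_t")
    g = _as2d(gt_n, "gt_n")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    mu_p, mu_g = p.mean(), g.mean()
    var_p = np.mean((p - mu_p) ** 2)
    var_g = np.mean((g - mu_g) ** 2)
    cov = np.mean((p - mu_p) * (g - mu_g))
    cov_term = 2.0 * cov if consts.form == "corrected" else cov
    num = (2.0 * mu_p * mu_g + consts.c1) * (cov_term + consts.c2)
    den = (mu_p**2 + mu_g**2 + consts.c1) * (var_p + var_g + consts.c2)
    return float(num / den)


def pcc(pred_t, gt_n) -> float:
    """Pearson correlation coefficient over all pixels."""
    p = _as2d(pred_t, "pred_t").ravel()
    g = _as2d(gt_n, "gt_n").ravel()
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {pred_t.shape} vs {gt_n.shape}")
    sd_p = p.std()
    sd_g = g.std()
    if sd_p == 0 or sd_g == 0:
        raise ValueError("constant input: correlation undefined (zero variance)")
    value = float(np.mean((p - p.mean()) * (g - g.mean())) / (sd_p * sd_g))
    return float(np.clip(value, -1.0, 1.0))


def evaluate(
    pred,
    gt,
    params: NormalizationParams = NormalizationParams(),
    consts: SsimConstants = SsimConstants(),
    channel_names: tuple[str, ...] = (),
) -> MetricsReport:
    """Run the full chain per channel and report NRMSE / SSIM / PCC.

    Both stacks are percentile-normalized, the affine transform is
    fitted on the normalized pair and applied to the prediction, and
    the three metrics are computed between the transformed prediction
    and the normalized ground truth.
    """
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.ndim == 2:
        p = p[None]
        g = g[None]
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    n_channels = p.shape[0]
    out_nrmse = np.empty(n_channels)
    out_ssim = np.empty(n_channels)
    out_pcc = np.empty(n_channels)
    transforms: list[LinearTransformParams] = []
    for c in range(n_channels):
        try:
            pred_n = percentile_normalize(p[c], params)
            gt_n = percentile_normalize(g[c], params)
            lt = fit_linear_transform(pred_n, gt_n)
            pred_t = lt.apply(pred_n)
            out_nrmse[c] = nrmse(pred_t, gt_n)
            out_ssim[c] = ssim_global(pred_t, gt_n, consts)
            out_pcc[c] = pcc(pred_t, gt_n)
            transforms.append(lt)
        except ValueError as exc:
            raise ValueError(f"channel {c}: {exc}") from exc
    return MetricsReport(out_nrmse, out_ssim, out_pcc, transforms, tuple(channel_names))


@dataclass(frozen=True)
class TukeyBox:
    """Five-number Tukey box summary plus flagged outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def tukey_summary(values) -> TukeyBox:
    """Tukey box-and-whisker summary with the 1.5*IQR fence rule.

    The box spans the 25th-75th percentiles; whiskers reach the most
    extreme data points inside the 1.5*IQR fences; points beyond the
    whiskers are outliers.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("tukey_summary requires at least one value")
    q1 = float(np.percentile(arr, 25))
    q3 = float(np.percentile(arr, 75))
    med = float(np.median(arr))
    iqr = q3 - q1
    hi_fence = q3 + 1.5 * iqr
    lo_fence = q1 - 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    # a nonempty box always contains its quartiles, so `inside` is nonempty
    whisker_high = float(inside.max())
    whisker_low = float(inside.min())
    outliers = tuple(float(v) for v in arr[(arr > whisker_high) | (arr < whisker_low)])
    return TukeyBox(med, q1, q3, whisker_low, whisker_high, outliers)
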