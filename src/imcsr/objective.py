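"""Training objectives: combination loss and summation-regularized loss.

The combination loss is a weighted sum of mean-square error and a
structural-dissimilarity term,

    L(y_hat, y) = lam * MSE(y_hat, y) + mu * (1 - SSIM(y_hat, y)),

with defaults lam = 1 and mu = 0.1.  SSIM here is the single global
statistic used by the evaluation chain (whole-patch means, variances
and covariance), not a windowed map; since a similarity peaking at 1
cannot be minimized directly, the loss uses 1 - SSIM, which has the
same gradients as -SSIM.

The all-channel strategy adds a summation term that supervises the
pixelwise sum of the output channels with the superimposed input x:

    L_all = L(y_hat, y) + alpha * [lam * MSE(sum_c y_hat, x)
                                   + mu * (1 - SSIM(sum_c y_hat, x))],

with alpha = 0.02 by default.  The data pipeline guarantees
x == sum_c y exactly, so the term vanishes at the optimum.

All functions accept autodiff tensors (for training) or plain numpy
arrays, and return a scalar :class:`~imcsr.autograd.Tensor` (use
``float(...)`` for the value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "LossWeights",
    "mse_term",
    "ssim_term",
    "combination_loss_single",
    "combination_loss_all",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the combination and summation losses."""

    lam: float = 1.0
    mu: float = 0.1
    alpha: float = 0.02

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0 or self.alpha < 0:
            raise ValueError("loss weights must be nonnegative")


def _pair(pred, target) -> tuple[Tensor, Tensor]:
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, p.data.dtype))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return p, t


def mse_term(pred, target) -> Tensor:
    """Mean over all pixels and channels of squared differences."""
    p, t = _pair(pred, target)
    return ((p - t) ** 2.0).mean()


def _global_ssim(p: Tensor, t: Tensor, c1: float = 0.01, c2: float = 0.03) -> Tensor:
    """Global SSIM of one image pair from whole-image moments.

    Uses the conventional numerator (2*cov + c2) so identical images
    score exactly 1.
    """
    mu_p = p.mean()
    mu_t = t.mean()
    dp = p - mu_p
    dt = t - mu_t
    var_p = (dp * dp).mean()
    var_t = (dt * dt).mean()
    cov = (dp * dt).mean()
    num = (2.0 * mu_p * mu_t + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_t * mu_t + c1) * (var_p + var_t + c2)
    return num / den


def ssim_term(pred, target, c1: float = 0.01, c2: float = 0.03) -> Tensor:
    """1 minus the mean per-channel global SSIM (0 when pred == target).

    pred/target may be (H, W), (C, H, W) or (N, C, H, W); SSIM is
    computed per leading-index image and averaged.
    """
    p, t = _pair(pred, target)
    if p.ndim == 2:
        return 1.0 - _global_ssim(p, t)
    lead = int(np.prod(p.shape[:-2]))
    h, w = p.shape[-2], p.shape[-1]
    pf = p.reshape(lead, h, w)
    tf = t.reshape(lead, h, w)
    mu_p = pf.mean(axis=(1, 2), keepdims=True)
    mu_t = tf.mean(axis=(1, 2), keepdims=True)
    dp = pf - mu_p
    dt = tf - mu_t
    var_p = (dp * dp).mean(axis=(1, 2), keepdims=True)
    var_t = (dt * dt).mean(axis=(1, 2), keepdims=True)
    cov = (dp * dt).mean(axis=(1, 2), keepdims=True)
    num = (2.0 * mu_p * mu_t + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_t * mu_t + c1) * (var_p + var_t + c2)
    return 1.0 - (num / den).mean()


def combination_loss_single(pred, target, weights: LossWeights = LossWeights()) -> Tensor:
    """lam * MSE + mu * (1 - SSIM): the per-structure training objective."""
    return weights.lam * mse_term(pred, target) + weights.mu * ssim_term(pred, target)


def combination_loss_all(
    input_image, pred, target, weights: LossWeights = LossWeights()
) -> Tensor:
    """Combination loss plus the alpha-weighted summation-consistency term.

    ``pred``/``target`` are (C, H, W) or (N, C, H, W) channel stacks;
    ``input_image`` is the superimposed image with matching spatial (and
    batch) shape, supervised against the channelwise sum of ``pred``.
    """
    p, t = _pair(pred, target)
    x = input_image if isinstance(input_image, Tensor) else Tensor(
        np.asarray(input_image, p.data.dtype)
    )
    if p.ndim < 3:
        raise ValueError("combination_loss_all requires a channel stack prediction")
    channel_axis = p.ndim - 3
    pred_sum = p.sum(axis=channel_axis)
    if x.ndim == pred_sum.ndim + 1 and x.shape[channel_axis] == 1:
        x = x.reshape(pred_sum.shape)
    if x.shape != pred_sum.shape:
        raise ValueError(
            f"input shape {x.shape} incompatible with channel-summed prediction {pred_sum.shape}"
        )
    base = combination_loss_single(p, t, weights)
    summation = weights.lam * mse_term(pred_sum, x) + weights.mu * ssim_term(pred_sum, x)
    return base + weights.alpha * summation
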