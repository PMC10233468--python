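# Methods

## The separation problem

Multicolor super-resolution (SR) imaging of living cells is expensive:
every additional fluorescent channel costs acquisition time, photon
budget and — because longer-wavelength dyes resolve worse — spatial
resolution. An alternative is to label several structures with the
*same* fluorophore, acquire one grayscale SR image in which their
signals superimpose, and separate the structures computationally.
`imcsr` implements this separation as a supervised image-to-image
regression: a convolutional network maps the superimposed image x to a
per-structure channel stack ŷ whose channels should reproduce the
single-structure images y that sum to x.

Unlike segmentation, the network must predict a *continuous intensity*
for every pixel of every output channel, and the decomposition is
underdetermined wherever structures overlap. The problem is well posed
only to the extent that the structure families are morphologically
distinct; the package's phantom generator is built so this can be
verified (see below).

## Network

The model is a shallower variant of the residual channel-attention
network (RCAN) family, adapted for channel separation rather than
upsampling:

- a stem of one 3×3 convolution + GELU (shallow feature extraction);
- `n_groups` residual groups (default 5), each a chain of `n_blocks`
  residual channel-attention blocks (default 10) with an additive skip
  from the group input to the output of the last block;
- each block is conv-GELU → conv-GELU → channel attention, plus an
  additive skip from the block input;
- channel attention is squeeze-and-excitation: global average pool per
  feature channel, a GELU bottleneck of width `n_features // reduction`
  (defaults 64 and 16), expansion back, sigmoid; each channel is scaled
  by its gate in (0, 1);
- a tail conv-GELU reorganizes features, and a final convolution with
  sigmoid produces the output channels in (0, 1).

All convolutions are 3×3 and same-padded, so spatial dimensions are
preserved at every layer; there is no upsampling head and no long skip
across groups. Feature width 64 and reduction 16 follow the RCAN
convention; both are configurable. In temporal-continuity mode the
network takes 3 input channels (the frames at t−1, t, t+1) instead
of 1.

The network, its reverse-mode differentiation and the Adam optimizer
are implemented in numpy inside the package (`imcsr.autograd`). The
engine provides exactly the primitives the model needs (broadcast
arithmetic, matmul, reductions, same-padded conv2d via im2col, GELU,
sigmoid) and is validated against central finite differences in the
test suite. Everything is deterministic given the seeds; there is no
global random state.

## Losses

Training minimizes a combination of mean-square error M and structural
dissimilarity:

    L(ŷ, y) = λ·M(ŷ, y) + μ·S(ŷ, y),    λ = 1, μ = 0.1,

where S = 1 − SSIM with SSIM the *global* single-statistic form used by
the evaluation chain (whole-patch means, variances, covariance, with
c1 = 0.01, c2 = 0.03). A similarity maximized at 1 cannot be minimized
directly; 1 − SSIM has the same gradients as −SSIM and is zero at a
perfect prediction.

Two training strategies share this loss:

- **single** — one model per structure class, out_channels = 1;
- **all** — one model emitting all C channels, with an additional
  summation term

      L_all = L(ŷ, y) + α·[λ·M(Σ_c ŷ_c, x) + μ·S(Σ_c ŷ_c, x)],  α = 0.02.

The training pairs are constructed so that x equals Σ_c y_c exactly
(shared-scale normalization, below), so the summation term vanishes at
the optimum and acts purely as a consistency regularizer. Its intended
effect is suppressing "false positives" — structure content leaking
into the wrong output channel, which unbalances the channel sum.

## Training pairs

Single-structure images are augmented into patches by random cropping,
horizontal/vertical flips and rotations by multiples of 90° only —
arbitrary-angle rotation would interpolate intensities and break the
exact summation identity. One patch per class is drawn uniformly with
replacement; the patches are summed pixelwise to form the input, and
input plus all target channels are divided by one shared scalar (the
summed image's maximum). Consequences: all values lie in [0, 1]
(matching the sigmoid output range), each input's maximum is exactly 1,
and `input == Σ_c target_c` holds to machine precision — an invariant
the tests enforce on thousands of generated pairs.

Temporal-continuity (TC) samples pack the superimposed frames at
(t−1, t, t+1) as a 3-channel input and the per-class decomposition of
the middle frame as the target, scaled by the maximum over the three
superimposed frames. At inference the first/last frames are replicated
at the sequence edges so the output has as many frames as the input.

## Optimization schedule

Adam (standard moments) with batch size 3. The reference schedule
starts at learning rate 1e-4 and halves whenever the validation NRMSE
has not improved for 10,000 iterations (the improvement clock resets on
each halving); full-scale runs are ~200,000 iterations. Validation is
the mean NRMSE of the full evaluation chain over a held-out fraction of
pairs (default 5%, checked every 1,000 iterations); the checkpoint with
the best validation NRMSE is returned. Every learning rate the
schedule can emit is initial_lr · 2^(−k).

The scaled-down experiments in the test suite and acceptance script use
2,000 iterations at initial rate 1e-3 — the iteration budget is ~100×
smaller than a full-scale run, so the rate is scaled up accordingly —
with validation every 200 iterations and a 10% held-out split.

## Evaluation chain

All metrics are computed after two standardization steps:

1. **Percentile normalization** of both prediction and ground truth:
   subtract the p_low quantile and divide by the inter-quantile range,
   with p_low = 0.1 and p_high = 0.99 as quantile fractions (10th and
   99th percentiles), quantiles by linear interpolation of order
   statistics, no clipping.
2. **Linear transform**: ordinary least-squares slope/intercept fitted
   over all pixels mapping the normalized prediction onto the
   normalized ground truth, applied to the prediction only.

Then, between the transformed prediction and normalized ground truth:
NRMSE (root mean squared difference), the global SSIM described above,
and the Pearson correlation coefficient. The chain is exactly
invariant to positive affine rescalings of the raw prediction, and
`evaluate(X, X)` returns (0, 1, 1) identically — both properties are
acceptance-tested.

Two SSIM variants are exposed. The default `corrected` form uses
(2σ_xy + c2) in the numerator so identical images score exactly 1; the
`as_printed` form uses (σ_xy + c2), a variant that appears typeset in
parts of the literature but scores identical images below 1. The
`corrected` form is the default because downstream uses (box plots of
separation quality, the 1-is-perfect convention) assume it.

Batches of per-image metric values are summarized by `tukey_summary`:
box from the 25th/75th percentiles, whiskers at the most extreme data
points within 1.5×IQR of the box, points beyond flagged as outliers.

## Synthetic phantoms

The generator emulates the three morphological families the method is
demonstrated on:

- **filament** (microtubule-like): smooth random-walk tracks rendered
  as Gaussian-profile ridges; tracks are rejection-sampled to stay
  mutually separated (≥ 6 px) so the filament count is recoverable
  from the rendered image;
- **reticulum** (ER-like): the edge set of a Delaunay graph over
  uniform random nodes (longest 10% of edges dropped), rendered as
  ridges — guaranteed to contain cycles;
- **puncta** (lysosome/CCP-like): isotropic Gaussian spots with
  amplitudes in [0.6, 1.0] and centre separation ≥ 4·radius, so each
  spot is a distinct local maximum.

Ridge/spot Gaussian widths default to 2 px, standing in for ~100 nm
features at ~50 nm pixels (the SR-SIM resolution regime). A constant
background of 1% of peak avoids degenerate percentile normalization.
The imaging model applies optional Gaussian blur, then shot-like noise
(σ ∝ √intensity) plus additive Gaussian read noise. Named SNR presets
medium / high / very_high correspond to peak-signal-to-total-noise
ratios of 5, 15 and 50 — the qualitative regimes "visibly degraded",
"routine" and "clean"; the noise budget is split evenly in quadrature
between the two components. Time-lapse sequences translate a fixed
geometry by a constant drift vector per frame (direction drawn from the
seed), giving bounded frame-to-frame displacement.

What the phantoms do *not* emulate: realistic PSF/OTF physics, SIM
reconstruction artifacts, intensity nonuniformity across the field,
structure deformation and crossings at realistic densities, and
photobleaching. Passing the scaled-down experiments therefore shows
the pipeline is implemented coherently and the architecture can learn
morphology-based separation — not that it reaches publication-grade
quality on real SR acquisitions.

Class distinguishability is verified directly: a deliberately trivial
morphology rule (connected-component count and size, foreground area
fraction of the thresholded image) must identify the generating class
on ≥ 95% of seeded draws, certifying that the separation task posed to
the network is well-posed.

## Scaled-down experiments

The expensive claims are exercised at desk scale (one CPU, minutes):

- **Separation quality**: two classes (puncta vs filaments), 240 pairs
  of 64×64 patches from high-SNR phantoms, a tiny model (2 groups ×
  2 blocks × 16 features, reduction 4), 2,000 iterations. Held-out
  mean per-channel PCC must reach 0.6; measured runs reach ~0.84/0.94.
- **Summation-regularizer benefit**: the same experiment trained twice
  from identical seeds with α = 0.02 vs α = 0; the validation MSE
  between the channel sum and the input must be strictly lower with
  the regularizer (measured ~10% lower).
- **Temporal continuity**: a briefly trained 3-frame-input model must
  produce identical outputs for a static stack and temporally smooth
  outputs (mean frame-to-frame difference bounded by the input's) for
  a drifting phantom sequence.

Problem sizes were chosen so each experiment completes in minutes on a
single CPU while leaving the qualitative effect clearly resolvable;
they are stated in `tests/conftest.py` and `scripts/acceptance.py`.

## Numerical and design choices

- Float32 parameters and activations for training; float64 for all
  evaluation metrics. Metric stages agree with brute-force oracles to
  1e-8.
- The summation identity of training pairs is preserved exactly by
  construction (shared division), not re-imposed by renormalization.
- Inference normalization defaults to dividing each frame (or TC
  triple) by its maximum, matching the training-pair scale rule; the
  percentile normalization of the evaluation chain is available as an
  option.
- Plateau detection compares against the best validation NRMSE so far
  (not the last checkpoint).
- Degenerate inputs fail loudly: constant images in the metric chain,
  all-zero patch sums, too-short TC sequences, and channel/strategy
  mismatches raise `ValueError` before any computation runs.
- `step_lr` is stateless over the recorded history, so schedules can be
  replayed and audited from the training log alone.

## Known limitations

- The numpy engine is single-device and unaccelerated; full-scale
  runs (20,000 pairs of 128×128, 200,000 iterations) are supported by
  the API but impractical without hours of CPU time.
- Global SSIM (one statistic per patch) is less sensitive to local
  artifacts than windowed SSIM maps; the windowed variant is
  deliberately out of scope because the evaluation chain defines one
  SSIM and the loss reuses it for consistency.
- Phantom realism limits (above) mean measured metric values should be
  compared between configurations of this package, not against numbers
  reported for real SR-SIM data.
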