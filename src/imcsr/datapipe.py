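"""Training-pair construction for multicolor separation.

Single-structure SR images are augmented into patches (random crop,
flips, 90-degree rotations); one patch per structure class is then
summed pixelwise into a superimposed input, with the original patches
kept as the per-channel ground truth.  Input and targets share one
normalization scale (the maximum of the summed image) so that the
summation identity ``input == sum of target channels`` holds exactly in
the normalized data — the property the summation loss regularizes.

Temporal-continuity samples pack three consecutive superimposed frames
as the network input and the per-class decomposition of the middle
frame as the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phantoms import StructureImage

__all__ = [
    "PatchPair",
    "TemporalSample",
    "augment_patches",
    "make_pair",
    "build_dataset",
    "build_tc_samples",
]


@dataclass
class PatchPair:
    """One superimposed input patch with its C-channel ground truth.

    ``input`` is the pixelwise sum of the ``target`` channels, both
    divided by the shared ``scale`` (the summed image's maximum), so all
    values lie in [0, 1] and the sum identity is exact.
    """

    input: np.ndarray          # (H, W)
    target: np.ndarray         # (C, H, W)
    scale: float
    class_names: tuple[str, ...] = ()

    def input_array(self) -> np.ndarray:
        """Network input as a (C_in, H, W) stack (C_in = 1)."""
        return self.input[None, :, :]


@dataclass
class TemporalSample:
    """Three consecutive superimposed frames plus the middle frame's decomposition."""

    input_frames: np.ndarray   # (3, H, W), timepoints t-1, t, t+1
    target: np.ndarray         # (C, H, W) for the median timepoint t
    scale: float
    class_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.input_frames.shape[0] != 3:
            raise ValueError("TemporalSample requires exactly 3 input frames")

    def input_array(self) -> np.ndarray:
        return self.input_frames


def augment_patches(
    image: StructureImage | np.ndarray,
    n_patches: int,
    patch_size: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Cut seeded random patches with random flips and 90-degree rotations.

    Each patch is a verbatim sub-grid of the source up to an element of
    the dihedral group (horizontal/vertical flip, rotation by a multiple
    of 90 degrees), so intensities are never interpolated.
    """
    px = image.pixels if isinstance(image, StructureImage) else np.asarray(image)
    h, w = px.shape
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    if patch_size > h or patch_size > w:
        raise ValueError(
            f"patch_size {patch_size} exceeds image shape {(h, w)}"
        )
    rng = np.random.default_rng(seed)
    patches: list[np.ndarray] = []
    for _ in range(n_patches):
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        p = px[r : r + patch_size, c : c + patch_size]
        if rng.integers(0, 2):
            p = p[::-1, :]
        if rng.integers(0, 2):
            p = p[:, ::-1]
        p = np.rot90(p, k=int(rng.integers(0, 4)))
        patches.append(np.ascontiguousarray(p))
    return patches


def make_pair(
    patches: Sequence[np.ndarray],
    class_names: Sequence[str] = (),
    clip: bool = False,
) -> PatchPair:
    """Sum one patch per class into a superimposed input pair.

    All patches and the summed input are divided by the summed image's
    maximum (one shared scale), preserving the summation identity
    exactly while mapping values into [0, 1].
    """
    if len(patches) < 2:
        raise ValueError("make_pair requires at least two class patches")
    shapes = {p.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError(f"class patches disagree in shape: {sorted(shapes)}")
    target = np.stack([np.asarray(p, dtype=np.float64) for p in patches])
    total = target.sum(axis=0)
    scale = float(total.max())
    if scale <= 0:
        raise ValueError("all-zero patch sum; cannot form a pair")
    inp = total / scale
    tgt = target / scale
    if clip:
        inp = np.clip(inp, 0.0, 1.0)
        tgt = np.clip(tgt, 0.0, 1.0)
    return PatchPair(inp, tgt, scale, tuple(class_names))


def build_dataset(
    patch_sets: Mapping[str, Sequence[np.ndarray]],
    n_pairs: int,
    seed: int = 0,
) -> list[PatchPair]:
    """Form ``n_pairs`` pairs by uniform with-replacement patch selection.

    One patch is drawn independently per class for every pair;
    reproducible for a fixed seed.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    names = tuple(patch_sets.keys())
    for name in names:
        if len(patch_sets[name]) == 0:
            raise ValueError(f"empty patch list for class {name!r}")
    rng = np.random.default_rng(seed)
    pairs: list[PatchPair] = []
    for _ in range(n_pairs):
        chosen = [
            patch_sets[name][int(rng.integers(0, len(patch_sets[name])))]
            for name in names
        ]
        pairs.append(make_pair(chosen, class_names=names))
    return pairs


def build_tc_samples(
    series: Mapping[str, Sequence[StructureImage | np.ndarray]],
    seed: int = 0,
) -> list[TemporalSample]:
    """Assemble temporal-continuity samples from per-class time-lapse series.

    For every interior timepoint t the sample input is the cross-class
    superposition at (t-1, t, t+1) and the target the per-class stack at
    t, all divided by the sample-wide maximum of the three superimposed
    frames.
    """
    names = tuple(series.keys())
    if len(names) < 2:
        raise ValueError("need at least two class series")
    arrays = {
        k: np.stack([
            f.pixels if isinstance(f, StructureImage) else np.asarray(f, dtype=np.float64)
            for f in v
        ])
        for k, v in series.items()
    }
    lengths = {k: a.shape[0] for k, a in arrays.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"class series disagree in length: {lengths}")
    T = next(iter(lengths.values()))
    if T < 3:
        raise ValueError(f"temporal continuity requires >= 3 frames, got {T}")
    super_frames = sum(arrays.values())   # (T, H, W)
    samples: list[TemporalSample] = []
    for t in range(1, T - 1):
        triple = super_frames[t - 1 : t + 2]
        scale = float(triple.max())
        if scale <= 0:
            raise ValueError(f"all-zero superposition around timepoint {t}")
        target = np.stack([arrays[k][t] for k in names]) / scale
        samples.append(
            TemporalSample(triple / scale, target, scale, names)
        )
    return samples
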