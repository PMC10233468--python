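"""File I/O, inference and composite export.

Reads single-channel grayscale TIFFs (single- or multi-page) into float
stacks, runs a trained separation model over frames — independently in
static mode, or from sliding triples of consecutive frames in
temporal-continuity mode with edge frames replicated so the output
length matches the input — and writes ImageJ-convention multi-channel
hyperstacks plus optional additive RGB composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .evalmetrics import NormalizationParams
from .network import SeparationModel

__all__ = [
    "SeparationResult",
    "read_image_stack",
    "write_image_stack",
    "separate",
    "write_separation",
    "composite_rgb",
    "DEFAULT_COLORS",
]

#: additive channel -> RGB weights, in the conventional rendering order
#: green / magenta / yellow used for MT / ER / Lyso overlays
DEFAULT_COLORS: tuple[tuple[float, float, float], ...] = (
    (0.0, 1.0, 0.0),   # green
    (1.0, 0.0, 1.0),   # magenta
    (1.0, 1.0, 0.0),   # yellow
)


@dataclass
class SeparationResult:
    """Per-frame C-channel separation output plus provenance."""

    channels: np.ndarray                 # (T, C, H, W)
    channel_names: tuple[str, ...] = ()
    source: str = ""
    model_id: str = ""

    def __post_init__(self):
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4:
            raise ValueError("SeparationResult.channels must be (T, C, H, W)")


def read_image_stack(path) -> np.ndarray:
    """Read a grayscale TIFF into a float (T, H, W) stack, values unscaled."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected single-channel grayscale TIFF, got shape {arr.shape}; "
            "extract one channel first"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError(f"{path}: looks like an RGB image; extract one channel first")
    return arr.astype(np.float32)


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) or (H, W) float stack as an ImageJ-compatible TIFF."""
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(str(path), arr, imagej=True, metadata={"axes": "TYX"})


def separate(
    model: SeparationModel,
    frames: np.ndarray,
    tc: bool = False,
    normalize: str = "max",
    norm_params: NormalizationParams = NormalizationParams(),
    source: str = "",
    model_id: str = "",
) -> SeparationResult:
    """Separate every frame of a stack into per-structure channels.

    Static mode (``tc=False``, model in_channels=1) processes frames
    independently.  Temporal-continuity mode (``tc=True``, in_channels=3)
    separates frame t from the triple (t-1, t, t+1), replicating the
    first/last frame at the edges so the output frame count equals the
    input's.

    ``normalize`` controls the per-frame intensity scaling applied
    before the forward pass: ``"max"`` (divide by the frame maximum,
    matching the training-pair construction; default), ``"percentile"``
    (the evaluation-chain percentile normalization) or ``"none"``.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"frames must be (T, H, W), got {frames.shape}")
    expected = 3 if tc else 1
    if model.config.in_channels != expected:
        raise ValueError(
            f"{'temporal-continuity' if tc else 'static'} mode requires a model "
            f"with in_channels={expected}, got {model.config.in_channels}"
        )

    def prep(frame: np.ndarray) -> np.ndarray:
        if normalize == "max":
            m = float(frame.max())
            return frame / m if m > 0 else frame
        if normalize == "percentile":
            from .evalmetrics import percentile_normalize

            return percentile_normalize(frame, norm_params).astype(np.float32)
        if normalize == "none":
            return frame
        raise ValueError(f"unknown normalize mode {normalize!r}")

    T = frames.shape[0]
    outputs = []
    if not tc:
        for t in range(T):
            x = prep(frames[t])[None]
            outputs.append(model(x).data)
    else:
        for t in range(T):
            triple = np.stack(
                [
                    frames[max(t - 1, 0)],
                    frames[t],
                    frames[min(t + 1, T - 1)],
                ]
            )
            # one shared scale per triple keeps the three timepoints comparable
            if normalize == "max":
                m = float(triple.max())
                x = triple / m if m > 0 else triple
            else:
                x = np.stack([prep(f) for f in triple])
            outputs.append(model(x.astype(np.float32)).data)
    channels = np.stack(outputs)
    return SeparationResult(channels, source=str(source), model_id=str(model_id))


def composite_rgb(
    channels: np.ndarray,
    colors: tuple[tuple[float, float, float], ...] = DEFAULT_COLORS,
    gamma: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Additive RGB composite of a (C, H, W) channel stack, uint8.

    Each channel is normalized to [0, 1] over its own range, optionally
    gamma-corrected, multiplied by its RGB color and summed; the result
    is clipped to [0, 1] and quantized to 8 bits.
    """
    ch = np.asarray(channels, dtype=np.float64)
    if ch.ndim != 3:
        raise ValueError("composite_rgb expects a (C, H, W) stack")
    c = ch.shape[0]
    if c > len(colors):
        raise ValueError(f"{c} channels but only {len(colors)} colors")
    if gamma is None:
        gamma = (1.0,) * c
    rgb = np.zeros((ch.shape[1], ch.shape[2], 3))
    for i in range(c):
        img = ch[i]
        lo, hi = img.min(), img.max()
        norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        norm = norm ** float(gamma[i])
        for j in range(3):
            rgb[:, :, j] += colors[i][j] * norm
    return (np.clip(rgb, 0.0, 1.0) * 255).round().astype(np.uint8)


def write_separation(
    result: SeparationResult,
    out,
    composite: bool = False,
    colors: tuple[tuple[float, float, float], ...] = DEFAULT_COLORS,
    gamma: tuple[float, ...] | None = None,
) -> list[Path]:
    """Write the separation as a float TCYX hyperstack (+ optional RGB composite).

    Returns the list of files written.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written = []
    tifffile.imwrite(
        str(out),
        result.channels.astype(np.float32),
        imagej=True,
        metadata={"axes": "TCYX"},
    )
    written.append(out)
    if composite:
        frames_rgb = np.stack(
            [composite_rgb(f, colors, gamma) for f in result.channels]
        )
        comp_path = out.with_name(out.stem + "_composite.tif")
        tifffile.imwrite(str(comp_path), frames_rgb, photometric="rgb")
        written.append(comp_path)
    return written


def read_separation(path) -> np.ndarray:
    """Read back a TCYX hyperstack written by :func:`write_separation`."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a TCYX hyperstack, got shape {arr.shape}")
    return arr
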