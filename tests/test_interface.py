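"""I/O round trips, inference bookkeeping, composites, CLI dispatch."""

import numpy as np
import pytest
import tifffile

from imcsr import interface as io
from imcsr.cli import run_cli
from imcsr.network import ModelConfig, build_model

STATIC = ModelConfig(
    n_groups=1, n_blocks=1, n_features=8, reduction=4, in_channels=1, out_channels=2
)
TC = ModelConfig(
    n_groups=1, n_blocks=1, n_features=8, reduction=4, in_channels=3, out_channels=2
)


def test_stack_round_trip_float(tmp_path):
    stack = np.random.default_rng(0).random((4, 16, 16)).astype(np.float32)
    path = tmp_path / "stack.tif"
    io.write_image_stack(path, stack)
    back = io.read_image_stack(path)
    np.testing.assert_array_equal(back, stack)


def test_single_page_and_uint16_values_preserved(tmp_path):
    img = ((np.arange(64) * 1000) % 65536).astype(np.uint16).reshape(8, 8)
    path = tmp_path / "one.tif"
    tifffile.imwrite(str(path), img)
    back = io.read_image_stack(path)
    assert back.shape == (1, 8, 8)
    np.testing.assert_array_equal(back[0], img.astype(np.float32))


def test_rgb_input_rejected(tmp_path):
    rgb = np.zeros((16, 16, 3), dtype=np.uint8)
    path = tmp_path / "rgb.tif"
    tifffile.imwrite(str(path), rgb, photometric="rgb")
    with pytest.raises(ValueError, match="channel"):
        io.read_image_stack(path)


def test_separate_static_per_frame():
    model = build_model(STATIC, seed=0)
    frames = np.random.default_rng(1).random((3, 16, 16)).astype(np.float32)
    result = io.separate(model, frames, tc=False)
    assert result.channels.shape == (3, 2, 16, 16)
    # frames processed independently: single-frame call agrees
    single = io.separate(model, frames[1:2], tc=False)
    np.testing.assert_array_equal(result.channels[1], single.channels[0])


def test_separate_mode_mismatch_errors():
    static_model = build_model(STATIC, seed=0)
    tc_model = build_model(TC, seed=0)
    frames = np.zeros((2, 16, 16), np.float32)
    with pytest.raises(ValueError, match="in_channels=3"):
        io.separate(static_model, frames, tc=True)
    with pytest.raises(ValueError, match="in_channels=1"):
        io.separate(tc_model, frames, tc=False)


def test_separate_tc_edge_replication_and_bookkeeping():
    model = build_model(TC, seed=2)
    T = 10
    frames = np.random.default_rng(2).random((T, 16, 16)).astype(np.float32)
    result = io.separate(model, frames, tc=True)
    assert result.channels.shape == (T, 2, 16, 16)
    # interior frame t uses the triple (t-1, t, t+1) under a shared scale
    t = 4
    triple = frames[t - 1 : t + 2]
    expected = model((triple / triple.max()).astype(np.float32)).data
    np.testing.assert_array_equal(result.channels[t], expected)
    # edge frames replicate the first/last frame
    first = np.stack([frames[0], frames[0], frames[1]])
    expected0 = model((first / first.max()).astype(np.float32)).data
    np.testing.assert_array_equal(result.channels[0], expected0)


def test_separate_tc_single_frame_and_static_series():
    model = build_model(TC, seed=3)
    frame = np.random.default_rng(3).random((1, 16, 16)).astype(np.float32)
    result = io.separate(model, frame, tc=True)   # triple is (f, f, f)
    assert result.channels.shape == (1, 2, 16, 16)
    static = np.repeat(frame, 5, axis=0)
    result5 = io.separate(model, static, tc=True)
    for t in range(1, 5):
        np.testing.assert_array_equal(result5.channels[t], result5.channels[0])


def test_composite_color_arithmetic_and_gamma_identity():
    rng = np.random.default_rng(4)
    channels = rng.random((3, 8, 8))
    rgb = io.composite_rgb(channels)
    # oracle: normalized channels times the green/magenta/yellow weights
    norm = [(c - c.min()) / (c.max() - c.min()) for c in channels]
    expected = np.zeros((8, 8, 3))
    for weights, n in zip(io.DEFAULT_COLORS, norm):
        for j in range(3):
            expected[:, :, j] += weights[j] * n
    expected = (np.clip(expected, 0, 1) * 255).round().astype(np.uint8)
    np.testing.assert_array_equal(rgb, expected)
    np.testing.assert_array_equal(
        io.composite_rgb(channels, gamma=(1.0, 1.0, 1.0)), rgb
    )


def test_write_separation_round_trip(tmp_path):
    channels = np.random.default_rng(5).random((2, 3, 8, 8)).astype(np.float32)
    result = io.SeparationResult(channels, ("a", "b", "c"))
    out = tmp_path / "sep.tif"
    files = io.write_separation(result, out, composite=True)
    assert [f.name for f in files] == ["sep.tif", "sep_composite.tif"]
    np.testing.assert_array_equal(io.read_separation(out), channels)


def test_cli_help_and_unknown_command(capsys):
    assert run_cli(["--help"]) == 0
    assert run_cli(["no-such-command"]) != 0


def test_cli_end_to_end_smoke(tmp_path):
    """simulate -> build-dataset -> train tiny -> separate -> evaluate."""
    sim_a = tmp_path / "puncta.tif"
    sim_b = tmp_path / "filament.tif"
    assert run_cli([
        "simulate", "--structure", "puncta", "--shape", "96", "96", "--n", "10",
        "--snr", "high", "--seed", "1", "--out", str(sim_a),
    ]) == 0
    assert run_cli([
        "simulate", "--structure", "filament", "--shape", "96", "96", "--n", "4",
        "--snr", "high", "--seed", "2", "--out", str(sim_b),
    ]) == 0

    data_dir = tmp_path / "data"
    assert run_cli([
        "build-dataset", "--inputs", str(sim_a), "--inputs", str(sim_b),
        "--classes", "puncta,filament", "--n-pairs", "40",
        "--patches-per-image", "20", "--patch-size", "32", "--seed", "3",
        "--out", str(data_dir),
    ]) == 0
    assert (data_dir / "manifest.txt").exists()

    config = tmp_path / "run.yaml"
    config.write_text(
        "model: {n_groups: 1, n_blocks: 1, n_features: 8, reduction: 4,\n"
        "        in_channels: 1, out_channels: 2}\n"
        "train: {strategy: all, initial_lr: 1.0e-3, batch_size: 2,\n"
        "        max_iterations: 30, val_fraction: 0.1, val_interval: 10, seed: 4}\n"
        "loss: {lam: 1.0, mu: 0.1, alpha: 0.02}\n"
    )
    run_dir = tmp_path / "run"
    assert run_cli(["train", "--config", str(config), "--data", str(data_dir),
                    "--out", str(run_dir)]) == 0
    assert (run_dir / "model.npz").exists() and (run_dir / "history.csv").exists()

    sep_out = tmp_path / "sep.tif"
    assert run_cli([
        "separate", "--model", str(run_dir / "model.npz"), "--input", str(sim_a),
        "--composite", "--out", str(sep_out),
    ]) == 0
    assert sep_out.exists()

    # evaluate the separation against a ground-truth stack of matching shape
    gt = tmp_path / "gt.tif"
    pred_stack = io.read_separation(sep_out)
    rng = np.random.default_rng(0)
    tifffile.imwrite(str(gt), pred_stack[0] + rng.random(pred_stack[0].shape).astype(np.float32) * 0.05)
    report_csv = tmp_path / "report.csv"
    assert run_cli(["evaluate", "--pred", str(sep_out), "--gt", str(gt),
                    "--out", str(report_csv)]) == 0
    import pandas as pd

    report = pd.read_csv(report_csv)
    assert list(report.columns) == ["channel", "nrmse", "ssim", "pcc"]
    assert len(report) == 3  # two channels + mean row
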