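"""Segmentation workflow tests, including the brute-force Otsu oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import t6sspipe as tp
from t6sspipe.segmentation import (SegmentationParams, binarize_plane,
                                   exact_otsu_threshold, inverse_reshape,
                                   label_and_count, otsu_normalized_threshold,
                                   reshape_stack, segment_cells, _majority)


# ---------------------------------------------------------------------------
# reshape
# ---------------------------------------------------------------------------


def test_reshape_single_slice_is_identity():
    stack = tp.ImageStack(np.arange(4.0).reshape(2, 2, 1), 0.08, 0.2)
    assert np.array_equal(reshape_stack(stack), stack.voxels[:, :, 0])


def test_reshape_concatenates_slices_in_order():
    vox = np.zeros((2, 2, 3))
    for k in range(3):
        vox[:, :, k] = k
    plane = reshape_stack(tp.ImageStack(vox + 1.0, 0.08, 0.2))
    for k in range(3):
        assert np.all(plane[:, 2 * k:2 * (k + 1)] == k + 1)


def test_reshape_round_trip_bit_identical():
    rng = np.random.default_rng(0)
    vox = rng.random((16, 16, 13))
    plane = reshape_stack(tp.ImageStack(vox, 0.08, 0.2))
    assert np.array_equal(inverse_reshape(plane, 16), vox)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------


def brute_force_otsu_split(values: np.ndarray):
    """Oracle: scan all candidate splits, maximize between-class variance."""
    v = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(v)
    best, best_cut = -1.0, None
    n = v.size
    for i in range(len(uniq) - 1):
        cut = (uniq[i] + uniq[i + 1]) / 2.0
        lo, hi = v[v < cut], v[v >= cut]
        between = (len(lo) / n) * (len(hi) / n) * (lo.mean() - hi.mean()) ** 2
        if between > best + 1e-15:
            best, best_cut = between, cut
    return best_cut


def test_otsu_example_single_bright_pixel():
    plane = np.array([[0.0, 0.0], [0.0, 10.0]])
    assert otsu_normalized_threshold(plane) == 0.0


def test_otsu_example_two_level():
    plane = np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 9.0]])
    assert otsu_normalized_threshold(plane) == pytest.approx(1 / 9)


def test_otsu_constant_image_raises():
    with pytest.raises(tp.DegenerateHistogramError):
        otsu_normalized_threshold(np.full((2, 2), 5.0))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 255), min_size=2, max_size=16))
def test_exact_otsu_matches_brute_force_oracle(pixels):
    values = np.asarray(pixels, dtype=float)
    if np.unique(values).size < 2:
        with pytest.raises(tp.DegenerateHistogramError):
            exact_otsu_threshold(values)
        return
    thr = exact_otsu_threshold(values)
    oracle = brute_force_otsu_split(values)
    # identical class split
    assert np.array_equal(values < thr, values < oracle)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def test_binarize_all_zero_plane_is_empty():
    out = binarize_plane(np.zeros((32, 32)), 0.5)
    assert not out.any()


def test_majority_removes_isolated_pixel():
    binary = np.zeros((9, 9), dtype=bool)
    binary[4, 4] = True
    assert not _majority(binary).any()


def test_majority_keeps_solid_block_interior():
    binary = np.zeros((9, 9), dtype=bool)
    binary[2:7, 2:7] = True
    out = _majority(binary)
    assert out[3:6, 3:6].all()


def test_bright_rectangle_segments_to_one_component():
    plane = np.full((40, 60), 10.0)
    plane[10:26, 15:45] = 200.0
    t = otsu_normalized_threshold(plane)
    binary = binarize_plane(plane, t)
    mask = label_and_count(binary)
    assert mask.n_cells == 1
    # component covers the rectangle interior within +/- 2 px of the boundary
    assert binary[12:24, 17:43].all()
    assert not binary[:8, :].any() and not binary[28:, :].any()


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


def test_label_empty_is_zero_cells():
    assert label_and_count(np.zeros((8, 8), dtype=bool)).n_cells == 0


def test_label_two_separated_squares():
    binary = np.zeros((12, 12), dtype=bool)
    binary[1:5, 1:5] = True
    binary[1:5, 7:11] = True
    assert label_and_count(binary).n_cells == 2


def test_diagonal_connectivity_convention():
    binary = np.zeros((4, 4), dtype=bool)
    binary[1, 1] = True
    binary[2, 2] = True
    assert label_and_count(binary, connectivity=2).n_cells == 1
    assert label_and_count(binary, connectivity=1).n_cells == 2


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------


def test_noiseless_field_count_is_exact(small_field_truth):
    cfg, channels, truth = small_field_truth
    optics = tp.OpticsModel()
    stack = tp.render_channel(truth, channels[0], optics, seed=0, noise=False)
    seg = segment_cells(stack)
    assert seg.n_cells == len(truth.cells) == 20


def test_noisy_empty_field_counts_zero_cells():
    cfg = tp.FieldConfig(n_cells=0, width_um=10.24, height_um=10.24)
    truth = tp.sample_field(cfg, [], seed=0)
    stack = tp.render_channel(truth, tp.mask_channel(), tp.OpticsModel(n_z=3),
                              seed=1)
    assert segment_cells(stack).n_cells == 0


def test_count_robust_to_noise_seed(small_field_truth):
    cfg, channels, truth = small_field_truth
    optics = tp.OpticsModel()
    counts = []
    for seed in (11, 12):
        stack = tp.render_channel(truth, channels[0], optics, seed=seed)
        counts.append(segment_cells(stack).n_cells)
    assert abs(counts[0] - counts[1]) <= 1


def test_count_error_within_5pct_at_default_snr():
    """|n_cells - truth| / truth <= 5% across seeded default-SNR fields."""
    total_err = 0
    total = 0
    optics = tp.OpticsModel()
    for seed in range(6):
        cfg = tp.FieldConfig(n_cells=40, width_um=28.0, height_um=28.0)
        truth = tp.sample_field(cfg, [tp.mask_channel()], seed=seed)
        stack = tp.render_channel(truth, tp.mask_channel(), optics,
                                  seed=100 + seed)
        n = segment_cells(stack).n_cells
        total_err += abs(n - 40)
        total += 40
    assert total_err / total <= 0.05


def test_segmentation_is_deterministic(small_field_stacks):
    _, _, _, stacks = small_field_stacks
    m1 = segment_cells(stacks["gfp"]).mask.labels
    m2 = segment_cells(stacks["gfp"]).mask.labels
    assert np.array_equal(m1, m2)


def test_plane_label_mode_counts_slice_appearances(small_field_stacks):
    """Plane labeling counts each cell once per z slice it binarizes in."""
    _, truth, _, stacks = small_field_stacks
    params = SegmentationParams(label_mode="plane")
    n_plane = segment_cells(stacks["gfp"], params).n_cells
    n_3d = segment_cells(stacks["gfp"]).n_cells
    assert n_3d == len(truth.cells)
    assert n_plane > n_3d  # each cell spans several z slices
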