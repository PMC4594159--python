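"""Generator tests: placement constraints, calibration, forward-model physics."""

import numpy as np
import pytest

import t6sspipe as tp
from t6sspipe.simulate import boundary_distance, pmf_mean


def test_empty_field_has_no_cells_and_no_foci():
    cfg = tp.FieldConfig(n_cells=0)
    truth = tp.sample_field(cfg, [tp.tssb_channel()], seed=0)
    assert truth.cells == []
    assert truth.foci["tssb"] == []


def test_isolated_layout_respects_min_separation():
    cfg = tp.FieldConfig(n_cells=50, min_separation_um=1.0)
    truth = tp.sample_field(cfg, [], seed=7)
    cells = truth.cells
    assert len(cells) == 50
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            assert boundary_distance(cells[i], cells[j]) >= 1.0 - 1e-9


def test_microcolony_layout_allows_touching_but_not_overlap():
    cfg = tp.FieldConfig(n_cells=30, layout="microcolony", overlap_tol_um=0.2)
    truth = tp.sample_field(cfg, [], seed=11)
    assert len(truth.cells) == 30
    for i in range(30):
        for j in range(i + 1, 30):
            assert boundary_distance(truth.cells[i], truth.cells[j]) >= -0.2 - 1e-9


def test_crowded_field_raises():
    cfg = tp.FieldConfig(n_cells=500, width_um=10.0, height_um=10.0,
                         max_retries=200)
    with pytest.raises(tp.FieldTooCrowdedError):
        tp.sample_field(cfg, [], seed=0)


def test_focus_counts_match_pmf_expectation():
    """Empirical mean focus count over many cells is within 3 SE of the pmf mean."""
    pmf = tp.TSSB_POPULATION_PMF
    expected = pmf_mean(pmf)  # direct summation over the pmf
    var = sum(p * (k - expected) ** 2 for k, p in enumerate(pmf))
    counts = []
    cfg = tp.FieldConfig(n_cells=500, width_um=102.4, height_um=102.4)
    for seed in range(20):  # 10,000 cells total
        truth = tp.sample_field(cfg, [tp.tssb_channel()], seed=seed)
        counts.extend(truth.counts_per_cell("tssb").values())
    counts = np.asarray(counts)
    assert counts.size == 10_000
    se = np.sqrt(var / counts.size)
    assert abs(counts.mean() - expected) < 3 * se


def test_fraction_with_focus_matches_pmf_binomial_ci():
    """Fraction of cells with >=1 true focus converges to 1 - pmf[0]."""
    pmf = tp.TSSB_POPULATION_PMF
    p = 1.0 - pmf[0]
    counts = []
    cfg = tp.FieldConfig(n_cells=500, width_um=102.4, height_um=102.4)
    for seed in range(20):
        truth = tp.sample_field(cfg, [tp.tssb_channel()], seed=seed)
        counts.extend(truth.counts_per_cell("tssb").values())
    frac = np.mean(np.asarray(counts) >= 1)
    se = np.sqrt(p * (1 - p) / len(counts))
    assert abs(frac - p) < 3 * se


def test_every_true_focus_lies_inside_its_cell(small_field_truth):
    cfg, _, truth = small_field_truth
    cells = {c.id: c for c in truth.cells}
    for foci in truth.foci.values():
        for f in foci:
            if f.cell_id is None:
                continue
            cell = cells[f.cell_id]
            assert cell.contains(f.x, f.y, f.z - cfg.z_mid_um)


def test_same_channel_foci_are_resolvable(small_field_truth):
    """Hard-core constraint: same-cell foci sit >= 0.272 um apart."""
    _, _, truth = small_field_truth
    by_cell = {}
    for f in truth.foci["tssb"]:
        by_cell.setdefault(f.cell_id, []).append((f.x, f.y))
    for pts in by_cell.values():
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                assert d >= 0.272 - 1e-9


def test_seeded_reproducibility_bit_identical():
    cfg = tp.FieldConfig(n_cells=5, width_um=10.24, height_um=10.24)
    ch = tp.tssb_channel()
    optics = tp.OpticsModel(n_z=3)
    t1 = tp.sample_field(cfg, [ch], seed=42)
    t2 = tp.sample_field(cfg, [ch], seed=42)
    assert [c.center for c in t1.cells] == [c.center for c in t2.cells]
    assert [(f.x, f.y, f.z) for f in t1.foci["tssb"]] == \
        [(f.x, f.y, f.z) for f in t2.foci["tssb"]]
    img1 = tp.render_channel(t1, ch, optics, seed=9)
    img2 = tp.render_channel(t2, ch, optics, seed=9)
    assert np.array_equal(img1.voxels, img2.voxels)
    img3 = tp.render_channel(t1, ch, optics, seed=10)
    assert not np.array_equal(img1.voxels, img3.voxels)


def test_zero_signal_render_is_constant_offset():
    cfg = tp.FieldConfig(n_cells=3, width_um=10.24, height_um=10.24)
    truth = tp.sample_field(cfg, [], seed=1)
    dark = tp.ChannelModel(name="dark", mode="foci_only", focus_count_pmf=(1.0,),
                           diffuse_intensity=0.0, focus_intensity=0.0)
    optics = tp.OpticsModel(n_z=3, read_noise_sd=0.0, offset=100.0)
    img = tp.render_channel(truth, dark, optics, seed=0)
    assert np.all(img.voxels == 100.0)


def test_single_focus_noiseless_peak_within_one_pixel():
    cfg = tp.FieldConfig(n_cells=1, width_um=10.24, height_um=10.24)
    truth = tp.sample_field(cfg, [], seed=3)
    cell = truth.cells[0]
    from t6sspipe.simulate import TrueFocus
    truth.foci["spot"] = [TrueFocus(0, "spot", cell.id, cell.center[0],
                                    cell.center[1], cfg.z_mid_um)]
    ch = tp.ChannelModel(name="spot", mode="foci_only", focus_count_pmf=(1.0,),
                         diffuse_intensity=0.0, focus_intensity=5000.0)
    optics = tp.OpticsModel(n_z=5)
    img = tp.render_channel(truth, ch, optics, seed=0, noise=False)
    proj = img.max_projection()
    r, c = np.unravel_index(np.argmax(proj), proj.shape)
    ps = optics.pixel_size_um
    assert abs(c - cell.center[0] / ps) <= 1.0
    assert abs(r - cell.center[1] / ps) <= 1.0


def test_forward_model_linear_in_focus_intensity():
    """Doubling focus_intensity doubles the expected background-subtracted
    integrated signal in a 7x7 window (Monte-Carlo average over seeds)."""
    cfg = tp.FieldConfig(n_cells=1, width_um=5.12, height_um=5.12,
                         z_mid_um=0.4, margin_um=0.4,
                         cell_length_um=(2.0, 2.0))
    truth = tp.sample_field(cfg, [], seed=5)
    cell = truth.cells[0]
    from t6sspipe.simulate import TrueFocus
    truth.foci["spot"] = [TrueFocus(0, "spot", cell.id, cell.center[0],
                                    cell.center[1], cfg.z_mid_um)]
    optics = tp.OpticsModel(n_z=3)
    ps = optics.pixel_size_um
    r0, c0 = int(round(cell.center[1] / ps)), int(round(cell.center[0] / ps))

    def mean_signal(intensity: float) -> float:
        ch = tp.ChannelModel(name="spot", mode="foci_only",
                             focus_count_pmf=(1.0,), diffuse_intensity=0.0,
                             focus_intensity=intensity)
        sums = []
        for seed in range(120):
            img = tp.render_channel(truth, ch, optics, seed=seed)
            # a single plane: the z maximum-projection is not linear
            win = img.plane(optics.n_z // 2)[r0 - 3:r0 + 4, c0 - 3:c0 + 4]
            sums.append(win.sum() - 49 * optics.offset)
        return float(np.mean(sums))

    s1, s2 = mean_signal(1000.0), mean_signal(2000.0)
    assert s2 == pytest.approx(2 * s1, rel=0.05)


class TestTimelapse:
    def test_fixed_persistence_and_zero_ramps_give_exact_durations(self):
        cfg = tp.FieldConfig(n_cells=5, width_um=10.24, height_um=10.24)
        kin = tp.KineticsConfig(t_assemble_s=1e-9, t_disassemble_s=1e-9,
                                persistence="fixed", persistence_mean_s=60.0,
                                event_rate_per_cell_per_s=0.01)
        optics = tp.OpticsModel(n_z=1)
        _, truth = tp.simulate_timelapse(cfg, tp.tssb_channel(), optics, kin,
                                         10.0, 60.0, seed=2, noise=False)
        assert truth.events
        for ev in truth.events:
            assert ev.t_disappear - ev.t_appear == pytest.approx(60.0, abs=1e-6)

    def test_zero_event_rate_frames_identical_without_noise(self):
        cfg = tp.FieldConfig(n_cells=5, width_um=10.24, height_um=10.24)
        kin = tp.KineticsConfig(event_rate_per_cell_per_s=0.0)
        optics = tp.OpticsModel(n_z=1)
        frames, truth = tp.simulate_timelapse(cfg, tp.tssb_channel(), optics,
                                              kin, 10.0, 50.0, seed=2,
                                              noise=False)
        assert truth.events == []
        for f in frames[1:]:
            assert np.array_equal(f.voxels, frames[0].voxels)

    def test_default_kinetics_movie_has_persistent_focus(self):
        """With defaults over 4 min at 10 s frames, some focus is visible in
        >= 3 consecutive frames (checked against the event log)."""
        cfg = tp.FieldConfig(n_cells=20, width_um=20.48, height_um=20.48)
        kin = tp.KineticsConfig()
        optics = tp.OpticsModel(n_z=1)
        frames, truth = tp.simulate_timelapse(cfg, tp.tssb_channel(), optics,
                                              kin, 10.0, 240.0, seed=4)
        spans = []
        for ev in truth.events:
            visible = [k for k in range(len(frames))
                       if ev.t_appear < k * 10.0 < ev.t_disappear]
            if visible:
                spans.append(len(visible))
        assert max(spans) >= 3
        # and the rendered movie shows it: detections in >=3 consecutive frames
        from t6sspipe.detection import detect_foci
        n_det = [len(detect_foci(f.max_projection())) for f in frames]
        runs = 0
        best = 0
        for n in n_det:
            runs = runs + 1 if n > 0 else 0
            best = max(best, runs)
        assert best >= 3

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(Exception):
            tp.KineticsConfig(t_assemble_s=-1.0)
        cfg = tp.FieldConfig(n_cells=1, width_um=10.24, height_um=10.24)
        with pytest.raises(ValueError):
            tp.simulate_timelapse(cfg, tp.tssb_channel(), tp.OpticsModel(n_z=1),
                                  tp.KineticsConfig(), 0.0, 100.0, seed=0)


def test_invalid_pmf_rejected():
    with pytest.raises(Exception):
        tp.ChannelModel(name="x", focus_count_pmf=(0.5, 0.4))
    with pytest.raises(Exception):
        tp.ChannelModel(name="x", focus_count_pmf=(0.5, 0.5),
                        focus_count_mean=1.0)
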