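"""Sharpness features, SVM classifier, and region/slide scoring."""

import numpy as np
import pytest

import cytofocus as cf
from cytofocus.sharpness import (CellImage, ScoreConfig, cells_vs_score_stability,
                                 detect_cells, exclusion_filter, extract_features,
                                 features_matrix, partition_regions, score_slide,
                                 train_model)
from cytofocus.synthetic import make_cell_tile, render_overview
from cytofocus.workflow import ScannedSlide


def test_partition_exact_division():
    tiles = partition_regions((4000.0, 4000.0))
    assert len(tiles) == 16
    assert all(w == 1000.0 and h == 1000.0 for _, _, w, h in tiles)


def test_partition_remainder_and_area_law():
    tiles = partition_regions((4001.0, 4000.0))
    widths = {round(w, 6) for _, _, w, _ in tiles}
    assert max(widths) - min(widths) <= 1.0
    assert sum(w * h for _, _, w, h in tiles) == pytest.approx(4001.0 * 4000.0)


def test_partition_rejects_degenerate_bounds():
    with pytest.raises(ValueError):
        partition_regions((0.0, 100.0))


def test_detect_cells_blank_region_empty():
    blank = np.full((64, 64, 3), 235, dtype=np.uint8)
    assert detect_cells(blank, scale=8.0, pixel_size_um=0.46) == []


def test_detect_cells_caps_and_is_deterministic(small_slide):
    overview = render_overview(small_slide, scale=8.0)
    kwargs = dict(scale=8.0, pixel_size_um=small_slide.pixel_size_um,
                  max_cells=20)
    a = detect_cells(overview, rng=np.random.default_rng(4), **kwargs)
    b = detect_cells(overview, rng=np.random.default_rng(4), **kwargs)
    assert len(a) == 20
    assert a == b


def test_detect_cells_rejects_achromatic_objects():
    img = np.full((64, 64, 3), 235, dtype=np.uint8)
    img[20:40, 20:40] = (100, 100, 100)   # gray debris
    assert detect_cells(img, scale=8.0, pixel_size_um=0.46) == []


def _cell(area):
    return CellImage(np.zeros((1, 1, 3), dtype=np.uint8), (0, 0), area_px=area)


def test_exclusion_filter_boundaries():
    kept = exclusion_filter([_cell(4_000_001), _cell(1_000), _cell(199),
                             _cell(200), _cell(4_000_000)])
    assert [c.area_px for c in kept] == [1_000, 200, 4_000_000]


def test_exclusion_filter_resolution_scaling():
    # at half resolution every area shrinks 4x, thresholds follow
    kept = exclusion_filter([_cell(1_000_001), _cell(51)], resolution_factor=2.0)
    assert [c.area_px for c in kept] == [51]


def test_constant_tile_features_degenerate():
    tile = np.full((64, 64, 3), 200, dtype=np.uint8)
    f = extract_features(CellImage(tile, (0, 0)))
    assert f.edge_count == 0 and f.gradient_score == 0.0
    assert f.diff_blurred == 0.0 and f.blur_metric == 1.0


def test_checkerboard_diff_blurred_positive():
    tile = np.zeros((64, 64, 3), dtype=np.uint8)
    tile[::2, ::2] = 255
    f = extract_features(CellImage(tile, (0, 0)))
    assert f.diff_blurred > 0.0


def test_features_discriminate_focus():
    sharp = extract_features(CellImage(make_cell_tile(3, 0.0), (0, 0)))
    blurred = extract_features(CellImage(make_cell_tile(3, 10.0), (0, 0)))
    assert sharp.edge_count > blurred.edge_count
    assert sharp.gradient_score > blurred.gradient_score
    assert sharp.diff_blurred > blurred.diff_blurred
    assert sharp.blur_metric < blurred.blur_metric


def test_train_model_rejects_single_class():
    cells = [CellImage(make_cell_tile(i, 0.0), (0, 0), true_label=1)
             for i in range(4)]
    with pytest.raises(ValueError):
        train_model(cells)


def test_train_model_deterministic(sharpness_model):
    again = train_model(cf.make_training_set(60, seed=11), seed=11)
    probe = features_matrix(cf.make_training_set(10, seed=77))
    np.testing.assert_array_equal(sharpness_model.predict(probe),
                                  again.predict(probe))


def test_model_round_trip_and_config_guard(tmp_path, sharpness_model):
    from cytofocus.sharpness import FeatureConfig, SharpnessModel
    path = tmp_path / "model.bundle"
    sharpness_model.save(path)
    back = SharpnessModel.load(path)
    probe = features_matrix(cf.make_training_set(5, seed=9))
    np.testing.assert_array_equal(back.predict(probe),
                                  sharpness_model.predict(probe))
    with pytest.raises(ValueError):
        SharpnessModel.load(path, expect_feature_config=FeatureConfig(blur_sigma=3.0))


def test_perfectly_focused_scan_scores_high(small_slide, sharpness_model):
    """Scanning exactly at the true surface: nearly every cell is in focus."""
    scanned = ScannedSlide(small_slide, small_slide.surface)
    report = score_slide(scanned, sharpness_model, seed=0)
    assert report.slide_score >= 90.0
    scored = [s for s in report.region_scores if s is not None]
    assert report.slide_score == pytest.approx(float(np.mean(scored)))
    assert all(0.0 <= s <= 100.0 for s in scored)


def test_badly_focused_scan_scores_low(small_slide, sharpness_model):
    scanned = ScannedSlide(small_slide,
                           lambda x, y: small_slide.surface(x, y) + 12.0)
    report = score_slide(scanned, sharpness_model, seed=0)
    assert report.slide_score < 50.0
    assert len(report.out_of_focus_regions) >= 12


def test_empty_slide_reports_no_data(sharpness_model):
    empty = cf.make_virtual_slide(n_cells=0, dust_density_per_mm2=0.0,
                                  width_um=500, height_um=500, seed=1)
    report = score_slide(ScannedSlide(empty, 100.0), sharpness_model, seed=0)
    assert report.no_data and report.slide_score is None


def test_score_stability_improves_with_cell_count(sharpness_model):
    """Sampling spread shrinks as more cells are examined per region."""
    slide = cf.make_virtual_slide(width_um=700, height_um=700, n_cells=260,
                                  seed=13)
    # half-defocused scan: region scores sit mid-range, so sampling matters
    scanned = ScannedSlide(slide, lambda x, y: slide.surface(x, y)
                           + (4.0 if x > 350 else 0.0))
    out = cells_vs_score_stability(scanned, sharpness_model,
                                   cell_counts=[3, 30], runs=6, seed=3)
    assert out[30][1] <= out[3][1]


def test_single_run_stability_sd_zero(small_slide, sharpness_model):
    scanned = ScannedSlide(small_slide, small_slide.surface)
    out = cells_vs_score_stability(scanned, sharpness_model,
                                   cell_counts=[10], runs=1, seed=1)
    assert out[10][1] == 0.0
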