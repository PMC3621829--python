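"""Virtual-slide generator: determinism, geometry, defocus optics."""

import numpy as np
import pytest
from scipy.ndimage import laplace

import cytofocus as cf
from cytofocus.focus_filters import FocusPointImage, edge_filter
from cytofocus.synthetic import (ConfigurationError, DefocusModel, SlideConfig,
                                 StainPalette, make_cell_tile, make_focus_strip,
                                 make_macro_image, make_training_set,
                                 make_virtual_slide, render_at)


def test_identical_seed_gives_bit_identical_slide():
    a = make_virtual_slide(n_cells=500, seed=7, width_um=800, height_um=800)
    b = make_virtual_slide(n_cells=500, seed=7, width_um=800, height_um=800)
    assert a.cell_records == b.cell_records
    assert a.dust_records == b.dust_records
    np.testing.assert_array_equal(a.surface.control_grid, b.surface.control_grid)


def test_identical_seed_gives_bit_identical_render():
    a = make_virtual_slide(n_cells=80, seed=3, width_um=500, height_um=500)
    b = make_virtual_slide(n_cells=80, seed=3, width_um=500, height_um=500)
    ra = render_at(a, (100, 100, 150, 150), a.surface)
    rb = render_at(b, (100, 100, 150, 150), b.surface)
    np.testing.assert_array_equal(ra, rb)


def test_empty_slide_renders_pure_background():
    slide = make_virtual_slide(n_cells=0, dust_density_per_mm2=0.0, seed=1,
                               width_um=400, height_um=400)
    img = render_at(slide, (0, 0, 400, 400), 100.0)
    assert np.all(img == slide.config.palette.background_value)


def test_surface_range_matches_requested():
    slide = make_virtual_slide(z_range_um=29.5, seed=1, n_cells=10,
                               width_um=500, height_um=500)
    assert slide.surface.peak_to_peak == pytest.approx(29.5, rel=0.05)


def test_flat_surface_when_zero_range():
    slide = make_virtual_slide(z_range_um=0.0, seed=1, n_cells=10,
                               width_um=500, height_um=500)
    assert slide.surface.peak_to_peak == 0.0


def test_cells_confined_to_circle():
    slide = make_virtual_slide(n_cells=300, seed=9, width_um=900, height_um=900)
    assert all(slide.in_circle(c.x_um, c.y_um) for c in slide.cell_records)


def test_dust_plane_disjoint_from_cell_layer():
    slide = make_virtual_slide(n_cells=50, z_range_um=20.0,
                               dust_layer_offset_um=60.0, seed=2,
                               width_um=500, height_um=500)
    assert slide.dust_z_um < slide.surface.z_min


def test_defocus_sigma_zero_at_focus_and_monotone():
    model = DefocusModel()
    assert model.sigma(0.0) == 0.0
    sigmas = [model.sigma(dz) for dz in np.linspace(0, 40, 30)]
    assert all(b >= a for a, b in zip(sigmas, sigmas[1:]))
    # linear regime: strictly larger at 10 um than at 5 um
    assert model.sigma(5.0) < model.sigma(10.0) <= model.max_sigma


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        make_virtual_slide(width_um=-5, seed=0)
    with pytest.raises(ConfigurationError):
        make_virtual_slide(n_cells=-1, seed=0)
    with pytest.raises(ConfigurationError):
        SlideConfig(z_range_um=-2.0)


def test_render_region_outside_slide_errors(small_slide):
    with pytest.raises(ValueError):
        render_at(small_slide, (5000, 5000, 50, 50), 100.0)


def test_focus_strip_shape_and_blank_background():
    slide = make_virtual_slide(n_cells=0, dust_density_per_mm2=0.0, seed=1,
                               width_um=600, height_um=200)
    strip = make_focus_strip(slide, (300, 100), 100.0, strip_shape=(512, 64))
    assert strip.shape == (64, 512, 3)
    assert np.all(strip == slide.config.palette.background_value)


def test_defocused_strip_has_fewer_edges_than_focused(small_slide):
    cell = small_slide.cell_records[0]
    point = (cell.x_um, cell.y_um)
    z = float(small_slide.surface(*point))
    sharp = make_focus_strip(small_slide, point, z)
    blurred = make_focus_strip(small_slide, point, z + 15.0)
    _, n_sharp = edge_filter(FocusPointImage(sharp))
    _, n_blur = edge_filter(FocusPointImage(blurred))
    assert n_sharp > n_blur


def test_focus_on_dust_plane_sharpens_dust_blurs_cells(dusty_sparse_slide):
    slide = dusty_sparse_slide
    dust = slide.dust_records[0]
    region = (dust.x_um - 30, dust.y_um - 30, 60, 60)
    region = (min(max(region[0], 0), slide.width_um - 60),
              min(max(region[1], 0), slide.height_um - 60), 60, 60)
    on_dust = render_at(slide, region, slide.dust_z_um)
    on_cells = render_at(slide, region, float(slide.surface(dust.x_um, dust.y_um)))
    # the dust speck is crisp only when focused at the dust plane
    lap_dust = np.var(laplace(on_dust.astype(float).mean(axis=2)))
    lap_cell = np.var(laplace(on_cells.astype(float).mean(axis=2)))
    assert lap_dust > lap_cell


def test_laplacian_variance_collapses_with_defocus():
    """Defocus destroys high-frequency content: the Laplacian variance drops
    by an order of magnitude within one grid step and stays at the 8-bit
    quantization floor thereafter (below that floor, ordering is noise)."""
    for seed in (2, 5):
        tile_var = []
        for dz in range(0, 16, 2):
            tile = make_cell_tile(seed, float(dz), tile_px=128)
            gray = tile.astype(float).mean(axis=2)
            tile_var.append(float(np.var(laplace(gray))))
        assert tile_var[1] < tile_var[0] / 10
        assert all(v <= tile_var[0] / 10 for v in tile_var[1:])


def test_training_set_counts_and_balance():
    images = make_training_set(5, seed=3)
    assert len(images) == 10
    labels = [img.true_label for img in images]
    assert labels.count(1) == labels.count(0) == 5


def test_training_set_single_pair():
    images = make_training_set(1, seed=3)
    assert sorted(img.true_label for img in images) == [0, 1]


def test_training_set_deterministic():
    a = make_training_set(4, seed=8)
    b = make_training_set(4, seed=8)
    assert [i.true_label for i in a] == [i.true_label for i in b]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.pixels, y.pixels)


def test_palette_validation():
    with pytest.raises(ConfigurationError):
        StainPalette(nucleus_hue_range=(0.5, 1.5))
    with pytest.raises(ConfigurationError):
        StainPalette(background_value=300)


def test_macro_image_has_dark_border_marks(small_slide):
    macro = make_macro_image(small_slide)
    gray = macro.astype(float).mean(axis=2)
    assert (gray < 0.1 * 255).sum() > 0


def test_slide_json_round_trip(tmp_path, small_slide):
    path = tmp_path / "slide.json"
    small_slide.to_json(path)
    back = cf.VirtualSlide.from_json(path)
    assert back.cell_records == small_slide.cell_records
    assert back.dust_z_um == small_slide.dust_z_um
    np.testing.assert_array_equal(back.surface.control_grid,
                                  small_slide.surface.control_grid)
    ra = render_at(back, (100, 100, 80, 80), back.surface)
    rb = render_at(small_slide, (100, 100, 80, 80), small_slide.surface)
    np.testing.assert_array_equal(ra, rb)
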