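"""Closed-loop scan control against the virtual scanner."""

import numpy as np
import pytest

import cytofocus as cf
from cytofocus.workflow import (STATUS_COMPLETED, STATUS_NOT_SCANNABLE,
                                CellCircle, CircleNotFoundError, FocusPoint,
                                ScannedSlide, VirtualScanner, WorkflowConfig,
                                build_focus_map, detect_cell_circle, focus_round,
                                place_focus_points, repeat_scan_cv, run_workflow)


# --------------------------------------------------------------------------
# cell-circle detection


def test_circle_detected_near_truth(small_slide):
    scanner = VirtualScanner(small_slide, seed=1)
    circle = detect_cell_circle(scanner.macro_image(),
                                pixel_size_um=scanner.macro_pixel_size_um,
                                diameter_um=small_slide.circle_diameter_um)
    err_px = max(abs(circle.center_um[0] - small_slide.circle_center_um[0]),
                 abs(circle.center_um[1] - small_slide.circle_center_um[1])
                 ) / scanner.macro_pixel_size_um
    assert err_px <= 2.0
    assert circle.diameter_um == small_slide.circle_diameter_um


def test_blank_macro_raises_circle_not_found():
    blank = np.full((128, 128, 3), 235, dtype=np.uint8)
    with pytest.raises(CircleNotFoundError):
        detect_cell_circle(blank, pixel_size_um=7.36, diameter_um=800.0)


def test_circle_detection_translation_equivariant():
    def frame(offset):
        img = np.full((200, 200, 3), 235, dtype=np.uint8)
        r0, c0 = 40 + offset, 50 + offset
        img[r0:r0 + 3, c0:c0 + 101] = 0
        img[r0 + 100:r0 + 103, c0:c0 + 101] = 0
        img[r0:r0 + 103, c0:c0 + 3] = 0
        img[r0:r0 + 103, c0 + 98:c0 + 101] = 0
        return img

    a = detect_cell_circle(frame(0), pixel_size_um=1.0, diameter_um=90.0)
    b = detect_cell_circle(frame(20), pixel_size_um=1.0, diameter_um=90.0)
    assert b.center_um[0] - a.center_um[0] == pytest.approx(20.0, abs=0.1)
    assert b.center_um[1] - a.center_um[1] == pytest.approx(20.0, abs=0.1)


# --------------------------------------------------------------------------
# focus-point placement


def test_initial_layout_inside_circle(rng):
    circle = CellCircle((500.0, 500.0), 800.0)
    pts = place_focus_points(circle, 12, rng=rng)
    assert len(pts) == 12
    assert all(circle.contains(x, y) for x, y in pts)
    assert max(np.hypot(x - 500, y - 500) for x, y in pts) <= 400.0


def test_bad_region_placement_constrained(rng):
    circle = CellCircle((500.0, 500.0), 800.0)
    quadrant = [(500.0, 500.0, 250.0, 250.0)]
    pts = place_focus_points(circle, 12, bad_regions=quadrant, rng=rng)
    assert len(pts) == 12
    assert all(500 <= x <= 750 and 500 <= y <= 750 for x, y in pts)
    assert all(circle.contains(x, y) for x, y in pts)


def test_no_duplicates_with_existing(rng):
    circle = CellCircle((500.0, 500.0), 800.0)
    existing = place_focus_points(circle, 12, rng=rng)
    extra = place_focus_points(circle, 12, existing=existing, rng=rng)
    for x, y in extra:
        assert all(np.hypot(x - ex, y - ey) >= 5.0 for ex, ey in existing)


# --------------------------------------------------------------------------
# focus map


def test_three_coplanar_points_reproduce_plane():
    pts = [FocusPoint(0.0, 0.0, 10.0), FocusPoint(100.0, 0.0, 20.0),
           FocusPoint(0.0, 100.0, 30.0)]
    fmap = build_focus_map(pts)
    # plane z = 10 + 0.1x + 0.2y, checked at an interior point
    assert fmap(30.0, 30.0) == pytest.approx(10 + 3 + 6, abs=1e-9)
    for p in pts:
        assert fmap(p.x_um, p.y_um) == pytest.approx(p.z_um, abs=1e-9)


def test_single_point_gives_constant_surface():
    fmap = build_focus_map([FocusPoint(50.0, 50.0, 42.0)])
    assert fmap(0.0, 0.0) == 42.0
    assert fmap(999.0, -10.0) == 42.0


def test_map_error_shrinks_with_more_points(small_slide, rng):
    circle = CellCircle(small_slide.circle_center_um,
                        small_slide.circle_diameter_um)
    gx, gy = np.meshgrid(np.linspace(150, 850, 20), np.linspace(150, 850, 20))
    inside = ((gx - 500) ** 2 + (gy - 500) ** 2
              <= (small_slide.circle_diameter_um / 2) ** 2)

    def rmse(n):
        errs = []
        for _ in range(5):
            pts = place_focus_points(circle, n, rng=rng)
            fmap = build_focus_map([
                FocusPoint(x, y, float(small_slide.surface(x, y)))
                for x, y in pts])
            z_true = small_slide.surface(gx[inside], gy[inside])
            errs.append(np.sqrt(np.mean((z_true - fmap(gx[inside], gy[inside])) ** 2)))
        return float(np.mean(errs))

    assert rmse(30) < rmse(5)


def test_empty_point_list_rejected():
    with pytest.raises(ValueError):
        build_focus_map([])


# --------------------------------------------------------------------------
# focus rounds


def test_blank_glass_points_all_invalid():
    empty = cf.make_virtual_slide(n_cells=0, dust_density_per_mm2=0.0,
                                  width_um=600, height_um=600, seed=3)
    scanner = VirtualScanner(empty, seed=1)
    pts = [(150.0, 150.0), (300.0, 300.0), (450.0, 450.0)]
    assert focus_round(scanner, pts) == []


def test_cell_rich_points_all_valid(small_slide):
    scanner = VirtualScanner(small_slide, seed=1)
    cells = small_slide.cell_records[:6]
    pts = [(c.x_um, c.y_um) for c in cells]
    valid = focus_round(scanner, pts)
    assert len(valid) == 6


def test_dust_locked_points_excluded(dusty_sparse_slide):
    scanner = VirtualScanner(dusty_sparse_slide, seed=13)
    circle = CellCircle(dusty_sparse_slide.circle_center_um,
                        dusty_sparse_slide.circle_diameter_um)
    pts = place_focus_points(circle, 60, rng=np.random.default_rng(1))
    raw = scanner.focus_at(pts)
    dust_z = dusty_sparse_slide.dust_z_um
    assert any(abs(z - dust_z) < 5 for z, _ in raw), "dust capture should occur"
    scanner.reseed(13)
    valid = focus_round(scanner, pts)
    assert all(abs(p.z_um - dust_z) >= 5 for p in valid)


# --------------------------------------------------------------------------
# full workflow


class _StubScanner:
    """Scanner double with a scripted number of valid probes per call."""

    def __init__(self, slide, valid_sequence):
        self.slide = slide
        self._inner = VirtualScanner(slide, seed=1, z_noise_um=0.0)
        self.valid_sequence = list(valid_sequence)
        self.calls = 0

    def macro_image(self):
        return self._inner.macro_image()

    @property
    def macro_pixel_size_um(self):
        return self._inner.macro_pixel_size_um

    def focus_at(self, points):
        n_valid = (self.valid_sequence[self.calls]
                   if self.calls < len(self.valid_sequence) else len(points))
        self.calls += 1
        out = []
        cells = self.slide.cell_records
        for i, (x, y) in enumerate(points):
            if i < n_valid:
                c = cells[i % len(cells)]
                z = float(self.slide.surface(c.x_um, c.y_um))
                strip = cf.make_focus_strip(self.slide, (c.x_um, c.y_um), z)
            else:
                z = self.slide.dust_z_um
                strip = np.full((64, 512, 3), 235, dtype=np.uint8)
            out.append((z, strip))
        return out

    def scan(self, focus_map):
        # scripted scanner always produces a perfectly focused scan
        return ScannedSlide(self.slide, self.slide.surface)


def test_five_valid_points_trigger_another_iteration(small_slide,
                                                     sharpness_model):
    """Exactly 5 valid probes is not enough; 6 lets the scan proceed."""
    scanner = _StubScanner(small_slide, valid_sequence=[5, 6])
    session = run_workflow(scanner, sharpness_model, WorkflowConfig(seed=1))
    assert scanner.calls == 2
    assert session.focus_iterations == 2
    assert session.status == STATUS_COMPLETED
    assert session.per_round[0].n_valid == 6


def test_workflow_completes_on_well_populated_slide(small_slide,
                                                    sharpness_model):
    scanner = VirtualScanner(small_slide, seed=11)
    session = run_workflow(scanner, sharpness_model, WorkflowConfig(seed=21))
    assert session.status == STATUS_COMPLETED
    assert session.final_score >= 90.0
    assert session.scan_rounds <= 2


def test_sparse_slide_not_scannable_within_bounds(sharpness_model):
    sparse = cf.make_virtual_slide(n_cells=5, seed=6)
    session = run_workflow(VirtualScanner(sparse, seed=12), sharpness_model,
                           WorkflowConfig(seed=22))
    assert session.status == STATUS_NOT_SCANNABLE
    assert session.scan_rounds <= 7
    cfg = WorkflowConfig()
    assert session.focus_iterations <= (cfg.restart_cap + 1) * cfg.max_focus_iters


def test_refocused_regions_subset_of_previous_failures(sharpness_model):
    """Partial refocusing only ever targets regions that just failed."""
    rough = cf.make_virtual_slide(width_um=1000, height_um=1000, n_cells=400,
                                  z_range_um=30.0, surface_grid_shape=(8, 8),
                                  seed=9)
    session = run_workflow(VirtualScanner(rough, seed=3), sharpness_model,
                           WorkflowConfig(seed=5))
    assert session.scan_rounds >= 2, "rough surface should need a refocus round"
    threshold = WorkflowConfig().sharpness_threshold
    for prev, nxt in zip(session.per_round, session.per_round[1:]):
        failed_before = {i for i, s in enumerate(prev.region_scores)
                         if s is not None and s < threshold}
        assert set(nxt.refocused_regions).issubset(failed_before)
    assert session.status == STATUS_COMPLETED


def test_session_log_round_trips_to_json(small_slide, sharpness_model):
    import json
    session = run_workflow(VirtualScanner(small_slide, seed=11),
                           sharpness_model, WorkflowConfig(seed=21))
    payload = json.loads(session.to_json())
    assert payload["status"] == session.status
    assert len(payload["per_round"]) == session.scan_rounds


def test_repeat_scan_cv_identical_runs():
    """A flat, noise-free slide scores identically on every repeat: CV 0."""
    flat = cf.make_virtual_slide(width_um=700, height_um=700, n_cells=250,
                                 z_range_um=0.0, dust_density_per_mm2=0.0,
                                 seed=15)
    from cytofocus.sharpness import train_model
    model = train_model(cf.make_training_set(40, seed=2), seed=2)
    scanner = VirtualScanner(flat, seed=8, z_noise_um=0.0)
    scores, cv = repeat_scan_cv(scanner, model, n_repeats=2,
                                config=WorkflowConfig(seed=30))
    assert len(scores) == 2
    assert scores[0] == scores[1] == 100.0
    assert cv == 0.0


def test_repeat_scan_cv_requires_two_repeats(small_slide, sharpness_model):
    with pytest.raises(ValueError):
        repeat_scan_cv(VirtualScanner(small_slide, seed=1), sharpness_model,
                       n_repeats=1)
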