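"""Closed-loop single-layer scan control, run against a virtual scanner.

The scanning algorithm iteratively determines a "master-focus layer" — a
single focal surface capturing essentially all cells in focus — instead
of multi-layer z-stacking:

1. locate the cell circle on the macro image (the dark border marks
   framing the ThinPrep deposition area);
2. place 12 focus points in the circle and let the autofocus measure a
   z-height and probe strip at each;
3. keep only semantically valid points (in-focus cellular material, per
   the three-criterion filter); if at most five are valid, escalate the
   point count and refocus (five tries per attempt, then restart);
4. with more than five valid points, interpolate them into a focus map,
   scan, and score slide sharpness;
5. if the slide scores below threshold, refocus — everywhere when it is
   completely out of focus, otherwise only in the failing regions — and
   re-scan, up to seven scan rounds, after which the slide is declared
   not scannable.

The ``VirtualScanner`` plays the role of the instrument: its autofocus
can be captured by the dust plane with probability proportional to the
local dust-vs-cell coverage, which is exactly the failure mode the
validity filter exists to reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from . import synthetic
from .focus_filters import (ColorClassTable, FilterConfig, FocusPointImage,
                            classify_focus_point)
from .metrics import coefficient_of_variation
from .sharpness import ScoreConfig, SharpnessModel, SlideSharpnessReport, score_slide

__all__ = [
    "FocusPoint",
    "FocusMap",
    "CellCircle",
    "CircleNotFoundError",
    "VirtualScanner",
    "ScannedSlide",
    "ScanSession",
    "RoundRecord",
    "WorkflowConfig",
    "detect_cell_circle",
    "place_focus_points",
    "focus_round",
    "build_focus_map",
    "run_workflow",
    "repeat_scan_cv",
]

STATUS_COMPLETED = "completed"
STATUS_NOT_SCANNABLE = "not_scannable"

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class CircleNotFoundError(RuntimeError):
    """The macro image contains no detectable border marks."""


@dataclass(frozen=True)
class FocusPoint:
    """A focused probe: slide location, measured z, and validity verdict."""

    x_um: float
    y_um: float
    z_um: float
    valid: bool = True


@dataclass(frozen=True)
class CellCircle:
    center_um: tuple[float, float]
    diameter_um: float

    def contains(self, x: float, y: float) -> bool:
        cx, cy = self.center_um
        return (x - cx) ** 2 + (y - cy) ** 2 <= (self.diameter_um / 2) ** 2


class FocusMap:
    """Focal surface interpolated from valid focus points.

    Piecewise-linear over the Delaunay triangulation of the points, with
    nearest-point extrapolation outside the hull; exact at every data
    point.  One or two points degenerate to nearest-neighbor (constant /
    two-sided) extrapolation.
    """

    def __init__(self, points: list[FocusPoint]):
        if not points:
            raise ValueError("a focus map needs at least one valid point")
        self.points = list(points)
        xy = np.array([[p.x_um, p.y_um] for p in points])
        z = np.array([p.z_um for p in points])
        self._nearest = NearestNDInterpolator(xy, z)
        self._linear = None
        if len(points) >= 3:
            try:
                self._linear = LinearNDInterpolator(xy, z)
            except Exception:  # degenerate (collinear) point sets
                self._linear = None

    def __call__(self, x_um, y_um):
        pts = np.column_stack([np.atleast_1d(x_um), np.atleast_1d(y_um)])
        z = None
        if self._linear is not None:
            z = self._linear(pts)
            fill = ~np.isfinite(z)
            if fill.any():
                z[fill] = self._nearest(pts[fill])
        else:
            z = self._nearest(pts)
        z = np.asarray(z, dtype=float)
        return float(z[0]) if np.isscalar(x_um) else z

    @property
    def z_values(self) -> np.ndarray:
        return np.array([p.z_um for p in self.points])


# ---------------------------------------------------------------------------
# virtual scanner


class ScannedSlide:
    """Slide imagery as acquired with a given focus map (a SlideImageSource)."""

    def __init__(self, slide: synthetic.VirtualSlide, focus):
        self._slide = slide
        self._focus = focus

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self._slide.width_um, self._slide.height_um)

    @property
    def pixel_size_um(self) -> float:
        return self._slide.pixel_size_um

    def region_image(self, region_um, pixel_size_um=None) -> np.ndarray:
        return synthetic.render_at(self._slide, region_um, self._focus,
                                   pixel_size_um=pixel_size_um)


class VirtualScanner:
    """Simulated scanner honoring the instrument-control contract.

    ``focus_at`` models a contrast-based autofocus as a contrast
    competition over the probe strip's footprint: any stained cell
    material out-contrasts translucent dust, so the probe locks onto the
    cell surface whenever at least a nucleus-sized patch of cell lies in
    the footprint; otherwise the only contrast left is on the coverslip
    (dust specks or bare glass) and the probe locks onto the dust plane —
    reproducing the spurious second focus layer seen on real slides.
    Deterministic for a given seed (the seed only drives the small
    z-measurement noise).
    """

    #: minimum cell area (µm²) in the footprint for cells to win the
    #: contrast competition — about one small nucleus
    MIN_CELL_AREA_UM2 = 50.0

    def __init__(self, slide: synthetic.VirtualSlide, seed: int = 0,
                 z_noise_um: float = 0.25,
                 strip_shape: tuple[int, int] = synthetic.NATIVE_STRIP_SHAPE):
        self.slide = slide
        self.z_noise_um = z_noise_um
        self.strip_shape = strip_shape
        self.reseed(seed)

    def reseed(self, seed: int) -> None:
        self.seed = seed
        self._rng = np.random.default_rng(seed)

    def macro_image(self, scale: float = 16.0) -> np.ndarray:
        return synthetic.make_macro_image(self.slide, scale=scale)

    @property
    def macro_pixel_size_um(self) -> float:
        return self.slide.pixel_size_um * 16.0

    def _footprint_cell_area(self, x: float, y: float) -> float:
        """Total cell area (µm²) intersecting the probe strip's footprint."""
        w_px, h_px = self.strip_shape
        ps = self.slide.pixel_size_um
        half_w, half_h = w_px * ps / 2.0, h_px * ps / 2.0
        area = 0.0
        for c in self.slide.cell_records:
            if (abs(c.x_um - x) <= half_w + c.radius_um
                    and abs(c.y_um - y) <= half_h + c.radius_um):
                area += np.pi * c.radius_um ** 2
        return area

    def focus_at(self, points) -> list[tuple[float, np.ndarray]]:
        """Autofocus each (x, y): returns (measured z, probe strip) pairs."""
        out = []
        for (x, y) in points:
            if self._footprint_cell_area(x, y) >= self.MIN_CELL_AREA_UM2:
                z = float(self.slide.surface(x, y))
            else:
                # nothing but coverslip contrast: dust plane / bare glass
                z = self.slide.dust_z_um
            if self.z_noise_um > 0:
                z += float(self._rng.normal(0.0, self.z_noise_um))
            strip = synthetic.make_focus_strip(self.slide, (x, y), z,
                                               self.strip_shape)
            out.append((z, strip))
        return out

    def scan(self, focus_map: FocusMap) -> ScannedSlide:
        return ScannedSlide(self.slide, focus_map)


# ---------------------------------------------------------------------------
# workflow operations


def detect_cell_circle(macro: np.ndarray, *, pixel_size_um: float,
                       diameter_um: float,
                       threshold: float = 0.1) -> CellCircle:
    """Locate the cell circle from the dark border marks on the macro image.

    The border marks are segmented by a fixed normalized threshold (0.1);
    their centroid is the circle center, and the diameter is the known
    deposition-circle diameter (22 mm on a physical ThinPrep slide, scaled
    here to simulator units).
    """
    if macro.size == 0:
        raise ValueError("macro image is empty")
    gray = (macro.astype(float) @ np.array([0.299, 0.587, 0.114])
            if macro.ndim == 3 else macro.astype(float))
    dark = gray / 255.0 < threshold
    if not dark.any():
        raise CircleNotFoundError("circle not found: no border marks detected")
    ys, xs = np.nonzero(dark)
    cy = float(ys.mean()) * pixel_size_um
    cx = float(xs.mean()) * pixel_size_um
    return CellCircle(center_um=(cx, cy), diameter_um=diameter_um)


def place_focus_points(circle: CellCircle, n: int,
                       existing: list[tuple[float, float]] | None = None,
                       bad_regions: list[tuple[float, float, float, float]] | None = None,
                       rng: np.random.Generator | None = None,
                       min_separation_um: float = 5.0) -> list[tuple[float, float]]:
    """Place ``n`` focus points inside the cell circle.

    Without constraints the layout is a quasi-uniform sunflower spiral
    (rings plus center).  With ``bad_regions``, new points are drawn inside
    those rectangles (intersected with the circle) round-robin.  Points
    never duplicate ``existing`` ones.
    """
    if n < 1:
        raise ValueError("need at least one focus point")
    rng = rng or np.random.default_rng(0)
    cx, cy = circle.center_um
    R = circle.diameter_um / 2.0
    existing = list(existing or [])

    def too_close(x: float, y: float, pts) -> bool:
        return any((x - px) ** 2 + (y - py) ** 2 < min_separation_um ** 2
                   for px, py in pts)

    placed: list[tuple[float, float]] = []
    if bad_regions:
        k = 0
        attempts = 0
        while len(placed) < n and attempts < 200 * n:
            rx, ry, rw, rh = bad_regions[k % len(bad_regions)]
            x = float(rng.uniform(rx, rx + rw))
            y = float(rng.uniform(ry, ry + rh))
            attempts += 1
            if circle.contains(x, y) and not too_close(x, y, existing + placed):
                placed.append((x, y))
                k += 1
        # degenerate region/circle overlap: fall back to circle-wide placement
        if len(placed) < n:
            placed += place_focus_points(circle, n - len(placed),
                                         existing + placed, None, rng,
                                         min_separation_um)
        return placed

    phase = float(rng.uniform(0, 2 * np.pi))
    k = 0
    while len(placed) < n:
        k += 1
        r = R * 0.92 * np.sqrt(k / (n + 1))
        theta = k * _GOLDEN_ANGLE + phase
        x = cx + r * np.cos(theta)
        y = cy + r * np.sin(theta)
        if too_close(x, y, existing + placed):
            phase += 0.37  # nudge the spiral until the slot is free
            continue
        placed.append((float(x), float(y)))
    return placed


def focus_round(scanner, points, filter_config: FilterConfig | None = None,
                color_table: ColorClassTable | None = None) -> list[FocusPoint]:
    """Focus every point and keep those whose strips pass the validity filter."""
    if not points:
        raise ValueError("focus_round needs at least one point")
    results = scanner.focus_at(points)
    valid: list[FocusPoint] = []
    for (x, y), (z, strip) in zip(points, results):
        verdict = classify_focus_point(FocusPointImage(strip, (x, y), z),
                                       filter_config, color_table)
        if verdict.valid:
            valid.append(FocusPoint(x, y, z, True))
    return valid


def build_focus_map(valid_points: list[FocusPoint]) -> FocusMap:
    """Interpolate valid focus points into a slide-wide focus map."""
    return FocusMap(valid_points)


# ---------------------------------------------------------------------------
# session state


@dataclass
class RoundRecord:
    n_focus_points: int
    n_valid: int
    slide_score: float | None
    refocused_regions: list[int]
    region_scores: list[float | None] = field(default_factory=list)
    focus_points: list[dict] = field(default_factory=list)


@dataclass
class ScanSession:
    """Audit log of one workflow run."""

    focus_iterations: int = 0
    scan_rounds: int = 0
    per_round: list[RoundRecord] = field(default_factory=list)
    status: str | None = None
    final_score: float | None = None

    def to_dict(self) -> dict:
        return {
            "focus_iterations": self.focus_iterations,
            "scan_rounds": self.scan_rounds,
            "per_round": [asdict(r) for r in self.per_round],
            "status": self.status,
            "final_score": self.final_score,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


@dataclass(frozen=True)
class WorkflowConfig:
    """Scan-control constants.

    ``min_valid`` encodes the "more than five valid points" rule (>= 6);
    escalation adds 12 points per failed focus iteration up to 85 (the
    largest point count observed in practice); a slide is completely out
    of focus when its score drops below 30 with at least 12 failing
    regions, otherwise failing regions are refocused individually.
    """

    initial_points: int = 12
    escalation_step: int = 12
    max_points: int = 85
    min_valid: int = 6
    max_focus_iters: int = 5
    restart_cap: int = 2
    max_scan_rounds: int = 7
    sharpness_threshold: float = 90.0
    completely_oof_score: float = 30.0
    completely_oof_regions: int = 12
    circle_diameter_um: float | None = None  # default: slide's true circle
    seed: int = 0


def run_workflow(scanner, model: SharpnessModel,
                 config: WorkflowConfig | None = None,
                 filter_config: FilterConfig | None = None,
                 color_table: ColorClassTable | None = None,
                 score_config: ScoreConfig | None = None) -> ScanSession:
    """Run the full iterative scan loop until the slide passes or is abandoned.

    Returns the session log; ``status`` is ``completed`` (final score at or
    above threshold) or ``not_scannable`` (focus never succeeded within the
    restart budget, or seven scan rounds did not reach the threshold).
    """
    cfg = config or WorkflowConfig()
    score_cfg = score_config or ScoreConfig(region_threshold=cfg.sharpness_threshold)
    rng = np.random.default_rng(cfg.seed)
    session = ScanSession()

    diameter = cfg.circle_diameter_um or getattr(scanner.slide, "circle_diameter_um",
                                                 None)
    if diameter is None:
        raise ValueError("circle diameter must be configured for this scanner")
    circle = detect_cell_circle(scanner.macro_image(),
                                pixel_size_um=scanner.macro_pixel_size_um,
                                diameter_um=diameter)

    n_points = cfg.initial_points
    valid: list[FocusPoint] = []
    bad_region_rects = None
    bad_region_idx: list[int] = []
    restarts = 0
    report: SlideSharpnessReport | None = None

    while session.scan_rounds < cfg.max_scan_rounds:
        # --- focus phase -------------------------------------------------
        # each iteration re-places a (larger) point set and is judged on
        # its own valid count, per the flowchart's "valid > 5?" test
        focused_enough = len(valid) >= cfg.min_valid
        iters = 0
        while not focused_enough and iters < cfg.max_focus_iters:
            points = place_focus_points(circle, n_points, None,
                                        bad_region_rects, rng)
            new_valid = focus_round(scanner, points, filter_config, color_table)
            session.focus_iterations += 1
            iters += 1
            if len(new_valid) >= cfg.min_valid:
                valid = new_valid
                focused_enough = True
            else:
                n_points = min(n_points + cfg.escalation_step, cfg.max_points)
        if not focused_enough:
            restarts += 1
            if restarts > cfg.restart_cap:
                session.status = STATUS_NOT_SCANNABLE
                break
            # re-set points and restart the whole focusing procedure
            valid = []
            bad_region_rects = None
            bad_region_idx = []
            n_points = cfg.initial_points
            continue

        # --- scan + sharpness phase --------------------------------------
        focus_map = build_focus_map(valid)
        scanned = scanner.scan(focus_map)
        session.scan_rounds += 1
        report = score_slide(scanned, model, score_cfg,
                             seed=int(rng.integers(0, 2**31 - 1)))
        session.per_round.append(RoundRecord(
            n_focus_points=n_points,
            n_valid=len(valid),
            slide_score=report.slide_score,
            refocused_regions=list(bad_region_idx),
            region_scores=list(report.region_scores),
            focus_points=[asdict(p) for p in valid],
        ))
        session.final_score = report.slide_score

        if report.no_data:
            # nothing measurable on the slide; escalate and try again
            n_points = min(n_points + cfg.escalation_step, cfg.max_points)
            valid = []
            bad_region_rects = None
            bad_region_idx = []
            continue
        if report.slide_score >= cfg.sharpness_threshold:
            session.status = STATUS_COMPLETED
            break

        n_bad = len(report.out_of_focus_regions)
        completely = (report.slide_score < cfg.completely_oof_score
                      and n_bad >= cfg.completely_oof_regions)
        if completely:
            # full refocus with more points
            n_points = min(n_points + cfg.escalation_step, cfg.max_points)
            valid = []
            bad_region_rects = None
            bad_region_idx = []
        else:
            # partial: add points in the failing regions only
            from .sharpness import partition_regions
            regions = partition_regions(scanned.extent_um)
            bad_region_idx = list(report.out_of_focus_regions)
            bad_region_rects = [regions[i] for i in bad_region_idx]
            n_points = min(n_points + cfg.escalation_step, cfg.max_points)
            extra = place_focus_points(circle, cfg.escalation_step,
                                       [(p.x_um, p.y_um) for p in valid],
                                       bad_region_rects, rng)
            valid = valid + focus_round(scanner, extra, filter_config, color_table)
            session.focus_iterations += 1

    if session.status is None:
        session.status = STATUS_NOT_SCANNABLE
    return session


def repeat_scan_cv(scanner, model: SharpnessModel, n_repeats: int = 5,
                   config: WorkflowConfig | None = None,
                   **workflow_kwargs) -> tuple[list[float], float]:
    """Repeat the whole workflow and report score reproducibility.

    Each repeat uses an independent RNG substream of the configured seed
    but otherwise identical settings.  Returns (scores, CV%) where CV is
    the sample standard deviation over the mean, in percent.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats for a CV")
    cfg = config or WorkflowConfig()
    master = np.random.default_rng(cfg.seed)
    scores: list[float] = []
    for _ in range(n_repeats):
        sub = int(master.integers(0, 2**31 - 1))
        scanner.reseed(sub)
        run_cfg = WorkflowConfig(**{**asdict(cfg), "seed": sub})
        session = run_workflow(scanner, model, run_cfg, **workflow_kwargs)
        if session.final_score is not None:
            scores.append(session.final_score)
    cv = coefficient_of_variation(scores) if len(scores) >= 2 else float("nan")
    return scores, cv
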