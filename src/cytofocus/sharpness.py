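"""Whole-slide sharpness scoring from per-cell focus classification.

The focus quality of a scanned slide is judged the way a cytologist
would: are the cells sharp?  The scanned area is divided into a 4x4 grid
of regions; in each region up to 200 cells are detected on a low-
resolution overview (Otsu segmentation plus an HSV stain test), their
full-resolution tiles are extracted, five no-reference sharpness
features are computed per cell, and an RBF-kernel SVM classifies each
cell as in-focus or out-of-focus.  A region's score is its percentage of
in-focus cells; the slide score is the mean of the region scores, and a
slide passes when it exceeds a threshold (90 by default).

The five features — Canny edge count, mean gradient magnitude,
difference to an unsharp-masked copy, difference to a Gaussian-blurred
copy, and a perceptual no-reference blur estimate — all degrade
monotonically with defocus, which is what makes the two classes
separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Protocol, runtime_checkable

import joblib
import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.filters import gaussian, sobel, threshold_otsu, unsharp_mask
from skimage.measure import label, regionprops, blur_effect
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CellImage",
    "SharpnessFeatures",
    "FeatureConfig",
    "SharpnessModel",
    "SlideSharpnessReport",
    "ScoreConfig",
    "SlideImageSource",
    "partition_regions",
    "detect_cells",
    "CellDetection",
    "exclusion_filter",
    "extract_features",
    "features_matrix",
    "train_model",
    "score_slide",
    "cells_vs_score_stability",
]

IN_FOCUS = 1
OUT_OF_FOCUS = 0

_LUMA = np.array([0.299, 0.587, 0.114])

MODEL_FORMAT_VERSION = 1


@dataclass
class CellImage:
    """An RGB tile of one detected cell/cluster.

    ``true_label`` carries synthetic ground truth (1 in-focus, 0 out) and is
    absent for real detections.
    """

    pixels: np.ndarray
    location: tuple[float, float]
    region_index: int = 0
    area_px: int = 1
    true_label: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")
        if not (0 <= self.region_index < 16):
            raise ValueError("region_index must be in 0..15")


@dataclass(frozen=True)
class FeatureConfig:
    """Kernel sizes and thresholds behind the five sharpness features."""

    canny_high: float = 0.07
    canny_sigma: float = 1.41
    canny_low_ratio: float = 0.4
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    blur_sigma: float = 2.0
    # re-blur kernel of the perceptual blur metric; must exceed the largest
    # blur scale to be resolved, else the metric saturates and loses order
    blur_h_size: int = 51


@dataclass(frozen=True)
class SharpnessFeatures:
    """Five no-reference sharpness measurements of one cell tile."""

    edge_count: int
    gradient_score: float
    diff_sharpened: float
    diff_blurred: float
    blur_metric: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.edge_count, self.gradient_score,
                         self.diff_sharpened, self.diff_blurred,
                         self.blur_metric], dtype=float)


FEATURE_NAMES = ("edge_count", "gradient_score", "diff_sharpened",
                 "diff_blurred", "blur_metric")


def extract_features(cell: CellImage, config: FeatureConfig | None = None
                     ) -> SharpnessFeatures:
    """Compute the five sharpness features of a cell tile.

    A degenerate (constant) tile has no structure to measure: every
    difference feature is 0 and the blur metric is defined as 1
    (maximally blurred).
    """
    cfg = config or FeatureConfig()
    px = np.asarray(cell.pixels)
    if px.size == 0:
        raise ValueError("empty cell tile")
    gray = (px.astype(float) @ _LUMA) / 255.0 if px.ndim == 3 else px.astype(float) / 255.0

    if np.ptp(gray) == 0:
        return SharpnessFeatures(0, 0.0, 0.0, 0.0, 1.0)

    edges = canny(gray, sigma=cfg.canny_sigma,
                  low_threshold=cfg.canny_high * cfg.canny_low_ratio,
                  high_threshold=cfg.canny_high)
    # RMS rather than mean: the mean |gradient| is a total variation, which
    # can grow with blur as an object's edge ring widens; the L2 gradient
    # norm decreases monotonically under Gaussian blur
    grad = float(np.sqrt(np.mean(sobel(gray) ** 2)))
    sharp = unsharp_mask(gray, radius=cfg.unsharp_radius, amount=cfg.unsharp_amount)
    diff_sharp = float(np.mean(np.abs(gray - sharp)))
    blurred = gaussian(gray, sigma=cfg.blur_sigma)
    diff_blur = float(np.mean(np.abs(gray - blurred)))
    bm = blur_effect(gray, h_size=cfg.blur_h_size)
    bm = 1.0 if not np.isfinite(bm) else float(np.clip(bm, 0.0, 1.0))
    return SharpnessFeatures(int(edges.sum()), grad, diff_sharp, diff_blur, bm)


def features_matrix(cells: list[CellImage], config: FeatureConfig | None = None
                    ) -> np.ndarray:
    return np.array([extract_features(c, config).as_vector() for c in cells])


# ---------------------------------------------------------------------------
# SVM model


@dataclass
class SharpnessModel:
    """z-scored RBF-SVM cell focus classifier.

    The RBF kernel uses scaling factor sigma (default 1) in the
    K = exp(-||x-y||^2 / (2 sigma^2)) convention, i.e. gamma = 1/(2 sigma^2);
    features are standardized with the training statistics so that sigma = 1
    is meaningful across features of very different scales.
    """

    scaler: StandardScaler
    svm: SVC
    feature_config: FeatureConfig
    sigma: float
    n_per_class: dict[int, int]
    seed: int
    training_accuracy: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return self.svm.predict(self.scaler.transform(features))

    def predict_cells(self, cells: list[CellImage]) -> np.ndarray:
        return self.predict(features_matrix(cells, self.feature_config))

    def save(self, path) -> None:
        joblib.dump({
            "format_version": MODEL_FORMAT_VERSION,
            "feature_config": asdict(self.feature_config),
            "scaler": self.scaler,
            "svm": self.svm,
            "sigma": self.sigma,
            "n_per_class": self.n_per_class,
            "seed": self.seed,
            "training_accuracy": self.training_accuracy,
        }, path)

    @staticmethod
    def load(path, expect_feature_config: FeatureConfig | None = None
             ) -> "SharpnessModel":
        bundle = joblib.load(path)
        if bundle.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model bundle version")
        fc = FeatureConfig(**bundle["feature_config"])
        if expect_feature_config is not None and fc != expect_feature_config:
            raise ValueError("model was trained with a different feature config")
        return SharpnessModel(
            scaler=bundle["scaler"], svm=bundle["svm"], feature_config=fc,
            sigma=bundle["sigma"], n_per_class=bundle["n_per_class"],
            seed=bundle["seed"], training_accuracy=bundle["training_accuracy"],
        )


def train_model(training: list[CellImage], sigma: float = 1.0, seed: int = 0,
                feature_config: FeatureConfig | None = None) -> SharpnessModel:
    """Fit the in-focus/out-of-focus SVM on labeled cell images.

    Both classes must be present.  The fit is deterministic given the
    training set; ``seed`` is recorded as training metadata.
    """
    fc = feature_config or FeatureConfig()
    labels = np.array([c.true_label for c in training])
    if any(lab is None for lab in labels):
        raise ValueError("all training cells need a ground-truth label")
    labels = labels.astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    X = features_matrix(training, fc)
    scaler = StandardScaler().fit(X)
    gamma = 1.0 / (2.0 * sigma ** 2)
    svm = SVC(kernel="rbf", gamma=gamma, C=1.0).fit(scaler.transform(X), labels)
    acc = float(np.mean(svm.predict(scaler.transform(X)) == labels))
    return SharpnessModel(
        scaler=scaler, svm=svm, feature_config=fc, sigma=sigma,
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
        seed=seed, training_accuracy=acc,
    )


# ---------------------------------------------------------------------------
# region partitioning and cell detection


def partition_regions(bounds_um: tuple[float, float], grid: tuple[int, int] = (4, 4)
                      ) -> list[tuple[float, float, float, float]]:
    """Tile the scanned area into a 4x4 grid of rectangles.

    Returns 16 (x0, y0, w, h) rectangles in row-major order whose union is
    exactly the scanned area; edge lengths differ by at most one output
    pixel's worth of rounding.
    """
    w, h = bounds_um
    if w <= 0 or h <= 0:
        raise ValueError("slide bounds must be positive")
    ny, nx = grid
    xs = np.linspace(0.0, w, nx + 1)
    ys = np.linspace(0.0, h, ny + 1)
    return [(float(xs[j]), float(ys[i]), float(xs[j + 1] - xs[j]),
             float(ys[i + 1] - ys[i]))
            for i in range(ny) for j in range(nx)]


@dataclass(frozen=True)
class CellDetection:
    """A detected cell's full-resolution location and approximate area."""

    x_um: float
    y_um: float
    area_px: int         # approximate area at full resolution


def detect_cells(overview: np.ndarray, *, scale: float,
                 pixel_size_um: float, origin_um: tuple[float, float] = (0.0, 0.0),
                 hsv_table=None, max_cells: int = 200,
                 rng: np.random.Generator | None = None,
                 min_overview_px: int = 4,
                 stain_fraction: float = 0.25) -> list[CellDetection]:
    """Find cells on a low-resolution region overview and sample up to
    ``max_cells`` of them.

    Objects are separated from the background with Otsu's threshold on the
    grayscale overview; an object counts as a cell when at least
    ``stain_fraction`` of its pixels fall into one of the stain HSV classes
    (dust and debris are achromatic and fail).  Coordinates are mapped back
    to full resolution; areas are scaled by ``scale``^2.
    """
    from .focus_filters import ColorClassTable  # local import: no cycle at module load

    if overview.size == 0:
        raise ValueError("overview image is empty")
    rng = rng or np.random.default_rng(0)
    table = hsv_table or ColorClassTable()
    gray = overview.astype(float) @ _LUMA if overview.ndim == 3 else overview.astype(float)
    if np.ptp(gray) == 0:
        return []
    thresh = threshold_otsu(gray)
    mask = gray < thresh
    if not mask.any():
        return []
    hsv = rgb2hsv(overview.astype(np.uint8))
    member = table.classify_pixels(hsv)
    stain_any = np.zeros(mask.shape, dtype=bool)
    for sel in member.values():
        stain_any |= sel

    detections: list[CellDetection] = []
    for obj in regionprops(label(mask, connectivity=2)):
        if obj.area < min_overview_px:
            continue
        coords = obj.coords
        frac = float(stain_any[coords[:, 0], coords[:, 1]].mean())
        if frac < stain_fraction:
            continue
        cy, cx = obj.centroid
        detections.append(CellDetection(
            x_um=origin_um[0] + cx * pixel_size_um * scale,
            y_um=origin_um[1] + cy * pixel_size_um * scale,
            area_px=int(round(obj.area * scale ** 2)),
        ))
    if len(detections) > max_cells:
        idx = rng.choice(len(detections), size=max_cells, replace=False)
        detections = [detections[i] for i in sorted(idx)]
    return detections


def exclusion_filter(cells, huge_cluster_px: float = 4_000_000,
                     small_cell_px: float = 200,
                     resolution_factor: float = 1.0):
    """Drop huge cell clusters (>4 Mpx) and very small cells (<200 px).

    ``resolution_factor`` rescales both thresholds by its square when areas
    were measured on downscaled imagery.
    """
    hi = huge_cluster_px / resolution_factor ** 2
    lo = small_cell_px / resolution_factor ** 2
    return [c for c in cells if lo <= c.area_px <= hi]


# ---------------------------------------------------------------------------
# slide scoring


@runtime_checkable
class SlideImageSource(Protocol):
    """Anything that can serve region imagery of a scanned slide."""

    @property
    def extent_um(self) -> tuple[float, float]: ...

    @property
    def pixel_size_um(self) -> float: ...

    def region_image(self, region_um: tuple[float, float, float, float],
                     pixel_size_um: float | None = None) -> np.ndarray: ...


@dataclass(frozen=True)
class ScoreConfig:
    """Constants of the region/slide scoring pipeline."""

    max_cells_per_region: int = 200
    overview_scale: float = 8.0
    tile_px: int = 64
    region_threshold: float = 90.0
    huge_cluster_px: float = 4_000_000
    small_cell_px: float = 200
    strict_mean: bool = False   # divide by all 16 regions even if empty


@dataclass
class SlideSharpnessReport:
    """16 region scores (% in-focus cells) and their slide-level mean."""

    region_scores: list[float | None]
    cells_examined: list[int]
    slide_score: float | None
    out_of_focus_regions: list[int]
    no_data: bool = False

    def to_dict(self) -> dict:
        return {
            "region_scores": self.region_scores,
            "cells_examined": self.cells_examined,
            "slide_score": self.slide_score,
            "out_of_focus_regions": self.out_of_focus_regions,
            "no_data": self.no_data,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def score_slide(source: SlideImageSource, model: SharpnessModel,
                config: ScoreConfig | None = None,
                seed: int = 0) -> SlideSharpnessReport:
    """Score a scanned slide's focus quality region by region.

    Per region: detect cells on an overview, exclude inappropriate ones,
    classify each full-resolution tile with the SVM, and record the
    percentage classified in-focus.  The slide score is the mean over
    regions that contained cells (strict mode divides by all 16); regions
    scoring below the threshold are listed for refocusing.
    """
    cfg = config or ScoreConfig()
    rng = np.random.default_rng(seed)
    w, h = source.extent_um
    regions = partition_regions((w, h))
    ps = source.pixel_size_um

    region_scores: list[float | None] = []
    cells_examined: list[int] = []
    for idx, region in enumerate(regions):
        overview = source.region_image(region, pixel_size_um=ps * cfg.overview_scale)
        detections = detect_cells(
            overview, scale=cfg.overview_scale, pixel_size_um=ps,
            origin_um=(region[0], region[1]),
            max_cells=cfg.max_cells_per_region, rng=rng)
        if not detections:
            region_scores.append(None)
            cells_examined.append(0)
            continue
        # render the region once at full resolution and crop the cell tiles
        full = source.region_image(region, pixel_size_um=ps)
        rh, rw = full.shape[:2]
        cells: list[CellImage] = []
        t = cfg.tile_px
        for det in detections:
            col = int(round((det.x_um - region[0]) / ps)) - t // 2
            row = int(round((det.y_um - region[1]) / ps)) - t // 2
            col = min(max(col, 0), max(rw - t, 0))
            row = min(max(row, 0), max(rh - t, 0))
            tile = full[row:row + t, col:col + t]
            cells.append(CellImage(pixels=tile, location=(det.x_um, det.y_um),
                                   region_index=idx, area_px=det.area_px))
        cells = exclusion_filter(cells, cfg.huge_cluster_px, cfg.small_cell_px)
        if not cells:
            region_scores.append(None)
            cells_examined.append(0)
            continue
        preds = model.predict_cells(cells)
        region_scores.append(float(np.mean(preds == IN_FOCUS) * 100.0))
        cells_examined.append(len(cells))

    scored = [s for s in region_scores if s is not None]
    if not scored:
        return SlideSharpnessReport(region_scores, cells_examined, None, [],
                                    no_data=True)
    denom = len(region_scores) if cfg.strict_mean else len(scored)
    slide_score = float(sum(scored) / denom)
    bad = [i for i, s in enumerate(region_scores)
           if s is not None and s < cfg.region_threshold]
    return SlideSharpnessReport(region_scores, cells_examined, slide_score, bad)


def cells_vs_score_stability(source: SlideImageSource, model: SharpnessModel,
                             cell_counts, runs: int = 10,
                             config: ScoreConfig | None = None,
                             seed: int = 0) -> dict[int, tuple[float, float]]:
    """Mean and SD of the slide score across repeated random cell samples.

    Checks sampling stability: above ~200 cells per region the slide score
    barely moves between re-samples.
    """
    cfg = config or ScoreConfig()
    out: dict[int, tuple[float, float]] = {}
    master = np.random.default_rng(seed)
    for count in cell_counts:
        if count < 1:
            raise ValueError("cell counts must be >= 1")
        scores = []
        for _ in range(runs):
            sub = int(master.integers(0, 2**31 - 1))
            c = ScoreConfig(max_cells_per_region=count,
                            overview_scale=cfg.overview_scale,
                            tile_px=cfg.tile_px,
                            region_threshold=cfg.region_threshold,
                            huge_cluster_px=cfg.huge_cluster_px,
                            small_cell_px=cfg.small_cell_px,
                            strict_mean=cfg.strict_mean)
            report = score_slide(source, model, c, seed=sub)
            if report.slide_score is not None:
                scores.append(report.slide_score)
        mean = float(np.mean(scores)) if scores else float("nan")
        sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
        out[int(count)] = (mean, sd)
    return out
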