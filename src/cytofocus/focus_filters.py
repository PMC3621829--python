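"""Semantic validity filtering of autofocus probe images.

A contrast-based autofocus happily locks onto dust, debris, or nothing at
all.  A focus point is only useful if its probe image shows in-focus
cellular material, so each strip is screened by three conjunctive
criteria:

* **size** — thresholding against the background must yield at least one
  object as large as a small superficial-cell nucleus (200 px at 20x);
* **edge** — a Canny detector (high threshold 0.07, sigma 1.41) must find
  at least one edge pixel, rejecting blurred strips;
* **color** — at least 10 object pixels must fall into one of the four
  stain HSV classes (nuclei, cytoplasm, DAB/p16, Fast Red/Ki-67),
  rejecting achromatic artifacts such as dust.

A strip is valid iff all three pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.measure import label, regionprops

__all__ = [
    "FocusPointImage",
    "FilterVerdict",
    "ColorClassTable",
    "FilterConfig",
    "estimate_background_level",
    "segment_objects",
    "size_filter",
    "edge_filter",
    "color_filter",
    "classify_focus_point",
]

#: Rec. 601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    """8-bit RGB -> float grayscale in [0, 255] by luma weighting."""
    return pixels.astype(float) @ _LUMA


@dataclass
class FocusPointImage:
    """An RGB probe strip with its slide location and measured focus height."""

    pixels: np.ndarray
    location: tuple[float, float] = (0.0, 0.0)
    z_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("focus point image must be h x w x 3 RGB")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("focus point image must be nonempty")


@dataclass(frozen=True)
class HSVInterval:
    """Closed HSV box; the hue interval may wrap around the circle."""

    hue: tuple[float, float]
    saturation: tuple[float, float] = (0.0, 1.0)
    value: tuple[float, float] = (0.0, 1.0)

    def contains(self, h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        h_lo, h_hi = self.hue
        if h_lo <= h_hi:
            in_h = (h >= h_lo) & (h <= h_hi)
        else:  # wrap-around, e.g. red hues (0.96, 0.03)
            in_h = (h >= h_lo) | (h <= h_hi)
        in_s = (s >= self.saturation[0]) & (s <= self.saturation[1])
        in_v = (v >= self.value[0]) & (v <= self.value[1])
        return in_h & in_s & in_v


def _default_classes() -> dict[str, HSVInterval]:
    # Stain-chemistry defaults: hematoxylin blue-violet nuclei, faint
    # blue-gray cytoplasm, DAB brown, Fast Red.  Pale thin-layer material
    # carries little chroma, so the saturation floors sit just above the
    # achromatic (dust/glass) level.  Calibratable via config.
    return {
        "nucleus": HSVInterval((0.50, 0.75), (0.035, 1.0), (0.10, 0.96)),
        "cytoplasm": HSVInterval((0.45, 0.75), (0.035, 0.35), (0.50, 0.97)),
        "p16": HSVInterval((0.03, 0.14), (0.035, 1.0), (0.10, 0.96)),
        "ki67": HSVInterval((0.90, 0.03), (0.035, 1.0), (0.10, 0.96)),
    }


@dataclass
class ColorClassTable:
    """Per-stain-class HSV intervals used by the color filter."""

    classes: dict[str, HSVInterval] = field(default_factory=_default_classes)

    def __post_init__(self) -> None:
        for name, iv in self.classes.items():
            for ch in (iv.hue, iv.saturation, iv.value):
                if not (0.0 <= ch[0] <= 1.0 and 0.0 <= ch[1] <= 1.0):
                    raise ValueError(f"HSV interval out of [0,1] for class {name}")

    def classify_pixels(self, hsv: np.ndarray) -> dict[str, np.ndarray]:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        return {name: iv.contains(h, s, v) for name, iv in self.classes.items()}


@dataclass(frozen=True)
class FilterConfig:
    """Tunable constants of the three-criterion focus-point classifier."""

    size_min_px: int = 200
    canny_high: float = 0.07
    canny_sigma: float = 1.41
    canny_low_ratio: float = 0.4
    color_min_px: int = 10
    background_level: float | None = None   # None: estimate per image
    background_fallback: float = 230.0
    scale_factor: float = 1.0               # image downscale factor f

    @property
    def effective_size_min(self) -> float:
        # physical-area semantics survive rescaling: threshold 200/f^2
        return self.size_min_px / (self.scale_factor ** 2)


@dataclass
class FilterVerdict:
    """Outcome of the three filters; valid iff all three pass."""

    size_pass: bool
    edge_pass: bool
    color_pass: bool
    largest_area_px: int
    edge_count: int
    color_counts: dict[str, int]

    @property
    def valid(self) -> bool:
        return self.size_pass and self.edge_pass and self.color_pass

    @property
    def pooled_color_count(self) -> int:
        return sum(self.color_counts.values())


def estimate_background_level(pixels: np.ndarray, fallback: float = 230.0) -> float:
    """Background gray level as the mode of the intensity histogram.

    On a bright-field slide the background dominates, so the most frequent
    gray level is the glass.  If the mode is implausibly dark (the image is
    wall-to-wall objects) the configured fallback is used.
    """
    gray = _to_gray(pixels)
    hist, _ = np.histogram(gray, bins=256, range=(0, 256))
    mode = int(np.argmax(hist))
    return float(mode) if mode >= 128 else float(fallback)


def segment_objects(img: FocusPointImage, background_level: float
                    ) -> tuple[np.ndarray, list]:
    """Threshold darker-than-background pixels and label connected components.

    Returns (binary mask, regionprops list); an empty mask is a legal result.
    """
    if not (0 <= background_level <= 255):
        raise ValueError("background_level must be in [0, 255]")
    gray = _to_gray(img.pixels)
    # small margin below background so flat glass with quantization noise
    # does not segment as objects
    mask = gray < (background_level - 2.0)
    labeled = label(mask, connectivity=2)
    return mask, regionprops(labeled)


def size_filter(objects, min_px: float = 200) -> bool:
    """True iff any segmented object is at least ``min_px`` pixels."""
    return any(obj.area >= min_px for obj in objects)


def edge_filter(img: FocusPointImage, config: FilterConfig | None = None
                ) -> tuple[bool, int]:
    """Canny edge presence test; a blurred strip yields no edges.

    Thresholds are absolute on the gradient magnitude of the [0, 1]
    grayscale image (high 0.07; low = 0.4 x high for hysteresis).
    """
    cfg = config or FilterConfig()
    gray01 = _to_gray(img.pixels) / 255.0
    edges = canny(gray01, sigma=cfg.canny_sigma,
                  low_threshold=cfg.canny_high * cfg.canny_low_ratio,
                  high_threshold=cfg.canny_high)
    count = int(edges.sum())
    return count >= 1, count


def color_filter(img: FocusPointImage, mask: np.ndarray,
                 table: ColorClassTable | None = None, min_pixels: int = 10
                 ) -> tuple[bool, dict[str, int]]:
    """True iff >= ``min_pixels`` object pixels fall in one stain class.

    Only pixels under the object mask are considered; counting is
    per-class ("belonged to one of these classes"), with the pooled count
    available from the verdict for comparison.
    """
    if mask.shape != img.pixels.shape[:2]:
        raise ValueError("mask shape does not match image")
    table = table or ColorClassTable()
    counts = {name: 0 for name in table.classes}
    if mask.any():
        hsv = rgb2hsv(img.pixels[mask].reshape(-1, 1, 3).astype(np.uint8))
        member = table.classify_pixels(hsv.reshape(-1, 3))
        counts = {name: int(sel.sum()) for name, sel in member.items()}
    return any(c >= min_pixels for c in counts.values()), counts


def classify_focus_point(img: FocusPointImage, config: FilterConfig | None = None,
                         table: ColorClassTable | None = None) -> FilterVerdict:
    """Run size, edge, and color filters; valid is their conjunction.

    Diagnostics (largest object area, edge count, per-class color counts)
    are populated even when an early criterion fails.
    """
    cfg = config or FilterConfig()
    bg = (cfg.background_level if cfg.background_level is not None
          else estimate_background_level(img.pixels, cfg.background_fallback))
    mask, objects = segment_objects(img, bg)
    largest = max((int(o.area) for o in objects), default=0)
    size_ok = size_filter(objects, cfg.effective_size_min)
    edge_ok, edge_count = edge_filter(img, cfg)
    color_ok, counts = color_filter(img, mask, table, cfg.color_min_px)
    return FilterVerdict(size_pass=size_ok, edge_pass=edge_ok,
                         color_pass=color_ok, largest_area_px=largest,
                         edge_count=edge_count, color_counts=counts)
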