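"""Virtual liquid-based cytology slides with known ground truth.

A ThinPrep-style LBC slide deposits cells inside a 22 mm circle as a thin
but genuinely three-dimensional layer: focus heights vary smoothly by up
to ~30 µm across the circle, and dust on the coverslip forms a second,
spurious focal plane closer to the objective.  This module builds a
desk-scale virtual slide that reproduces exactly those properties — cell
positions on a smooth focal surface, a disjoint dust plane, stain colors
(hematoxylin, DAB/p16, Fast Red/Ki-67) drawn from configurable HSV ranges
— and renders any region of it at any focus height with defocus modeled
as Gaussian blur growing linearly in focal error.

Every generator is a pure function of (config, seed); identical seeds give
bit-identical slides and renders.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .sharpness import CellImage

__all__ = [
    "StainPalette",
    "FocalSurface",
    "DefocusModel",
    "CellRecord",
    "DustRecord",
    "VirtualSlide",
    "SlideConfig",
    "make_virtual_slide",
    "render_at",
    "render_overview",
    "make_focus_strip",
    "make_macro_image",
    "make_training_set",
    "make_cell_tile",
    "make_validation_strips",
    "NATIVE_PIXEL_SIZE_UM",
    "NATIVE_STRIP_SHAPE",
]

#: native scanner sampling: 20x objective, 0.46 µm per pixel
NATIVE_PIXEL_SIZE_UM = 0.46
#: desk-scale focus strip (the physical scanner's line sensor is 4096x64)
NATIVE_STRIP_SHAPE = (512, 64)

STAIN_HEMATOXYLIN = "hematoxylin"
STAIN_P16 = "p16"
STAIN_KI67 = "ki67"
STAIN_CLASSES = (STAIN_HEMATOXYLIN, STAIN_P16, STAIN_KI67)


class ConfigurationError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class StainPalette:
    """HSV ranges (hue fraction in [0,1], hue may wrap) used to draw cells.

    Hematoxylin nuclei are blue-violet, cytoplasm a faint blue-gray, DAB
    (p16) brown, Fast Red (Ki-67) red.  The background is bright neutral
    glass, always brighter than rendered cell material.
    """

    nucleus_hue_range: tuple[float, float] = (0.56, 0.70)
    cytoplasm_hue_range: tuple[float, float] = (0.52, 0.66)
    dab_hue_range: tuple[float, float] = (0.05, 0.11)
    fastred_hue_range: tuple[float, float] = (0.96, 0.015)
    background_value: int = 235

    def __post_init__(self) -> None:
        for name in ("nucleus_hue_range", "cytoplasm_hue_range",
                     "dab_hue_range", "fastred_hue_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not (0 <= self.background_value <= 255):
            raise ConfigurationError("background_value must be in [0, 255]")


def _sample_hue(hue_range: tuple[float, float], rng: np.random.Generator) -> float:
    """Uniform hue from a range that may wrap around the hue circle."""
    lo, hi = hue_range
    if lo <= hi:
        return float(rng.uniform(lo, hi))
    return float(rng.uniform(lo, hi + 1.0) % 1.0)


@dataclass
class FocalSurface:
    """Smooth focal surface z(x, y) in µm over the slide extent.

    Defined by a control grid of z heights at evenly spaced nodes spanning
    the slide; evaluation is piecewise-bilinear, so the evaluated range
    equals the control-grid range exactly.
    """

    control_grid: np.ndarray
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        self.control_grid = np.asarray(self.control_grid, dtype=float)
        if self.control_grid.ndim != 2 or min(self.control_grid.shape) < 2:
            raise ConfigurationError("control grid must be at least 2x2")
        if not np.all(np.isfinite(self.control_grid)):
            raise ConfigurationError("control grid must be finite")
        ny, nx = self.control_grid.shape
        self._interp = RegularGridInterpolator(
            (np.linspace(0.0, self.height_um, ny), np.linspace(0.0, self.width_um, nx)),
            self.control_grid, method="linear", bounds_error=False, fill_value=None,
        )

    def __call__(self, x_um, y_um):
        """Evaluate z at physical (x, y); coordinates are clamped to the slide."""
        x = np.clip(np.asarray(x_um, dtype=float), 0.0, self.width_um)
        y = np.clip(np.asarray(y_um, dtype=float), 0.0, self.height_um)
        z = self._interp(np.stack([y, x], axis=-1))
        if np.isscalar(x_um) and np.isscalar(y_um):
            return float(np.asarray(z).ravel()[0])
        return z

    @property
    def z_min(self) -> float:
        return float(self.control_grid.min())

    @property
    def z_max(self) -> float:
        return float(self.control_grid.max())

    @property
    def peak_to_peak(self) -> float:
        return self.z_max - self.z_min


@dataclass(frozen=True)
class DefocusModel:
    """Gaussian-blur defocus: sigma grows linearly with |Δz| and saturates.

    sigma(Δz) = min(blur_sigma_per_um * |Δz|, max_sigma), in pixels at the
    native 0.46 µm/px sampling.  sigma(0) = 0 and sigma is nondecreasing in
    |Δz|.  The default slope follows the geometric blur of a 0.75-NA
    objective: the blur disc radius grows by about NA µm per µm of defocus,
    i.e. roughly 1.6 px/µm at 0.46 µm/px, giving sigma ≈ 1.2 px/µm.
    """

    blur_sigma_per_um: float = 1.2
    # cap ≈ the blur at 8 µm defocus: beyond that the image carries no
    # usable structure and further widening changes nothing measurable
    max_sigma: float = 9.6

    def sigma(self, delta_z_um: float) -> float:
        return float(min(self.blur_sigma_per_um * abs(delta_z_um), self.max_sigma))


@dataclass(frozen=True)
class CellRecord:
    """One cell (or cluster) on the slide; appearance derives from its seed."""

    x_um: float
    y_um: float
    radius_um: float
    stain_class: str
    is_cluster: bool
    appearance_seed: int


@dataclass(frozen=True)
class DustRecord:
    """A dust speck on the coverslip plane."""

    x_um: float
    y_um: float
    radius_um: float
    appearance_seed: int


@dataclass(frozen=True)
class SlideConfig:
    """Generator parameters for one virtual slide.

    The defaults are a desk-scale rendition of a scanned ThinPrep slide:
    the native 4096-px scan width at 0.46 µm/px (≈1.88 mm), a cell circle
    filling most of it, a 20 µm focal range (the six-slide survey measured
    11.8–29.5 µm), and a dust plane 60 µm above the cell layer toward the
    objective.
    """

    width_um: float = 4096 * NATIVE_PIXEL_SIZE_UM
    height_um: float = 4096 * NATIVE_PIXEL_SIZE_UM
    pixel_size_um: float = NATIVE_PIXEL_SIZE_UM
    n_cells: int = 1200
    z_range_um: float = 20.0
    z_base_um: float = 100.0
    surface_grid_shape: tuple[int, int] = (4, 4)
    dust_density_per_mm2: float = 10.0
    dust_layer_offset_um: float = 60.0
    circle_diameter_um: float | None = None  # default: 0.85 * min extent
    cluster_fraction: float = 0.15
    stain_mix: tuple[float, float, float] = (0.70, 0.18, 0.12)
    cell_radius_um_range: tuple[float, float] = (7.0, 16.0)
    dust_radius_um_range: tuple[float, float] = (2.0, 7.0)
    palette: StainPalette = field(default_factory=StainPalette)
    defocus: DefocusModel = field(default_factory=DefocusModel)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0 or self.pixel_size_um <= 0:
            raise ConfigurationError("slide dimensions and pixel size must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be nonnegative")
        if self.z_range_um < 0:
            raise ConfigurationError("z_range_um must be nonnegative")
        if self.dust_density_per_mm2 < 0:
            raise ConfigurationError("dust density must be nonnegative")


@dataclass
class VirtualSlide:
    """A simulated LBC slide: cells on a 3D focal surface plus a dust plane."""

    config: SlideConfig
    surface: FocalSurface
    cell_records: list[CellRecord]
    dust_records: list[DustRecord]
    dust_z_um: float
    circle_center_um: tuple[float, float]
    circle_diameter_um: float

    @property
    def width_um(self) -> float:
        return self.config.width_um

    @property
    def height_um(self) -> float:
        return self.config.height_um

    @property
    def pixel_size_um(self) -> float:
        return self.config.pixel_size_um

    @property
    def seed(self) -> int:
        return self.config.seed

    def contains(self, x_um: float, y_um: float) -> bool:
        return 0.0 <= x_um <= self.width_um and 0.0 <= y_um <= self.height_um

    def in_circle(self, x_um: float, y_um: float) -> bool:
        cx, cy = self.circle_center_um
        return (x_um - cx) ** 2 + (y_um - cy) ** 2 <= (self.circle_diameter_um / 2) ** 2

    def dust_coverage(self, x_um: float, y_um: float, radius_um: float = 120.0) -> float:
        """Fraction of a neighborhood disc covered by dust specks."""
        if not self.dust_records:
            return 0.0
        d2 = np.array([(d.x_um - x_um) ** 2 + (d.y_um - y_um) ** 2
                       for d in self.dust_records])
        areas = np.array([np.pi * d.radius_um ** 2 for d in self.dust_records])
        inside = d2 <= radius_um ** 2
        return float(min(1.0, areas[inside].sum() / (np.pi * radius_um ** 2)))

    def cell_area_near(self, x_um: float, y_um: float, radius_um: float = 120.0) -> float:
        """Fraction of a neighborhood disc covered by cell material."""
        if not self.cell_records:
            return 0.0
        d2 = np.array([(c.x_um - x_um) ** 2 + (c.y_um - y_um) ** 2
                       for c in self.cell_records])
        areas = np.array([np.pi * c.radius_um ** 2 for c in self.cell_records])
        inside = d2 <= radius_um ** 2
        return float(min(1.0, areas[inside].sum() / (np.pi * radius_um ** 2)))

    def to_json(self, path) -> None:
        """Ground-truth sidecar: config, surface grid, cells, dust, seed."""
        payload = {
            "config": _config_to_jsonable(self.config),
            "surface_control_grid": self.surface.control_grid.tolist(),
            "cell_records": [asdict(c) for c in self.cell_records],
            "dust_records": [asdict(d) for d in self.dust_records],
            "dust_z_um": self.dust_z_um,
            "circle_center_um": list(self.circle_center_um),
            "circle_diameter_um": self.circle_diameter_um,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def from_json(path) -> "VirtualSlide":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = _config_from_jsonable(payload["config"])
        surface = FocalSurface(np.array(payload["surface_control_grid"]),
                               cfg.width_um, cfg.height_um)
        return VirtualSlide(
            config=cfg,
            surface=surface,
            cell_records=[CellRecord(**c) for c in payload["cell_records"]],
            dust_records=[DustRecord(**d) for d in payload["dust_records"]],
            dust_z_um=payload["dust_z_um"],
            circle_center_um=tuple(payload["circle_center_um"]),
            circle_diameter_um=payload["circle_diameter_um"],
        )


def _config_to_jsonable(cfg: SlideConfig) -> dict:
    d = asdict(cfg)
    return d


def _config_from_jsonable(d: dict) -> SlideConfig:
    d = dict(d)
    d["palette"] = StainPalette(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d["palette"].items()})
    d["defocus"] = DefocusModel(**d["defocus"])
    for key in ("surface_grid_shape", "stain_mix", "cell_radius_um_range",
                "dust_radius_um_range"):
        d[key] = tuple(d[key])
    return SlideConfig(**d)


# ---------------------------------------------------------------------------
# generation


def make_virtual_slide(config: SlideConfig | None = None, **overrides) -> VirtualSlide:
    """Build a deterministic virtual slide from a config (or keyword overrides).

    The focal surface's evaluated peak-to-peak range equals the requested
    ``z_range_um`` exactly (bilinear interpolation attains its extrema at
    grid nodes); identical configs give bit-identical slides.
    """
    if config is None:
        config = SlideConfig(**overrides)
    elif overrides:
        raise ConfigurationError("pass either a config or keyword overrides, not both")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    surf_rng, cell_rng, dust_rng = rng.spawn(3)

    # focal surface: random control grid rescaled to the requested range
    ny, nx = cfg.surface_grid_shape
    grid = surf_rng.normal(size=(ny, nx))
    span = grid.max() - grid.min()
    if cfg.z_range_um == 0 or span == 0:
        grid = np.full((ny, nx), cfg.z_base_um)
    else:
        grid = (grid - grid.min()) / span * cfg.z_range_um + cfg.z_base_um
    surface = FocalSurface(grid, cfg.width_um, cfg.height_um)

    diameter = cfg.circle_diameter_um or 0.85 * min(cfg.width_um, cfg.height_um)
    center = (cfg.width_um / 2.0, cfg.height_um / 2.0)

    # cells uniform in the circle (polar sqrt sampling)
    cells: list[CellRecord] = []
    r_lo, r_hi = cfg.cell_radius_um_range
    for _ in range(cfg.n_cells):
        rho = diameter / 2.0 * np.sqrt(cell_rng.uniform())
        theta = cell_rng.uniform(0, 2 * np.pi)
        x = center[0] + rho * np.cos(theta)
        y = center[1] + rho * np.sin(theta)
        radius = float(cell_rng.uniform(r_lo, r_hi))
        stain = STAIN_CLASSES[int(cell_rng.choice(3, p=cfg.stain_mix))]
        is_cluster = bool(cell_rng.uniform() < cfg.cluster_fraction)
        seed = int(cell_rng.integers(0, 2**31 - 1))
        cells.append(CellRecord(float(x), float(y), radius, stain, is_cluster, seed))

    # dust specks anywhere on the slide, on a plane nearer the objective
    area_mm2 = cfg.width_um * cfg.height_um / 1e6
    n_dust = int(np.round(cfg.dust_density_per_mm2 * area_mm2))
    d_lo, d_hi = cfg.dust_radius_um_range
    dust: list[DustRecord] = []
    for _ in range(n_dust):
        dust.append(DustRecord(
            float(dust_rng.uniform(0, cfg.width_um)),
            float(dust_rng.uniform(0, cfg.height_um)),
            float(dust_rng.uniform(d_lo, d_hi)),
            int(dust_rng.integers(0, 2**31 - 1)),
        ))
    dust_z = float(np.mean(grid)) - cfg.dust_layer_offset_um

    return VirtualSlide(
        config=cfg, surface=surface, cell_records=cells, dust_records=dust,
        dust_z_um=dust_z, circle_center_um=center, circle_diameter_um=diameter,
    )


# ---------------------------------------------------------------------------
# rendering

def _ellipse_coverage(hh: int, ww: int, cy: float, cx: float, a: float, b: float,
                      theta: float, aa_px: float = 1.2) -> np.ndarray:
    """Anti-aliased coverage of a rotated ellipse on an (hh, ww) patch grid."""
    yy, xx = np.mgrid[0:hh, 0:ww]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    f = np.sqrt((u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2)
    # smooth edge ~aa_px wide in pixel units near the boundary
    edge = aa_px / max(min(a, b), 1e-6)
    return np.clip((1.0 - f) / max(edge, 1e-6) + 0.5, 0.0, 1.0)


def _hsv(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v), dtype=float)


def _absorb(trans: np.ndarray, coverage: np.ndarray, color: np.ndarray,
            opacity: float) -> None:
    """Beer-Lambert-style composition: stains multiply transmittance down."""
    trans *= 1.0 - coverage[..., None] * opacity * (1.0 - color[None, None, :])


def _absorb_depth(trans: np.ndarray, coverage: np.ndarray, color: np.ndarray,
                  depth: float) -> None:
    """Absorb so the peak grayscale step is ~``depth`` (in [0,1] luma units).

    The opacity is solved from the stain color's luma; keeping each
    structure's boundary step gentle matches pale real-world cytology,
    where crisp detail lives in chromatin texture, not in outlines.
    """
    luma = float(color @ _LUMA_W)
    opacity = np.clip(depth / max((1.0 - luma) * 0.92, 1e-6), 0.0, 1.0)
    _absorb(trans, coverage, color, opacity)


_LUMA_W = np.array([0.299, 0.587, 0.114])


def _chromatin_texture(size: int, rng: np.random.Generator,
                       scale_px: float = 1.6, amount: float = 1.5) -> np.ndarray:
    """Fine multiplicative chromatin texture in [1-amount, 1+amount]."""
    noise = gaussian_filter(rng.normal(size=(size, size)), scale_px)
    noise /= max(np.abs(noise).max(), 1e-9)
    return 1.0 + amount * noise


def _blur_pad(trans: np.ndarray, margin: int, sigma_px: float
              ) -> tuple[np.ndarray, int]:
    """Pad a sharp transmittance patch with clear glass and defocus-blur it.

    Padding before blurring keeps the sharp rendering independent of the
    defocus, so one cell's appearance is identical at every focus height.
    """
    if sigma_px <= 0.05:
        return trans, margin
    pad = int(np.ceil(3.0 * sigma_px)) + 1
    out = np.pad(trans, ((pad, pad), (pad, pad), (0, 0)), constant_values=1.0)
    for c in range(3):
        out[..., c] = gaussian_filter(out[..., c], sigma_px,
                                      mode="constant", cval=1.0)
    return out, margin + pad


def _draw_cell_patch(rec: CellRecord, palette: StainPalette, radius_px: float,
                     sigma_px: float) -> tuple[np.ndarray, int]:
    """Render one cell into a transmittance patch; returns (patch, half-size)."""
    rng = np.random.default_rng(rec.appearance_seed)
    margin = int(np.ceil(radius_px * 1.6 + 2))
    size = 2 * margin + 1
    trans = np.ones((size, size, 3), dtype=float)

    n_lobes = int(rng.integers(3, 6)) if rec.is_cluster else 1
    for _ in range(n_lobes):
        if n_lobes == 1:
            cx = cy = float(margin)
            r = radius_px
        else:
            cx = margin + float(rng.uniform(-0.8, 0.8)) * radius_px
            cy = margin + float(rng.uniform(-0.8, 0.8)) * radius_px
            r = radius_px * float(rng.uniform(0.5, 0.85))
        theta = float(rng.uniform(0, np.pi))
        aspect = float(rng.uniform(0.6, 1.0))

        # cytoplasm: faint wash with fine granularity; the crisp in-focus
        # detail lives in this grain, not in the gentle outline.  A DAB-
        # positive (p16) cell's cytoplasm takes the brown chromogen hue —
        # the stain recolors the material rather than thickening it.
        if rec.stain_class == STAIN_P16:
            cyt_hue = _sample_hue(palette.dab_hue_range, rng)
        else:
            cyt_hue = _sample_hue(palette.cytoplasm_hue_range, rng)
        cyt = _hsv(cyt_hue, float(rng.uniform(0.45, 0.65)), float(rng.uniform(0.80, 0.92)))
        cov = _ellipse_coverage(size, size, cy, cx, r, r * aspect, theta)
        grain = _chromatin_texture(size, rng, scale_px=1.6, amount=0.9)
        _absorb_depth(trans, np.clip(cov * grain, 0.0, 1.0), cyt,
                      depth=float(rng.uniform(0.035, 0.055)))

        # nucleus: stain-class dependent color, crisp chromatin texture
        nr = r * float(rng.uniform(0.32, 0.50))
        if rec.stain_class == STAIN_KI67:
            hue = _sample_hue(palette.fastred_hue_range, rng)
            nuc = _hsv(hue, float(rng.uniform(0.80, 0.95)), float(rng.uniform(0.80, 0.95)))
        else:
            hue = _sample_hue(palette.nucleus_hue_range, rng)
            nuc = _hsv(hue, float(rng.uniform(0.80, 0.95)), float(rng.uniform(0.80, 0.95)))
        ncov = _ellipse_coverage(size, size, cy, cx, nr, nr * aspect, theta)
        tex = _chromatin_texture(size, rng)
        _absorb_depth(trans, np.clip(ncov * tex, 0.0, 1.0), nuc,
                      depth=float(rng.uniform(0.055, 0.075)))

    return _blur_pad(trans, margin, sigma_px)


def _draw_dust_patch(rec: DustRecord, radius_px: float, sigma_px: float
                     ) -> tuple[np.ndarray, int]:
    rng = np.random.default_rng(rec.appearance_seed)
    margin = int(np.ceil(radius_px + 2))
    size = 2 * margin + 1
    trans = np.ones((size, size, 3), dtype=float)
    theta = float(rng.uniform(0, np.pi))
    aspect = float(rng.uniform(0.5, 1.0))
    gray = float(rng.uniform(0.25, 0.55))
    color = np.array([gray, gray, gray])  # achromatic: fails every stain class
    cov = _ellipse_coverage(size, size, margin, margin, radius_px,
                            radius_px * aspect, theta)
    _absorb(trans, cov, color, opacity=float(rng.uniform(0.7, 0.95)))
    return _blur_pad(trans, margin, sigma_px)


def _composite(canvas: np.ndarray, patch: np.ndarray, row: int, col: int) -> None:
    """Multiply a patch's transmittance into the canvas at (row, col) top-left."""
    h, w = canvas.shape[:2]
    ph, pw = patch.shape[:2]
    r0, c0 = max(row, 0), max(col, 0)
    r1, c1 = min(row + ph, h), min(col + pw, w)
    if r0 >= r1 or c0 >= c1:
        return
    canvas[r0:r1, c0:c1] *= patch[r0 - row:r1 - row, c0 - col:c1 - col]


def render_at(slide: VirtualSlide, region_um: tuple[float, float, float, float],
              focus, *, pixel_size_um: float | None = None,
              noise_sigma: float | None = None) -> np.ndarray:
    """Render a slide region as an 8-bit RGB image at a given focus height.

    Parameters
    ----------
    region_um : (x0, y0, width, height) in µm, origin at the slide's top-left
        with x along columns and y along rows.  Must intersect the slide.
    focus : a focus height in µm, or a callable z(x_um, y_um) — e.g. a focus
        map — evaluated at each object's position.
    pixel_size_um : output sampling; defaults to the slide's native value.

    Each cell is blurred with sigma = defocus(|focus − surface(x, y)|); dust
    is keyed to the dust plane instead, so focusing on the dust plane makes
    dust sharp and cells blurred.
    """
    x0, y0, w, h = region_um
    if w <= 0 or h <= 0:
        raise ValueError("region width and height must be positive")
    if x0 + w <= 0 or y0 + h <= 0 or x0 >= slide.width_um or y0 >= slide.height_um:
        raise ValueError("region does not intersect the slide")
    ps = pixel_size_um or slide.pixel_size_um
    W = max(1, int(round(w / ps)))
    H = max(1, int(round(h / ps)))
    # blur sigmas are defined at native sampling; rescale to the output grid
    sigma_scale = NATIVE_PIXEL_SIZE_UM / ps

    bg = slide.config.palette.background_value / 255.0
    trans = np.ones((H, W, 3), dtype=float)

    def focus_z_at(x: float, y: float) -> float:
        return float(focus(x, y)) if callable(focus) else float(focus)

    defocus = slide.config.defocus
    for rec in slide.cell_records:
        radius_px = rec.radius_um / ps
        dz = abs(focus_z_at(rec.x_um, rec.y_um) - slide.surface(rec.x_um, rec.y_um))
        sigma = defocus.sigma(dz) * sigma_scale
        reach = (rec.radius_um * 1.6 + 3 * sigma * ps + 2 * ps)
        if (rec.x_um + reach < x0 or rec.x_um - reach > x0 + w or
                rec.y_um + reach < y0 or rec.y_um - reach > y0 + h):
            continue
        patch, margin = _draw_cell_patch(rec, slide.config.palette, radius_px, sigma)
        row = int(round((rec.y_um - y0) / ps)) - margin
        col = int(round((rec.x_um - x0) / ps)) - margin
        _composite(trans, patch, row, col)

    for rec in slide.dust_records:
        radius_px = rec.radius_um / ps
        dz = abs(focus_z_at(rec.x_um, rec.y_um) - slide.dust_z_um)
        sigma = defocus.sigma(dz) * sigma_scale
        reach = rec.radius_um + 3 * sigma * ps + 2 * ps
        if (rec.x_um + reach < x0 or rec.x_um - reach > x0 + w or
                rec.y_um + reach < y0 or rec.y_um - reach > y0 + h):
            continue
        patch, margin = _draw_dust_patch(rec, radius_px, sigma)
        row = int(round((rec.y_um - y0) / ps)) - margin
        col = int(round((rec.x_um - x0) / ps)) - margin
        _composite(trans, patch, row, col)

    img = bg * trans
    ns = slide.config.noise_sigma if noise_sigma is None else noise_sigma
    if ns > 0:
        nrng = np.random.default_rng((slide.seed, int(abs(x0)), int(abs(y0))))
        img = img + nrng.normal(0.0, ns / 255.0, img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def render_overview(slide: VirtualSlide, scale: float = 8.0, focus=None) -> np.ndarray:
    """Low-resolution whole-slide image (pixel size = native x scale)."""
    if focus is None:
        focus = slide.surface  # overview assumed focused; detail is irrelevant
    return render_at(slide, (0.0, 0.0, slide.width_um, slide.height_um), focus,
                     pixel_size_um=slide.pixel_size_um * scale)


def make_focus_strip(slide: VirtualSlide, point_um: tuple[float, float],
                     focus_z: float, strip_shape: tuple[int, int] = NATIVE_STRIP_SHAPE
                     ) -> np.ndarray:
    """Render the wide-and-short strip a line-sensor autofocus probe captures.

    ``strip_shape`` is (width, height) in pixels at native sampling; the strip
    is centered on ``point_um`` and clamped inside the slide.
    """
    x, y = point_um
    if not slide.contains(x, y):
        raise ValueError("focus point lies outside the slide")
    w_px, h_px = strip_shape
    ps = slide.pixel_size_um
    w_um, h_um = w_px * ps, h_px * ps
    x0 = min(max(x - w_um / 2.0, 0.0), max(slide.width_um - w_um, 0.0))
    y0 = min(max(y - h_um / 2.0, 0.0), max(slide.height_um - h_um, 0.0))
    return render_at(slide, (x0, y0, w_um, h_um), focus_z)


def make_macro_image(slide: VirtualSlide, scale: float = 16.0) -> np.ndarray:
    """Macro overview with the black border marks framing the cell circle.

    ThinPrep slides carry dark border marks around the cell circle; the
    scan-area detector segments these marks to locate the circle center.
    """
    img = render_overview(slide, scale=scale).astype(float) / 255.0
    ps = slide.pixel_size_um * scale
    cx, cy = slide.circle_center_um
    r = slide.circle_diameter_um / 2.0
    pad = 6.0 * ps   # frame sits just outside the circle
    bar = max(2, int(round(3.0)))  # bar thickness in macro pixels

    def to_px(v_um: float, limit: int) -> int:
        return int(np.clip(round(v_um / ps), 0, limit - 1))

    H, W = img.shape[:2]
    top = to_px(cy - r - pad, H)
    bot = to_px(cy + r + pad, H)
    left = to_px(cx - r - pad, W)
    right = to_px(cx + r + pad, W)
    img[top:top + bar, left:right + 1] = 0.0
    img[max(bot - bar + 1, 0):bot + 1, left:right + 1] = 0.0
    img[top:bot + 1, left:left + bar] = 0.0
    img[top:bot + 1, max(right - bar + 1, 0):right + 1] = 0.0
    return (img * 255.0 + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# labeled sets for training and validation


def make_cell_tile(rng_or_seed, defocus_um: float = 0.0, tile_px: int = 64,
                   palette: StainPalette | None = None,
                   defocus: DefocusModel | None = None,
                   stain_class: str | None = None) -> np.ndarray:
    """Render one synthetic cell tile at a given defocus offset (µm)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    palette = palette or StainPalette()
    defocus = defocus or DefocusModel()
    ps = NATIVE_PIXEL_SIZE_UM
    radius_um = float(rng.uniform(6.0, min(13.0, tile_px * ps / 2.4)))
    stain = stain_class or STAIN_CLASSES[int(rng.integers(0, 3))]
    rec = CellRecord(0.0, 0.0, radius_um, stain, False,
                     int(rng.integers(0, 2**31 - 1)))
    sigma = defocus.sigma(defocus_um)
    patch, margin = _draw_cell_patch(rec, palette, radius_um / ps, sigma)
    bg = palette.background_value / 255.0
    canvas = np.ones((tile_px, tile_px, 3), dtype=float)
    _composite(canvas, patch, tile_px // 2 - margin, tile_px // 2 - margin)
    return (np.clip(bg * canvas, 0, 1) * 255.0 + 0.5).astype(np.uint8)


def make_training_set(n_per_class: int, seed: int = 0, *, tile_px: int = 64,
                      in_focus_max_offset_um: float = 2.0,
                      out_focus_min_offset_um: float = 8.0,
                      out_focus_max_offset_um: float = 15.0,
                      palette: StainPalette | None = None,
                      defocus: DefocusModel | None = None) -> list[CellImage]:
    """Balanced labeled cell images: half in-focus, half defocused.

    The in-focus class is rendered at focal errors below 1 µm (within the
    objective's depth of field); the out-of-focus class at offsets sampled
    uniformly above the configured minimum (default 8 µm, clearly blurred).
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if not (0 <= out_focus_min_offset_um <= out_focus_max_offset_um):
        raise ConfigurationError("invalid out-of-focus offset range")
    rng = np.random.default_rng(seed)
    images: list[CellImage] = []
    for i in range(n_per_class):
        for label in (1, 0):
            if label == 1:
                dz = float(rng.uniform(0.0, in_focus_max_offset_um))
            else:
                dz = float(rng.uniform(out_focus_min_offset_um,
                                       out_focus_max_offset_um))
            tile = make_cell_tile(rng, dz, tile_px, palette, defocus)
            area = int(np.sum(np.mean(tile, axis=2) <
                              (palette or StainPalette()).background_value - 10))
            images.append(CellImage(pixels=tile, location=(0.0, 0.0),
                                    region_index=0, area_px=max(area, 1),
                                    true_label=label))
    return images


def make_validation_strips(n: int, seed: int = 0, *,
                           strip_shape: tuple[int, int] = NATIVE_STRIP_SHAPE,
                           invalid_defocus_um: float = 10.0
                           ) -> list[tuple[np.ndarray, bool]]:
    """Labeled focus-point strips: half valid, half invalid by construction.

    Valid strips contain in-focus stained cells.  Invalid strips cycle
    through the failure modes an autofocus probe actually meets: blank
    glass, in-focus dust with no cells, and cells defocused by at least
    ``invalid_defocus_um``.
    """
    rng = np.random.default_rng(seed)
    w_px, h_px = strip_shape
    ps = NATIVE_PIXEL_SIZE_UM
    w_um, h_um = w_px * ps * 1.5, h_px * ps * 6  # mini-slide with margin

    def mini_slide(sub: int, dust_density: float = 0.0) -> VirtualSlide:
        return make_virtual_slide(SlideConfig(
            width_um=w_um, height_um=h_um, n_cells=0, z_range_um=0.0,
            dust_density_per_mm2=dust_density,
            dust_radius_um_range=(3.0, 8.0), seed=sub))

    def add_cells_in_strip(mini: VirtualSlide, count: int) -> None:
        # cells placed on the strip's center line so every "cell" strip
        # actually contains cellular material
        strip_w_um = w_px * ps
        for _ in range(count):
            x = float(rng.uniform(w_um / 2 - strip_w_um / 2 + 15,
                                  w_um / 2 + strip_w_um / 2 - 15))
            y = float(rng.uniform(h_um / 2 - 6.0, h_um / 2 + 6.0))
            radius = float(rng.uniform(7.0, 13.0))
            stain = STAIN_CLASSES[int(rng.integers(0, 3))]
            mini.cell_records.append(CellRecord(
                x, y, radius, stain, bool(rng.uniform() < 0.15),
                int(rng.integers(0, 2**31 - 1))))

    out: list[tuple[np.ndarray, bool]] = []
    center = (w_um / 2, h_um / 2)
    for i in range(n):
        valid = i % 2 == 0
        mode = (i // 2) % 3
        sub = int(rng.integers(0, 2**31 - 1))
        if valid:
            mini = mini_slide(sub)
            add_cells_in_strip(mini, int(rng.integers(2, 6)))
            strip = make_focus_strip(mini, center, mini.surface.z_min, strip_shape)
        elif mode == 0:      # blank glass
            mini = mini_slide(sub)
            strip = make_focus_strip(mini, center, mini.surface.z_min, strip_shape)
        elif mode == 1:      # in-focus dust, no cells
            mini = mini_slide(sub, dust_density=4000.0)
            strip = make_focus_strip(mini, center, mini.dust_z_um, strip_shape)
        else:                # defocused cells
            mini = mini_slide(sub)
            add_cells_in_strip(mini, int(rng.integers(2, 6)))
            dz = float(rng.uniform(invalid_defocus_um, invalid_defocus_um + 8.0))
            strip = make_focus_strip(mini, center, mini.surface.z_min + dz,
                                     strip_shape)
        out.append((strip, valid))
    return out
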