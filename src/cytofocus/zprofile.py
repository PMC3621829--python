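"""Z-dimension analysis of focus-point datasets.

Autofocus probes on a liquid-based cytology slide return one z-height per
(x, y) location.  Plotting those heights reveals two layers: the cell layer
itself (a smooth, gently folded surface a few tens of micrometres thick)
and a spurious layer from dust on the coverslip, which sits closer to the
objective and which general-purpose autofocus happily locks onto.  This
module separates the two layers, computes descriptive statistics of the
cell layer, and answers the multi-layer arithmetic question: how many
evenly spaced z-stack planes a given focal range would require.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ZDataset",
    "ZStats",
    "separate_layers",
    "z_stats",
    "layers_needed",
    "read_zdataset_csv",
    "write_zdataset_csv",
    "stats_table",
]

LAYER_CELL = "cell"
LAYER_DUST = "dust"


@dataclass
class ZDataset:
    """Focus-point heights with optional per-point layer labels.

    ``points`` is an (n, 3) array of (x_um, y_um, z_um).  The scanner reports
    z relative to an origin inside the objective; ``normalization_offset_um``
    records the constant already subtracted so that stored z values are small
    and nonnegative.
    """

    points: np.ndarray
    normalization_offset_um: float = 0.0
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (x, y, z)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("z dataset contains non-finite coordinates")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels length must match number of points")

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def subset(self, label: str) -> "ZDataset":
        if self.labels is None:
            raise ValueError("dataset is unlabeled; run separate_layers first")
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return ZDataset(
            self.points[keep],
            self.normalization_offset_um,
            [self.labels[i] for i in keep],
        )


@dataclass(frozen=True)
class ZStats:
    """Descriptive statistics of a z-height sample, all in micrometres."""

    n_valid: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    range: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_valid": self.n_valid,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "range": self.range,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def separate_layers(data: ZDataset, min_gap_factor: float = 3.0) -> ZDataset:
    """Label each point as cell-layer or dust-layer by a 1-D split on z.

    The split is the largest gap between consecutive sorted z values,
    accepted only if it exceeds ``min_gap_factor`` times the pooled
    within-cluster standard deviation (otherwise the sample is a single
    layer and everything is labeled cell).  Dust sits nearer the objective,
    i.e. at smaller normalized z, so the lower cluster is labeled dust.
    """
    z = data.z
    if len(z) < 2:
        raise ValueError("layer separation needs at least 2 points")

    order = np.argsort(z)
    zs = z[order]
    gaps = np.diff(zs)
    split = int(np.argmax(gaps))
    gap = float(gaps[split])

    lower = zs[: split + 1]
    upper = zs[split + 1 :]
    # pooled within-cluster sd; singleton clusters contribute zero spread
    sds = [np.std(c, ddof=1) for c in (lower, upper) if len(c) > 1]
    pooled = float(np.sqrt(np.mean(np.square(sds)))) if sds else 0.0

    labels = [LAYER_CELL] * len(z)
    threshold = min_gap_factor * pooled
    if gap > threshold and gap > 0:
        cut = float(zs[split]) + gap / 2.0
        labels = [LAYER_DUST if zi < cut else LAYER_CELL for zi in z]
    return replace(data, labels=labels)


def z_stats(data: ZDataset) -> ZStats:
    """Descriptive statistics of the (cell-layer) z heights.

    Uses the sample (n-1) standard deviation; a single point has sd 0 by
    convention.
    """
    z = data.z
    if len(z) == 0:
        raise ValueError("cannot compute statistics of an empty dataset")
    sd = float(np.std(z, ddof=1)) if len(z) > 1 else 0.0
    return ZStats(
        n_valid=int(len(z)),
        mean=float(np.mean(z)),
        median=float(np.median(z)),
        sd=sd,
        min=float(np.min(z)),
        max=float(np.max(z)),
        range=float(np.max(z) - np.min(z)),
    )


def layers_needed(z_range_um: float, spacing_um: float) -> int:
    """Number of evenly spaced z-stack planes needed to cover a focal range.

    ceil(range / spacing), at least 1: even a perfectly flat sample needs
    one layer.
    """
    if spacing_um <= 0:
        raise ValueError("layer spacing must be positive")
    if z_range_um < 0:
        raise ValueError("z range must be nonnegative")
    return max(1, math.ceil(z_range_um / spacing_um))


def read_zdataset_csv(path) -> ZDataset:
    """Read a focus-point dataset from CSV (x_um, y_um, z_um[, label])."""
    df = pd.read_csv(path)
    required = ["x_um", "y_um", "z_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing columns: {missing}")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return ZDataset(df[required].to_numpy(dtype=float), labels=labels)


_STAT_ROWS = [
    ("Nr. of valid focus points", "n_valid"),
    ("Arithmetic average (um)", "mean"),
    ("Median (um)", "median"),
    ("Standard deviation (um)", "sd"),
    ("Minimum (um)", "min"),
    ("Maximum (um)", "max"),
    ("Range (um)", "range"),
]


def stats_table(per_slide: dict[str, ZStats]) -> pd.DataFrame:
    """Descriptive-statistics table: one column per slide, stats as rows."""
    data = {name: [getattr(s, attr) for _, attr in _STAT_ROWS]
            for name, s in per_slide.items()}
    return pd.DataFrame(data, index=[label for label, _ in _STAT_ROWS])


def write_zdataset_csv(data: ZDataset, path) -> None:
    df = pd.DataFrame(data.points, columns=["x_um", "y_um", "z_um"])
    if data.labels is not None:
        df["label"] = data.labels
    df.to_csv(path, index=False)
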