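"""Quantification of Grad-CAM ROIs into 20 scattergram parameters.

Three image-processing metric families summarize each of the four views:

* particle count inside ROIs — ``APL-Ratio``: fraction of foreground
  ("particle") pixels covered by the Grad-CAM ROI masks;
* particle population area — ``Neu-Area``: foreground pixel count inside
  the neutrophil gate;
* particle population spacing — ``ClusterDist`` (mean pairwise centroid
  distance of the largest foreground components) and ``LymMonDist`` /
  ``NeuMonDist`` (centroid distances between gated populations).

Five metrics x four views = the fixed 20-parameter roster.  Foreground is
defined by a fixed intensity threshold on the density image; population
gates are fixed pixel-space rectangles derived from the shipped population
geometry, one set per view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skimage import measure

from .cnnroi import ROISet
from .prep import ALL_VIEWS, PROJECTIONS, RESOLUTION, ScattergramImage, ViewTag
from .synthgram import ConfigurationError, ValidationError, _DIFF_BASE, _WNB_BASE

logger = logging.getLogger(__name__)

METRICS = ("APL-Ratio", "ClusterDist", "Neu-Area", "LymMonDist", "NeuMonDist")
VIEW_ORDER = tuple(v.name for v in ALL_VIEWS)  # DIFF-XY, DIFF-YZ, WNB-XY, WNB-YZ

#: the fixed 20-name roster, e.g. "D-APL-Ratio-XY", "N-ClusterDist-YZ"
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{view.prefix}-{metric}-{view.projection}"
    for view in ALL_VIEWS for metric in METRICS
)
assert len(FEATURE_NAMES) == 20


@dataclass(frozen=True)
class Gate:
    """Half-open pixel rectangle [row_lo, row_hi) x [col_lo, col_hi)."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int

    def __post_init__(self) -> None:
        ok = (0 <= self.row_lo < self.row_hi <= RESOLUTION
              and 0 <= self.col_lo < self.col_hi <= RESOLUTION)
        if not ok:
            raise ValidationError(f"gate {self} outside image bounds")

    def mask(self, shape=(RESOLUTION, RESOLUTION)) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row_lo:self.row_hi, self.col_lo:self.col_hi] = True
        return m


def _event_to_pixel(x: float, y_fl: float, log_x: bool) -> tuple[int, int]:
    """Map event-space (x, FL) to (row, col) with the render conventions."""
    if log_x:
        x = math.log1p(x) / math.log(2.0)
    col = min(max(int(x * RESOLUTION), 0), RESOLUTION - 1)
    row = RESOLUTION - 1 - min(max(int(y_fl * RESOLUTION), 0), RESOLUTION - 1)
    return row, col


def _default_gate(view: ViewTag, pop: str, half_width: float = 0.14) -> Gate:
    """Rectangle around the shipped population center, +-half_width (event
    units) per axis, mapped through the render transform."""
    base = _DIFF_BASE if view.channel == "DIFF" else _WNB_BASE
    fs, ss, fl = base[pop][0]
    ax_x, _ = PROJECTIONS[view.projection]
    x = ss if ax_x == "ss" else fs
    log_x = ax_x == "ss"
    # high fluorescence sits at small row indices (image is FL-flipped)
    r_lo, c_lo = _event_to_pixel(max(x - half_width, 0.0),
                                 min(fl + half_width, 1.0 - 1e-9), log_x)
    r_hi, c_hi = _event_to_pixel(min(x + half_width, 1.0 - 1e-9),
                                 max(fl - half_width, 0.0), log_x)
    return Gate(r_lo, r_hi + 1, c_lo, c_hi + 1)


def default_gates() -> dict[tuple[str, str], Gate]:
    """(view name, population) -> gate, for Neu/Lym/Mon in all four views."""
    return {(view.name, pop): _default_gate(view, pop)
            for view in ALL_VIEWS for pop in ("Neu", "Lym", "Mon")}


@dataclass
class QuantConfig:
    foreground_threshold: float = 10.0
    cluster_top_k: int = 3
    gates: dict[tuple[str, str], Gate] = field(default_factory=default_gates)

    def __post_init__(self) -> None:
        if not 0 < self.foreground_threshold <= 255:
            raise ValidationError("foreground_threshold must be in (0, 255]")
        if self.cluster_top_k < 2:
            raise ValidationError("cluster_top_k must be >= 2")


@dataclass
class ScatterFeatures:
    """The 20 named scattergram parameters for one sample."""

    values: dict[str, float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValidationError("feature roster mismatch")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def foreground_mask(image: ScattergramImage | np.ndarray,
                    threshold: float = 10.0) -> np.ndarray:
    """Particle pixels: channel-mean intensity >= threshold."""
    px = image.pixels if isinstance(image, ScattergramImage) else np.asarray(image)
    if px.ndim == 3:
        px = px.astype(float).mean(axis=2)
    return px >= threshold


def apl_ratio(mask: np.ndarray, rois: ROISet) -> float:
    """Fraction of foreground pixels inside the ROI union (0 if no
    foreground)."""
    for m in rois.masks:
        if m.shape != mask.shape:
            raise ValidationError("ROI/mask dimension mismatch")
    total = int(mask.sum())
    if total == 0:
        return 0.0
    union = rois.union(mask.shape)
    return float((mask & union).sum() / total)


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def cluster_dist(mask: np.ndarray, top_k: int = 3) -> float:
    """Mean pairwise centroid distance of the ``top_k`` largest 8-connected
    foreground components (0 with fewer than two components)."""
    if top_k < 2:
        raise ValidationError("top_k must be >= 2")
    labeled = measure.label(mask, connectivity=2)
    comps = sorted(
        (labeled == lab for lab in range(1, labeled.max() + 1)),
        key=lambda m: -int(m.sum()),
    )[:top_k]
    if len(comps) < 2:
        return 0.0
    cents = [_centroid(c) for c in comps]
    dists = [math.dist(a, b) for a, b in combinations(cents, 2)]
    return float(np.mean(dists))


def population_metrics(mask: np.ndarray, view_name: str,
                       gates: dict[tuple[str, str], Gate]
                       ) -> tuple[float, float, float]:
    """(Neu area, Lym-Mon centroid distance, Neu-Mon centroid distance)
    from gated foreground pixels; metrics touching an empty population are
    0 with a logged warning."""
    pix: dict[str, np.ndarray] = {}
    for pop in ("Neu", "Lym", "Mon"):
        key = (view_name, pop)
        if key not in gates:
            raise ConfigurationError(f"no gate for {key}")
        pix[pop] = mask & gates[key].mask(mask.shape)
    neu_area = float(pix["Neu"].sum())

    def _dist(a: str, b: str) -> float:
        if not pix[a].any() or not pix[b].any():
            logger.warning("empty %s/%s population in %s; distance set to 0",
                           a, b, view_name)
            return 0.0
        return float(math.dist(_centroid(pix[a]), _centroid(pix[b])))

    return neu_area, _dist("Lym", "Mon"), _dist("Neu", "Mon")


def quantify_sample(images: dict[str, ScattergramImage],
                    rois: dict[str, ROISet],
                    cfg: QuantConfig | None = None,
                    sample_id: str = "") -> ScatterFeatures:
    """Assemble the 20-parameter vector for one sample from its four views."""
    cfg = cfg or QuantConfig()
    missing = [v.name for v in ALL_VIEWS if v.name not in images or v.name not in rois]
    if missing:
        raise ValidationError(f"missing views: {missing}")
    values: dict[str, float] = {}
    for view in ALL_VIEWS:
        mask = foreground_mask(images[view.name], cfg.foreground_threshold)
        ratio = apl_ratio(mask, rois[view.name])
        cdist = cluster_dist(mask, cfg.cluster_top_k)
        neu_area, lymmon, neumon = population_metrics(mask, view.name, cfg.gates)
        p, proj = view.prefix, view.projection
        values[f"{p}-APL-Ratio-{proj}"] = ratio
        values[f"{p}-ClusterDist-{proj}"] = cdist
        values[f"{p}-Neu-Area-{proj}"] = neu_area
        values[f"{p}-LymMonDist-{proj}"] = lymmon
        values[f"{p}-NeuMonDist-{proj}"] = neumon
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return ScatterFeatures(ordered, sample_id)


def features_to_frame(feats: list[ScatterFeatures]):
    """Samples x 20 DataFrame with a sample_id column."""
    import pandas as pd

    rows = []
    for f in feats:
        row = {"sample_id": f.sample_id}
        row.update(f.values)
        rows.append(row)
    return pd.DataFrame(rows)
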