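"""Scattergram rendering and image preprocessing.

Event clouds are projected onto two planes per channel — SS-FL (the "XY"
perspective) and FS-FL (the "YZ" perspective) — binned into a 256x256
density grid, log-compressed and min-max scaled to 8-bit, mirroring the
scattergrams a hematology analyzer exports.  Side-scatter values are
log-transformed before binning to spread the particle clusters apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize

from .synthgram import CHANNELS, EventCloud, ValidationError

RESOLUTION = 256

#: projection -> (x-axis, y-axis) in event space; XY is the SS-FL plane and
#: YZ the FS-FL plane (the y axis is always fluorescence).
PROJECTIONS = {"XY": ("ss", "fl"), "YZ": ("fs", "fl")}

#: channel prefix used in feature names (DIFF -> "D", WNB -> "N")
CHANNEL_PREFIX = {"DIFF": "D", "WNB": "N"}


@dataclass(frozen=True)
class ViewTag:
    """One of the four (channel, projection) scattergram views."""

    channel: str
    projection: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.projection not in PROJECTIONS:
            raise ValidationError(f"unknown projection {self.projection!r}")

    @property
    def name(self) -> str:
        return f"{self.channel}-{self.projection}"

    @property
    def prefix(self) -> str:
        return CHANNEL_PREFIX[self.channel]


ALL_VIEWS = tuple(
    ViewTag(c, p) for c in ("DIFF", "WNB") for p in ("XY", "YZ")
)


@dataclass
class ScattergramImage:
    """256x256x3 8-bit scattergram; row 0 is the highest-fluorescence row."""

    pixels: np.ndarray
    view: ViewTag
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (RESOLUTION, RESOLUTION, 3):
            raise ValidationError(f"expected {RESOLUTION}x{RESOLUTION}x3, got {px.shape}")
        self.pixels = px.astype(np.uint8)


def log_transform_ssc(ss_values) -> np.ndarray:
    """Elementwise y = ln(1 + s); strictly monotone, maps 0 to 0."""
    s = np.asarray(ss_values, dtype=float)
    if (s < 0).any():
        raise ValidationError("side-scatter values must be non-negative")
    return np.log1p(s)


def _axis_values(cloud: EventCloud, axis: str) -> np.ndarray:
    v = getattr(cloud, axis)
    if axis == "ss":
        # log-compress, then rescale so the unit interval stays the bin range
        return log_transform_ssc(v) / np.log(2.0)
    return np.asarray(v, dtype=float)


def render_scattergram(cloud: EventCloud, view: ViewTag,
                       resolution: int = RESOLUTION) -> ScattergramImage:
    """Render an event cloud into one scattergram view.

    Events are histogrammed into ``resolution``^2 half-open bins over [0, 1)
    (a coordinate of exactly 1.0 falls in the last bin), intensity is
    ln(1 + count) min-max scaled to [0, 255], replicated to three channels,
    and the fluorescence axis is flipped so high FL sits at image row 0.
    """
    if cloud.channel != view.channel:
        raise ValidationError(
            f"cloud channel {cloud.channel} does not match view {view.name}")
    counts = np.zeros((resolution, resolution), dtype=np.int64)
    if cloud.n_events == 0:
        warnings.warn(f"empty event cloud for {view.name}; rendering blank image")
    else:
        ax_x, ax_y = PROJECTIONS[view.projection]
        x = _axis_values(cloud, ax_x)
        y = _axis_values(cloud, ax_y)
        ix = np.clip((x * resolution).astype(np.int64), 0, resolution - 1)
        iy = np.clip((y * resolution).astype(np.int64), 0, resolution - 1)
        np.add.at(counts, (iy, ix), 1)
    img = np.log1p(counts.astype(float))
    mx = img.max()
    if mx > 0:
        img = img / mx * 255.0
    img = np.flipud(img)  # row 0 = highest fluorescence
    px = np.repeat(np.rint(img).astype(np.uint8)[:, :, None], 3, axis=2)
    return ScattergramImage(px, view, cloud.sample_id)


def render_counts(cloud: EventCloud, view: ViewTag,
                  resolution: int = RESOLUTION) -> np.ndarray:
    """Raw bin counts for a view, before log scaling (same geometry as
    :func:`render_scattergram`, fluorescence flipped).  Sum equals the
    event count."""
    counts = np.zeros((resolution, resolution), dtype=np.int64)
    if cloud.n_events:
        ax_x, ax_y = PROJECTIONS[view.projection]
        x = _axis_values(cloud, ax_x)
        y = _axis_values(cloud, ax_y)
        ix = np.clip((x * resolution).astype(np.int64), 0, resolution - 1)
        iy = np.clip((y * resolution).astype(np.int64), 0, resolution - 1)
        np.add.at(counts, (iy, ix), 1)
    return np.flipud(counts)


def normalize_image(img, view: ViewTag | None = None,
                    target_size: int = RESOLUTION,
                    sample_id: str = "") -> ScattergramImage | np.ndarray:
    """Bilinear-resize to ``target_size`` square and min-max scale to [0, 255].

    A constant input maps to all zeros ("no particles").  Returns a
    :class:`ScattergramImage` when ``view`` is given, else the raw array.
    """
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot normalize an empty image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[:2] != (target_size, target_size):
        arr = _sk_resize(arr, (target_size, target_size), order=1,
                         preserve_range=True, anti_aliasing=False)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    out = np.rint(arr).astype(np.uint8)
    if view is None:
        return out
    return ScattergramImage(out, view, sample_id)


def minmax_rescale(values) -> np.ndarray:
    """Min-max rescale any array to [0, 255] without resizing (constant
    arrays map to zeros)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo) * 255.0


# ---------------------------------------------------------------------------
# PNG round trip


def image_filename(sample_id: str, view: ViewTag) -> str:
    return f"{sample_id}_{view.channel}_{view.projection}.png"


def save_png(image: ScattergramImage, directory) -> str:
    from pathlib import Path

    path = Path(directory) / image_filename(image.sample_id, image.view)
    PILImage.fromarray(image.pixels, mode="RGB").save(path)
    return str(path)


def load_png(path, view: ViewTag, sample_id: str = "") -> ScattergramImage:
    px = np.asarray(PILImage.open(path).convert("RGB"))
    return ScattergramImage(px, view, sample_id)


def render_sample(sample) -> dict[str, ScattergramImage]:
    """All four views for one cohort sample, keyed by view name."""
    out = {}
    for view in ALL_VIEWS:
        cloud = sample.diff_cloud if view.channel == "DIFF" else sample.wnb_cloud
        out[view.name] = render_scattergram(cloud, view)
    return out
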