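"""Synthetic cut-specimen photographs and the measurement chain.

A thermochromic tissue-mimicking phantom turns irreversibly from off-white
to magenta where it was heated above 60 degC, so a cut along the probe axis
exposes the ablation cross-section as a magenta region.  The specimen is
photographed on a canvas with dark square fiducial markers of known
physical side length; the markers recover the pixel spacing, a
hue/saturation window segments the magenta region, and the principal-axis
width profile of the segmented mask gives physical ablation dimensions.

Rendering is fully synthetic and fronto-parallel (no perspective or lens
model); it exists to exercise and validate the measurement chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from ablashape.shape_margin import AblationShape

__all__ = [
    "SpecimenImage",
    "ColorConfig",
    "SegmentationResult",
    "DEFAULT_NOISE",
    "render_specimen",
    "estimate_pixel_spacing",
    "segment_ablation",
    "extract_width_profile",
    "measure_specimen",
    "save_image",
    "load_image",
]

#: Default channel noise sd (on the [0, 1] intensity scale) for renders.
DEFAULT_NOISE = 0.02

_BACKGROUND = np.array([0.94, 0.94, 0.90])
_MAGENTA = np.array([0.78, 0.12, 0.62])
_MARKER = np.array([0.08, 0.08, 0.08])


@dataclass
class SpecimenImage:
    """RGB photograph (uint8) of a cut specimen with fiducial markers.

    Synthetic renders carry the ground truth: true pixel spacing, the
    marker side length and corner positions, and the noiseless ablation
    mask.
    """

    image: np.ndarray
    spacing_mm_px: float
    marker_side_mm: float
    marker_corners_px: list = field(default_factory=list)
    true_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spacing_mm_px <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass(frozen=True)
class ColorConfig:
    """Hue/saturation window around the magenta reference color."""

    hue_center_deg: float = 300.0
    hue_tol_deg: float = 40.0
    sat_min: float = 0.3
    val_min: float = 0.15
    selem_size: int = 3


@dataclass
class SegmentationResult:
    """Output of the full measurement chain on one specimen image."""

    mask: np.ndarray
    spacing_mm_px: float
    x_mm: np.ndarray
    width_mm: np.ndarray
    length_mm: float
    flags: list = field(default_factory=list)


def render_specimen(
    shape: AblationShape,
    spacing: float = 0.2,
    marker_side: float = 10.0,
    noise: float = DEFAULT_NOISE,
    seed: int | None = None,
    frame_margin_mm: float = 18.0,
    frame_size_mm: tuple[float, float] | None = None,
) -> SpecimenImage:
    """Render a synthetic specimen photo of an ablation cross-section.

    Off-white background, magenta region equal to the shape's axial slice,
    four dark square fiducials of ``marker_side`` mm near the corners.
    ``noise`` adds seeded Gaussian color noise (with a slight blur); at
    ``noise = 0`` the magenta pixel set equals the rasterized slice
    exactly and renders are bit-identical for equal seeds.
    """
    if spacing <= 0 or marker_side <= 0:
        raise ValueError("spacing and marker_side must be positive")
    r0, r1 = shape.cap_radii
    extent_x = shape.total_length
    extent_y = shape.max_width

    marker_px = max(int(round(marker_side / spacing)), 1)
    margin_px = int(round(frame_margin_mm / spacing))
    if frame_size_mm is not None:
        frame_w, frame_h = frame_size_mm
        if extent_x + 2 * frame_margin_mm > frame_w or extent_y + 2 * frame_margin_mm > frame_h:
            raise ValueError(
                f"shape extent {extent_x:.0f} x {extent_y:.0f} mm (plus margins) "
                f"does not fit the {frame_w:.0f} x {frame_h:.0f} mm frame"
            )
        w_px = int(round(frame_w / spacing))
        h_px = int(round(frame_h / spacing))
    else:
        w_px = int(round(extent_x / spacing)) + 2 * margin_px
        h_px = int(round(extent_y / spacing)) + 2 * margin_px
    min_frame = 2 * (marker_px + 8)
    if w_px < min_frame or h_px < min_frame:
        w_px = max(w_px, min_frame)
        h_px = max(h_px, min_frame)

    # axial slice mask in pixel coordinates (rows = transverse, cols = axial)
    cols = (np.arange(w_px) + 0.5) * spacing  # mm from left edge
    rows = (np.arange(h_px) + 0.5) * spacing
    x0_mm = margin_px * spacing + r0  # active span start in frame coords
    axis_y = h_px / 2 * spacing
    xg = cols[None, :] - x0_mm
    yg = rows[:, None] - axis_y
    span = float(shape.x[-1] - shape.x[0])
    half_w = np.interp(np.clip(xg, 0, span), shape.x - shape.x[0], shape.width) / 2.0
    mask = (xg >= 0) & (xg <= span) & (np.abs(yg) <= half_w)
    mask |= (xg < 0) & (xg**2 + yg**2 <= r0**2)
    mask |= (xg > span) & ((xg - span) ** 2 + yg**2 <= r1**2)

    img = np.empty((h_px, w_px, 3))
    img[:] = _BACKGROUND
    img[mask] = _MAGENTA

    inset = 4
    corners = [
        (inset, inset),
        (inset, w_px - inset - marker_px),
        (h_px - inset - marker_px, inset),
        (h_px - inset - marker_px, w_px - inset - marker_px),
    ]
    for r, c in corners:
        if mask[r : r + marker_px, c : c + marker_px].any():
            raise ValueError("shape too large for the frame: it overlaps a fiducial")
        img[r : r + marker_px, c : c + marker_px] = _MARKER

    if noise > 0:
        rng = np.random.default_rng(seed)
        img = skfilters.gaussian(img, sigma=0.6, channel_axis=-1)
        img = img + rng.normal(0.0, noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SpecimenImage(
        image=(img * 255).round().astype(np.uint8),
        spacing_mm_px=spacing,
        marker_side_mm=marker_side,
        marker_corners_px=corners,
        true_mask=mask,
    )


def _as_float_rgb(img) -> np.ndarray:
    arr = img.image if isinstance(img, SpecimenImage) else np.asarray(img)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return arr


def estimate_pixel_spacing(img: SpecimenImage, marker_side: float | None = None) -> float:
    """Pixel spacing [mm/px] from the dark square fiducials.

    Dark, square-ish connected components (high fill ratio, near-unit
    aspect) are taken as markers; the estimate is ``marker_side`` divided
    by the mean marker side in pixels (sqrt of component area).
    """
    arr = _as_float_rgb(img)
    if marker_side is None:
        if not isinstance(img, SpecimenImage):
            raise ValueError("marker_side must be given for raw arrays")
        marker_side = img.marker_side_mm
    gray = arr.mean(axis=-1)
    dark = gray < 0.35
    labels = skmeasure.label(dark)
    sides = []
    for region in skmeasure.regionprops(labels):
        if region.area < 16:
            continue
        h = region.bbox[2] - region.bbox[0]
        w = region.bbox[3] - region.bbox[1]
        aspect = max(h, w) / max(min(h, w), 1)
        fill = region.area / (h * w)
        if aspect <= 1.3 and fill >= 0.8:
            sides.append(np.sqrt(region.area))
    if not sides:
        raise ValueError("no fiducial marker detected")
    return float(marker_side / np.mean(sides))


def segment_ablation(img: SpecimenImage, config: ColorConfig | None = None) -> np.ndarray:
    """Color-based segmentation of the magenta ablation region.

    Pixels inside the configured hue/saturation window are morphologically
    opened and closed (square footprint) and the largest connected
    component is kept.  An empty result returns an all-false mask (checked
    via ``mask.any()``), never an exception.
    """
    config = config or ColorConfig()
    arr = _as_float_rgb(img)
    hsv = skcolor.rgb2hsv(arr)
    hue_deg = hsv[..., 0] * 360.0
    d_hue = np.abs((hue_deg - config.hue_center_deg + 180.0) % 360.0 - 180.0)
    mask = (
        (d_hue <= config.hue_tol_deg)
        & (hsv[..., 1] >= config.sat_min)
        & (hsv[..., 2] >= config.val_min)
    )
    footprint = skmorph.footprint_rectangle((config.selem_size, config.selem_size))
    mask = skmorph.opening(mask, footprint)
    mask = skmorph.closing(mask, footprint)
    if not mask.any():
        return mask
    labels = skmeasure.label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def extract_width_profile(
    mask: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Axial width profile of a segmented ablation mask.

    The principal axis is the major second-moment axis of the mask; the
    width at each axial station is the perpendicular pixel extent times
    ``spacing``.  Returns ``(x_mm, width_mm, length_mm)``.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    if coords.shape[0] == 1:
        return np.array([0.0]), np.array([spacing]), spacing
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis  # deterministic orientation
    perp = np.array([-axis[1], axis[0]])
    a = centered @ axis
    b = centered @ perp
    length = float((a.max() - a.min() + 1.0) * spacing)
    stations = np.round(a - a.min()).astype(int)
    n = stations.max() + 1
    widths = np.zeros(n)
    b_min = np.full(n, np.inf)
    b_max = np.full(n, -np.inf)
    np.minimum.at(b_min, stations, b)
    np.maximum.at(b_max, stations, b)
    filled = b_max >= b_min
    widths[filled] = (b_max[filled] - b_min[filled] + 1.0) * spacing
    x = np.arange(n)[filled] * spacing
    return x, widths[filled], length


def measure_specimen(
    img: SpecimenImage,
    marker_side: float | None = None,
    config: ColorConfig | None = None,
) -> SegmentationResult:
    """Full measurement chain: spacing -> segmentation -> width profile."""
    flags: list[str] = []
    spacing = estimate_pixel_spacing(img, marker_side=marker_side)
    mask = segment_ablation(img, config)
    if not mask.any():
        flags.append("empty-mask")
        return SegmentationResult(
            mask=mask, spacing_mm_px=spacing,
            x_mm=np.array([]), width_mm=np.array([]), length_mm=0.0, flags=flags,
        )
    x, w, length = extract_width_profile(mask, spacing)
    return SegmentationResult(
        mask=mask, spacing_mm_px=spacing, x_mm=x, width_mm=w, length_mm=length, flags=flags,
    )


def save_image(img: SpecimenImage | np.ndarray, path: str | Path) -> None:
    from PIL import Image

    arr = img.image if isinstance(img, SpecimenImage) else np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(str(path))


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path)).convert("RGB"))
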