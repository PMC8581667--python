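"""Tumor-nest / stroma tissue segmentation for chromogenic multiplex IHC.

The segmentation chain operates on signal-high grayscale marker images
(chromogenic slides are inverted first so stain = bright):

1. tissue vs. blank classification by a global threshold on a structural
   channel (hematoxylin by default), giving the analyzable ROI;
2. binary mask cleaning by mathematical morphology
   (closing -> fill holes -> opening -> small-object removal);
3. tumor cell nest extraction by Huang minimum-fuzziness thresholding of
   the tumor-marker channel, with the histogram restricted to the ROI;
4. intratumoral stroma derived as the exact set difference ROI minus nest.

Huang thresholding and the Kapur maximum-entropy threshold are implemented
here; both are exhaustive searches over the 256 candidate gray levels,
vectorized over the level axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as _morph
from skimage.filters import threshold_otsu, threshold_triangle

__all__ = [
    "GrayImage",
    "BinaryMask",
    "MorphParams",
    "SegmentationResult",
    "RoiBox",
    "invert_chromogenic",
    "histogram256",
    "huang_threshold",
    "kapur_threshold",
    "compute_tissue_mask",
    "clean_mask",
    "segment_nests",
    "derive_stroma",
    "segment_slide",
    "select_rois",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayImage:
    """A single-marker grayscale image on a physical pixel grid.

    Intensities live in [0, 255] with the signal-high convention (stain is
    bright); ``pixel_size_um`` is the edge length of one pixel in microns.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage intensities must be finite")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("GrayImage intensities must lie in [0, 255]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean region mask sharing the grid of its source image."""

    pixels: np.ndarray
    pixel_size_um: float
    threshold: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * (self.pixel_size_um / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class MorphParams:
    """Parameters of the binary mask cleaning chain.

    ``max_hole_area_px=None`` means every interior hole is filled
    (the default inside tumor nests); zero disables hole filling.
    """

    opening_radius_px: int = 3
    closing_radius_px: int = 5
    max_hole_area_px: int | None = None
    min_object_area_px: int = 500

    def __post_init__(self) -> None:
        for name in ("opening_radius_px", "closing_radius_px", "min_object_area_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_hole_area_px is not None and self.max_hole_area_px < 0:
            raise ValueError("max_hole_area_px must be non-negative or None")


@dataclass(frozen=True)
class SegmentationResult:
    """ROI / nest / stroma / blank partition of one slide.

    Invariants (checked at construction): nest and stroma partition the ROI
    exactly, and ROI and blank partition the full frame.
    """

    roi: BinaryMask
    nest: BinaryMask
    stroma: BinaryMask
    blank: BinaryMask
    nest_threshold: float

    def __post_init__(self) -> None:
        r, n, s, b = (m.pixels for m in (self.roi, self.nest, self.stroma, self.blank))
        if not (r.shape == n.shape == s.shape == b.shape):
            raise ValueError("all masks must share one shape")
        if np.any(n & s):
            raise ValueError("nest and stroma overlap")
        if not np.array_equal(n | s, r):
            raise ValueError("nest and stroma do not partition the ROI")
        if np.any(r & b) or not np.all(r | b):
            raise ValueError("ROI and blank do not partition the frame")


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned analysis window, half-open pixel extents."""

    x_px: int
    y_px: int
    width_px: int
    height_px: int
    pixel_size_um: float

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.pixel_size_um / 1000.0) ** 2

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y_px, self.y_px + self.height_px),
            slice(self.x_px, self.x_px + self.width_px),
        )

    def overlaps(self, other: "RoiBox") -> bool:
        return not (
            self.x_px + self.width_px <= other.x_px
            or other.x_px + other.width_px <= self.x_px
            or self.y_px + self.height_px <= other.y_px
            or other.y_px + other.height_px <= self.y_px
        )


# ---------------------------------------------------------------------------
# pixel-level operations
# ---------------------------------------------------------------------------


def invert_chromogenic(image: GrayImage) -> GrayImage:
    """Map chromogenic (signal-dark) intensities to signal-high: 255 - x.

    An involution: applying it twice restores the input.
    """
    return GrayImage(255.0 - np.asarray(image.pixels), image.pixel_size_um)


def histogram256(pixels: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """256-bin count histogram of intensities rounded to integer gray levels."""
    values = np.asarray(pixels)
    if mask is not None:
        values = values[np.asarray(mask, bool)]
    levels = np.clip(np.rint(values), 0, 255).astype(np.intp)
    return np.bincount(levels.ravel(), minlength=256).astype(np.int64)


def _shannon(u: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy S(u) = -u ln u - (1-u) ln(1-u), S(0)=S(1)=0."""
    u = np.clip(u, 0.0, 1.0)
    out = np.zeros_like(u, dtype=float)
    inner = (u > 0) & (u < 1)
    ui = u[inner]
    out[inner] = -ui * np.log(ui) - (1.0 - ui) * np.log(1.0 - ui)
    return out


def huang_threshold(histogram: np.ndarray) -> int:
    """Huang minimum-fuzziness threshold of a 256-bin histogram.

    For a candidate level ``t``, pixels at gray level ``g`` get a fuzzy
    membership ``u(g) = 1 / (1 + |g - m| / C)`` to the side (background
    ``g <= t`` or foreground ``g > t``) that contains them, where ``m`` is
    that side's mean gray level and ``C`` the populated gray-level range.
    The returned threshold minimizes the total fuzziness
    ``E(t) = sum_g h(g) * S(u(g))`` with S the binary Shannon entropy;
    ties are broken toward the smallest level. Candidates are restricted to
    populated levels below the top populated level: sliding ``t`` across
    empty bins moves no mass between the two sides, so ``E`` is exactly
    constant there and the smallest minimizer always sits on a populated
    level (this also keeps tie-breaking exact in floating point).
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    populated = np.flatnonzero(h)
    if populated.size < 2:
        raise ValueError("no threshold exists: fewer than two populated bins")
    gmin, gmax = int(populated[0]), int(populated[-1])
    crange = float(gmax - gmin)

    g = np.arange(256, dtype=float)
    cum_n = np.cumsum(h)
    cum_w = np.cumsum(h * g)
    ts = populated[:-1]  # foreground = levels > t, so t < gmax
    mean_lo = cum_w[ts] / cum_n[ts]
    mean_hi = (cum_w[-1] - cum_w[ts]) / (cum_n[-1] - cum_n[ts])

    side_mean = np.where(g[None, :] <= ts[:, None], mean_lo[:, None], mean_hi[:, None])
    membership = 1.0 / (1.0 + np.abs(g[None, :] - side_mean) / crange)
    fuzziness = (_shannon(membership) * h[None, :]).sum(axis=1)
    return int(ts[int(np.argmin(fuzziness))])


def kapur_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of a 256-bin histogram.

    Maximizes the sum of background (levels <= t) and foreground (levels > t)
    Shannon entropies of the normalized histogram; ties break to the
    smallest level.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    populated = np.flatnonzero(h)
    if populated.size < 2:
        raise ValueError("no threshold exists: fewer than two populated bins")
    p = h / h.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    ts = np.arange(int(populated[0]), int(populated[-1]))
    p0 = cum_p[ts]
    p1 = 1.0 - p0
    h0 = np.log(p0) - cum_plogp[ts] / p0
    h1 = np.log(p1) - (cum_plogp[-1] - cum_plogp[ts]) / p1
    return int(ts[int(np.argmax(h0 + h1))])


def compute_tissue_mask(
    image: GrayImage,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> BinaryMask:
    """Classify tissue vs. blank pixels by a global threshold.

    ``method`` is one of ``otsu`` (default), ``max_entropy`` (Kapur),
    ``triangle`` or ``fixed`` (requires ``fixed_value``). Pixels strictly
    above the threshold are tissue (signal-high convention). Otsu is the
    default because the blank class of an inverted chromogenic slide is
    clipped into a near-degenerate spike at 0, on which the maximum-entropy
    criterion systematically picks a split inside the tissue mode instead.
    A constant image has no threshold: the full frame is returned as tissue
    with a warning flag.
    """
    px = np.asarray(image.pixels)
    if px.size == 0:
        raise ValueError("empty image")
    if px.min() == px.max():
        return BinaryMask(
            np.ones_like(px, dtype=bool),
            image.pixel_size_um,
            threshold=None,
            warning="constant image: threshold undefined, returning all-tissue",
        )
    if method == "otsu":
        t = float(threshold_otsu(px))
    elif method == "max_entropy":
        t = float(kapur_threshold(histogram256(px)))
    elif method == "triangle":
        t = float(threshold_triangle(px))
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        t = float(fixed_value)
    else:
        raise ValueError(f"unknown thresholding method: {method!r}")
    return BinaryMask(px > t, image.pixel_size_um, threshold=t)


def clean_mask(mask: BinaryMask, params: MorphParams) -> BinaryMask:
    """Morphological mask cleaning: closing, fill holes, opening, despeckle.

    Order is fixed: (1) binary closing with a disk of ``closing_radius_px``,
    (2) fill interior holes of area <= ``max_hole_area_px`` (all holes when
    None), (3) binary opening with a disk of ``opening_radius_px``,
    (4) remove connected components of area < ``min_object_area_px``.
    Closing and hole filling only ever add pixels; opening and component
    removal only ever remove them (asserted on every call).
    """
    px = np.asarray(mask.pixels, bool)

    grown = px
    if params.closing_radius_px > 0:
        grown = _morph.closing(grown, _morph.disk(params.closing_radius_px))
        # closing is extensive on the padded frame; enforce it at the border too
        grown = grown | px
    if params.max_hole_area_px is None:
        grown = ndi.binary_fill_holes(grown)
    elif params.max_hole_area_px > 0:
        # fills holes with area <= max_hole_area_px
        grown = _morph.remove_small_holes(grown, max_size=params.max_hole_area_px)
    assert np.all(grown >= px), "closing/fill-hole removed pixels"

    shrunk = grown
    if params.opening_radius_px > 0:
        shrunk = _morph.opening(shrunk, _morph.disk(params.opening_radius_px))
        shrunk = shrunk & grown
    if params.min_object_area_px > 0:
        # drop components with area < min_object_area_px (i.e. <= min - 1)
        shrunk = _morph.remove_small_objects(
            shrunk, max_size=params.min_object_area_px - 1
        )
    assert np.all(shrunk <= grown), "opening/despeckle added pixels"

    return mask.with_pixels(shrunk)


def segment_nests(
    tumor_marker: GrayImage,
    roi: BinaryMask,
    params: MorphParams | None = None,
) -> BinaryMask:
    """Extract tumor cell nests inside the ROI by Huang thresholding.

    The intensity histogram is built from ROI pixels only; ROI pixels
    strictly above the Huang threshold form the raw nest mask, which is then
    cleaned by :func:`clean_mask` and re-intersected with the ROI. When the
    ROI histogram has a single populated level no threshold exists and an
    empty nest mask is returned (the whole ROI is stroma).
    """
    if tumor_marker.shape != roi.shape:
        raise ValueError("tumor_marker and roi must share one shape")
    if not roi.pixels.any():
        raise ValueError("empty ROI: nothing to segment")
    params = params or MorphParams()
    hist = histogram256(tumor_marker.pixels, roi.pixels)
    try:
        t = huang_threshold(hist)
    except ValueError:
        return BinaryMask(
            np.zeros(roi.shape, bool),
            roi.pixel_size_um,
            threshold=None,
            warning="degenerate ROI histogram: no nest threshold",
        )
    raw = roi.pixels & (np.asarray(tumor_marker.pixels) > t)
    cleaned = clean_mask(BinaryMask(raw, roi.pixel_size_um, threshold=float(t)), params)
    return cleaned.with_pixels(cleaned.pixels & roi.pixels)


def derive_stroma(roi: BinaryMask, nest: BinaryMask) -> BinaryMask:
    """Intratumoral stroma as the exact set difference ROI minus nest."""
    if roi.shape != nest.shape:
        raise ValueError("roi and nest must share one shape")
    if np.any(nest.pixels & ~roi.pixels):
        raise ValueError("nest mask is not a subset of the ROI")
    return BinaryMask(roi.pixels & ~nest.pixels, roi.pixel_size_um)


def segment_slide(
    tumor_marker: GrayImage,
    structural: GrayImage,
    morph: MorphParams | None = None,
    tissue_method: str = "otsu",
    tissue_fixed_value: float | None = None,
) -> SegmentationResult:
    """Full slide partition: ROI from the structural (hematoxylin) channel,
    nests from the tumor marker, stroma by subtraction, blank as the ROI
    complement."""
    morph = morph or MorphParams()
    tissue = compute_tissue_mask(structural, tissue_method, tissue_fixed_value)
    roi = clean_mask(tissue, morph)
    nest = segment_nests(tumor_marker, roi, morph)
    stroma = derive_stroma(roi, nest)
    blank = BinaryMask(~roi.pixels, roi.pixel_size_um)
    return SegmentationResult(
        roi=roi,
        nest=nest,
        stroma=stroma,
        blank=blank,
        nest_threshold=float(nest.threshold) if nest.threshold is not None else float("nan"),
    )


def select_rois(
    cd3: GrayImage,
    tissue: BinaryMask,
    k: int = 3,
    window_mm: float = 2.5,
    stride_mm: float = 0.25,
) -> list[RoiBox]:
    """Greedy selection of up to ``k`` disjoint high-CD3-density windows.

    Square windows of side ``window_mm`` (default 2.5 mm, i.e. 6.25 mm^2)
    are scored by integrated CD3 signal over tissue pixels and placed on a
    ``stride_mm`` grid; each pick maximizes the score among candidates that
    do not overlap earlier picks and contain some tissue. Ties break in
    top-left scan order. Windows shrink to the frame when the image is
    smaller than the requested side.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not tissue.pixels.any():
        raise ValueError("empty tissue mask: nothing analyzable")
    if cd3.shape != tissue.shape:
        raise ValueError("cd3 and tissue must share one shape")
    h, w = cd3.shape
    px_um = cd3.pixel_size_um
    side = int(round(window_mm * 1000.0 / px_um))
    side = max(1, min(side, h, w))
    stride = max(1, int(round(stride_mm * 1000.0 / px_um)))

    score_img = np.asarray(cd3.pixels, float) * tissue.pixels
    tissue_img = tissue.pixels.astype(float)

    def _window_sums(img: np.ndarray) -> np.ndarray:
        sat = np.zeros((h + 1, w + 1))
        sat[1:, 1:] = img.cumsum(0).cumsum(1)
        ys = np.arange(0, h - side + 1, stride)
        xs = np.arange(0, w - side + 1, stride)
        return (
            sat[np.ix_(ys + side, xs + side)]
            - sat[np.ix_(ys, xs + side)]
            - sat[np.ix_(ys + side, xs)]
            + sat[np.ix_(ys, xs)],
            ys,
            xs,
        )

    scores, ys, xs = _window_sums(score_img)
    tissue_sums, _, _ = _window_sums(tissue_img)

    allowed = tissue_sums > 0
    boxes: list[RoiBox] = []
    while len(boxes) < k and allowed.any():
        masked = np.where(allowed, scores, -np.inf)
        flat = int(np.argmax(masked))  # row-major: top-left wins ties
        iy, ix = np.unravel_index(flat, masked.shape)
        box = RoiBox(int(xs[ix]), int(ys[iy]), side, side, px_um)
        boxes.append(box)
        for jy, yy in enumerate(ys):
            for jx, xx in enumerate(xs):
                if allowed[jy, jx] and box.overlaps(RoiBox(int(xx), int(yy), side, side, px_um)):
                    allowed[jy, jx] = False
    return boxes
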