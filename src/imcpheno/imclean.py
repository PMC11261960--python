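"""Artifact correction for multiplexed ion-count channel images.

Imaging mass cytometry (IMC) and MIBI produce one 2-D ion-count image per
antibody channel.  Three artifact classes corrupt these images:

* **channel spillover** -- a "source" channel (isotopic impurity, oxide
  formation) contaminates a "target" channel; corrected by building a binary
  mask of the source signal (cap, Gaussian smooth, binarize) and subtracting a
  fixed removal value from target pixels under the mask;
* **shot noise** -- weak, spatially uncorrelated counts; corrected with a
  floor threshold followed by a local-support test on the floored image;
* **antibody aggregates** ("hot pixels") -- small, bright connected blobs not
  associated with tissue structure; corrected by blurring, binarizing,
  labelling connected components and zeroing components smaller than a size
  threshold.

Every operator is pixelwise non-amplifying (output <= input) except the
Gaussian smoothing used internally for mask construction, and all preserve
non-negativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DimensionError, ParameterError

__all__ = [
    "ChannelImage",
    "SpilloverParams",
    "NoiseParams",
    "AggregateParams",
    "ImageStack",
    "cap_intensities",
    "gaussian_smooth",
    "binarize",
    "spillover_mask",
    "spillover_correct",
    "denoise",
    "remove_aggregates",
    "preprocess_channel",
    "build_stack",
]


@dataclass
class ChannelImage:
    """One antibody channel: a 2-D grid of non-negative ion counts."""

    pixels: np.ndarray
    marker: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"channel image must be 2-D, got {self.pixels.ndim}-D"
            )
        if np.any(self.pixels < 0):
            raise ParameterError("channel image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return replace(self, pixels=pixels)


def _as_pixels(img) -> tuple[np.ndarray, "ChannelImage | None"]:
    """Accept either a ChannelImage or a bare 2-D array."""
    if isinstance(img, ChannelImage):
        return img.pixels, img
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got {arr.ndim}-D")
    return arr, None


def _wrap(pixels: np.ndarray, template: "ChannelImage | None"):
    if template is None:
        return pixels
    return template.with_pixels(pixels)


@dataclass(frozen=True)
class SpilloverParams:
    """Parameters of the source-mask construction and target subtraction.

    ``cap_threshold`` caps overly bright source pixels before smoothing;
    ``gauss_radius`` is the standard deviation (pixels) of the isotropic
    Gaussian used to blur the capped source; ``binarize_threshold`` turns the
    blurred source into a binary mask (strictly greater-than); and
    ``removal_value`` is subtracted (clamped at zero) from target pixels under
    the mask.
    """

    source_marker: str
    cap_threshold: float
    gauss_radius: float
    binarize_threshold: float
    removal_value: float

    def __post_init__(self) -> None:
        if self.cap_threshold <= 0:
            raise ParameterError("cap_threshold must be > 0")
        if self.gauss_radius < 0:
            raise ParameterError("gauss_radius must be >= 0")
        if self.removal_value < 0:
            raise ParameterError("removal_value must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Floor threshold plus local-support window for noise removal.

    ``floor_threshold = 0`` with ``window_size = 1`` is a legal no-op, which is
    how a user opts a channel out of this step.  ``erosion=True`` switches the
    floor step to a grey-scale erosion (local minimum over the window) before
    thresholding, for parity with the named library filter; the default is the
    plain floor, matching the prose definition ("any pixel with a signal level
    below the designated minimum threshold ... set to zero").
    """

    floor_threshold: float = 0.0
    window_size: int = 3
    erosion: bool = False

    def __post_init__(self) -> None:
        if self.floor_threshold < 0:
            raise ParameterError("floor_threshold must be >= 0")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ParameterError("window_size must be an odd integer >= 1")


@dataclass(frozen=True)
class AggregateParams:
    """Blur/binarize/size-filter parameters for aggregate (hot pixel) removal.

    ``size_threshold = 0`` is a legal no-op.  ``binarize_threshold`` defaults
    to 0 (any positive blurred signal counts) and connectivity to 8-connected.
    """

    blur_radius: float = 1.0
    binarize_threshold: float = 0.0
    size_threshold: int = 8
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.blur_radius < 0:
            raise ParameterError("blur_radius must be >= 0")
        if self.size_threshold < 0:
            raise ParameterError("size_threshold must be >= 0")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")


def cap_intensities(img, cap: float):
    """Clip every pixel at ``cap`` (elementwise minimum)."""
    if cap <= 0:
        raise ParameterError("cap must be > 0")
    px, tpl = _as_pixels(img)
    return _wrap(np.minimum(px, float(cap)), tpl)


def gaussian_smooth(img, radius: float):
    """Convolve with a normalized isotropic Gaussian of sd ``radius`` pixels.

    ``radius = 0`` is the identity.  Boundaries are handled by reflection.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    px, tpl = _as_pixels(img)
    if radius == 0:
        return _wrap(px.copy(), tpl)
    return _wrap(ndimage.gaussian_filter(px, sigma=radius, mode="reflect"), tpl)


def binarize(img, threshold: float) -> np.ndarray:
    """Return a {0,1} mask: 1 where pixel is strictly greater than threshold."""
    px, _ = _as_pixels(img)
    return (px > threshold).astype(np.uint8)


def spillover_mask(source, params: SpilloverParams) -> np.ndarray:
    """Cap, smooth and binarize a source channel into a contamination mask."""
    capped = cap_intensities(source, params.cap_threshold)
    smoothed = gaussian_smooth(capped, params.gauss_radius)
    return binarize(smoothed, params.binarize_threshold)


def spillover_correct(target, source_mask: np.ndarray, removal_value: float):
    """Subtract ``removal_value`` (clamped at zero) under the source mask."""
    if removal_value < 0:
        raise ParameterError("removal_value must be >= 0")
    px, tpl = _as_pixels(target)
    mask = np.asarray(source_mask)
    if mask.shape != px.shape:
        raise DimensionError(
            f"mask shape {mask.shape} != target shape {px.shape}"
        )
    out = np.where(mask > 0, np.maximum(px - removal_value, 0.0), px)
    return _wrap(out, tpl)


def denoise(img, params: NoiseParams):
    """Floor-threshold then keep floored counts wherever locally supported.

    Step 1 zeroes pixels strictly below ``floor_threshold`` (or, with
    ``erosion=True``, pixels whose local window minimum is below it).  Step 2
    keeps the floored original intensity wherever the local window mean of the
    floored image is positive and zeroes it elsewhere; the smoothed image is
    used only for support detection and is never emitted, which preserves true
    ion counts and the non-amplification invariant.
    """
    px, tpl = _as_pixels(img)
    if params.erosion:
        local_min = ndimage.minimum_filter(
            px, size=params.window_size, mode="reflect"
        )
        floored = np.where(local_min < params.floor_threshold, 0.0, px)
    else:
        floored = np.where(px < params.floor_threshold, 0.0, px)
    # For a non-negative image the window mean is > 0 exactly where the window
    # maximum is > 0; the max filter gives that support test without float
    # round-off.
    support = (
        ndimage.maximum_filter(floored, size=params.window_size, mode="reflect")
        > 0
    )
    return _wrap(np.where(support, floored, 0.0), tpl)


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=int)
    return ndimage.generate_binary_structure(2, 1)


def remove_aggregates(img, params: AggregateParams):
    """Zero connected positive components smaller than ``size_threshold``.

    The component labelling runs on the blurred-and-binarized image; the
    zeroing is applied to the *original* pixels of each small component, so
    surviving pixels keep their raw counts.
    """
    px, tpl = _as_pixels(img)
    blurred = gaussian_smooth(px, params.blur_radius)
    mask = blurred > params.binarize_threshold
    labels, n = ndimage.label(mask, structure=_label_structure(params.connectivity))
    if n == 0 or params.size_threshold == 0:
        return _wrap(px.copy(), tpl)
    sizes = np.bincount(labels.ravel())
    small = sizes < params.size_threshold
    small[0] = False  # background is never a component
    out = np.where(small[labels], 0.0, px)
    return _wrap(out, tpl)


def preprocess_channel(
    img,
    spill: SpilloverParams | None = None,
    noise: NoiseParams | None = None,
    agg: AggregateParams | None = None,
    source=None,
):
    """Apply the present steps in the fixed order spillover -> denoise ->
    aggregate removal.  Each step is optional; with all absent this is the
    identity."""
    px, tpl = _as_pixels(img)
    out = px.copy()
    if spill is not None:
        if source is None:
            raise ConfigurationError(
                "spillover correction requires a source channel"
            )
        src_px, _ = _as_pixels(source)
        if src_px.shape != out.shape:
            raise DimensionError(
                f"source shape {src_px.shape} != target shape {out.shape}"
            )
        mask = spillover_mask(src_px, spill)
        out = spillover_correct(out, mask, spill.removal_value)
    if noise is not None:
        out = denoise(out, noise)
    if agg is not None:
        out = remove_aggregates(out, agg)
    return _wrap(out, tpl)


@dataclass
class ImageStack:
    """Ordered channels of one ROI; channel order equals panel order."""

    channels: list[ChannelImage] = field(default_factory=list)
    panel: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def roi_id(self) -> str:
        return self.channels[0].roi_id if self.channels else ""

    def pixels(self) -> np.ndarray:
        """(channels, rows, cols) float array in panel order."""
        return np.stack([c.pixels for c in self.channels], axis=0)

    def channel(self, marker: str) -> ChannelImage:
        try:
            return self.channels[self.panel.index(marker)]
        except ValueError:
            raise KeyError(f"marker {marker!r} not in stack panel") from None


def build_stack(channels: list[ChannelImage], panel: list[str]) -> ImageStack:
    """Order channel images by panel, validating shapes and names."""
    if len(set(panel)) != len(panel):
        dupes = sorted({m for m in panel if panel.count(m) > 1})
        raise ConfigurationError(f"duplicate marker names in panel: {dupes}")
    by_marker: dict[str, ChannelImage] = {}
    for ch in channels:
        if ch.marker in by_marker:
            raise ConfigurationError(f"duplicate channel for marker {ch.marker!r}")
        by_marker[ch.marker] = ch
    missing = [m for m in panel if m not in by_marker]
    if missing:
        raise ConfigurationError(f"missing channels for panel markers: {missing}")
    ordered = [by_marker[m] for m in panel]
    shape = ordered[0].shape
    for ch in ordered[1:]:
        if ch.shape != shape:
            raise DimensionError(
                f"channel {ch.marker!r} shape {ch.shape} != {shape}"
            )
    return ImageStack(channels=ordered, panel=list(panel))
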