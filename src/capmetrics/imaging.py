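"""SEM micrograph particle-sizing pipeline.

The pipeline mirrors how spray-dried microcapsule micrographs are sized in
practice: crop the instrument databar off the bottom edge, min-max
normalize contrast to 8-bit, run instance segmentation, discard particles
that intersect the image boundary (their diameters would be truncated),
fit a minimum enclosing circle to each remaining particle's contour, and
convert pixel diameters to micrometers using the scale-bar calibration.

Segmentation is a pluggable backend (any callable mapping an 8-bit image
and config to an integer label mask).  The default classical backend is
Otsu thresholding -> hole filling -> Euclidean distance transform -> seed
detection -> watershed, which separates moderately touching near-spherical
granules; heavily fused agglomerates may legitimately remain unsplit and
are simply counted as one (or excluded downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .errors import EmptyTableError, SegmentationError
from .geometry import Circle, min_enclosing_circle
from . import reference

__all__ = [
    "Micrograph",
    "Scale",
    "ImagingConfig",
    "SizeSummary",
    "crop_databar",
    "normalize_contrast",
    "segment_instances",
    "exclude_border_particles",
    "calibrate_scale",
    "measure_particles",
    "summarize_sizes",
    "render_overlay",
    "size_micrograph",
    "read_micrograph",
    "register_backend",
]


@dataclass
class Micrograph:
    """A grayscale SEM-style image plus the metadata the pipeline needs.

    ``pixels`` is a 2-D array of non-negative intensities.  ``databar_height``
    counts the instrument databar rows still present at the bottom of the
    image (0 once cropped).  The scale bar length in pixels together with its
    physical length calibrates micrometers per pixel.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    databar_height: int = reference.DATABAR_CROP_ROWS
    scalebar_px: int = reference.SCALEBAR_PX
    scalebar_um: float = reference.SCALEBAR_UM

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D grayscale array")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("micrograph intensities must be non-negative")
        if self.pixels.size and self.pixels.max() >= 2 ** self.bit_depth:
            raise ValueError(
                f"intensities exceed declared bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Scale:
    """Physical calibration in micrometers per pixel."""

    um_per_px: float

    def __post_init__(self):
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class ImagingConfig:
    crop_rows: int = reference.DATABAR_CROP_ROWS
    base_diameter_px: int = reference.BASE_DIAMETER_PX
    min_area_px: int = 9
    norm_low: int = 0
    norm_high: int = 255
    backend: str = "watershed"

    def __post_init__(self):
        if self.crop_rows < 0:
            raise ValueError("crop_rows must be >= 0")
        if self.base_diameter_px <= 0:
            raise ValueError("base_diameter_px must be positive")


@dataclass
class SizeSummary:
    """Descriptors of a retained-particle diameter sample."""

    valid_n: int
    mean_um: float
    sd_um: float
    d10_um: float
    d50_um: float
    d90_um: float
    histogram_edges_um: np.ndarray = field(repr=False)
    histogram_counts: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "valid_n": self.valid_n,
            "mean_um": self.mean_um,
            "sd_um": self.sd_um,
            "d10_um": self.d10_um,
            "d50_um": self.d50_um,
            "d90_um": self.d90_um,
        }


# ---------------------------------------------------------------------------
# Pipeline stages


def crop_databar(img: Micrograph, crop_rows: int | None = None) -> Micrograph:
    """Remove *crop_rows* rows from the bottom edge (the instrument databar).

    Defaults to the micrograph's own ``databar_height``.
    """
    rows = img.databar_height if crop_rows is None else int(crop_rows)
    h = img.pixels.shape[0]
    if rows >= h:
        raise ValueError(f"crop_rows={rows} >= image height {h}")
    out = img.pixels[: h - rows, :] if rows else img.pixels
    return Micrograph(
        out.copy(),
        bit_depth=img.bit_depth,
        databar_height=0,
        scalebar_px=img.scalebar_px,
        scalebar_um=img.scalebar_um,
    )


def normalize_contrast(img: Micrograph) -> Micrograph:
    """Min-max normalize to the full 0-255 8-bit range (affine mapping,
    round-half-even).  A constant image maps to all zeros with a warning."""
    px = img.pixels
    if px.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: contrast normalization maps to zeros")
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        out = np.rint((px.astype(float) - lo) * (255.0 / (hi - lo)))
        out = out.astype(np.uint8)
    return Micrograph(
        out,
        bit_depth=8,
        databar_height=img.databar_height,
        scalebar_px=img.scalebar_px,
        scalebar_um=img.scalebar_um,
    )


def _watershed_backend(arr: np.ndarray, config: ImagingConfig) -> np.ndarray:
    """Classical instance segmentation: Otsu -> fill holes -> EDT -> per-
    component peak seeds (min separation base_diameter_px/2) -> watershed."""
    if arr.max() == arr.min():
        return np.zeros(arr.shape, dtype=np.int32)
    thresh = threshold_otsu(arr)
    binary = arr > thresh
    if not binary.any():
        return np.zeros(arr.shape, dtype=np.int32)
    binary = ndi.binary_fill_holes(binary)
    dist = ndi.distance_transform_edt(binary)
    # Smoothing removes spurious EDT ridges from noisy boundaries that
    # would otherwise over-seed large single particles.
    dist_s = ndi.gaussian_filter(dist, sigma=2.0)
    comp, _ = ndi.label(binary)
    min_dist = max(1, config.base_diameter_px // 2)
    coords = peak_local_max(
        dist_s, min_distance=min_dist, labels=comp, exclude_border=False
    )
    markers = np.zeros(arr.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return np.zeros(arr.shape, dtype=np.int32)
    return watershed(-dist_s, markers, mask=binary).astype(np.int32)


_BACKENDS: dict[str, Callable[[np.ndarray, ImagingConfig], np.ndarray]] = {
    "watershed": _watershed_backend,
}


def register_backend(name: str, fn: Callable) -> None:
    """Register a segmentation backend: ``fn(image_array, config) -> labels``.

    This is the seam where a learned instance-segmentation model would plug
    in; the rest of the pipeline is agnostic to how the mask was produced.
    """
    _BACKENDS[name] = fn


def segment_instances(
    img: Micrograph,
    config: ImagingConfig | None = None,
    backend: str | Callable | None = None,
) -> np.ndarray:
    """Run the configured backend and return a compacted integer label mask.

    Instances smaller than ``config.min_area_px`` are dropped and the
    remaining labels renumbered to a contiguous 1..K.
    """
    config = config or ImagingConfig()
    if backend is None:
        backend = config.backend
    if callable(backend):
        fn, name = backend, getattr(backend, "__name__", "custom")
    else:
        name = backend
        if name not in _BACKENDS:
            raise SegmentationError(
                f"unknown segmentation backend '{name}'; "
                f"registered: {sorted(_BACKENDS)}"
            )
        fn = _BACKENDS[name]
    try:
        labels = np.asarray(fn(img.pixels, config))
    except Exception as exc:  # noqa: BLE001 - contract: name the backend
        raise SegmentationError(f"backend '{name}' failed: {exc}") from exc
    if labels.shape != img.pixels.shape:
        raise SegmentationError(
            f"backend '{name}' returned shape {labels.shape}, "
            f"expected {img.pixels.shape}"
        )
    if config.min_area_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < config.min_area_px)
        if small.size:
            labels = np.where(np.isin(labels, small), 0, labels)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def exclude_border_particles(mask: np.ndarray) -> pd.DataFrame:
    """Flag instances with any pixel on the image boundary.

    Returns a frame with columns ``label`` and ``touches_border``.
    """
    mask = np.asarray(mask)
    border = np.unique(
        np.concatenate(
            [mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]]
        )
    )
    border = set(int(b) for b in border if b != 0)
    labels = [int(v) for v in np.unique(mask) if v != 0]
    return pd.DataFrame(
        {"label": labels, "touches_border": [lb in border for lb in labels]}
    )


def calibrate_scale(scalebar_px: float, scalebar_um: float) -> Scale:
    """Micrometers per pixel from a scale bar of known physical length."""
    if not (scalebar_px > 0 and scalebar_um > 0):
        raise ValueError("scale bar length and physical length must be positive")
    return Scale(um_per_px=scalebar_um / scalebar_px)


def _boundary_points(patch: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Outer-boundary pixel centers of a binary patch, in image coordinates."""
    interior = ndi.binary_erosion(patch)
    boundary = patch & ~interior
    rr, cc = np.nonzero(boundary)
    return np.column_stack([rr + offset[0], cc + offset[1]]).astype(float)


def measure_particles(
    mask: np.ndarray,
    scale: Scale,
    config: ImagingConfig | None = None,
) -> pd.DataFrame:
    """Per-particle contour, minimum-enclosing-circle diameter, and physical
    diameter.

    Border-touching and sub-``min_area_px`` instances are kept in the table
    with their ``excluded_reason`` ("border" / "min_area") but carry no
    micrometer diameter; retained rows have ``excluded_reason == "none"``.
    """
    config = config or ImagingConfig()
    mask = np.asarray(mask)
    border_flags = exclude_border_particles(mask)
    border_set = set(
        border_flags.loc[border_flags.touches_border, "label"].tolist()
    )
    rows = []
    for prop in regionprops(mask):
        label = int(prop.label)
        patch = prop.image
        offset = (prop.bbox[0], prop.bbox[1])
        contour = _boundary_points(patch, offset)
        if prop.area < config.min_area_px:
            reason = "min_area"
        elif label in border_set:
            reason = "border"
        else:
            reason = "none"
        if reason == "none":
            circ: Circle = min_enclosing_circle(contour)
            d_px = circ.diameter
            d_um = d_px * scale.um_per_px
        else:
            d_px = np.nan
            d_um = np.nan
        rows.append(
            {
                "label": label,
                "contour": contour,
                "diameter_px": d_px,
                "diameter_um": d_um,
                "excluded_reason": reason,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "contour", "diameter_px", "diameter_um",
                       "excluded_reason"]
    )


def summarize_sizes(table: pd.DataFrame, bin_width_um: float = 0.5) -> SizeSummary:
    """Valid N, mean +/- SD (n-1 denominator), D10/D50/D90 by linear
    interpolation, and a histogram in ``bin_width_um`` bins from 0."""
    retained = table[table["excluded_reason"] == "none"]
    d = retained["diameter_um"].to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise EmptyTableError("no retained particles to summarize")
    d10, d50, d90 = np.percentile(d, [10, 50, 90])
    n_bins = max(1, int(np.ceil(d.max() / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, edges = np.histogram(d, bins=edges)
    return SizeSummary(
        valid_n=int(d.size),
        mean_um=float(d.mean()),
        sd_um=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        d10_um=float(d10),
        d50_um=float(d50),
        d90_um=float(d90),
        histogram_edges_um=edges,
        histogram_counts=counts,
    )


def render_overlay(img: Micrograph, mask: np.ndarray, alpha: float = 0.45) -> np.ndarray:
    """RGB uint8 overlay: background pixels unchanged, each instance tinted
    with a deterministic per-label color at fixed alpha."""
    mask = np.asarray(mask)
    if mask.shape != img.pixels.shape:
        raise ValueError(
            f"mask shape {mask.shape} != image shape {img.pixels.shape}"
        )
    gray = img.pixels.astype(float)
    if img.bit_depth != 8:
        gray = gray * (255.0 / (2 ** img.bit_depth - 1))
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    labels = [int(v) for v in np.unique(mask) if v != 0]
    golden = 0.61803398875
    for lb in labels:
        hue = (lb * golden) % 1.0
        color = np.array(_hsv_to_rgb(hue, 0.85, 1.0)) * 255.0
        sel = mask == lb
        rgb[sel] = (1 - alpha) * rgb[sel] + alpha * color
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[float, float, float]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]


# ---------------------------------------------------------------------------
# Convenience composition


def size_micrograph(
    img: Micrograph,
    config: ImagingConfig | None = None,
    scale: Scale | None = None,
) -> tuple[pd.DataFrame, SizeSummary, np.ndarray]:
    """Full sizing pipeline on one micrograph.

    Crops the databar (if any), normalizes contrast, segments, measures
    retained particles, and summarizes.  Returns (particle table, size
    summary, label mask).
    """
    config = config or ImagingConfig()
    if img.databar_height:
        img = crop_databar(img)
    img = normalize_contrast(img)
    mask = segment_instances(img, config)
    if scale is None:
        scale = calibrate_scale(img.scalebar_px, img.scalebar_um)
    table = measure_particles(mask, scale, config)
    summary = summarize_sizes(table)
    return table, summary, mask


def read_micrograph(
    path,
    databar_height: int = reference.DATABAR_CROP_ROWS,
    scalebar_px: int = reference.SCALEBAR_PX,
    scalebar_um: float = reference.SCALEBAR_UM,
) -> Micrograph:
    """Load a grayscale TIFF/PNG micrograph from disk."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB to luma if needed
        arr = np.rint(arr[..., :3].mean(axis=2)).astype(arr.dtype)
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return Micrograph(
        arr,
        bit_depth=bit_depth,
        databar_height=databar_height,
        scalebar_px=scalebar_px,
        scalebar_um=scalebar_um,
    )
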