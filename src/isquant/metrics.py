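"""Per-cell scalar metrics at the synaptic interface.

Covers the around-bead fraction (lysosome accumulation within a concentric
disc around the bead), antigen-extraction time courses, spreading area,
the BCR recruitment index (central vs total fluorescence density at the
synaptic plane), circularity, focus counting and intensity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.affinity import scale as shapely_scale
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.measure import label as sk_label

from .core_io import ChannelStack, PlaneImage, Scene, project
from .segmentation import filter_particles_2d


class ZeroIntensityError(Exception):
    """A normalizing intensity total is zero; the metric is undefined."""


class DegenerateOutlineError(Exception):
    """The outline encloses no area."""


class MultiComponentError(Exception):
    """Circularity needs a single connected region; pass the largest component."""


@dataclass
class BeadROI:
    """Analysis disc concentric with a bead.

    ``analysis_radius`` is the radius of the disc measured from the bead
    center (default 3.5 μm — wide enough to contain a 3-μm bead plus a
    docking rim); it must not be smaller than the bead radius.
    """

    center: tuple[float, float]  # (x, y) μm
    bead_radius: float
    analysis_radius: float = 3.5

    def __post_init__(self):
        if not self.bead_radius > 0:
            raise ValueError("bead_radius must be > 0")
        if self.analysis_radius < self.bead_radius:
            raise ValueError("analysis_radius must be >= bead_radius")


@dataclass
class SynapticPlane:
    """One z-slice at the cell–substrate/bead interface.

    ``outline`` is the 2D cell boundary, either a boolean mask or a shapely
    polygon in μm; ``images`` maps channel name to its 2D intensity at the
    plane.
    """

    z_index: int
    images: dict[str, np.ndarray]
    outline: np.ndarray | Polygon
    pixel_size: tuple[float, float]  # (dy, dx) μm

    def outline_mask(self, shape) -> np.ndarray:
        """Outline as a boolean pixel mask of the given (ny, nx) shape."""
        if isinstance(self.outline, Polygon):
            return rasterize_polygon(self.outline, shape, self.pixel_size)
        return np.asarray(self.outline, dtype=bool)


def rasterize_polygon(poly: Polygon, shape, pixel_size) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon given in μm."""
    dy, dx = pixel_size
    pts = np.asarray(poly.exterior.coords)  # (x, y) μm
    rc = np.column_stack([pts[:, 1] / dy, pts[:, 0] / dx])  # (row, col) pixels
    return polygon2mask(shape, rc)


def select_synaptic_plane(
    scene: Scene, actin_channel: str = "actin", z_index: int | None = None
) -> int:
    """The synaptic z-slice: supplied explicitly, or the slice of maximal
    integrated intensity in the actin-style channel (phalloidin template)."""
    if z_index is not None:
        if not 0 <= z_index < scene.shape[0]:
            raise ValueError(f"z_index {z_index} outside stack depth {scene.shape[0]}")
        return z_index
    if actin_channel not in scene.channels:
        raise KeyError(f"no channel {actin_channel!r} to select the synaptic plane from")
    per_slice = scene.channels[actin_channel].data.sum(axis=(1, 2))
    return int(np.argmax(per_slice))


# ---------------------------------------------------------------------------
# around-bead accumulation and antigen extraction
# ---------------------------------------------------------------------------

def _disc_mask(shape, pixel_size, center_xy, radius) -> np.ndarray:
    dy, dx = pixel_size
    cx, cy = center_xy
    yy = np.arange(shape[0]) * dy - cy
    xx = np.arange(shape[1]) * dx - cx
    return yy[:, None] ** 2 + xx[None, :] ** 2 <= radius * radius


def around_bead_fraction(
    channel: ChannelStack, bead: BeadROI, cell_mask: np.ndarray
) -> float:
    """Fraction of a cell's fluorescence inside the concentric disc around a bead.

    The channel is sum-projected along z; the numerator sums intensity over
    cell pixels whose (x, y) lies within ``analysis_radius`` of the bead
    center, the denominator over all cell pixels. Always in [0, 1].
    """
    proj = project(channel, method="sum")
    cell2d = np.asarray(cell_mask, dtype=bool)
    if cell2d.ndim == 3:
        cell2d = cell2d.any(axis=0)
    total = proj.data[cell2d].sum()
    if total == 0:
        raise ZeroIntensityError(f"channel {channel.name!r}: zero total cell intensity")
    disc = _disc_mask(proj.data.shape, proj.pixel_size, bead.center, bead.analysis_radius)
    return float(proj.data[cell2d & disc].sum() / total)


def extraction_remaining(
    series: Sequence[tuple[float, Scene]],
    antigen_channel: str,
    bead: BeadROI,
) -> dict[float, float]:
    """Percent of bead-associated antigen fluorescence remaining per time point.

    A fixed disc around the bead is measured on the sum projection of each
    scene's antigen channel and normalized to the time-0 value (100%).
    """
    times = [t for t, _ in series]
    if 0 not in times and 0.0 not in times:
        raise ValueError("extraction series must include time 0 for normalization")
    measured: dict[float, float] = {}
    for t, scene in series:
        proj = project(scene.channels[antigen_channel], method="sum")
        disc = _disc_mask(
            proj.data.shape, proj.pixel_size, bead.center, bead.analysis_radius
        )
        measured[t] = float(proj.data[disc].sum())
    baseline = measured[0 if 0 in measured else 0.0]
    if baseline == 0:
        raise ZeroIntensityError("zero antigen intensity at time 0")
    return {t: 100.0 * v / baseline for t, v in measured.items()}


# ---------------------------------------------------------------------------
# spreading, recruitment, circularity
# ---------------------------------------------------------------------------

def spreading_area(plane: SynapticPlane) -> float:
    """Physical area (μm²) enclosed by the cell outline at the synaptic plane."""
    if isinstance(plane.outline, Polygon):
        area = plane.outline.area
        if area == 0:
            raise DegenerateOutlineError("outline polygon encloses no area")
        return float(area)
    mask = np.asarray(plane.outline, dtype=bool)
    if not mask.any():
        raise DegenerateOutlineError("outline mask is empty")
    dy, dx = plane.pixel_size
    return float(np.count_nonzero(mask) * dy * dx)


def _central_region_mask(mask: np.ndarray, factor: float = 0.5) -> np.ndarray:
    """Image of a raster outline under scaling by ``factor`` about its centroid.

    A pixel belongs to the central region iff mapping it back through the
    inverse scaling lands inside the outline; the result has ~factor² of
    the outline's area.
    """
    yy, xx = np.nonzero(mask)
    cy, cx = yy.mean(), xx.mean()
    ny, nx = mask.shape
    Y, X = np.mgrid[0:ny, 0:nx]
    srcY = np.rint(cy + (Y - cy) / factor).astype(int)
    srcX = np.rint(cx + (X - cx) / factor).astype(int)
    inside = (srcY >= 0) & (srcY < ny) & (srcX >= 0) & (srcX < nx)
    out = np.zeros_like(mask, dtype=bool)
    out[inside] = mask[srcY[inside], srcX[inside]]
    return out


def recruitment_index(
    channel_plane: np.ndarray,
    outline: np.ndarray | Polygon,
    pixel_size: tuple[float, float],
    variant: str = "ratio",
) -> float:
    """Central-vs-total fluorescence density index at the synaptic plane.

    The central region is the outline scaled by a linear factor 0.5 about
    its centroid (¼ of the total area). With density = intensity/area, the
    default ``ratio`` variant returns central density / total density − 1:
    0 for a uniform distribution, negative for peripheral, positive for
    central (up to 3 when all signal is central). ``log_ratio`` returns
    log2 of the density ratio instead. Invariant to global intensity
    scaling.
    """
    img = np.asarray(channel_plane, dtype=np.float64)
    if isinstance(outline, Polygon):
        if outline.area == 0:
            raise DegenerateOutlineError("outline polygon encloses no area")
        total_mask = rasterize_polygon(outline, img.shape, pixel_size)
        central_poly = shapely_scale(outline, xfact=0.5, yfact=0.5, origin="centroid")
        central_mask = rasterize_polygon(central_poly, img.shape, pixel_size)
        area_total, area_central = outline.area, central_poly.area
    else:
        total_mask = np.asarray(outline, dtype=bool)
        if not total_mask.any():
            raise DegenerateOutlineError("outline mask is empty")
        central_mask = _central_region_mask(total_mask, factor=0.5)
        dy, dx = pixel_size
        area_total = np.count_nonzero(total_mask) * dy * dx
        area_central = np.count_nonzero(central_mask) * dy * dx
    total_int = img[total_mask].sum()
    if total_int == 0:
        raise ZeroIntensityError("zero total intensity inside the outline")
    if area_central == 0:
        raise DegenerateOutlineError("central region has zero area")
    central_density = img[central_mask].sum() / area_central
    total_density = total_int / area_total
    if variant == "ratio":
        return float(central_density / total_density - 1.0)
    if variant == "log_ratio":
        if central_density == 0:
            return float("-inf")
        return float(np.log2(central_density / total_density))
    raise ValueError(f"unknown recruitment variant {variant!r}")


def mask_perimeter(
    mask: np.ndarray, pixel_size: tuple[float, float], smooth_px: float = 1.0
) -> float:
    """Physical perimeter of a raster region by marching-squares contour tracing.

    The binary mask is lightly smoothed (Gaussian, ``smooth_px`` pixels)
    before tracing the 0.5 level set: on a hard mask the contour staircases
    and overestimates smooth boundaries by ~6%, while the smoothed level set
    places the boundary at subpixel accuracy (<1% error on discs/ellipses,
    ~2% corner rounding on rectangles).
    """
    dy, dx = pixel_size
    padded = np.pad(np.asarray(mask, dtype=float), 4)
    if smooth_px > 0:
        padded = gaussian_filter(padded, smooth_px)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise DegenerateOutlineError("mask has no boundary contour")
    # a single region still yields interior hole contours; sum them all
    total = 0.0
    for c in contours:
        d = np.diff(c, axis=0)
        total += float(np.sqrt((d[:, 0] * dy) ** 2 + (d[:, 1] * dx) ** 2).sum())
    return total


def circularity(
    shape_in: np.ndarray | Polygon, pixel_size: tuple[float, float] | None = None
) -> float:
    """Shape circularity 4π·A/P²: 1 for a circle, π/4 for a square.

    Accepts a polygon in μm or a single-connected-region raster mask with
    its pixel size; the raster perimeter comes from marching-squares
    contour tracing of the boundary.
    """
    if isinstance(shape_in, Polygon):
        a, p = shape_in.area, shape_in.length
        if a == 0 or p == 0:
            raise DegenerateOutlineError("degenerate polygon")
        return float(4 * np.pi * a / p**2)
    mask = np.asarray(shape_in, dtype=bool)
    if pixel_size is None:
        raise ValueError("pixel_size required for raster masks")
    if not mask.any():
        raise DegenerateOutlineError("mask is empty")
    n_comp = sk_label(mask, connectivity=2).max()
    if n_comp > 1:
        raise MultiComponentError(
            f"mask has {n_comp} connected components; pass the largest component explicitly"
        )
    dy, dx = pixel_size
    area = np.count_nonzero(mask) * dy * dx
    perim = mask_perimeter(mask, pixel_size)
    return float(4 * np.pi * area / perim**2)


# ---------------------------------------------------------------------------
# foci and intensity summaries
# ---------------------------------------------------------------------------

def count_foci(
    plane: SynapticPlane,
    channel: str,
    min_area: float = 0.10,
    max_area: float = 4.00,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> int:
    """Number of discrete puncta of a channel at the synaptic plane.

    The channel image is thresholded inside the cell outline and surviving
    8-connected particles are size-filtered to [min_area, max_area] μm².
    """
    if channel not in plane.images:
        raise KeyError(f"plane has no channel {channel!r}")
    img = np.asarray(plane.images[channel], dtype=np.float64)
    outline = plane.outline_mask(img.shape)
    inside = np.where(outline, img, 0.0)
    if threshold_method == "otsu":
        vals = img[outline]
        if vals.size == 0 or vals.min() == vals.max():
            return 0
        binary = inside > threshold_otsu(vals)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        binary = inside > threshold_value
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    binary &= outline
    particles = filter_particles_2d(binary, min_area, max_area, plane.pixel_size)
    return len(particles)


@dataclass
class IntensitySummary:
    integrated: float
    n_pixels: int
    area_um2: float
    mean: float  # integrated / n_pixels


def intensity_summary(
    image: np.ndarray | PlaneImage,
    mask: np.ndarray,
    pixel_size: tuple[float, float] | None = None,
) -> IntensitySummary:
    """Mean and integrated intensity of an image (projection or plane) in a mask."""
    if isinstance(image, PlaneImage):
        pixel_size = image.pixel_size
        image = image.data
    if pixel_size is None:
        raise ValueError("pixel_size required when image is a bare array")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateOutlineError("mask is empty")
    vals = np.asarray(image, dtype=np.float64)[mask]
    dy, dx = pixel_size
    return IntensitySummary(
        integrated=float(vals.sum()),
        n_pixels=int(vals.size),
        area_um2=float(vals.size * dy * dx),
        mean=float(vals.mean()),
    )
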