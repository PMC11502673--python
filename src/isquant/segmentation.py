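"""Binary marker models and labeled 3D compartments.

Replicates the quantification chain used on the microscopy data: threshold
each channel (per-slice or globally), erode slices by one pixel to refine
boundaries, connect adjacent in-plane ROIs along z into 3D compartments,
and quantify their volume by voxel counting. A trained-classifier step is
intentionally not reproduced: thresholding (Otsu or fixed) plus an escape
hatch for user-supplied masks covers the same pathway, and the downstream
metrics are what matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .core_io import ChannelStack


class ConstantChannelError(Exception):
    """Otsu thresholding is undefined for a constant-intensity input."""


@dataclass
class BinaryStack:
    """3D boolean grid with physical voxel size and a provenance record."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryStack data must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        return float(np.count_nonzero(self.data) * self.voxel_volume)


@dataclass
class Component:
    """One 3D ROI: its voxels and derived physical measurements."""

    id: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices
    volume_um3: float
    slice_areas_um2: dict[int, float]
    bbox: tuple  # (z0, y0, x0, z1, y1, x1)
    centroid_um: np.ndarray  # (x, y, z)


@dataclass
class LabeledComponents:
    """Disjoint 3D components, ids sorted by volume descending (1 = largest)."""

    components: list[Component]
    labels: np.ndarray = field(repr=False)  # int grid, 0 = background
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def total_volume_um3(self) -> float:
        return float(sum(c.volume_um3 for c in self.components))

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def component_mask(self, ids) -> np.ndarray:
        return np.isin(self.labels, list(ids))


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_stack(
    channel: ChannelStack,
    method: str = "otsu",
    value: float | None = None,
    per_slice: bool = False,
) -> BinaryStack:
    """Binarize a channel: voxel true iff intensity > threshold.

    ``method='otsu'`` derives the threshold from the intensity histogram
    (one per z-slice when ``per_slice`` is set, else one global value);
    ``method='fixed'`` uses the supplied ``value``.
    """
    data = channel.data
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        out = data > value
        prov = f"{channel.name}:fixed({value})"
    elif method == "otsu":
        if per_slice:
            out = np.zeros(data.shape, dtype=bool)
            for k in range(data.shape[0]):
                sl = data[k]
                if sl.min() == sl.max():
                    raise ConstantChannelError(
                        f"channel {channel.name!r}: slice {k} is constant; "
                        "Otsu has no separable classes"
                    )
                out[k] = sl > threshold_otsu(sl)
            prov = f"{channel.name}:otsu(per_slice)"
        else:
            if data.min() == data.max():
                raise ConstantChannelError(
                    f"channel {channel.name!r} is constant; Otsu has no separable classes"
                )
            out = data > threshold_otsu(data)
            prov = f"{channel.name}:otsu(global)"
    else:
        raise ValueError(f"unknown threshold method {method!r}; use 'otsu' or 'fixed'")
    return BinaryStack(data=out, voxel_size=channel.voxel_size, provenance=prov)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def erode_slices(binary: BinaryStack, iterations: int = 1) -> BinaryStack:
    """Per-slice 2D erosion with a 3×3 structuring element, ``iterations`` times."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        out = binary.data.copy()
    else:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1] = True  # full 3x3 in-plane, nothing across z
        out = ndi.binary_erosion(
            binary.data, structure=structure, iterations=iterations, border_value=0
        )
    return BinaryStack(
        data=out,
        voxel_size=binary.voxel_size,
        provenance=f"{binary.provenance};erode_slices(x{iterations})",
    )


def _z_link_structure(in_plane_connectivity: int = 8) -> np.ndarray:
    """3D structuring element: 4/8-connectivity in-plane, face adjacency across z."""
    s = np.zeros((3, 3, 3), dtype=bool)
    if in_plane_connectivity == 8:
        s[1] = True
    elif in_plane_connectivity == 4:
        s[1, 1, :] = True
        s[1, :, 1] = True
    else:
        raise ValueError("in_plane_connectivity must be 4 or 8")
    s[0, 1, 1] = True
    s[2, 1, 1] = True
    return s


def link_roi_3d(binary: BinaryStack, in_plane_connectivity: int = 8) -> LabeledComponents:
    """Connect in-plane ROIs of consecutive slices into 3D components.

    Two voxels belong to the same component when they touch within a slice
    (8-connected by default, 4 as a config option) or occupy the same (y, x)
    column in consecutive slices — the minimal reading of connecting adjacent
    ROIs along the z-axis. Volumes are voxel counts times the voxel volume.
    """
    structure = _z_link_structure(in_plane_connectivity)
    raw_labels, n = ndi.label(binary.data, structure=structure)
    dz, dy, dx = binary.voxel_size
    voxel_vol = dz * dy * dx
    pixel_area = dy * dx

    comps: list[Component] = []
    objects = ndi.find_objects(raw_labels)
    for raw_id, slc in enumerate(objects, start=1):
        sub = raw_labels[slc] == raw_id
        zz, yy, xx = np.nonzero(sub)
        z0, y0, x0 = slc[0].start, slc[1].start, slc[2].start
        voxels = np.column_stack([zz + z0, yy + y0, xx + x0])
        slice_areas = {
            int(z): float(np.count_nonzero(voxels[:, 0] == z) * pixel_area)
            for z in np.unique(voxels[:, 0])
        }
        centroid_um = np.array(
            [voxels[:, 2].mean() * dx, voxels[:, 1].mean() * dy, voxels[:, 0].mean() * dz]
        )
        comps.append(
            Component(
                id=raw_id,
                voxels=voxels,
                volume_um3=float(len(voxels) * voxel_vol),
                slice_areas_um2=slice_areas,
                bbox=(z0, y0, x0, slc[0].stop, slc[1].stop, slc[2].stop),
                centroid_um=centroid_um,
            )
        )

    # stable ids: sorted by volume descending, ties by raw label order
    comps.sort(key=lambda c: (-c.volume_um3, c.id))
    relabel = np.zeros(n + 1, dtype=np.int32)
    for new_id, c in enumerate(comps, start=1):
        relabel[c.id] = new_id
        c.id = new_id
    labels = relabel[raw_labels]
    return LabeledComponents(components=comps, labels=labels, voxel_size=binary.voxel_size)


# ---------------------------------------------------------------------------
# 2D particle analysis
# ---------------------------------------------------------------------------

@dataclass
class Particle2D:
    id: int
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    coords: np.ndarray  # (n, 2) (row, col)


def filter_particles_2d(
    plane: np.ndarray,
    min_area: float,
    max_area: float,
    pixel_size: tuple[float, float],
    connectivity: int = 8,
) -> list[Particle2D]:
    """2D particles whose physical area lies in [min_area, max_area] μm², inclusive.

    Mirrors particle analysis with a size window: components are 8-connected
    (4 optional) and both bounds are inclusive, matching a printed closed
    range like 0.10–4.00 μm².
    """
    if min_area < 0 or max_area < 0:
        raise ValueError("area bounds must be non-negative")
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    plane = np.asarray(plane, dtype=bool)
    dy, dx = pixel_size
    pixel_area = dy * dx
    labels = sk_label(plane, connectivity=2 if connectivity == 8 else 1)
    out: list[Particle2D] = []
    # inclusive bounds must survive float products like 400 * 0.1**2
    eps = 1e-9 * max(1.0, max_area)
    for prop in regionprops(labels):
        area = prop.num_pixels * pixel_area
        if min_area - eps <= area <= max_area + eps:
            cy, cx = prop.centroid
            out.append(
                Particle2D(
                    id=prop.label,
                    area_um2=float(area),
                    centroid_um=(float(cx * dx), float(cy * dy)),
                    coords=prop.coords,
                )
            )
    return out
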