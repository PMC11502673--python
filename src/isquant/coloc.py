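"""3D voxel models, compartment selection and colocalization coefficients.

Implements the voxel-model arithmetic used to ask which lysosomes contain
antigen and SNX5: pairwise voxel-level intersections of binary marker
models, all-or-nothing selection of labeled compartments that touch a
second marker, nested volume fractions, per-cell volume binning, and the
intensity-based Pearson and Manders M1 coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ChannelStack
from .segmentation import BinaryStack, LabeledComponents

logger = logging.getLogger(__name__)


class GeometryMismatchError(Exception):
    """Operands do not share grid shape and voxel size."""


class UndefinedMetricError(Exception):
    """A denominator is zero; the quantity is undefined, not 0."""


@dataclass
class VoxelModel:
    """Binary 3D model of one marker; volume = true-voxel count × voxel volume."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    marker: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("VoxelModel data must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @classmethod
    def from_binary(cls, binary: BinaryStack, marker: str = "") -> "VoxelModel":
        return cls(data=binary.data, voxel_size=binary.voxel_size, marker=marker)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def volume_um3(self) -> float:
        return float(np.count_nonzero(self.data) * self.voxel_volume)


@dataclass
class CompartmentSelection:
    """Result of selecting labeled compartments by marker overlap."""

    selected_ids: list[int]
    selected_volume_um3: float
    reference_volume_um3: float

    @property
    def fraction_pct(self) -> float:
        """selected / reference volume as percent; undefined for empty reference."""
        if self.reference_volume_um3 == 0:
            raise UndefinedMetricError("reference volume is zero; fraction undefined")
        return 100.0 * self.selected_volume_um3 / self.reference_volume_um3


@dataclass
class ColocCoefficients:
    pearson_r: float
    manders_m1: float
    n_voxels: int


def _check_geometry(a, b) -> None:
    if a.data.shape != b.data.shape:
        raise GeometryMismatchError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.voxel_size, b.voxel_size):
        raise GeometryMismatchError(
            f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}"
        )


# ---------------------------------------------------------------------------
# voxel-model arithmetic
# ---------------------------------------------------------------------------

def intersect(a: VoxelModel, b: VoxelModel) -> VoxelModel:
    """Voxelwise logical AND of two marker models; marker records both parents."""
    _check_geometry(a, b)
    return VoxelModel(
        data=a.data & b.data,
        voxel_size=a.voxel_size,
        marker=f"{a.marker}&{b.marker}" if a.marker or b.marker else "",
    )


def select_compartments_containing(
    comps: LabeledComponents,
    marker: VoxelModel,
    min_overlap_voxels: int = 1,
) -> CompartmentSelection:
    """Compartments that contain a second marker, counted all-or-nothing.

    A compartment is selected iff at least ``min_overlap_voxels`` of its
    voxels intersect the marker model (default 1: any overlap selects,
    regardless of the amount of marker inside); its whole volume then
    counts toward the selected volume.
    """
    if comps.labels.shape != marker.data.shape or not np.allclose(
        comps.voxel_size, marker.voxel_size
    ):
        raise GeometryMismatchError("components and marker model differ in geometry")
    if min_overlap_voxels < 1:
        raise ValueError("min_overlap_voxels must be >= 1")
    selected, sel_vol = [], 0.0
    for c in comps.components:
        zz, yy, xx = c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]
        overlap = int(np.count_nonzero(marker.data[zz, yy, xx]))
        if overlap >= min_overlap_voxels:
            selected.append(c.id)
            sel_vol += c.volume_um3
    return CompartmentSelection(
        selected_ids=selected,
        selected_volume_um3=sel_vol,
        reference_volume_um3=comps.total_volume_um3,
    )


@dataclass
class NestedFraction:
    """Two-level compartment selection percentages.

    ``containing_pct``: volume of compartments touching marker1 over total
    compartment volume, as percent. ``nested_pct``: volume of the
    intersection of marker1-selected compartments with marker2, over the
    volume of the intersection of all compartments with marker2, as
    percent; ``None`` (flagged) when the denominator is zero.
    """

    containing_pct: float | None
    nested_pct: float | None

    @property
    def defined(self) -> bool:
        return self.containing_pct is not None and self.nested_pct is not None


def nested_fraction(
    comps: LabeledComponents,
    marker1: VoxelModel,
    marker2: VoxelModel,
    min_overlap_voxels: int = 1,
) -> NestedFraction:
    """Fraction of compartment volume containing marker1, and of that
    selection's marker2 overlap relative to all compartments' marker2 overlap."""
    sel = select_compartments_containing(comps, marker1, min_overlap_voxels)
    if comps.total_volume_um3 == 0:
        logger.warning("nested_fraction: no compartment volume; both percents undefined")
        return NestedFraction(containing_pct=None, nested_pct=None)
    containing = 100.0 * sel.selected_volume_um3 / comps.total_volume_um3

    all_mask = comps.mask()
    sel_mask = comps.component_mask(sel.selected_ids)
    voxel_vol = marker2.voxel_volume
    denom = float(np.count_nonzero(all_mask & marker2.data) * voxel_vol)
    if denom == 0:
        logger.warning("nested_fraction: marker2 does not intersect compartments; "
                       "nested percent undefined")
        return NestedFraction(containing_pct=containing, nested_pct=None)
    numer = float(np.count_nonzero(sel_mask & marker2.data) * voxel_vol)
    return NestedFraction(containing_pct=containing, nested_pct=100.0 * numer / denom)


# ---------------------------------------------------------------------------
# volume distribution and counts
# ---------------------------------------------------------------------------

def bin_volumes(
    comps: LabeledComponents, edges: tuple[float, float] = (6.0, 12.0)
) -> list[float]:
    """Percent of total compartment volume per size category.

    With edges (e1, e2) the categories are [0, e1), [e1, e2], (e2, ∞):
    the convention for a printed "<e1, e1–e2, >e2" labeling, with both
    middle boundaries inclusive. Volume-weighted; percentages sum to 100.
    """
    if not all(e2 > e1 for e1, e2 in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("edges must be positive and strictly increasing")
    if len(comps) == 0:
        raise UndefinedMetricError("no components; volume distribution undefined")
    vols = np.array([c.volume_um3 for c in comps.components])
    total = vols.sum()
    n_bins = len(edges) + 1
    out = np.zeros(n_bins)
    for v in vols:
        if v < edges[0]:
            b = 0
        elif v > edges[-1]:
            b = n_bins - 1
        else:
            # closed middle bins; a value on an interior edge goes to the lower bin
            b = next(
                i + 1
                for i in range(len(edges))
                if edges[i] <= v and (i + 1 == len(edges) or v <= edges[i + 1])
            )
        out[b] += v
    return list(100.0 * out / total)


def count_components(comps: LabeledComponents) -> int:
    """Number of 3D compartments."""
    return len(comps)


# ---------------------------------------------------------------------------
# intensity-based colocalization
# ---------------------------------------------------------------------------

def pearson(a: ChannelStack, b: ChannelStack, mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation of paired voxel intensities over the z-stack.

    ``mask`` restricts the voxel pairs (e.g. to one cell); ``None`` uses
    every voxel. Requires non-zero variance in both channels.
    """
    if a.shape != b.shape:
        raise GeometryMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    x = a.data[mask].astype(np.float64)
    y = b.data[mask].astype(np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 masked voxels")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("zero variance in a channel; Pearson undefined")
    return float((xc * yc).sum() / (sx * sy))


def manders_m1(
    intensity: ChannelStack,
    reference: VoxelModel,
    mask: np.ndarray | None = None,
) -> float:
    """Manders M1: fraction of a channel's integrated intensity inside the
    reference marker's labeled region. In [0, 1]; invariant to uniform
    rescaling of the intensity channel."""
    if intensity.shape != reference.data.shape:
        raise GeometryMismatchError(
            f"shape mismatch: {intensity.shape} vs {reference.data.shape}"
        )
    if mask is None:
        mask = np.ones(intensity.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    total = float(intensity.data[mask].sum())
    if total == 0:
        raise UndefinedMetricError("zero total masked intensity; M1 undefined")
    inside = float(intensity.data[mask & reference.data].sum())
    return inside / total


def coloc_coefficients(
    a: ChannelStack,
    b: ChannelStack,
    reference: VoxelModel,
    mask: np.ndarray | None = None,
) -> ColocCoefficients:
    """Convenience bundle: Pearson r of (a, b) and Manders M1 of a over the reference."""
    n = int(np.count_nonzero(mask)) if mask is not None else int(np.prod(a.shape))
    return ColocCoefficients(
        pearson_r=pearson(a, b, mask),
        manders_m1=manders_m1(a, reference, mask),
        n_voxels=n,
    )
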