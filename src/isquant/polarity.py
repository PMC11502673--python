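"""Polarity index of a fluorescent label relative to the cell–bead axis.

The index measures how far a label's fluorescence center of mass has moved
toward the antigen-coated bead. The label center is projected onto the axis
running from the cell center of mass (Cellmc) to the bead center of mass
(Beadmc); the signed projection length divided by the axis length gives the
index: +1 when the label sits at the bead center (fully polarized), 0 at the
cell center, −1 at the mirror point through the cell center (anti-polarized).
Values beyond [−1, +1] (label past the bead along the axis) are clamped and
the clamp is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ChannelStack

logger = logging.getLogger(__name__)


class EmptyMaskError(Exception):
    """The mask selects no voxels."""


class ZeroIntensityError(Exception):
    """The mask is non-empty but the total masked intensity is zero."""


class DegenerateAxisError(Exception):
    """Beadmc coincides with Cellmc; the polarity axis is undefined."""


@dataclass(frozen=True)
class PolarityFrame:
    """Reference frame for the index: cell and bead centers of mass in μm (x, y, z)."""

    cellmc: np.ndarray
    beadmc: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "cellmc", np.asarray(self.cellmc, dtype=float))
        object.__setattr__(self, "beadmc", np.asarray(self.beadmc, dtype=float))
        if self.axis_length == 0.0:
            raise DegenerateAxisError("Beadmc equals Cellmc: polarity axis undefined")

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(self.beadmc - self.cellmc))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector Cellmc → Beadmc."""
        return (self.beadmc - self.cellmc) / self.axis_length


@dataclass(frozen=True)
class PolarityIndex:
    value: float
    label: str
    pmtoc: np.ndarray
    clamped: bool = False


def center_of_mass(channel: ChannelStack, mask: np.ndarray) -> np.ndarray:
    """Intensity-weighted mean position of masked voxels, in μm (x, y, z).

    Raises :class:`EmptyMaskError` for an empty mask and the distinct
    :class:`ZeroIntensityError` when the mask holds only zero intensity.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != channel.shape:
        raise ValueError(f"mask shape {mask.shape} != channel shape {channel.shape}")
    if not mask.any():
        raise EmptyMaskError(f"channel {channel.name!r}: mask selects no voxels")
    w = np.where(mask, channel.data.astype(np.float64), 0.0)
    total = w.sum()
    if total == 0.0:
        raise ZeroIntensityError(f"channel {channel.name!r}: zero total intensity in mask")
    zz, yy, xx = np.nonzero(mask)
    wv = w[zz, yy, xx]
    dz, dy, dx = channel.voxel_size
    cz = float((wv * zz).sum() / total) * dz
    cy = float((wv * yy).sum() / total) * dy
    cx = float((wv * xx).sum() / total) * dx
    return np.array([cx, cy, cz])


def mask_centroid(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Uniform-weight centroid of a binary stack in μm (x, y, z); Cellmc source."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask selects no voxels")
    zz, yy, xx = np.nonzero(mask)
    dz, dy, dx = voxel_size
    return np.array([xx.mean() * dx, yy.mean() * dy, zz.mean() * dz])


def polarity_index(
    frame: PolarityFrame, label_cm, label: str = "", clamp: bool = True
) -> PolarityIndex:
    """Signed projection of ``label_cm`` onto the Cellmc→Beadmc axis over the axis length.

    Works identically for 3D points and for 2D points (single-plane mode for
    epifluorescence-style data) as long as frame and label share the dimension.
    """
    label_cm = np.asarray(label_cm, dtype=float)
    proj = float(np.dot(label_cm - frame.cellmc, frame.axis))
    pmtoc = frame.cellmc + proj * frame.axis
    value = proj / frame.axis_length
    clamped = False
    if clamp and not -1.0 <= value <= 1.0:
        logger.warning(
            "polarity index %.4f for label %r outside [-1, 1]; clamped", value, label
        )
        value = float(np.clip(value, -1.0, 1.0))
        clamped = True
    return PolarityIndex(value=value, label=label, pmtoc=pmtoc, clamped=clamped)
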