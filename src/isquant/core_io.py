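"""Image-stack I/O and projections.

Conventions used throughout the package:

* voxel grids are indexed ``(z, y, x)``;
* physical coordinates are reported as ``(x, y, z)`` in micrometres;
* voxel indices are 0-based and a voxel's *center* sits at ``index * spacing``;
* anisotropy is carried, never resampled — volumes are voxel counts times
  ``dz*dy*dx`` and in-plane areas are pixel counts times ``dy*dx``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml


class SceneReadError(Exception):
    """The stack file could not be read or the channel map does not fit it."""


class MissingVoxelSizeError(SceneReadError):
    """Neither file metadata nor the config declares a voxel size."""


@dataclass
class ChannelStack:
    """One fluorescence channel as a 3D intensity grid with physical voxel size.

    Parameters
    ----------
    name : str
        Channel label, e.g. ``"LAMP1"``, ``"SNX5"``, ``"Ag"``, ``"actin"``.
    data : ndarray
        3D non-negative intensity grid indexed ``(z, y, x)``.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in micrometres; all components > 0.
    """

    name: str
    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"channel {self.name!r}: data must be 3D (z, y, x)")
        if np.any(self.data < 0):
            raise ValueError(f"channel {self.name!r}: intensities must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"channel {self.name!r}: voxel_size must be 3 positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class Bead:
    """A rigid spherical bead: center ``(x, y, z)`` in μm and radius in μm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        if self.radius <= 0:
            raise ValueError("bead radius must be > 0")


@dataclass
class Scene:
    """Co-registered channels plus bead geometry, masks and optional ground truth."""

    channels: dict[str, ChannelStack]
    beads: list[Bead] = field(default_factory=list)
    cell_masks: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        sizes = {c.voxel_size for c in self.channels.values()}
        if len(sizes) > 1:
            raise ValueError(f"channels have mismatched voxel sizes: {sizes}")
        for name, stack in self.channels.items():
            if name != stack.name:
                raise ValueError(f"channel key {name!r} != stack name {stack.name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_size


@dataclass
class PlaneImage:
    """A 2D intensity image carrying its physical pixel size ``(dy, dx)`` μm."""

    data: np.ndarray
    pixel_size: tuple[float, float]

    @property
    def pixel_area(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _ome_image(tif: tifffile.TiffFile) -> dict | None:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        return image
    except Exception:
        return None


def _beads_from_description(image: dict | None) -> list[Bead]:
    if not image or "Description" not in image:
        return []
    try:
        desc = json.loads(image["Description"])
        return [Bead(center=tuple(b["center"]), radius=b["radius"]) for b in desc["beads"]]
    except (ValueError, TypeError, KeyError):
        return []


def _voxel_size_from_ome(pixels: dict | None) -> tuple[float, float, float] | None:
    if not pixels:
        return None
    try:
        return (
            float(pixels["PhysicalSizeZ"]),
            float(pixels["PhysicalSizeY"]),
            float(pixels["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _channel_names_from_ome(pixels: dict | None) -> list[str] | None:
    if not pixels:
        return None
    try:
        chan = pixels["Channel"]
        if isinstance(chan, dict):
            chan = [chan]
        names = [c["Name"] for c in chan]
    except (KeyError, TypeError):
        return None
    if any(not isinstance(n, str) for n in names):
        return None
    return names


def read_scene(path: str | Path, config: Mapping) -> Scene:
    """Read a multi-channel TIFF/OME-TIFF z-stack into a :class:`Scene`.

    Parameters
    ----------
    path : path-like
        Multi-channel z-stack (axes interpreted as C,Z,Y,X or Z,C,Y,X per
        the file's axis metadata; a plain 4D array is taken as (C, Z, Y, X)).
    config : mapping
        ``channels``: mapping of channel index -> name. ``voxel_size``:
        ``(dz, dy, dx)`` μm, used when the file metadata carries none —
        if both are absent this is an explicit failure, never a default.

    Returns
    -------
    Scene
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            axes = tif.series[0].axes if tif.series else ""
            image = _ome_image(tif)
            pixels = image.get("Pixels") if image else None
            meta_voxel = _voxel_size_from_ome(pixels)
            meta_names = _channel_names_from_ome(pixels)
            beads = _beads_from_description(image)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise SceneReadError(f"cannot read {path}: {exc}") from exc

    if arr.ndim == 3:
        arr = arr[np.newaxis]  # single channel
        axes = "C" + axes if axes else ""
    if arr.ndim != 4:
        raise SceneReadError(f"{path}: expected a (C, Z, Y, X) stack, got shape {arr.shape}")
    if axes in ("ZCYX",):
        arr = np.swapaxes(arr, 0, 1)

    voxel_size = meta_voxel
    if voxel_size is None:
        voxel_size = config.get("voxel_size")
    if voxel_size is None:
        raise MissingVoxelSizeError(
            f"{path}: no voxel size in file metadata and none in config; "
            "declare config['voxel_size'] = (dz, dy, dx) in μm"
        )
    voxel_size = tuple(float(v) for v in voxel_size)

    channel_map = {int(k): str(v) for k, v in dict(config.get("channels", {})).items()}
    if not channel_map:
        if meta_names and len(meta_names) == arr.shape[0]:
            channel_map = dict(enumerate(meta_names))  # names stored in OME metadata
        else:
            channel_map = {i: f"ch{i}" for i in range(arr.shape[0])}
    for idx in channel_map:
        if idx < 0 or idx >= arr.shape[0]:
            raise SceneReadError(
                f"{path}: channel index {idx} out of range for {arr.shape[0]}-channel file"
            )
    names = list(channel_map.values())
    if len(set(names)) != len(names):
        raise SceneReadError(f"{path}: duplicate channel names in map: {names}")

    channels = {}
    cell_masks = {}
    for idx, name in channel_map.items():
        if name.startswith("mask:"):
            cell_masks[name[len("mask:") :]] = arr[idx] > 0
        else:
            channels[name] = ChannelStack(name=name, data=arr[idx], voxel_size=voxel_size)
    return Scene(
        channels=channels,
        beads=beads,
        cell_masks=cell_masks,
        metadata={"path": str(path)},
    )


def write_scene(scene: Scene, path: str | Path) -> None:
    """Write a Scene's channels as an OME-TIFF.

    Voxel size and channel names go into the OME metadata; bead geometry is
    serialized as JSON into the image Description; cell masks are stored as
    extra uint8 channels under reserved ``mask:`` names — so a written scene
    reads back complete.
    """
    path = Path(path)
    names = sorted(scene.channels)
    planes = [scene.channels[n].data for n in names]
    for mname in sorted(scene.cell_masks):
        names.append(f"mask:{mname}")
        planes.append(np.asarray(scene.cell_masks[mname], dtype=np.uint8))
    common = np.result_type(*(p.dtype for p in planes))
    arr = np.stack([p.astype(common) for p in planes])
    dz, dy, dx = scene.voxel_size
    description = json.dumps(
        {"beads": [{"center": list(b.center), "radius": b.radius} for b in scene.beads]}
    )
    tifffile.imwrite(
        path,
        arr,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "Channel": {"Name": names},
            "Description": description,
        },
        ome=True,
    )


def write_mask(mask: np.ndarray, voxel_size: Sequence[float], path: str | Path) -> None:
    """Write a binary stack as a single-channel 8-bit TIFF."""
    tifffile.imwrite(Path(path), mask.astype(np.uint8) * 255, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF as a boolean stack."""
    return np.asarray(tifffile.imread(Path(path))) > 0


def load_channel_config(path: str | Path) -> dict:
    """Load a YAML/JSON channel-map config ({'channels': {idx: name}, 'voxel_size': ...})."""
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def project(
    stack: ChannelStack,
    method: str = "sum",
    z_range: tuple[int, int] | None = None,
) -> PlaneImage:
    """Project a stack along z by SUM or MAX over the selected slices.

    ``z_range`` is a half-open ``(start, stop)`` slice bound; ``None`` uses
    the full depth. The physical in-plane pixel size is preserved on the
    returned :class:`PlaneImage`.
    """
    nz = stack.shape[0]
    if z_range is None:
        lo, hi = 0, nz
    else:
        lo, hi = z_range
        if lo < 0 or hi > nz:
            raise ValueError(f"z_range {z_range} outside stack depth {nz}")
    if hi <= lo:
        raise ValueError(f"empty z_range {z_range}")
    block = stack.data[lo:hi]
    if method == "sum":
        out = block.sum(axis=0, dtype=np.float64)
    elif method == "max":
        out = block.max(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}; use 'sum' or 'max'")
    return PlaneImage(data=out, pixel_size=stack.voxel_size[1:])


def voxel_centers_um(shape: tuple[int, int, int], voxel_size: Sequence[float]):
    """Coordinate arrays (μm) of voxel centers along each axis, (z, y, x) order."""
    dz, dy, dx = voxel_size
    z = np.arange(shape[0]) * dz
    y = np.arange(shape[1]) * dy
    x = np.arange(shape[2]) * dx
    return z, y, x
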