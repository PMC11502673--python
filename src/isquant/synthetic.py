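"""Synthetic immune-synapse scenes with known ground truth.

A scene emulates a single B cell in contact with an antigen-coated bead:
an ellipsoidal cell volume, a 3-μm bead docked at the cell surface, and a
population of spherical vesicular compartments (lysosome-like) whose
placement is biased toward the bead by a polarization parameter ``p``.
Each compartment independently carries each fluorescence marker with a
per-marker probability, so compartments can carry one, two or three labels
and every intensity-overlap pathway downstream is exercised. Channels are
rendered as solid-sphere kernels, blurred by a Gaussian PSF and corrupted
by Poisson shot noise plus Gaussian read noise; ground truth is computed
from the pre-noise geometry.

Placement model: with probability ``p`` a compartment center direction is
drawn from a von Mises–Fisher kernel peaked at the bead direction
(concentration ``kappa``), otherwise uniformly over the sphere; the radial
coordinate is uniform in volume inside the cell shrunk by the compartment
radius, so compartments always sit strictly inside the cell. This yields a
monotone map from ``p`` to the polarity index, which is what parameter-
recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter

from .core_io import Bead, ChannelStack, Scene
from .polarity import PolarityFrame, polarity_index


class PlacementError(Exception):
    """Compartments cannot be placed inside the cell under the spec's constraints."""


class NoiseSpec(BaseModel):
    """Noise model: Poisson shot noise (``poisson_scale`` photons per intensity
    unit, 0 disables) followed by additive Gaussian noise of sd ``gaussian_sd``
    (0 disables); negative values are clipped to zero afterwards."""

    poisson_scale: float = Field(default=1.0, ge=0)
    gaussian_sd: float = Field(default=2.0, ge=0)


class SceneSpec(BaseModel):
    """Parameters of one synthetic cell–bead scene.

    All lengths in μm. Defaults describe a ~8-μm B cell imaged at confocal
    sampling (0.25 μm in-plane, 0.5 μm in z) activated with a 3-μm bead,
    with a few dozen lysosome-sized compartments.
    """

    shape: tuple[int, int, int] = (24, 64, 64)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.5, 0.25, 0.25)  # (dz, dy, dx)
    cell_center: tuple[float, float, float] | None = None  # (x, y, z); None = grid center
    cell_semiaxes: tuple[float, float, float] = (4.0, 4.0, 4.0)  # (x, y, z)
    bead_radius: float = Field(default=1.5, gt=0)  # 3-μm bead
    bead_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_compartments: int = Field(default=40, ge=0)
    radius_mean: float = Field(default=0.4, gt=0)
    radius_sd: float = Field(default=0.08, ge=0)
    radius_min: float = Field(default=0.15, gt=0)
    radius_max: float = Field(default=1.2, gt=0)
    polarization: float = Field(default=0.5, ge=0.0, le=1.0)
    kappa: float = Field(default=8.0, gt=0)
    marker_table: dict[str, float] = Field(
        default_factory=lambda: {"LAMP1": 1.0, "Ag": 0.6, "SNX5": 0.6}
    )
    amplitude: float = Field(default=100.0, gt=0)
    psf_sigma: float = Field(default=0.2, ge=0)  # μm; 0 disables blur
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    bead_coat: dict[str, float] = Field(default_factory=dict)  # marker -> shell amplitude
    seed: int = 0
    max_retries: int = 1000

    @model_validator(mode="after")
    def _check(self):
        if any(not 0.0 <= q <= 1.0 for q in self.marker_table.values()):
            raise ValueError("marker_table probabilities must lie in [0, 1]")
        if self.radius_min > self.radius_max:
            raise ValueError("radius_min must be <= radius_max")
        if any(a <= 0 for a in self.cell_semiaxes):
            raise ValueError("cell semi-axes must be > 0")
        return self

    # -- derived geometry ---------------------------------------------------

    def resolved_cell_center(self) -> np.ndarray:
        """Cell center in μm (x, y, z); defaults to the grid center."""
        if self.cell_center is not None:
            return np.asarray(self.cell_center, dtype=float)
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_size
        return np.array([(nx - 1) * dx / 2, (ny - 1) * dy / 2, (nz - 1) * dz / 2])

    def bead_center(self) -> np.ndarray:
        """Bead center: on the cell surface along ``bead_direction``, tangent contact."""
        u = np.asarray(self.bead_direction, dtype=float)
        u = u / np.linalg.norm(u)
        a = np.asarray(self.cell_semiaxes, dtype=float)
        # distance from cell center to the ellipsoid surface along u
        t = 1.0 / np.sqrt(np.sum((u / a) ** 2))
        return self.resolved_cell_center() + (t + self.bead_radius) * u


@dataclass
class GroundTruth:
    """Pre-noise geometry of a synthetic scene and the analytic values it implies."""

    table: pd.DataFrame  # id, x, y, z, radius_um, volume_um3, markers, unlabeled
    label_centers: dict[str, np.ndarray]
    expected_index: dict[str, float]
    pairwise_overlap_um3: dict[tuple[str, str], float]
    marker_masks: dict[str, np.ndarray]  # pre-blur solid-sphere voxelizations
    cell_center: np.ndarray
    bead_center: np.ndarray

    @property
    def n_compartments(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# placement sampling (shared by generate_scene and expected_polarity)
# ---------------------------------------------------------------------------

def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One unit vector from a von Mises–Fisher density on S² peaked at mu."""
    u = rng.random()
    # inverse CDF of cos(theta) for vMF on the 2-sphere
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    v = np.array([w, s * np.cos(phi), s * np.sin(phi)])
    # rotate the pole (1,0,0) onto mu
    e1 = np.array([1.0, 0.0, 0.0])
    if np.allclose(mu, e1):
        return v
    if np.allclose(mu, -e1):
        return -v
    b = np.cross(e1, mu)
    b /= np.linalg.norm(b)
    c = np.cross(mu, b)
    basis = np.column_stack([mu, b, c])  # orthonormal, first column = mu
    return basis @ v


def _sample_placements(spec: SceneSpec, rng: np.random.Generator):
    """Sample compartment radii and centers; returns (centers μm xyz, radii)."""
    a = np.asarray(spec.cell_semiaxes, dtype=float)
    center = spec.resolved_cell_center()
    bead_dir = spec.bead_center() - center
    # bias direction in the scaled space where the cell is a unit ball
    mu = bead_dir / a
    mu /= np.linalg.norm(mu)

    radii = np.empty(spec.n_compartments)
    centers = np.empty((spec.n_compartments, 3))
    for i in range(spec.n_compartments):
        for attempt in range(spec.max_retries):
            r = rng.normal(spec.radius_mean, spec.radius_sd)
            if spec.radius_min <= r <= spec.radius_max:
                break
        else:
            raise PlacementError(
                f"could not draw a radius in [{spec.radius_min}, {spec.radius_max}] "
                f"from N({spec.radius_mean}, {spec.radius_sd}) in {spec.max_retries} tries"
            )
        shrunk = a - r  # compartment must fit strictly inside the cell
        if np.any(shrunk <= 0):
            raise PlacementError(
                f"compartment radius {r:.3f} μm does not fit inside cell "
                f"semi-axes {tuple(a)}"
            )
        if rng.random() < spec.polarization:
            v = _sample_vmf(mu, spec.kappa, rng)
        else:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
        s = rng.random() ** (1.0 / 3.0)  # uniform in volume along the ray
        centers[i] = center + shrunk * (s * v)
        radii[i] = r
    return centers, radii


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _rasterize_sphere(mask: np.ndarray, center_xyz, radius, voxel_size) -> None:
    """Set voxels whose centers fall inside the sphere (in place)."""
    dz, dy, dx = voxel_size
    cx, cy, cz = center_xyz
    nz, ny, nx = mask.shape
    z0 = max(0, int(np.floor((cz - radius) / dz)))
    z1 = min(nz, int(np.ceil((cz + radius) / dz)) + 1)
    y0 = max(0, int(np.floor((cy - radius) / dy)))
    y1 = min(ny, int(np.ceil((cy + radius) / dy)) + 1)
    x0 = max(0, int(np.floor((cx - radius) / dx)))
    x1 = min(nx, int(np.ceil((cx + radius) / dx)) + 1)
    z = np.arange(z0, z1) * dz - cz
    y = np.arange(y0, y1) * dy - cy
    x = np.arange(x0, x1) * dx - cx
    d2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    mask[z0:z1, y0:y1, x0:x1] |= d2 <= radius * radius


def rasterize_ellipsoid(shape, voxel_size, center_xyz, semiaxes_xyz) -> np.ndarray:
    """Boolean voxelization of an ellipsoid (voxel-center membership test)."""
    dz, dy, dx = voxel_size
    cx, cy, cz = center_xyz
    ax, ay, az = semiaxes_xyz
    z = (np.arange(shape[0]) * dz - cz) / az
    y = (np.arange(shape[1]) * dy - cy) / ay
    x = (np.arange(shape[2]) * dx - cx) / ax
    return (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    ) <= 1.0


def _sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Analytic volume of the intersection of two spheres (lens formula)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def generate_scene(spec: SceneSpec) -> tuple[Scene, GroundTruth]:
    """Render one synthetic scene and its ground truth. Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    centers, radii = _sample_placements(spec, rng)
    markers = sorted(spec.marker_table)
    membership = {
        m: rng.random(spec.n_compartments) < spec.marker_table[m] for m in markers
    }

    cell_center = spec.resolved_cell_center()
    bead_center = spec.bead_center()
    dz, dy, dx = spec.voxel_size

    # pre-noise geometry per marker
    marker_masks = {m: np.zeros(spec.shape, dtype=bool) for m in markers}
    for i in range(spec.n_compartments):
        for m in markers:
            if membership[m][i]:
                _rasterize_sphere(marker_masks[m], centers[i], radii[i], spec.voxel_size)

    channels: dict[str, ChannelStack] = {}
    sigma_vox = (spec.psf_sigma / dz, spec.psf_sigma / dy, spec.psf_sigma / dx)
    for m in markers:
        img = marker_masks[m].astype(np.float64) * spec.amplitude
        if m in spec.bead_coat and spec.bead_coat[m] > 0:
            img += spec.bead_coat[m] * _bead_shell(spec, bead_center)
        if spec.psf_sigma > 0:
            img = gaussian_filter(img, sigma=sigma_vox)
        if spec.noise.poisson_scale > 0:
            img = rng.poisson(img * spec.noise.poisson_scale) / spec.noise.poisson_scale
        if spec.noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.noise.gaussian_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
        channels[m] = ChannelStack(name=m, data=img, voxel_size=spec.voxel_size)

    cell_mask = rasterize_ellipsoid(
        spec.shape, spec.voxel_size, cell_center, spec.cell_semiaxes
    )
    scene = Scene(
        channels=channels,
        beads=[Bead(center=tuple(bead_center), radius=spec.bead_radius)],
        cell_masks={"cell": cell_mask},
        metadata={"synthetic": True, "seed": spec.seed, "polarization": spec.polarization},
    )

    volumes = 4.0 / 3.0 * np.pi * radii**3
    rows = []
    for i in range(spec.n_compartments):
        mm = tuple(m for m in markers if membership[m][i])
        rows.append(
            {
                "id": i,
                "x": centers[i, 0],
                "y": centers[i, 1],
                "z": centers[i, 2],
                "radius_um": radii[i],
                "volume_um3": volumes[i],
                "markers": mm,
                "unlabeled": len(mm) == 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["id", "x", "y", "z", "radius_um", "volume_um3", "markers", "unlabeled"],
    )

    frame = PolarityFrame(cellmc=cell_center, beadmc=bead_center)
    label_centers: dict[str, np.ndarray] = {}
    expected_index: dict[str, float] = {}
    for m in markers:
        sel = membership[m]
        if sel.any():
            w = volumes[sel]
            label_centers[m] = (centers[sel] * w[:, None]).sum(axis=0) / w.sum()
            expected_index[m] = polarity_index(frame, label_centers[m], label=m).value

    voxel_vol = dz * dy * dx
    overlap: dict[tuple[str, str], float] = {}
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1 :]:
            overlap[(m1, m2)] = float(
                np.count_nonzero(marker_masks[m1] & marker_masks[m2]) * voxel_vol
            )

    gt = GroundTruth(
        table=table,
        label_centers=label_centers,
        expected_index=expected_index,
        pairwise_overlap_um3=overlap,
        marker_masks=marker_masks,
        cell_center=cell_center,
        bead_center=bead_center,
    )
    return scene, gt


def _bead_shell(spec: SceneSpec, bead_center: np.ndarray) -> np.ndarray:
    """Unit-amplitude spherical shell on the bead surface (antigen coat)."""
    dz, dy, dx = spec.voxel_size
    cx, cy, cz = bead_center
    z = np.arange(spec.shape[0]) * dz - cz
    y = np.arange(spec.shape[1]) * dy - cy
    x = np.arange(spec.shape[2]) * dx - cx
    d = np.sqrt(z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2)
    thickness = max(spec.voxel_size)
    return (np.abs(d - spec.bead_radius) <= thickness / 2).astype(np.float64)


# ---------------------------------------------------------------------------
# placement-simulation oracle
# ---------------------------------------------------------------------------

def expected_polarity(
    spec: SceneSpec, n_sims: int = 200, seed: int | None = None
) -> tuple[float, float]:
    """Expected polarity index implied by the placement distribution.

    Simulates compartment placements only (no rendering): for each of
    ``n_sims`` simulated cells, the volume-weighted center of mass of the
    compartments is projected onto the cell→bead axis. Returns the mean and
    the Monte-Carlo standard deviation over cells of that index.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frame = PolarityFrame(cellmc=spec.resolved_cell_center(), beadmc=spec.bead_center())
    if spec.n_compartments == 0:
        raise PlacementError("expected_polarity undefined for a spec with no compartments")
    values = np.empty(n_sims)
    for k in range(n_sims):
        centers, radii = _sample_placements(spec, rng)
        w = radii**3
        cm = (centers * w[:, None]).sum(axis=0) / w.sum()
        values[k] = polarity_index(frame, cm, clamp=False).value
    return float(values.mean()), float(values.std(ddof=1))
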