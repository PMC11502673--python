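"""End-to-end orchestration: scenes in, per-cell metric tables out.

``run`` applies the full measurement chain to each scene — polarity indexes
per label, around-bead fractions, segmentation-derived volumes/counts/bins,
nested compartment selections, colocalization coefficients and synaptic-
plane metrics — and emits one MetricRecord row per cell. Per-scene failures
are logged and skipped, never abort the cohort. ``summarize`` reduces the
table to per-group mean ± SEM, matching the per-cell plotting style of the
underlying assays; hypothesis testing is intentionally out of scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy import ndimage as ndi

from . import __version__
from .coloc import (
    VoxelModel,
    intersect,
    manders_m1,
    nested_fraction,
    pearson,
)
from .core_io import ChannelStack, Scene, read_scene
from .metrics import (
    BeadROI,
    SynapticPlane,
    around_bead_fraction,
    circularity,
    count_foci,
    intensity_summary,
    recruitment_index,
    select_synaptic_plane,
    spreading_area,
)
from .polarity import PolarityFrame, center_of_mass, mask_centroid, polarity_index
from .segmentation import erode_slices, link_roi_3d, threshold_stack
from .synthetic import SceneSpec, generate_scene

logger = logging.getLogger(__name__)


class ThresholdConfig(BaseModel):
    method: str = "otsu"  # 'otsu' | 'fixed'
    value: float | None = None
    per_slice: bool = False


class PipelineConfig(BaseModel):
    """Every tunable of the measurement chain, validated before any computation."""

    seed: int = 0
    # scene reading
    channels: dict[int, str] = Field(default_factory=dict)
    voxel_size: tuple[float, float, float] | None = None
    # channel roles
    lysosome_channel: str = "LAMP1"
    antigen_channel: str = "Ag"
    snx_channel: str = "SNX5"
    recruitment_channel: str | None = None
    foci_channel: str | None = None
    # segmentation
    threshold: ThresholdConfig = Field(default_factory=ThresholdConfig)
    erode_iterations: int = Field(default=1, ge=0)
    in_plane_connectivity: int = 8
    # metrics
    analysis_radius: float = Field(default=3.5, gt=0)
    particle_min_area: float = Field(default=0.10, ge=0)
    particle_max_area: float = Field(default=4.00, ge=0)
    bin_edges: tuple[float, float] = (6.0, 12.0)
    min_overlap_voxels: int = Field(default=1, ge=1)
    synaptic_plane_z: int | None = None  # None = slice of maximal template intensity
    plane_template_channel: str | None = None  # None = lysosome channel
    recruitment_variant: str = "ratio"
    background_offset: float = Field(default=0.0, ge=0)
    # synthetic cohort (for the generate verb)
    n_scenes: int = Field(default=5, ge=0)
    scene: SceneSpec = Field(default_factory=SceneSpec)
    condition: str = "synthetic"
    time_point: float = 0.0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    table: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    @property
    def n_failed(self) -> int:
        return sum(1 for e in self.log if e.get("event") == "scene_failed")

    @property
    def partial(self) -> bool:
        return self.n_failed > 0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: PipelineConfig) -> list[tuple[str, Scene]]:
    """Synthetic cohort: ``n_scenes`` scenes with seeds derived from the config seed."""
    scenes = []
    for i in range(config.n_scenes):
        spec = config.scene.model_copy(update={"seed": int(config.seed) + i})
        scene, gt = generate_scene(spec)
        scene.metadata["ground_truth"] = gt
        scene.ground_truth = gt
        scenes.append((f"scene_{i:03d}", scene))
    return scenes


# ---------------------------------------------------------------------------
# per-scene measurement
# ---------------------------------------------------------------------------

def _derive_cell_mask(scene: Scene) -> np.ndarray:
    """Escape hatch when no cell mask is supplied: Otsu on the channel sum,
    hole-filled, largest connected component."""
    total = sum(c.data.astype(np.float64) for c in scene.channels.values())
    stack = ChannelStack(name="__sum__", data=total, voxel_size=scene.voxel_size)
    binary = threshold_stack(stack, method="otsu").data
    binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary)
    if n == 0:
        raise ValueError("could not derive a cell mask: empty segmentation")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _subtract_offset(channel: ChannelStack, offset: float) -> ChannelStack:
    if offset <= 0:
        return channel
    return ChannelStack(
        name=channel.name,
        data=np.clip(channel.data.astype(np.float64) - offset, 0.0, None),
        voxel_size=channel.voxel_size,
    )


def _segment(channel: ChannelStack, config: PipelineConfig):
    binary = threshold_stack(
        channel,
        method=config.threshold.method,
        value=config.threshold.value,
        per_slice=config.threshold.per_slice,
    )
    return erode_slices(binary, config.erode_iterations)


def quantify_scene(
    scene: Scene, config: PipelineConfig, scene_id: str = "scene"
) -> dict:
    """All per-cell metrics for one scene, as one MetricRecord dict.

    Metrics whose inputs are absent from the scene are explicitly None,
    never 0.
    """
    row: dict = {
        "scene_id": scene_id,
        "cell_id": 0,
        "condition": scene.metadata.get("condition", config.condition),
        "time_point": scene.metadata.get("time_point", config.time_point),
    }
    channels = {
        name: _subtract_offset(ch, config.background_offset)
        for name, ch in scene.channels.items()
    }
    cell_mask = (
        np.asarray(next(iter(scene.cell_masks.values())), dtype=bool)
        if scene.cell_masks
        else _derive_cell_mask(scene)
    )
    cellmc = mask_centroid(cell_mask, scene.voxel_size)

    # polarity + around-bead per labeled channel
    frame = None
    bead_roi = None
    if scene.beads:
        bead = scene.beads[0]
        frame = PolarityFrame(cellmc=cellmc, beadmc=np.asarray(bead.center))
        bead_roi = BeadROI(
            center=(bead.center[0], bead.center[1]),
            bead_radius=bead.radius,
            analysis_radius=config.analysis_radius,
        )
    for name, ch in channels.items():
        if frame is not None:
            cm = center_of_mass(ch, cell_mask)
            pi = polarity_index(frame, cm, label=name)
            row[f"polarity_{name}"] = pi.value
            row[f"polarity_{name}_clamped"] = pi.clamped
            row[f"around_bead_{name}"] = around_bead_fraction(ch, bead_roi, cell_mask)
        else:
            row[f"polarity_{name}"] = None
            row[f"polarity_{name}_clamped"] = None
            row[f"around_bead_{name}"] = None

    # volumetric chain on the lysosome channel
    lys = config.lysosome_channel
    if lys in channels:
        lys_binary = _segment(channels[lys], config)
        comps = link_roi_3d(lys_binary, config.in_plane_connectivity)
        row["n_compartments"] = len(comps)
        row["total_volume_um3"] = comps.total_volume_um3
        if len(comps) > 0:
            from .coloc import bin_volumes

            pct = bin_volumes(comps, config.bin_edges)
            row["volume_pct_small"], row["volume_pct_mid"], row["volume_pct_large"] = pct
        else:
            row["volume_pct_small"] = row["volume_pct_mid"] = row["volume_pct_large"] = None
        lys_model = VoxelModel.from_binary(lys_binary, marker=lys)
    else:
        comps = lys_model = None
        row["n_compartments"] = row["total_volume_um3"] = None
        row["volume_pct_small"] = row["volume_pct_mid"] = row["volume_pct_large"] = None

    ag = config.antigen_channel
    snx = config.snx_channel
    ag_model = (
        VoxelModel.from_binary(_segment(channels[ag], config), marker=ag)
        if ag in channels
        else None
    )
    snx_model = (
        VoxelModel.from_binary(_segment(channels[snx], config), marker=snx)
        if snx in channels
        else None
    )
    if comps is not None and ag_model is not None and snx_model is not None and len(comps):
        nf = nested_fraction(comps, ag_model, snx_model, config.min_overlap_voxels)
        row["pct_containing_antigen"] = nf.containing_pct
        row["pct_nested_snx"] = nf.nested_pct
    else:
        row["pct_containing_antigen"] = row["pct_nested_snx"] = None
    if lys_model is not None and ag_model is not None:
        row["lys_ag_overlap_um3"] = intersect(lys_model, ag_model).volume_um3
    else:
        row["lys_ag_overlap_um3"] = None

    # colocalization coefficients
    if lys in channels and ag in channels:
        row["pearson_r"] = pearson(channels[lys], channels[ag], cell_mask)
    else:
        row["pearson_r"] = None
    if snx in channels and lys_model is not None:
        row["manders_m1"] = manders_m1(channels[snx], lys_model, cell_mask)
    else:
        row["manders_m1"] = None

    # synaptic-plane metrics
    template = config.plane_template_channel or (lys if lys in channels else None)
    if template is not None and template in channels:
        z = select_synaptic_plane(scene, template, config.synaptic_plane_z)
        outline = cell_mask[z]
        if outline.any():
            plane = SynapticPlane(
                z_index=z,
                images={n: c.data[z] for n, c in channels.items()},
                outline=outline,
                pixel_size=scene.voxel_size[1:],
            )
            row["synaptic_z"] = z
            row["spreading_area_um2"] = spreading_area(plane)
            labels, _ = ndi.label(outline, structure=np.ones((3, 3), dtype=bool))
            largest = labels == (
                1 + int(np.argmax(np.bincount(labels[labels > 0])[1:]))
            )
            row["circularity"] = circularity(largest, plane.pixel_size)
            rec_ch = config.recruitment_channel
            row["recruitment_index"] = (
                recruitment_index(
                    plane.images[rec_ch],
                    outline,
                    plane.pixel_size,
                    config.recruitment_variant,
                )
                if rec_ch in plane.images
                else None
            )
            foci_ch = config.foci_channel
            row["foci_count"] = (
                count_foci(
                    plane,
                    foci_ch,
                    config.particle_min_area,
                    config.particle_max_area,
                    config.threshold.method if config.threshold.method != "fixed" else "fixed",
                    config.threshold.value,
                )
                if foci_ch in plane.images
                else None
            )
            if lys in plane.images:
                summ = intensity_summary(plane.images[lys], outline, plane.pixel_size)
                row["plane_intensity_mean"] = summ.mean
                row["plane_intensity_integrated"] = summ.integrated
            else:
                row["plane_intensity_mean"] = row["plane_intensity_integrated"] = None
        else:
            for k in (
                "synaptic_z",
                "spreading_area_um2",
                "circularity",
                "recruitment_index",
                "foci_count",
                "plane_intensity_mean",
                "plane_intensity_integrated",
            ):
                row[k] = None
    else:
        for k in (
            "synaptic_z",
            "spreading_area_um2",
            "circularity",
            "recruitment_index",
            "foci_count",
            "plane_intensity_mean",
            "plane_intensity_integrated",
        ):
            row[k] = None

    row["config_hash"] = config.config_hash()
    row["seed"] = config.seed
    row["version"] = __version__
    return row


def run(
    config: PipelineConfig,
    scenes: Sequence[tuple[str, Scene]] | None = None,
    scene_paths: Sequence[str | Path] | None = None,
) -> RunResult:
    """Measure a cohort. Deterministic given config + seed.

    ``scenes`` supplies in-memory scenes; ``scene_paths`` reads them from
    disk with the config's channel map; neither means a synthetic cohort is
    generated from the config. Per-scene failures are logged events, not
    aborts.
    """
    log: list[dict] = []
    if scenes is None and scene_paths is not None:
        scenes = []
        for p in scene_paths:
            try:
                scenes.append(
                    (
                        Path(p).stem,
                        read_scene(
                            p, {"channels": config.channels, "voxel_size": config.voxel_size}
                        ),
                    )
                )
            except Exception as exc:
                logger.warning("scene %s failed to load: %s", p, exc)
                log.append(
                    {"event": "scene_failed", "scene": str(p), "error": str(exc)}
                )
    elif scenes is None:
        scenes = generate_cohort(config)

    rows = []
    for scene_id, scene in scenes:
        try:
            rows.append(quantify_scene(scene, config, scene_id))
            log.append({"event": "scene_done", "scene": scene_id})
        except Exception as exc:  # per-scene isolation
            logger.warning("scene %s failed: %s", scene_id, exc)
            log.append({"event": "scene_failed", "scene": scene_id, "error": str(exc)})
    table = pd.DataFrame(rows)
    return RunResult(table=table, log=log)


def summarize(table: pd.DataFrame, group_keys: Sequence[str]) -> pd.DataFrame:
    """Per-group mean, SEM (ddof=1, SEM = sd/√n) and n of every numeric metric."""
    if table.empty:
        raise ValueError("empty metric table")
    for key in group_keys:
        if key not in table.columns:
            raise KeyError(f"unknown group key {key!r}")
    numeric = table.select_dtypes(include=[np.number]).columns.difference(
        ["cell_id", "seed", "synaptic_z"]
    )
    grouped = table.groupby(list(group_keys))[list(numeric)]
    out = grouped.agg(["mean", "sem", "count"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()
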