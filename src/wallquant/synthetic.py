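"""Synthetic microscopy fields, binding curves and colony counts with ground truth.

The field generator emulates the acquisition geometry the image pipeline
expects: a Z-stack of optical sections (default 28 at 300 nm step) holding
three channels — mCherry (cell-wall signal), Citrin (cytosol of the
reference strain) and CFP (cytosol of tester strains). Cells are ellipsoids
whose thin outer shell carries mCherry, either uniformly or restricted to a
polarized crescent; noise is camera offset plus Poisson shot noise and
Gaussian read noise, first-order sCMOS behaviour. Every generated object is
fully determined by one integer seed.

Ground truth exposes label/wall volumes and the per-cell mean wall mCherry
in the sum projection, the oracle for segmentation and measurement tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import yaml

from .io import DEFAULT_CHANNEL_ORDER, ImageField
from .segmentation import boundary_band
from .binding import BindingCurve, one_site
from .mating import MatingCount

#: cytosolic marker of each strain identity: the reference strain expresses
#: Citrin, tester strains express CFP.
IDENTITY_CHANNEL = {"reference": "Citrin", "tester": "CFP"}


@dataclass
class CellSpec:
    """One synthetic cell: ellipsoid geometry, identity and intensities.

    ``cytosol_intensity`` (ADU/voxel) is deposited in the cell interior in
    the cytosolic channel of the identity; ``wall_intensity`` goes into the
    mCherry channel of the shell — the voxels between the full ellipsoid
    (radii ``radii``) and the inner ellipsoid (radii reduced by
    ``wall_thickness``). With ``localization='crescent'`` the shell is
    restricted to the cone of half-angle ``crescent_halfangle`` around
    ``crescent_axis``; half-angle 180 degrees reproduces the uniform shell.
    """

    center: tuple  # (z, y, x) voxels
    radii: tuple  # (rz, ry, rx) voxels
    identity: str = "tester"
    cytosol_intensity: float = 400.0
    wall_intensity: float = 0.0
    wall_thickness: float = 2.0
    localization: str = "uniform"
    crescent_axis: tuple | None = None
    crescent_halfangle: float | None = None

    def __post_init__(self):
        self.center = tuple(float(v) for v in self.center)
        self.radii = tuple(float(v) for v in self.radii)
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be (z, y, x) triples")
        if self.identity not in IDENTITY_CHANNEL:
            raise ValueError(f"identity must be one of {sorted(IDENTITY_CHANNEL)}")
        if self.wall_thickness < 1:
            raise ValueError("wall_thickness must be >= 1 voxel")
        if min(self.radii) <= self.wall_thickness:
            raise ValueError("all radii must exceed wall_thickness")
        if self.cytosol_intensity < 0 or self.wall_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.localization not in ("uniform", "crescent"):
            raise ValueError("localization must be 'uniform' or 'crescent'")
        has_crescent = self.crescent_axis is not None and self.crescent_halfangle is not None
        if self.localization == "crescent" and not has_crescent:
            raise ValueError("crescent localization requires crescent_axis and crescent_halfangle")
        if self.localization == "uniform" and (
            self.crescent_axis is not None or self.crescent_halfangle is not None
        ):
            raise ValueError("crescent fields are only valid with localization='crescent'")
        if self.crescent_axis is not None:
            ax = np.asarray(self.crescent_axis, dtype=float)
            n = np.linalg.norm(ax)
            if n == 0:
                raise ValueError("crescent_axis must be a nonzero direction")
            self.crescent_axis = tuple(ax / n)


@dataclass
class SceneSpec:
    """A complete synthetic field: geometry, cells, camera and noise model.

    Noise model per voxel: ``Poisson(signal*poisson_scale)/poisson_scale +
    Normal(0, gaussian_sd) + camera_offset`` where ``signal`` is the
    noiseless fluorescence; ``poisson_scale=0`` disables shot noise,
    ``gaussian_sd=0`` disables read noise. Defaults emulate raw sCMOS
    frames (16-bit, offset 100 ADU).
    """

    image_shape: tuple = (28, 256, 256)  # (n_sections, height, width)
    voxel_step_z: float = 300.0
    cells: List[CellSpec] = dc_field(default_factory=list)
    camera_offset: float = 100.0
    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0
    seed: int = 0
    overlap_tolerance: int = 0

    def __post_init__(self):
        self.image_shape = tuple(int(v) for v in self.image_shape)
        if len(self.image_shape) != 3 or self.image_shape[0] < 1:
            raise ValueError("image_shape must be (n_sections >= 1, height, width)")
        if self.camera_offset < 0 or self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("camera_offset, gaussian_sd, poisson_scale must be >= 0")
        for cell in self.cells:
            for c, n in zip(cell.center, self.image_shape):
                if not (0 <= c < n):
                    raise ValueError(
                        f"cell center {cell.center} outside image bounds {self.image_shape}"
                    )


@dataclass
class GroundTruth:
    """Oracle companion of a generated field.

    ``true_mean_wall_mcherry`` is defined operationally in the sum
    projection: cytosolic markers delineate only the cell interior, so the
    segmentable footprint of a cell is its projected interior; the truth is
    the noiseless projected mCherry (camera offset included) averaged over
    the boundary band of that footprint at width = the cell's generative
    wall thickness — exactly the quantity the measurement pipeline targets.
    """

    label_volume: np.ndarray  # (Z, Y, X) int32, 0 background
    identity_map: Dict[int, str]
    wall_mask_volume: np.ndarray  # (Z, Y, X) bool
    true_mean_wall_mcherry: Dict[int, float]
    projected_interior_labels: np.ndarray  # (Y, X) int32
    projected_wall_bands: Dict[int, np.ndarray]  # label -> (Y, X) bool

    @property
    def n_cells(self) -> int:
        return len(self.identity_map)


def _ellipsoid_masks(cell: CellSpec, shape: tuple):
    """Boolean (interior, wall) volumes of one cell, clipped to the image."""
    nz, ny, nx = shape
    cz, cy, cx = cell.center
    rz, ry, rx = cell.radii
    z0, z1 = max(int(np.floor(cz - rz)) - 1, 0), min(int(np.ceil(cz + rz)) + 2, nz)
    y0, y1 = max(int(np.floor(cy - ry)) - 1, 0), min(int(np.ceil(cy + ry)) + 2, ny)
    x0, x1 = max(int(np.floor(cx - rx)) - 1, 0), min(int(np.ceil(cx + rx)) + 2, nx)
    dz = np.arange(z0, z1, dtype=float)[:, None, None] - cz
    dy = np.arange(y0, y1, dtype=float)[None, :, None] - cy
    dx = np.arange(x0, x1, dtype=float)[None, None, :] - cx
    norm_full = (dz / rz) ** 2 + (dy / ry) ** 2 + (dx / rx) ** 2
    t = cell.wall_thickness
    norm_inner = (dz / (rz - t)) ** 2 + (dy / (ry - t)) ** 2 + (dx / (rx - t)) ** 2
    cell_mask = norm_full <= 1.0
    interior = norm_inner < 1.0
    wall = cell_mask & ~interior
    if cell.localization == "crescent":
        az, ay, ax_ = cell.crescent_axis
        dot = dz * az + dy * ay + dx * ax_
        r = np.sqrt(dz**2 + dy**2 + dx**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(r > 0, dot / np.where(r > 0, r, 1.0), 1.0)
        cos_half = np.cos(np.deg2rad(cell.crescent_halfangle))
        wall = wall & (cosang >= cos_half)
    sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    return sl, interior, wall


def generate_field(spec: SceneSpec) -> tuple[ImageField, GroundTruth]:
    """Render a SceneSpec into a 3-channel stack plus its ground truth.

    Raises ``ValueError`` when cells overlap by more than
    ``spec.overlap_tolerance`` voxels (ground truth would be ambiguous) or
    when a cell center lies outside the image.
    """
    shape = spec.image_shape
    clean = np.zeros((3,) + shape, dtype=np.float64)  # (mCherry, Citrin, CFP)
    labels = np.zeros(shape, dtype=np.int32)
    wall_volume = np.zeros(shape, dtype=bool)
    interior_volume = np.zeros(shape, dtype=bool)
    identity_map: Dict[int, str] = {}

    ch_index = {name: i for i, name in enumerate(DEFAULT_CHANNEL_ORDER)}
    for k, cell in enumerate(spec.cells, start=1):
        sl, interior, wall = _ellipsoid_masks(cell, shape)
        mask = interior | wall
        overlap = int(np.count_nonzero(labels[sl][mask]))
        if overlap > spec.overlap_tolerance:
            raise ValueError(
                f"cell {k} overlaps a previous cell by {overlap} voxels "
                f"(tolerance {spec.overlap_tolerance})"
            )
        region = labels[sl]
        region[mask & (region == 0)] = k
        wall_volume[sl] |= wall
        interior_volume[sl] |= interior
        cyto_ch = ch_index[IDENTITY_CHANNEL[cell.identity]]
        clean[cyto_ch][sl][interior] += cell.cytosol_intensity
        clean[ch_index["mCherry"]][sl][wall] += cell.wall_intensity
        identity_map[k] = cell.identity

    # ground truth in the sum projection
    proj_mcherry = clean[ch_index["mCherry"]].sum(axis=0) + spec.camera_offset * shape[0]
    proj_interior_labels = np.zeros(shape[1:], dtype=np.int32)
    true_mean: Dict[int, float] = {}
    bands: Dict[int, np.ndarray] = {}
    for k, cell in enumerate(spec.cells, start=1):
        footprint = ((labels == k) & interior_volume).any(axis=0)
        proj_interior_labels[footprint & (proj_interior_labels == 0)] = k
        band, _ = boundary_band(footprint, cell.wall_thickness)
        bands[k] = band
        n_band = int(band.sum())
        true_mean[k] = float(proj_mcherry[band].sum() / n_band) if n_band else float("nan")

    gt = GroundTruth(
        label_volume=labels,
        identity_map=identity_map,
        wall_mask_volume=wall_volume,
        true_mean_wall_mcherry=true_mean,
        projected_interior_labels=proj_interior_labels,
        projected_wall_bands=bands,
    )

    rng = np.random.default_rng(spec.seed)
    if spec.poisson_scale > 0:
        data = rng.poisson(clean * spec.poisson_scale) / spec.poisson_scale
    else:
        data = clean.copy()
    if spec.gaussian_sd > 0:
        data = data + rng.normal(0.0, spec.gaussian_sd, size=data.shape)
    data = data + spec.camera_offset
    if spec.poisson_scale > 0 or spec.gaussian_sd > 0:
        # integer ADU semantics of a 16-bit camera
        data = np.clip(np.round(data), 0, 2**16 - 1).astype(np.uint16)
    field = ImageField(
        data=data,
        channel_names=DEFAULT_CHANNEL_ORDER,
        voxel_step_z=spec.voxel_step_z,
    )
    return field, gt


def generate_binding_curve(
    kd: float,
    bmax: float,
    ligand_points: Sequence[float],
    background_slope: float = 0.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> BindingCurve:
    """Simulate a saturation-binding experiment with a matched background.

    Total series: ``bmax*L/(kd+L) + background_slope*L + noise``; the
    protein-free background series is ``background_slope*L + noise``,
    mirroring an assay run without purified protein. Gaussian replicate
    noise with sd ``replicate_sd``; the seed fully determines the curve.
    """
    if kd <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ligand_points = np.asarray(list(ligand_points), dtype=float)
    if ligand_points.size == 0 or np.any(ligand_points <= 0):
        raise ValueError("ligand_points must be non-empty and positive")
    rng = np.random.default_rng(seed)
    ligand = np.repeat(ligand_points, n_replicates)
    model = one_site(ligand, kd=kd, bmax=bmax, background_slope=background_slope)
    noise_total = rng.normal(0.0, replicate_sd, size=ligand.size) if replicate_sd else 0.0
    noise_bg = rng.normal(0.0, replicate_sd, size=ligand.size) if replicate_sd else 0.0
    bound = model + noise_total
    background = background_slope * ligand + noise_bg
    return BindingCurve(ligand=ligand, bound=bound, background=background, unit="uM")


def generate_mating_counts(
    true_efficiency: float,
    n_cells_sampled: int,
    n_replicates: int,
    seed: int = 0,
) -> List[MatingCount]:
    """Simulate replicate colony counts at a known mating efficiency.

    Each replicate titers ``n_cells_sampled`` colonies on single selection;
    the diploid count is Binomial(total, efficiency).
    """
    if not 0.0 <= true_efficiency <= 1.0:
        raise ValueError("true_efficiency must lie in [0, 1]")
    if n_cells_sampled < 1 or n_replicates < 1:
        raise ValueError("n_cells_sampled and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    diploids = rng.binomial(n_cells_sampled, true_efficiency, size=n_replicates)
    return [
        MatingCount(replicate_id=i + 1, diploids=int(d), total=n_cells_sampled)
        for i, d in enumerate(diploids)
    ]


def simulate_kd_recovery(
    kd: float,
    n_repeats: int = 200,
    seed: int = 0,
    bmax: float = 1.0,
    n_ligand_points: int = 8,
    ligand_span: tuple[float, float] = (0.2, 4.0),
    noise_fraction: float = 0.05,
) -> np.ndarray:
    """Monte-Carlo Kd parameter-recovery experiment.

    Repeatedly simulates a saturation-binding curve (``n_ligand_points``
    ligand concentrations spanning ``ligand_span`` x Kd, Gaussian replicate
    noise with sd ``noise_fraction * bmax``) and refits the one-site model,
    returning the fitted Kd of every repeat. The median of the result
    measures how well the fitting recovers the generative affinity.
    """
    from .binding import fit_binding  # deferred: binding does not know about scenes

    ligand = np.linspace(ligand_span[0], ligand_span[1], n_ligand_points) * kd
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    fitted = np.empty(n_repeats)
    for i, s in enumerate(seeds):
        curve = generate_binding_curve(
            kd=kd,
            bmax=bmax,
            ligand_points=ligand,
            replicate_sd=noise_fraction * bmax,
            n_replicates=1,
            seed=int(s),
        )
        # noise-free background series: fit the total signal directly
        fitted[i] = fit_binding(
            BindingCurve(ligand=curve.ligand, bound=curve.bound, unit=curve.unit)
        ).kd
    return fitted


# --- scene (de)serialization -------------------------------------------------

def scene_to_dict(spec: SceneSpec) -> dict:
    return asdict(spec)


def scene_from_dict(d: dict) -> SceneSpec:
    cells = [CellSpec(**c) for c in d.get("cells", [])]
    kwargs = {k: v for k, v in d.items() if k != "cells"}
    return SceneSpec(cells=cells, **kwargs)


def save_scene(spec: SceneSpec, path) -> None:
    """Write a SceneSpec as YAML (default) or JSON, by file suffix."""
    path = Path(path)
    d = scene_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))


def load_scene(path) -> SceneSpec:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scene_from_dict(d)
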