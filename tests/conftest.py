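"""Shared fixtures: synthetic scenes with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from wallquant import CellSpec, SceneSpec, generate_field


def make_two_cell_scene(gaussian_sd=0.0, poisson_scale=0.0, camera_offset=100.0, seed=1):
    """One reference cell (no wall signal) and one tester cell (wall mCherry)."""
    cells = [
        CellSpec(center=(8, 30, 30), radii=(7, 14, 14), identity="reference",
                 cytosol_intensity=400, wall_intensity=0, wall_thickness=2),
        CellSpec(center=(8, 30, 80), radii=(7, 15, 15), identity="tester",
                 cytosol_intensity=400, wall_intensity=300, wall_thickness=2),
    ]
    return SceneSpec(
        image_shape=(16, 120, 120), cells=cells, camera_offset=camera_offset,
        gaussian_sd=gaussian_sd, poisson_scale=poisson_scale, seed=seed,
    )


def random_scene(seed, n_cells=None, shape=(12, 200, 200), wall_thickness=3.0,
                 camera_offset=100.0, gaussian_sd=0.0, poisson_scale=0.0,
                 identity_wall=None):
    """Random non-overlapping near-spherical cells inside the border margin.

    ``identity_wall`` optionally maps identity -> wall mCherry intensity;
    otherwise wall intensity is drawn uniformly in [150, 450].
    """
    rng = np.random.default_rng(seed)
    n_cells = n_cells or int(rng.integers(2, 5))
    nz, ny, nx = shape
    cells, placed = [], []
    attempts = 0
    while len(cells) < n_cells and attempts < 500:
        attempts += 1
        ry = float(rng.uniform(14, 20))
        rx = ry + float(rng.uniform(-2, 2))
        rz = float(rng.uniform(4.5, 5.5))
        margin = max(ry, rx) + 4
        cy = float(rng.uniform(margin, ny - margin))
        cx = float(rng.uniform(margin, nx - margin))
        if any(np.hypot(cy - py, cx - px) < max(ry, rx) + pr + 6 for py, px, pr in placed):
            continue
        identity = "reference" if rng.random() < 0.5 else "tester"
        if identity_wall is not None:
            wall = identity_wall[identity]
        else:
            wall = float(rng.uniform(150, 450))
        cells.append(CellSpec(
            center=(nz / 2, cy, cx), radii=(rz, ry, rx), identity=identity,
            cytosol_intensity=400, wall_intensity=wall, wall_thickness=wall_thickness,
        ))
        placed.append((cy, cx, max(ry, rx)))
    return SceneSpec(
        image_shape=shape, cells=cells, camera_offset=camera_offset,
        gaussian_sd=gaussian_sd, poisson_scale=poisson_scale, seed=seed,
    )


def match_labels(recovered_labels, truth):
    """Map recovered label -> ground-truth label by footprint overlap."""
    mapping = {}
    for k in np.unique(recovered_labels):
        if k == 0:
            continue
        mask = recovered_labels == k
        overlaps = {
            g: int((mask & (truth.projected_interior_labels == g)).sum())
            for g in truth.identity_map
        }
        best = max(overlaps, key=overlaps.get)
        if overlaps[best] > 0:
            mapping[int(k)] = best
    return mapping


@pytest.fixture
def two_cell_field():
    """Noiseless two-strain field with its ground truth."""
    return generate_field(make_two_cell_scene())


@pytest.fixture
def noisy_two_cell_field():
    """Same geometry at the default noise level."""
    return generate_field(make_two_cell_scene(gaussian_sd=2.0, poisson_scale=1.0))
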