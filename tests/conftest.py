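"""Shared fixtures: an exhaustive grid-search oracle and canonical simulations."""

from __future__ import annotations

import numpy as np
import pytest

_GRID_CACHE: dict[float, np.ndarray] = {}


def _lonlat_grid(resolution_deg: float) -> np.ndarray:
    """All unit vectors on a longitude/latitude grid at the given resolution."""
    if resolution_deg not in _GRID_CACHE:
        lon = np.deg2rad(np.arange(0.0, 360.0, resolution_deg))
        lat = np.deg2rad(np.arange(-90.0, 90.0 + resolution_deg / 2, resolution_deg))
        lo, la = np.meshgrid(lon, lat, indexing="ij")
        grid = np.column_stack(
            [
                (np.cos(la) * np.cos(lo)).ravel(),
                (np.cos(la) * np.sin(lo)).ravel(),
                np.sin(la).ravel(),
            ]
        )
        _GRID_CACHE[resolution_deg] = grid
    return _GRID_CACHE[resolution_deg]


def grid_search_min_msd(
    vectors: np.ndarray, resolution_deg: float = 0.25, refine: bool = True
) -> float:
    """Brute-force minimum mean spherical distance over a 3-D direction grid.

    Independent of the package's optimizer: enumerates every direction on
    a longitude/latitude grid and evaluates the mean arccos directly.
    With ``refine``, a dense tangent-plane patch around the coarse argmin
    is also enumerated, removing the coarse grid's discretization error
    (which reaches ~3e-3 rad at cone-like minima, e.g. a single vector).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    assert vectors.shape[1] == 3, "grid oracle is 3-D only"
    grid = _lonlat_grid(resolution_deg)
    best = np.inf
    best_dir = None
    for chunk in np.array_split(grid, max(1, grid.shape[0] // 200_000)):
        msd = np.arccos(np.clip(chunk @ vectors.T, -1.0, 1.0)).mean(axis=1)
        i = int(msd.argmin())
        if msd[i] < best:
            best, best_dir = float(msd[i]), chunk[i]
    if refine:
        e1 = np.cross(best_dir, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(best_dir, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(best_dir, e1)
        offs = np.linspace(-6e-3, 6e-3, 121)  # covers the coarse cell
        a, b = np.meshgrid(offs, offs, indexing="ij")
        patch = best_dir + a.ravel()[:, None] * e1 + b.ravel()[:, None] * e2
        patch /= np.linalg.norm(patch, axis=1)[:, None]
        msd = np.arccos(np.clip(patch @ vectors.T, -1.0, 1.0)).mean(axis=1)
        best = min(best, float(msd.min()))
    return best


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_search_min_msd


@pytest.fixture(scope="session")
def branching_embedding():
    """Canonical branching simulation: 90-degree turn at pseudotime 50."""
    from trajgeom import SimulationSpec, simulate_branching

    spec = SimulationSpec(
        n_cells=300, d=3, branch_direction=[0.0, 1.0, 0.0], branch_time=50.0,
        noise_sd=0.05, seed=20240,
    )
    return simulate_branching(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
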