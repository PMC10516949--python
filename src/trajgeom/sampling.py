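"""Pseudotime normalisation and path resampling.

Cells of one trajectory are ordered by a pseudotime that is min-max
normalised to ``[0, 100]`` per trajectory.  A representative path is then
drawn by splitting the pseudotime axis into windows of fixed width
(default 10 units, contiguous) and sampling one cell uniformly at random
from each non-empty window.  Repeating the draw many times (default 1000)
yields a distribution of paths whose spherical geometry characterises the
trajectory rather than any single arbitrary ordering of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import Path

__all__ = [
    "Embedding",
    "SamplingConfig",
    "SamplingError",
    "normalize_pseudotime",
    "make_windows",
    "sample_path",
    "sample_paths",
]


class SamplingError(ValueError):
    """Raised when a trajectory cannot supply a valid path."""


@dataclass(frozen=True)
class Embedding:
    """Per-cell reduced-space coordinates with pseudotime and lineage labels.

    Parameters
    ----------
    cell_ids
        Unique cell identifiers, length ``n``.
    coords
        Array of shape ``(n, D)`` with ``D >= 2`` reduced-space
        coordinates per cell (e.g. principal-component scores).
    pseudotime
        Non-negative pseudotime per cell (any scale; normalised to
        ``[0, 100]`` per trajectory before windowing).
    trajectory
        Categorical trajectory/branch label per cell.
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    pseudotime: np.ndarray
    trajectory: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.cell_ids)
        coords = np.asarray(self.coords, dtype=float)
        pt = np.asarray(self.pseudotime, dtype=float)
        traj = np.asarray(self.trajectory)
        n = len(ids)
        if len(np.unique(ids)) != n:
            raise ValueError("cell_ids must be unique")
        if coords.ndim != 2 or coords.shape[0] != n:
            raise ValueError("coords must be an (n_cells, D) array")
        if coords.shape[1] < 2:
            raise ValueError("embedding dimension D must be >= 2")
        if not np.isfinite(coords).all():
            raise ValueError("coords contain non-finite values")
        if pt.shape != (n,) or not np.isfinite(pt).all():
            raise ValueError("pseudotime must be a finite vector of length n_cells")
        if (pt < 0).any():
            raise ValueError("pseudotime must be non-negative")
        if traj.shape != (n,):
            raise ValueError("trajectory labels must have length n_cells")
        object.__setattr__(self, "cell_ids", ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "pseudotime", pt)
        object.__setattr__(self, "trajectory", traj)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def trajectories(self) -> list:
        """Distinct trajectory labels, in order of first appearance."""
        _, idx = np.unique(self.trajectory, return_index=True)
        return list(self.trajectory[np.sort(idx)])

    def subset(self, mask: np.ndarray) -> "Embedding":
        return Embedding(
            cell_ids=self.cell_ids[mask],
            coords=self.coords[mask],
            pseudotime=self.pseudotime[mask],
            trajectory=self.trajectory[mask],
        )


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the path-resampling procedure.

    Attributes
    ----------
    window_width
        Width of each pseudotime window on the normalised [0, 100]
        scale.  Default 10, i.e. ten contiguous windows per trajectory.
    window_step
        Spacing between window starts.  ``None`` (default) means
        contiguous, non-overlapping windows (step = width); a smaller
        step gives overlapping sliding windows.
    n_paths
        Number of independent path draws per trajectory (default 1000).
    dims
        Number of leading embedding coordinates used for the geometry
        (default 3: the first three principal components).
    min_points
        Minimum number of non-empty windows a path must span (default 3,
        the smallest path with at least two displacement vectors).
    seed
        Optional seed recorded with the analysis; the generator itself is
        passed explicitly to the sampling functions.
    """

    window_width: float = 10.0
    window_step: float | None = None
    n_paths: int = 1000
    dims: int = 3
    min_points: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.window_step is not None and self.window_step <= 0:
            raise ValueError("window_step must be positive")
        if self.dims < 2:
            raise ValueError("dims must be >= 2")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")

    @property
    def step(self) -> float:
        return self.window_width if self.window_step is None else self.window_step

    def with_(self, **kwargs) -> "SamplingConfig":
        return replace(self, **kwargs)


def normalize_pseudotime(values: np.ndarray) -> np.ndarray:
    """Min-max rescale pseudotime to ``[0, 100]``.

    The minimum maps to 0, the maximum to 100 and the ordering of cells
    is preserved.  Raises ``ValueError`` when all values coincide (zero
    range) or fewer than two values are supplied.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least two pseudotime values")
    if not np.isfinite(vals).all():
        raise ValueError("pseudotime values must be finite")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("pseudotime range is zero; cannot normalise")
    return (vals - lo) * 100.0 / (hi - lo)


def make_windows(
    start: float = 0.0,
    stop: float = 100.0,
    width: float = 10.0,
    step: float | None = None,
) -> list[tuple[float, float]]:
    """Pseudotime windows covering ``[start, stop]``.

    Windows are half-open ``[lo, lo+width)`` except the final one, which
    is closed at ``stop`` so the maximum pseudotime is never orphaned.
    With ``step is None`` the windows are contiguous.
    """
    if step is None:
        step = width
    if start >= stop:
        raise ValueError("start must be below stop")
    lows = []
    lo = start
    while lo < stop - 1e-9:
        lows.append(lo)
        lo += step
    return [(lo, min(lo + width, stop)) for lo in lows]


def _window_members(
    norm_pt: np.ndarray, windows: list[tuple[float, float]], stop: float = 100.0
) -> list[np.ndarray]:
    members = []
    for lo, hi in windows:
        if hi >= stop - 1e-9:  # final window keeps the endpoint
            mask = (norm_pt >= lo) & (norm_pt <= hi)
        else:
            mask = (norm_pt >= lo) & (norm_pt < hi)
        members.append(np.flatnonzero(mask))
    return members


def _trajectory_mask(embedding: Embedding, trajectory) -> np.ndarray:
    mask = embedding.trajectory == trajectory
    if not mask.any():
        raise SamplingError(f"trajectory {trajectory!r} not present in the embedding")
    return mask


def sample_path(
    embedding: Embedding,
    trajectory,
    config: SamplingConfig,
    rng: np.random.Generator,
    *,
    start: float = 0.0,
    norm_pt: np.ndarray | None = None,
) -> Path:
    """Draw one representative path from a trajectory.

    Pseudotime is normalised per trajectory, the ``[start, 100]`` range is
    split into windows per ``config``, and one cell is drawn uniformly at
    random from each non-empty window; empty windows are skipped.  The
    returned :class:`~trajgeom.geometry.Path` carries the chosen cells'
    first ``config.dims`` coordinates in window order.

    ``norm_pt`` allows a precomputed normalised pseudotime for the
    trajectory's cells to be reused across repeated draws (and keeps the
    global [0, 100] scale fixed when re-anchoring at ``start > 0``).

    Raises
    ------
    SamplingError
        If fewer than ``config.min_points`` windows are non-empty.
    """
    mask = _trajectory_mask(embedding, trajectory)
    coords = embedding.coords[mask]
    if config.dims > coords.shape[1]:
        raise ValueError(
            f"dims={config.dims} exceeds embedding dimension {coords.shape[1]}"
        )
    if norm_pt is None:
        norm_pt = normalize_pseudotime(embedding.pseudotime[mask])
    windows = make_windows(start=start, width=config.window_width, step=config.window_step)
    members = _window_members(norm_pt, windows)
    picked_rows = []
    picked_windows = []
    for w_idx, cells in enumerate(members):
        if cells.size == 0:
            continue
        picked_rows.append(cells[rng.integers(cells.size)])
        picked_windows.append(w_idx)
    if len(picked_rows) < config.min_points:
        raise SamplingError(
            f"trajectory {trajectory!r}: only {len(picked_rows)} non-empty "
            f"windows from pseudotime {start:g}, need {config.min_points}"
        )
    pts = coords[np.array(picked_rows)][:, : config.dims]
    return Path(points=pts, window_index=np.array(picked_windows))


def sample_paths(
    embedding: Embedding,
    trajectory,
    config: SamplingConfig,
    rng: np.random.Generator,
    *,
    start: float = 0.0,
) -> list[Path]:
    """Draw ``config.n_paths`` independent paths under one seeded stream."""
    if config.n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    mask = _trajectory_mask(embedding, trajectory)
    norm_pt = normalize_pseudotime(embedding.pseudotime[mask])
    return [
        sample_path(embedding, trajectory, config, rng, start=start, norm_pt=norm_pt)
        for _ in range(config.n_paths)
    ]
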