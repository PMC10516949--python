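"""Synthetic embeddings with known trajectory geometry.

The simulators generate reduced-space embeddings whose ground truth is
known exactly, so every downstream operation — path sampling, msd
minimisation, permutation tests, branch-point scans, gene scoring — can
be validated without external data:

* a **linear backbone**: cells drift along a fixed unit direction as
  pseudotime advances, blurred by isotropic Gaussian noise;
* a **branching trajectory**: a second lineage shares the backbone up to
  a branch pseudotime, then departs along an orthogonal direction (the
  canonical geometry of a lineage committing away from a default path);
* an **isotropic null**: pseudotime is random and carries no positional
  information, the calibration case for the directionality test;
* matched **gene loadings** with unit-norm rows, so each gene's true
  alignment with the drift direction is known.

Pseudotime is exact in simulation (no inference noise): the package
tests geometry downstream of pseudotime, which is an input here.  The
trajectory arc length is fixed at 100 so the normalised pseudotime scale
and the coordinate scale coincide; ``noise_sd`` is expressed as a
fraction of that arc length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import Embedding
from .scoring import LoadingsMatrix

__all__ = [
    "SimulationSpec",
    "ARC_LENGTH",
    "simulate_linear",
    "simulate_branching",
    "simulate_isotropic",
    "simulate_with_loadings",
]

#: total trajectory arc length in reduced-space units; noise_sd scales on it
ARC_LENGTH = 100.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic trajectory.

    Attributes
    ----------
    n_cells
        Cells per trajectory (default 300).
    d
        Embedding dimension (default 3).
    direction
        Unit vector of the backbone drift; default the first axis.
    branch_direction
        Unit vector orthogonal to ``direction`` for the branching
        lineage; ``None`` for purely linear simulations.
    branch_time
        Normalised pseudotime in (0, 100) at which the branch departs
        (default 50).
    noise_sd
        Isotropic Gaussian noise s.d. as a fraction of the trajectory
        arc length (default 0.05, i.e. 5% of the backbone length).
    seed
        Seed of the generator used for pseudotimes and noise.
    """

    n_cells: int = 300
    d: int = 3
    direction: np.ndarray | None = None
    branch_direction: np.ndarray | None = None
    branch_time: float = 50.0
    noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("dimension d must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.branch_time < 100.0):
            raise ValueError("branch_time must lie in (0, 100)")
        direction = self.direction
        if direction is None:
            direction = np.zeros(self.d)
            direction[0] = 1.0
        direction = np.asarray(direction, dtype=float)
        if direction.shape != (self.d,):
            raise ValueError("direction must have length d")
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            raise ValueError("direction must be nonzero")
        direction = direction / nrm
        object.__setattr__(self, "direction", direction)
        bdir = self.branch_direction
        if bdir is not None:
            bdir = np.asarray(bdir, dtype=float)
            if bdir.shape != (self.d,):
                raise ValueError("branch_direction must have length d")
            bnrm = np.linalg.norm(bdir)
            if bnrm == 0:
                raise ValueError("branch_direction must be nonzero")
            bdir = bdir / bnrm
            if abs(float(direction @ bdir)) >= 1e-6:
                raise ValueError("branch_direction must be orthogonal to direction")
            object.__setattr__(self, "branch_direction", bdir)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def ground_truth(self) -> dict:
        """Machine-readable ground truth to serialise next to the data."""
        gt = {
            "n_cells": self.n_cells,
            "d": self.d,
            "direction": list(map(float, self.direction)),
            "noise_sd": self.noise_sd,
            "arc_length": ARC_LENGTH,
            "seed": self.seed,
        }
        if self.branch_direction is not None:
            gt["branch_direction"] = list(map(float, self.branch_direction))
            gt["branch_time"] = self.branch_time
        return gt


def _check_samplable(spec: SimulationSpec, min_points: int = 3) -> None:
    if spec.n_cells < 3 * min_points:
        raise ValueError(
            f"n_cells={spec.n_cells} too small to sample paths of "
            f"{min_points}+ windows reliably (need >= {3 * min_points})"
        )


def _noise(rng: np.random.Generator, n: int, d: int, noise_sd: float) -> np.ndarray:
    return rng.normal(scale=noise_sd * ARC_LENGTH, size=(n, d))


def simulate_linear(spec: SimulationSpec, *, label: str = "linear") -> Embedding:
    """A straight trajectory: position = (t/100) * L * direction + noise."""
    _check_samplable(spec)
    rng = spec.rng()
    t = rng.uniform(0.0, 100.0, size=spec.n_cells)
    coords = (t[:, None] / 100.0) * ARC_LENGTH * spec.direction[None, :]
    coords = coords + _noise(rng, spec.n_cells, spec.d, spec.noise_sd)
    ids = np.array([f"{label}_{i}" for i in range(spec.n_cells)])
    return Embedding(
        cell_ids=ids,
        coords=coords,
        pseudotime=t,
        trajectory=np.full(spec.n_cells, label, dtype=object),
    )


def _bent_positions(t: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Noise-free positions of the branching lineage at pseudotimes t."""
    tb = spec.branch_time
    before = np.minimum(t, tb)
    after = np.maximum(t - tb, 0.0)
    scale = ARC_LENGTH / 100.0
    return (
        before[:, None] * scale * spec.direction[None, :]
        + after[:, None] * scale * spec.branch_direction[None, :]
    )


def simulate_branching(spec: SimulationSpec) -> Embedding:
    """A backbone plus a lineage that turns 90 degrees at ``branch_time``.

    Two trajectories are emitted: ``"backbone"`` (straight, as in
    :func:`simulate_linear`) and ``"branch"``, which shares the backbone
    until ``branch_time`` and then proceeds along ``branch_direction``.
    The branch's pseudotime continues monotonically across the turn.
    """
    if spec.branch_direction is None:
        raise ValueError("simulate_branching requires branch_direction")
    _check_samplable(spec)
    rng = spec.rng()

    t_back = rng.uniform(0.0, 100.0, size=spec.n_cells)
    back = (t_back[:, None] / 100.0) * ARC_LENGTH * spec.direction[None, :]
    back = back + _noise(rng, spec.n_cells, spec.d, spec.noise_sd)

    t_br = rng.uniform(0.0, 100.0, size=spec.n_cells)
    br = _bent_positions(t_br, spec) + _noise(rng, spec.n_cells, spec.d, spec.noise_sd)

    n = spec.n_cells
    ids = np.array(
        [f"backbone_{i}" for i in range(n)] + [f"branch_{i}" for i in range(n)]
    )
    return Embedding(
        cell_ids=ids,
        coords=np.vstack([back, br]),
        pseudotime=np.concatenate([t_back, t_br]),
        trajectory=np.array(["backbone"] * n + ["branch"] * n, dtype=object),
    )


def simulate_isotropic(
    n_cells: int = 300, d: int = 3, seed: int | None = None, *, scale: float = 1.0
) -> Embedding:
    """A null 'trajectory': random pseudotime, i.i.d. Gaussian coordinates.

    Pseudotime carries no positional information, so any apparent
    directionality is a false positive; this is the calibration input
    for the permutation test.
    """
    if n_cells < 9:
        raise ValueError("n_cells must be >= 9")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 100.0, size=n_cells)
    coords = rng.normal(scale=scale, size=(n_cells, d))
    ids = np.array([f"iso_{i}" for i in range(n_cells)])
    return Embedding(
        cell_ids=ids,
        coords=coords,
        pseudotime=t,
        trajectory=np.full(n_cells, "isotropic", dtype=object),
    )


def simulate_with_loadings(
    spec: SimulationSpec, n_genes: int
) -> tuple[Embedding, LoadingsMatrix]:
    """A linear embedding plus random unit-norm gene loadings.

    Each gene's true alignment with the drift is ``row . direction``,
    known exactly, so score recovery can be checked end to end.  The
    loadings come from a stream derived from the same seed as the
    embedding noise, keeping the whole fixture reproducible.
    """
    if n_genes < spec.d:
        raise ValueError("n_genes must be >= d")
    emb = simulate_linear(spec)
    # separate deterministic stream so loadings do not depend on n_cells
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    rows = rng.normal(size=(n_genes, spec.d))
    rows /= np.linalg.norm(rows, axis=1)[:, None]
    genes = np.array([f"gene_{i}" for i in range(n_genes)])
    return emb, LoadingsMatrix(gene_ids=genes, loadings=rows)
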