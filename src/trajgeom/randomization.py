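"""Permutation nulls, directionality tests and the branch-point scan.

The directionality of a trajectory is tested against a randomisation
scheme that destroys the coupling between coordinates while preserving
every marginal distribution: each coordinate column of a sampled path is
permuted independently across the path's rows.  Each sampled path is
paired with exactly one permuted counterpart, and the paired minimised
msd values are compared with a two-sided Wilcoxon signed-rank test.  Two
trajectories are compared with a Mann-Whitney U test on their empirical
msd distributions.

The branch-point scan re-anchors a trajectory at successively later
normalised pseudotimes and repeats the directionality test on each
suffix: a trajectory that turns at some pseudotime shows lower msd (and
typically stronger directionality) once the start point passes the turn,
so the curve of msd / -log10 p versus the start offset localises the
branch point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import DirectionResult, Path, find_center, representative_center, unit_vectors
from .sampling import (
    Embedding,
    SamplingConfig,
    SamplingError,
    _trajectory_mask,
    normalize_pseudotime,
    sample_path,
)

__all__ = [
    "TrajectoryStats",
    "ComparisonResult",
    "BranchScanResult",
    "permute_columns",
    "directionality_test",
    "compare_trajectories",
    "branch_point_scan",
]


@dataclass(frozen=True)
class TrajectoryStats:
    """Directionality statistics for one trajectory.

    ``empirical_msd[i]`` and ``null_msd[i]`` derive from the same sampled
    path — the null entry is the minimised msd of that path's own
    column-permuted counterpart — so the arrays form matched pairs.
    """

    trajectory: object
    n_paths: int
    empirical_msd: np.ndarray
    null_msd: np.ndarray
    p_vs_random: float
    per_path_centers: np.ndarray
    representative: DirectionResult
    n_zero_differences: int = 0

    def __post_init__(self) -> None:
        emp = np.asarray(self.empirical_msd, dtype=float)
        nul = np.asarray(self.null_msd, dtype=float)
        if emp.shape != (self.n_paths,) or nul.shape != (self.n_paths,):
            raise ValueError("empirical and null msd must both have length n_paths")
        for arr, name in ((emp, "empirical_msd"), (nul, "null_msd")):
            if ((arr < 0) | (arr > np.pi + 1e-12)).any():
                raise ValueError(f"{name} values must lie in [0, pi]")
        object.__setattr__(self, "empirical_msd", emp)
        object.__setattr__(self, "null_msd", nul)


@dataclass(frozen=True)
class ComparisonResult:
    """Mann-Whitney comparison of two trajectories' msd distributions."""

    p_value: float
    median_a: float
    median_b: float

    @property
    def median_difference(self) -> float:
        """median(a) - median(b); positive means a is less directional."""
        return self.median_a - self.median_b


@dataclass(frozen=True)
class BranchScanResult:
    """Directionality as a function of the path's starting pseudotime."""

    offsets: np.ndarray
    msd_distributions: list
    p_values: np.ndarray
    skipped_offsets: np.ndarray
    adjusted_p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        if off.size and not (np.diff(off) > 0).all():
            raise ValueError("offsets must be strictly increasing")
        if len(self.msd_distributions) != off.size or len(self.p_values) != off.size:
            raise ValueError("one msd distribution and p-value per retained offset")
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "p_values", np.asarray(self.p_values, dtype=float))
        object.__setattr__(
            self, "skipped_offsets", np.asarray(self.skipped_offsets, dtype=float)
        )

    @property
    def mean_msd(self) -> np.ndarray:
        return np.array([float(np.mean(d)) for d in self.msd_distributions])

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p_values, np.finfo(float).tiny))


def permute_columns(path: Path, rng: np.random.Generator) -> Path:
    """Randomised counterpart of a path: permute each column independently.

    Every coordinate column is shuffled across the path's rows on its
    own, so each column's multiset of values is preserved exactly while
    any consistent direction of motion is destroyed.
    """
    pts = path.points.copy()
    for j in range(pts.shape[1]):
        pts[:, j] = pts[rng.permutation(pts.shape[0]), j]
    return Path(points=pts, window_index=path.window_index.copy())


def _minimized_msd(path: Path, max_steps: int) -> DirectionResult:
    return find_center(unit_vectors(path), max_steps=max_steps)


def directionality_test(
    embedding: Embedding,
    trajectory,
    config: SamplingConfig,
    rng: np.random.Generator,
    *,
    start: float = 0.0,
    alternative: str = "two-sided",
    max_steps: int = 1000,
) -> TrajectoryStats:
    """Test a trajectory's directionality against its permutation null.

    For each of ``config.n_paths`` resampled paths the minimised msd is
    computed for the path and for one column-permuted copy of it; the
    paired differences feed a Wilcoxon signed-rank test (two-sided by
    default).  Zero differences are dropped before the statistic, in
    standard Wilcoxon fashion, and counted.  A representative center is
    fitted to the per-path centers.
    """
    if config.n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    mask = _trajectory_mask(embedding, trajectory)
    norm_pt = normalize_pseudotime(embedding.pseudotime[mask])

    emp = np.empty(config.n_paths)
    nul = np.empty(config.n_paths)
    centers = []
    for i in range(config.n_paths):
        path = sample_path(embedding, trajectory, config, rng, start=start, norm_pt=norm_pt)
        res = _minimized_msd(path, max_steps)
        emp[i] = res.msd
        centers.append(res.center)
        nul[i] = _minimized_msd(permute_columns(path, rng), max_steps).msd

    diffs = emp - nul
    n_zero = int(np.sum(diffs == 0.0))
    if n_zero == config.n_paths:
        warnings.warn(
            "all paired msd differences are zero; directionality is "
            "indistinguishable from the permutation null (p = 1)",
            stacklevel=2,
        )
        p = 1.0
    else:
        p = float(
            sps.wilcoxon(emp, nul, zero_method="wilcox", alternative=alternative).pvalue
        )

    per_path_centers = np.vstack(centers)
    rep = representative_center(per_path_centers, max_steps=max_steps)
    return TrajectoryStats(
        trajectory=trajectory,
        n_paths=config.n_paths,
        empirical_msd=emp,
        null_msd=nul,
        p_vs_random=p,
        per_path_centers=per_path_centers,
        representative=rep,
        n_zero_differences=n_zero,
    )


def compare_trajectories(
    a: TrajectoryStats, b: TrajectoryStats, *, alternative: str = "two-sided"
) -> ComparisonResult:
    """Mann-Whitney U test between two trajectories' empirical msd.

    Identical constant distributions (all ties) yield ``p = 1``.
    """
    if a.empirical_msd.size == 0 or b.empirical_msd.size == 0:
        raise ValueError("both msd distributions must be nonempty")
    xa, xb = a.empirical_msd, b.empirical_msd
    if np.ptp(np.concatenate([xa, xb])) == 0.0:
        p = 1.0  # all values tied; no evidence either way
    else:
        p = float(sps.mannwhitneyu(xa, xb, alternative=alternative).pvalue)
    return ComparisonResult(
        p_value=p, median_a=float(np.median(xa)), median_b=float(np.median(xb))
    )


def branch_point_scan(
    embedding: Embedding,
    trajectory,
    config: SamplingConfig,
    rng: np.random.Generator,
    *,
    offsets: np.ndarray | None = None,
    alternative: str = "two-sided",
    adjust: str = "none",
) -> BranchScanResult:
    """Repeat the directionality test from successively later start points.

    For each offset ``t0`` the trajectory is restricted to cells with
    normalised pseudotime ``>= t0`` — the original [0, 100] normalisation
    is kept, never recomputed on the suffix, so an offset means the same
    pseudotime throughout the scan — and the remaining range is
    re-windowed with the configured window width.  Offsets leaving fewer
    than ``config.min_points`` non-empty windows are skipped and
    recorded.

    ``adjust="bh"`` additionally reports Benjamini-Hochberg adjusted
    p-values across the retained offsets; raw p-values are always kept.
    """
    if offsets is None:
        offsets = np.arange(0.0, 90.0, 5.0)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must be nonempty")
    if not (np.diff(offsets) > 0).all():
        raise ValueError("offsets must be strictly increasing")
    if (offsets < 0).any() or (offsets >= 100).any():
        raise ValueError("offsets must lie within [0, 100)")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")

    kept, dists, pvals, skipped = [], [], [], []
    for t0 in offsets:
        try:
            stats_t0 = directionality_test(
                embedding, trajectory, config, rng, start=float(t0), alternative=alternative
            )
        except SamplingError:
            skipped.append(t0)
            continue
        kept.append(t0)
        dists.append(stats_t0.empirical_msd)
        pvals.append(stats_t0.p_vs_random)
    if not kept:
        raise SamplingError(
            f"trajectory {trajectory!r}: every offset left fewer than "
            f"{config.min_points} non-empty windows"
        )
    adj = sps.false_discovery_control(pvals, method="bh") if adjust == "bh" else None
    return BranchScanResult(
        offsets=np.array(kept),
        msd_distributions=dists,
        p_values=np.array(pvals),
        skipped_offsets=np.array(skipped),
        adjusted_p_values=None if adj is None else np.asarray(adj, dtype=float),
    )
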