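"""Reading embeddings/loadings from delimited text and writing results.

Embeddings arrive as one row per cell with a header: a pseudotime
column, a trajectory label column, and two or more numeric coordinate
columns (principal-component scores or any reduced-space coordinates).
Comma- or tab-separation is auto-detected from the file extension.
Results go out as a JSON summary (p-values, representative center,
config echo including the seed) plus plain CSV tables suitable for
external plotting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from . import __version__
from .randomization import BranchScanResult, TrajectoryStats
from .sampling import Embedding
from .scoring import LoadingsMatrix

__all__ = [
    "AnalysisConfig",
    "EmbeddingFormatError",
    "read_embedding",
    "write_embedding",
    "read_loadings",
    "write_scores",
    "write_results",
    "vectors_to_lonlat",
]

_TAB_EXTENSIONS = {".tsv", ".tab", ".txt"}


class EmbeddingFormatError(ValueError):
    """Raised when an input table does not satisfy the embedding contract."""


@dataclass
class AnalysisConfig:
    """Run configuration echoed into every output for reproducibility."""

    embedding_path: str = ""
    pseudotime_column: str = "pseudotime"
    trajectory_column: str = "trajectory"
    coordinate_columns: list[str] = field(default_factory=list)
    dims: int = 3
    n_paths: int = 1000
    window_width: float = 10.0
    window_step: float | None = None
    min_points: int = 3
    offsets: list[float] = field(default_factory=list)
    seed: int | None = None
    alternative: str = "two-sided"
    bh_adjust: bool = False
    output_dir: str = ""


def _sep_for(path: FsPath) -> str:
    return "\t" if path.suffix.lower() in _TAB_EXTENSIONS else ","


def read_embedding(
    path: str | FsPath,
    *,
    pseudotime_column: str = "pseudotime",
    trajectory_column: str = "trajectory",
    coordinate_columns: list[str] | None = None,
    cell_id_column: str | None = None,
) -> Embedding:
    """Read a cell embedding from delimited text.

    When ``coordinate_columns`` is omitted, every numeric column other
    than the pseudotime (and cell-id) column is used, in file order.
    Rows with missing pseudotime or coordinates are dropped with a
    warning listing their (1-based, data) row numbers; a non-numeric
    value in a coordinate column is an error naming the row.
    """
    path = FsPath(path)
    df = pd.read_csv(path, sep=_sep_for(path))

    required = [pseudotime_column, trajectory_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EmbeddingFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    if cell_id_column is None and "cell_id" in df.columns:
        cell_id_column = "cell_id"
    if cell_id_column is not None:
        if cell_id_column not in df.columns:
            raise EmbeddingFormatError(f"{path.name}: no column {cell_id_column!r}")
        ids = df[cell_id_column].astype(str).to_numpy()
    else:
        ids = np.array([f"cell_{i}" for i in range(len(df))])

    if coordinate_columns is None:
        reserved = {pseudotime_column, trajectory_column, cell_id_column}
        coordinate_columns = []
        for c in df.columns:
            if c in reserved:
                continue
            if pd.api.types.is_numeric_dtype(df[c]):
                coordinate_columns.append(c)
                continue
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.notna().any():
                # mostly-numeric column with stray text: a data error,
                # not a metadata column
                coordinate_columns.append(c)
    else:
        missing = [c for c in coordinate_columns if c not in df.columns]
        if missing:
            raise EmbeddingFormatError(
                f"{path.name}: missing coordinate column(s): {', '.join(missing)}"
            )
    if len(coordinate_columns) < 2:
        raise EmbeddingFormatError(
            f"{path.name}: need at least 2 coordinate columns, "
            f"found {len(coordinate_columns)}"
        )

    for col in coordinate_columns + [pseudotime_column]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise EmbeddingFormatError(
                f"{path.name}: non-numeric value {df[col].iloc[row - 1]!r} "
                f"in column {col!r} at data row {row}"
            )
        df[col] = coerced

    complete = df[coordinate_columns + [pseudotime_column]].notna().all(axis=1)
    if not complete.all():
        dropped = (np.flatnonzero(~complete.to_numpy()) + 1).tolist()
        warnings.warn(
            f"{path.name}: dropped {len(dropped)} row(s) with missing "
            f"pseudotime or coordinates (data rows {dropped})",
            stacklevel=2,
        )
        df = df[complete]
        ids = ids[complete.to_numpy()]

    return Embedding(
        cell_ids=ids,
        coords=df[coordinate_columns].to_numpy(dtype=float),
        pseudotime=df[pseudotime_column].to_numpy(dtype=float),
        trajectory=df[trajectory_column].to_numpy(),
    )


def write_embedding(embedding: Embedding, path: str | FsPath) -> None:
    """Write an embedding as delimited text (inverse of read_embedding)."""
    path = FsPath(path)
    cols = {f"PC{j + 1}": embedding.coords[:, j] for j in range(embedding.dim)}
    df = pd.DataFrame(
        {
            "cell_id": embedding.cell_ids,
            **cols,
            "pseudotime": embedding.pseudotime,
            "trajectory": embedding.trajectory,
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_loadings(path: str | FsPath, *, gene_id_column: str | None = None) -> LoadingsMatrix:
    """Read a genes x dimensions loadings table (header row of dimension names)."""
    path = FsPath(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if gene_id_column is None:
        gene_id_column = df.columns[0]
    if gene_id_column not in df.columns:
        raise EmbeddingFormatError(f"{path.name}: no column {gene_id_column!r}")
    ids = df[gene_id_column].astype(str).to_numpy()
    mat = df.drop(columns=[gene_id_column])
    non_numeric = [c for c in mat.columns if not pd.api.types.is_numeric_dtype(mat[c])]
    if non_numeric:
        raise EmbeddingFormatError(
            f"{path.name}: non-numeric loading column(s): {', '.join(non_numeric)}"
        )
    return LoadingsMatrix(gene_ids=ids, loadings=mat.to_numpy(dtype=float))


def write_scores(scores: pd.Series, path: str | FsPath) -> None:
    """Write gene scores as two-column delimited text, sorted descending."""
    path = FsPath(path)
    scores.rename("score").to_csv(path, sep=_sep_for(path), header=True)


def vectors_to_lonlat(vectors: np.ndarray) -> pd.DataFrame:
    """Longitude/latitude (degrees) of 3-D unit vectors, for sphere plots."""
    vecs = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vecs.shape[1] != 3:
        raise ValueError("longitude/latitude export requires 3-D vectors")
    lon = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0]))
    lat = np.degrees(np.arcsin(np.clip(vecs[:, 2], -1.0, 1.0)))
    return pd.DataFrame({"longitude": lon, "latitude": lat})


def _stats_summary(stats: TrajectoryStats) -> dict:
    return {
        "trajectory": str(stats.trajectory),
        "n_paths": stats.n_paths,
        "p_vs_random": stats.p_vs_random,
        "n_zero_differences": stats.n_zero_differences,
        "median_empirical_msd": float(np.median(stats.empirical_msd)),
        "median_null_msd": float(np.median(stats.null_msd)),
        "representative_center": [float(x) for x in stats.representative.center],
        "representative_msd": stats.representative.msd,
        "representative_converged": stats.representative.converged,
    }


def write_results(
    output_dir: str | FsPath,
    *,
    stats: TrajectoryStats | list[TrajectoryStats] | None = None,
    scan: BranchScanResult | None = None,
    scores: pd.Series | None = None,
    config: AnalysisConfig | None = None,
    extra: dict | None = None,
) -> FsPath:
    """Write a summary JSON plus CSV tables into ``output_dir``.

    Emits ``summary.json`` always; ``path_msd_<trajectory>.csv`` (one row
    per sampled path, empirical and null msd), ``centers_lonlat_<t>.csv``
    for 3-D runs, ``branch_scan.csv`` and ``gene_scores.csv`` when the
    corresponding results are given.  Returns the summary path.
    """
    out = FsPath(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"package_version": __version__}
    if config is not None:
        summary["config"] = asdict(config)
    if extra:
        summary.update(extra)

    stats_list = [stats] if isinstance(stats, TrajectoryStats) else (stats or [])
    if stats_list:
        summary["trajectories"] = [_stats_summary(s) for s in stats_list]
        for s in stats_list:
            tag = str(s.trajectory)
            pd.DataFrame(
                {
                    "path_index": np.arange(s.n_paths),
                    "empirical_msd": s.empirical_msd,
                    "null_msd": s.null_msd,
                }
            ).to_csv(out / f"path_msd_{tag}.csv", index=False)
            if s.per_path_centers.shape[1] == 3:
                ll = vectors_to_lonlat(s.per_path_centers)
                ll.insert(0, "path_index", np.arange(s.n_paths))
                ll.to_csv(out / f"centers_lonlat_{tag}.csv", index=False)

    if scan is not None:
        summary["branch_scan"] = {
            "offsets": [float(x) for x in scan.offsets],
            "p_values": [float(x) for x in scan.p_values],
            "skipped_offsets": [float(x) for x in scan.skipped_offsets],
        }
        rows = pd.DataFrame(
            {
                "offset": scan.offsets,
                "mean_msd": scan.mean_msd,
                "p_value": scan.p_values,
                "neg_log10_p": scan.neg_log10_p,
            }
        )
        if scan.adjusted_p_values is not None:
            rows["p_adjusted_bh"] = scan.adjusted_p_values
        rows.to_csv(out / "branch_scan.csv", index=False)

    if scores is not None:
        write_scores(scores, out / "gene_scores.csv")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary_path
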