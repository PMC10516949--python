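"""Score genes by alignment with a trajectory's consensus direction.

Given the gene x dimension loadings matrix ``F`` of the reduced-space
decomposition that produced the embedding, and a consensus direction
``c`` (a unit vector in that space), each gene's association with the
direction of motion is the dot product of its loading row with ``c``.
The sign is meaningful: positive scores mark genes whose expression
increases along the direction, negative scores genes that decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import _check_unit

__all__ = ["LoadingsMatrix", "score_genes"]


@dataclass(frozen=True)
class LoadingsMatrix:
    """Gene loadings on the reduced dimensions (genes x D)."""

    gene_ids: np.ndarray
    loadings: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.gene_ids)
        mat = np.asarray(self.loadings, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != len(ids):
            raise ValueError("loadings must be an (n_genes, D) array")
        if len(np.unique(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = list(dupes.index[dupes > 1][:5])
            raise ValueError(f"duplicate gene_ids: {dupes}")
        if not np.isfinite(mat).all():
            raise ValueError("loadings contain non-finite values")
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "loadings", mat)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def dim(self) -> int:
        return self.loadings.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LoadingsMatrix":
        return cls(gene_ids=df.index.to_numpy(), loadings=df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"dim{j + 1}" for j in range(self.dim)]
        return pd.DataFrame(self.loadings, index=pd.Index(self.gene_ids, name="gene_id"), columns=cols)


def score_genes(
    loadings: LoadingsMatrix, center: np.ndarray, *, normalize: bool = False
) -> pd.Series:
    """Per-gene alignment scores ``F . c``, sorted descending.

    Parameters
    ----------
    loadings
        Gene x dimension loadings; the dimension must equal the length
        of ``center`` exactly (a mismatch is an error, never silently
        truncated or padded).
    center
        Unit-norm consensus direction in the same reduced space.
    normalize
        When True, loading rows are scaled to unit norm first, so scores
        become cosines of the angle between gene and direction.  The
        default reports raw dot products.

    Returns
    -------
    pandas.Series
        Scores indexed by gene id, sorted descending.  Zero-norm rows
        under ``normalize=True`` score 0.
    """
    center = _check_unit(np.asarray(center, dtype=float), "center")
    if loadings.dim != center.size:
        raise ValueError(
            f"dimension mismatch: loadings have D={loadings.dim}, "
            f"center has D={center.size}"
        )
    mat = loadings.loadings
    if normalize:
        norms = np.linalg.norm(mat, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        mat = mat / safe[:, None]
    scores = mat @ center
    out = pd.Series(scores, index=pd.Index(loadings.gene_ids, name="gene_id"), name="score")
    return out.sort_values(ascending=False, kind="mergesort")
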