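"""Cover decoding, matrix transformations and the Bray-Curtis dissimilarity.

The analysis matrix handed to clustering is built as: cover codes -> percentage
midpoints -> square root -> Hellinger (row-profile square root).  Euclidean
distance on the Hellinger-transformed matrix equals the Hellinger distance on
the untransformed one, which is why K-means can run in plain Euclidean space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import CommunityMatrix, CoverScale, DEFAULT_SCALE

__all__ = ["cover_to_percent", "sqrt_transform", "hellinger", "bray_curtis"]


def cover_to_percent(matrix: CommunityMatrix, scale: CoverScale | None = None) -> CommunityMatrix:
    """Replace each ordinal cover code by its percentage midpoint."""
    if matrix.kind != "codes":
        raise ValueError(f"expected a code matrix, got kind={matrix.kind!r}")
    scale = scale or matrix.scale or DEFAULT_SCALE
    lookup = {code: pct for code, pct in zip(scale.codes, scale.midpoints)}
    lookup[""] = 0.0

    def decode(v: object) -> float:
        try:
            return lookup[str(v)]
        except KeyError:
            raise KeyError(f"unknown cover code {v!r}") from None

    out = matrix.data.map(decode).astype(float)
    return CommunityMatrix(out, kind="percent", scale=scale)


def sqrt_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Element-wise square root of percentage covers."""
    if matrix.kind != "percent":
        raise ValueError(f"expected a percent matrix, got kind={matrix.kind!r}")
    arr = matrix.data.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative cover value")
    out = pd.DataFrame(np.sqrt(arr), index=matrix.data.index, columns=matrix.data.columns)
    return CommunityMatrix(out, kind="transformed", scale=matrix.scale)


def hellinger(matrix: CommunityMatrix) -> CommunityMatrix:
    """Hellinger transformation: sqrt of the row profile, unit row norm."""
    arr = matrix.data.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative cover value")
    row_sums = arr.sum(axis=1)
    empty = np.flatnonzero(row_sums <= 0)
    if empty.size:
        names = [matrix.data.index[i] for i in empty]
        raise ValueError(f"empty plot row(s): {names}")
    out = np.sqrt(arr / row_sums[:, None])
    out = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return CommunityMatrix(out, kind="transformed", scale=matrix.scale)


def bray_curtis(matrix: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Plot x plot Bray-Curtis dissimilarity, D(i,j) = sum|x-y| / sum(x+y)."""
    data = matrix.data if isinstance(matrix, CommunityMatrix) else matrix
    arr = data.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("Bray-Curtis requires a non-negative matrix")
    zero_rows = np.flatnonzero(arr.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        names = [data.index[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between all-zero plots: {names}")
    dm = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dm, index=data.index, columns=data.index)
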