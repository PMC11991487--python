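"""Plot-level trait summaries: flowering-onset spectra and mean indicator values.

Flowering onset is a single month per species (raw months 2..9; February is
merged into March and September into August, giving the working range 3..8).
Spectra and indicator means are unweighted by cover: every recorded species
with a known trait value counts once.  Cover-weighted variants are available
behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import CommunityMatrix, EIV_COLUMNS

log = logging.getLogger(__name__)

MONTHS = (3, 4, 5, 6, 7, 8)
MONTH_NAMES = {3: "March", 4: "April", 5: "May", 6: "June", 7: "July", 8: "August"}

__all__ = [
    "MONTHS",
    "MONTH_NAMES",
    "recode_onset",
    "flowering_spectrum",
    "mean_eiv",
]


def recode_onset(month_raw: int | pd.Series) -> int | pd.Series:
    """Merge February into March and September into August (2->3, 9->8)."""
    if isinstance(month_raw, pd.Series):
        vals = month_raw.dropna()
        if ((vals < 2) | (vals > 9)).any():
            raise ValueError("raw onset month outside 2..9")
        return month_raw.clip(lower=3, upper=8)
    m = int(month_raw)
    if not 2 <= m <= 9:
        raise ValueError(f"raw onset month {m} outside 2..9")
    return min(max(m, 3), 8)


def flowering_spectrum(
    matrix: CommunityMatrix,
    traits: pd.DataFrame,
    cover_weighted: bool = False,
) -> pd.DataFrame:
    """Per-plot percentage of species starting to flower in each month.

    Species without a known onset are excluded from numerator and denominator.
    Returns a plot-indexed frame with one column per month (named by month) and
    an ``n_onset`` column with the per-plot count of species entering the
    denominator; a plot with no onset-carrying species gets an all-zero row.
    """
    onset = recode_onset(traits["onset"].reindex(matrix.species))
    known = onset.notna()
    if cover_weighted:
        if matrix.kind == "codes":
            raise ValueError("cover weighting requires a percent matrix")
        weights = matrix.data.to_numpy(dtype=float)
    else:
        weights = matrix.presence().to_numpy(dtype=float)
    weights = weights * known.to_numpy(dtype=float)[None, :]
    denom = weights.sum(axis=1)
    dropped = int((~known & (matrix.presence().sum(axis=0) > 0)).sum())
    if dropped:
        log.info("%d species without onset excluded from spectra", dropped)
    out = pd.DataFrame(index=matrix.data.index)
    for m in MONTHS:
        mask = (onset == m).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[MONTH_NAMES[m]] = np.where(denom > 0, 100.0 * (weights * mask).sum(axis=1) / denom, 0.0)
    out["n_onset"] = matrix.presence().to_numpy().astype(float) @ known.to_numpy(dtype=float)
    if (out["n_onset"] == 0).any():
        log.warning("plots with no onset-carrying species have zero spectra")
    return out


def mean_eiv(
    matrix: CommunityMatrix,
    traits: pd.DataFrame,
    indicators: tuple[str, ...] = EIV_COLUMNS,
    cover_weighted: bool = False,
) -> pd.DataFrame:
    """Per-plot mean ecological indicator values, unweighted by default.

    Species missing a given indicator are excluded for that indicator only.
    A plot with no scored species for an indicator gets NaN (never zero).
    Columns ``n_<ind>`` carry the species count behind each mean.
    """
    if cover_weighted and matrix.kind == "codes":
        raise ValueError("cover weighting requires a percent matrix")
    base = (
        matrix.data.to_numpy(dtype=float)
        if cover_weighted
        else matrix.presence().to_numpy(dtype=float)
    )
    out = pd.DataFrame(index=matrix.data.index)
    for ind in indicators:
        vals = traits[ind].reindex(matrix.species)
        known = vals.notna().to_numpy(dtype=float)
        w = base * known[None, :]
        denom = w.sum(axis=1)
        num = w @ np.nan_to_num(vals.to_numpy(dtype=float))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[ind] = np.where(denom > 0, num / denom, np.nan)
        out[f"n_{ind}"] = (matrix.presence().to_numpy() * (known[None, :] > 0)).sum(axis=1)
    return out
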