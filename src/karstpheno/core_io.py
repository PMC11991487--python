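"""Data model and CSV readers/writers for relevé tables, plot metadata and traits.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame` with
validated invariants.  All files are plain CSV with a header row; species and
plot identifiers are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverScale",
    "DEFAULT_SCALE",
    "CommunityMatrix",
    "SynopticTable",
    "read_community",
    "write_community",
    "read_plot_meta",
    "write_plot_meta",
    "read_traits",
    "write_traits",
    "write_synoptic",
    "read_synoptic",
]

EIV_COLUMNS = ("L", "T", "M", "N", "R")
META_COLUMNS = ("transect", "position", "depth", "svf", "bare_rock")


class SchemaError(ValueError):
    """A table violates the documented column/value contract."""


@dataclass(frozen=True)
class CoverScale:
    """Ordinal cover-abundance scale mapping codes to percentage midpoints.

    Parameters
    ----------
    codes
        Ordered code strings, rarest first (e.g. ``("r", "+", "1", ..., "5")``).
    midpoints
        Percentage midpoint for each code, strictly increasing, in [0, 100].
    """

    codes: tuple[str, ...]
    midpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("cover codes must be unique")
        if len(self.codes) != len(self.midpoints):
            raise ValueError("codes and midpoints must have equal length")
        mids = np.asarray(self.midpoints, dtype=float)
        if np.any(mids < 0) or np.any(mids > 100):
            raise ValueError("midpoints must lie in [0, 100]")
        if np.any(np.diff(mids) <= 0):
            raise ValueError("midpoints must be strictly increasing")

    def to_percent(self, code: str) -> float:
        try:
            return float(self.midpoints[self.codes.index(str(code))])
        except ValueError:
            raise KeyError(f"unknown cover code {code!r}") from None

    def percent_to_code(self, percent: float) -> str:
        """Nearest-boundary discretization of a percentage back to a code.

        Bin boundaries are the geometric midpoints between consecutive scale
        midpoints; values below the first boundary map to the first code.
        """
        if percent < 0:
            raise ValueError("cover percentage must be non-negative")
        mids = np.asarray(self.midpoints)
        bounds = (mids[:-1] + mids[1:]) / 2.0
        return self.codes[int(np.searchsorted(bounds, percent))]


#: Central European 7-degree scale with the conventional percentage midpoints.
DEFAULT_SCALE = CoverScale(
    codes=("r", "+", "1", "2", "3", "4", "5"),
    midpoints=(0.1, 0.5, 2.5, 15.0, 37.5, 62.5, 87.5),
)


@dataclass
class CommunityMatrix:
    """Plot x species table of cover values.

    ``kind`` declares the cell semantics: ``"codes"`` (ordinal cover codes,
    stored as strings with ``""`` for absence), ``"percent"`` (cover
    percentages, 0 = absent) or ``"transformed"`` (output of a matrix
    transformation; no range constraint beyond non-negativity not enforced).
    """

    data: pd.DataFrame
    kind: str = "percent"
    scale: CoverScale | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("codes", "percent", "transformed"):
            raise ValueError(f"unknown value kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise SchemaError("duplicate plot ids")
        if self.data.columns.has_duplicates:
            raise SchemaError("duplicate species ids")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "plot"
        self.data.columns.name = "species"
        if self.kind == "codes":
            scale = self.scale if self.scale is not None else DEFAULT_SCALE
            vals = self.data.to_numpy(dtype=object)
            known = set(scale.codes) | {""}
            bad = {str(v) for v in vals.ravel() if str(v) not in known}
            if bad:
                raise SchemaError(f"unknown cover code(s): {sorted(bad)}")
        else:
            arr = self.data.to_numpy(dtype=float)
            if np.any(arr < 0):
                raise SchemaError("negative cover values")
            if self.kind == "percent" and np.any(arr > 100):
                raise SchemaError("cover percentages above 100")
        empty = self.empty_plots()
        if empty:
            raise SchemaError(f"plot(s) with no species records: {empty}")

    def empty_plots(self) -> list[str]:
        if self.kind == "codes":
            occ = self.data.to_numpy(dtype=object) != ""
        else:
            occ = self.data.to_numpy(dtype=float) > 0
        return [str(p) for p, any_ in zip(self.data.index, occ.any(axis=1)) if not any_]

    @property
    def plots(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean plot x species occurrence table."""
        if self.kind == "codes":
            return self.data != ""
        return self.data > 0


def read_community(
    path: str | Path,
    format: str = "long",
    scale: CoverScale | None = None,
    kind: str = "codes",
) -> CommunityMatrix:
    """Read a relevé table from CSV.

    ``format="long"`` expects columns ``plot, species, value``; ``"wide"``
    expects a plot-indexed matrix with species columns.  ``kind`` declares how
    cell values are to be interpreted (``codes`` or ``percent``).
    """
    path = Path(path)
    if format == "long":
        df = pd.read_csv(path, dtype=str)
        required = {"plot", "species", "value"}
        if not required.issubset(df.columns):
            raise SchemaError(f"long format requires columns {sorted(required)}")
        dup = df.duplicated(subset=["plot", "species"])
        if dup.any():
            cells = df.loc[dup, ["plot", "species"]].to_records(index=False).tolist()
            raise SchemaError(f"duplicate (plot, species) cell(s): {cells}")
        wide = df.pivot(index="plot", columns="species", values="value")
        if kind == "codes":
            wide = wide.fillna("")
        else:
            wide = wide.astype(float).fillna(0.0)
        # preserve first-appearance order of plots and species
        wide = wide.reindex(index=pd.unique(df["plot"]), columns=pd.unique(df["species"]))
    elif format == "wide":
        wide = pd.read_csv(path, index_col=0, dtype=str if kind == "codes" else None)
        if kind == "codes":
            wide = wide.fillna("")
        else:
            wide = wide.astype(float).fillna(0.0)
    else:
        raise ValueError(f"unknown format {format!r}")
    wide.index.name = "plot"
    wide.columns.name = "species"
    return CommunityMatrix(wide, kind=kind, scale=scale)


def write_community(matrix: CommunityMatrix, path: str | Path) -> None:
    """Write a relevé table as a wide CSV (plots x species)."""
    matrix.data.to_csv(path)


def read_plot_meta(path: str | Path, community: CommunityMatrix | None = None) -> pd.DataFrame:
    """Read per-plot topography: transect, position (m), depth (m), SVF, bare rock (%).

    Returns a plot-indexed DataFrame.  SVF outside [0, 1], negative depth and
    bare rock outside [0, 100] are rejected, never clipped.  If ``community``
    is given, plots present there but missing here are reported as an error.
    """
    df = pd.read_csv(path, dtype={"plot": str, "transect": str})
    required = {"plot", *META_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"plot metadata missing column(s): {sorted(missing)}")
    if df["plot"].duplicated().any():
        raise SchemaError("duplicate plot records in metadata")
    df = df.set_index("plot")
    return validate_plot_meta(df, community)


def validate_plot_meta(df: pd.DataFrame, community: CommunityMatrix | None = None) -> pd.DataFrame:
    for col in ("position", "depth", "svf", "bare_rock"):
        df[col] = df[col].astype(float)
    if (df["depth"] < 0).any():
        raise SchemaError("negative plot depth")
    if ((df["svf"] < 0) | (df["svf"] > 1)).any():
        raise SchemaError("SVF outside [0, 1]")
    if ((df["bare_rock"] < 0) | (df["bare_rock"] > 100)).any():
        raise SchemaError("bare rock percentage outside [0, 100]")
    if community is not None:
        missing = sorted(set(community.plots) - set(df.index))
        if missing:
            raise SchemaError(f"plots missing from metadata: {missing}")
    return df


def write_plot_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index_label="plot")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read species traits: flowering-onset month plus five indicator values.

    Expects columns ``species, onset, L, T, M, N, R``; indicator values may be
    empty (missing), onset may be empty, but a present onset must be a raw
    month in 2..9 (recoding to 3..8 is a separate, explicit step).
    """
    df = pd.read_csv(path, dtype={"species": str})
    required = {"species", "onset", *EIV_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"trait table missing column(s): {sorted(missing)}")
    if df["species"].duplicated().any():
        raise SchemaError("duplicate species in trait table")
    df = df.set_index("species")
    for col in ("onset", *EIV_COLUMNS):
        df[col] = pd.to_numeric(df[col], errors="raise")
    onset = df["onset"].dropna()
    bad = onset[(onset < 2) | (onset > 9) | (onset != onset.round())]
    if not bad.empty:
        raise SchemaError(f"raw onset month outside 2..9 for: {sorted(bad.index)}")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index_label="species")


@dataclass
class SynopticTable:
    """Species x group summary: % presence, fidelity (phi x 100), Fisher p, flags.

    All four frames share the same species index (in presentation order) and
    group columns; ``group_sizes`` maps group label to plot count.
    """

    presence_pct: pd.DataFrame
    phi100: pd.DataFrame
    fisher_p: pd.DataFrame
    diagnostic: pd.DataFrame
    group_sizes: pd.Series
    phi_threshold: float = 0.20
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for frame in (self.phi100, self.fisher_p, self.diagnostic):
            if not frame.index.equals(self.presence_pct.index):
                raise ValueError("synoptic frames must share a species index")
            if list(frame.columns) != list(self.presence_pct.columns):
                raise ValueError("synoptic frames must share group columns")
        if ((self.presence_pct < 0) | (self.presence_pct > 100)).any().any():
            raise ValueError("presence percentages outside [0, 100]")
        flagged = self.diagnostic.to_numpy(dtype=bool)
        # 0.06 slack admits phi values rounded to 1 decimal on a write/read cycle
        ok = (self.phi100.to_numpy() > 100 * self.phi_threshold - 0.06) & (
            self.fisher_p.to_numpy() < self.alpha
        )
        if np.any(flagged & ~ok):
            raise ValueError("diagnostic flag set where phi/p thresholds not met")


def write_synoptic(table: SynopticTable, path: str | Path) -> None:
    """Write a synoptic table as CSV: per group, presence %, phi x 100 (1 dp), p, flag."""
    groups = list(table.presence_pct.columns)
    out = pd.DataFrame(index=table.presence_pct.index)
    for g in groups:
        out[f"pres_{g}"] = table.presence_pct[g].round(0).astype(int)
        out[f"phi_{g}"] = table.phi100[g].round(1)
        out[f"p_{g}"] = table.fisher_p[g]
        out[f"diag_{g}"] = table.diagnostic[g].astype(int)
    sizes = pd.DataFrame(
        {f"pres_{g}": [int(table.group_sizes[g])] for g in groups}, index=["#n_plots"]
    )
    pd.concat([sizes, out]).to_csv(path, index_label="species")


def read_synoptic(path: str | Path) -> SynopticTable:
    raw = pd.read_csv(path, index_col="species")
    sizes_row = raw.loc["#n_plots"]
    body = raw.drop(index="#n_plots")
    raw_groups = [c[len("pres_") :] for c in raw.columns if c.startswith("pres_")]
    # numeric group labels round-trip as ints
    groups = [int(g) if g.lstrip("-").isdigit() else g for g in raw_groups]
    presence = pd.DataFrame({g: body[f"pres_{r}"].astype(float) for g, r in zip(groups, raw_groups)})
    phi = pd.DataFrame({g: body[f"phi_{r}"].astype(float) for g, r in zip(groups, raw_groups)})
    pval = pd.DataFrame({g: body[f"p_{r}"].astype(float) for g, r in zip(groups, raw_groups)})
    diag = pd.DataFrame({g: body[f"diag_{r}"].astype(float) > 0 for g, r in zip(groups, raw_groups)})
    sizes = pd.Series({g: int(sizes_row[f"pres_{r}"]) for g, r in zip(groups, raw_groups)})
    return SynopticTable(presence, phi, pval, diag, sizes)
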