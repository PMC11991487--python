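"""Correspondence-analysis ordination and the three-tier significance machinery.

Implements:

* plain correspondence analysis (CA) via SVD of the chi-square standardized
  residual matrix;
* detrended correspondence analysis (DCA): axis 1 is the CA axis, higher axes
  are extracted by reciprocal averaging with detrending-by-segments against
  every lower axis inside each iteration;
* passive ("envfit"-style) projection of plot-level variables onto the first
  two axes, with parametric, permutation and modified-permutation p-values;
* Spearman correlations between flowering spectra / indicator means and
  topography, with the same three significance tiers;
* single-constraint canonical correspondence analysis (CCA) reporting the
  percentage of total variance (inertia) explained, the pseudo-F and a Monte
  Carlo p-value from unrestricted permutation of the constraint.

The modified permutation test addresses the circularity of community means of
species attributes (indicator values, onset months): the attribute values are
permuted *among species*, the plot-level means are rebuilt from the community
matrix, and the statistic is recomputed, so the null respects the dependence
of plot means on species composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "CCAResult",
    "correspondence_analysis",
    "dca",
    "envfit_vectors",
    "spearman_table",
    "modified_permutation_test",
    "cca_ptv",
    "spearman_statistic",
    "envfit_r_statistic",
]


@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame  # plots x axes
    species_scores: pd.DataFrame  # species x axes
    eigenvalues: np.ndarray
    method: str = "CA"
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev <= 0):
            raise ValueError("eigenvalues must be positive")
        # detrended axes are kept in extraction order; only CA guarantees monotone eigenvalues
        if self.method == "CA" and np.any(np.diff(ev) > 1e-10):
            raise ValueError("CA eigenvalues must be non-increasing")


@dataclass
class CCAResult:
    variable: str
    ptv: float  # % of total inertia explained
    f_stat: float
    p_value: float
    n_perm: int
    constrained_inertia: float
    total_inertia: float


def _chi_square_residuals(arr: np.ndarray, index, columns):
    if np.any(arr < 0):
        raise ValueError("ordination requires a non-negative matrix")
    zero_rows = [str(index[i]) for i in np.flatnonzero(arr.sum(axis=1) == 0)]
    zero_cols = [str(columns[j]) for j in np.flatnonzero(arr.sum(axis=0) == 0)]
    if zero_rows or zero_cols:
        raise ValueError(f"zero row(s)/column(s): plots {zero_rows}, species {zero_cols}")
    P = arr / arr.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return P, r, c, S


def _fix_signs(site: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude site score positive."""
    for j in range(site.shape[1]):
        i = int(np.argmax(np.abs(site[:, j])))
        if site[i, j] < 0:
            site[:, j] = -site[:, j]
    return site


def correspondence_analysis(matrix, n_axes: int | None = None) -> OrdinationResult:
    """CA site/species scores and eigenvalues.

    Site scores are standard coordinates (weighted mean 0, weighted sum of
    squares 1 under the row masses); species scores are the abundance-weighted
    averages of the site scores, so each eigenvalue is the shrinkage per
    reciprocal-averaging cycle.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    arr = data.to_numpy(dtype=float)
    P, r, c, S = _chi_square_residuals(arr, data.index, data.columns)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > 1e-10
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if n_axes is not None:
        U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    site = _fix_signs(U / np.sqrt(r)[:, None])
    # species at the weighted average of their plots' site scores
    species = (P / c).T @ site * 1.0
    axes = [f"axis{i+1}" for i in range(len(s))]
    return OrdinationResult(
        site_scores=pd.DataFrame(site, index=data.index, columns=axes),
        species_scores=pd.DataFrame(species, index=data.columns, columns=axes),
        eigenvalues=s**2,
        method="CA",
        settings={},
    )


def _detrend_by_segments(x: np.ndarray, z: np.ndarray, w: np.ndarray, n_segments: int) -> np.ndarray:
    """Subtract from x its weighted mean within equal-width segments of z."""
    lo, hi = z.min(), z.max()
    width = (hi - lo) / n_segments or 1.0
    seg = np.clip(((z - lo) / width).astype(int), 0, n_segments - 1)
    out = x.copy()
    for sidx in np.unique(seg):
        m = seg == sidx
        out[m] -= np.average(x[m], weights=w[m])
    return out


def dca(
    matrix,
    n_segments: int = 26,
    rescaling: bool = True,
    n_axes: int = 4,
    detrend: bool = True,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> OrdinationResult:
    """Detrended correspondence analysis by reciprocal averaging.

    Axis 1 is the CA axis.  Each higher axis is iterated to convergence with
    detrending-by-segments against every lower axis inside the loop.  With
    ``detrend=False`` and ``rescaling=False`` the result is exactly CA.
    Rescaling standardizes each axis to SD units: scores are divided by the
    abundance-weighted root-mean-square spread of species scores about their
    plots' scores (a linear calibration of the axis to average species-turnover
    units; no nonlinear within-axis stretching is applied).
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    data = matrix.data if hasattr(matrix, "data") else matrix
    arr = data.to_numpy(dtype=float)
    P, r, c, S = _chi_square_residuals(arr, data.index, data.columns)
    ca_res = correspondence_analysis(data, n_axes=n_axes)
    # keep >= ~3 plots per segment so detrending cannot annihilate an axis
    n_segments = max(2, min(n_segments, len(r) // 3)) if detrend else n_segments
    settings = {"n_segments": n_segments, "rescaling": rescaling, "detrend": detrend}
    if not detrend:
        site = ca_res.site_scores.to_numpy().copy()
        eigs = list(ca_res.eigenvalues)
    else:
        n_axes = min(n_axes, ca_res.site_scores.shape[1])
        site = np.empty((len(r), n_axes))
        site[:, 0] = ca_res.site_scores.to_numpy()[:, 0]
        eigs = [float(ca_res.eigenvalues[0])]
        for ax in range(1, n_axes):
            x = ca_res.site_scores.to_numpy()[:, ax].copy()
            lam = np.nan
            for _ in range(max_iter):
                u = (P.T @ x) / c  # species score = weighted average of plots
                xnew = (P @ u) / r  # plot score = weighted average of species
                for lower in range(ax):
                    xnew = _detrend_by_segments(xnew, site[:, lower], r, n_segments)
                xnew -= np.average(xnew, weights=r)
                lam_new = float(np.sqrt(np.sum(r * xnew**2)))
                xnew /= lam_new
                if abs(lam_new - lam) < tol and abs(abs(np.sum(r * xnew * x)) - 1) < 1e-10:
                    x = xnew
                    lam = lam_new
                    break
                x, lam = xnew, lam_new
            eigs.append(max(lam, 1e-12))
            site[:, ax] = x
        site = _fix_signs(site)
    if rescaling:
        for ax in range(site.shape[1]):
            u = (P.T @ site[:, ax]) / c
            # weighted mean squared spread of species scores within plots
            disp = float(np.sqrt((P * (u[None, :] - site[:, ax][:, None]) ** 2).sum()))
            if disp > 0:
                site[:, ax] = site[:, ax] / disp
    species = (P / c).T @ site
    axes = [f"axis{i+1}" for i in range(site.shape[1])]
    order = np.arange(len(eigs))  # axes stay in extraction order
    return OrdinationResult(
        site_scores=pd.DataFrame(site[:, order], index=data.index, columns=axes),
        species_scores=pd.DataFrame(species[:, order], index=data.columns, columns=axes),
        eigenvalues=np.array(eigs),
        method="DCA" if detrend else "CA",
        settings=settings,
    )


# ---------------------------------------------------------------------------
# statistics helpers


def _perm_count_p(null: np.ndarray, observed: float, n_perm: int) -> float:
    return float((1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1))


def spearman_statistic(y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized Spearman r of each column of a (plots x B) array against y."""
    ry = stats.rankdata(y)
    ry = (ry - ry.mean()) / (ry.std() or 1.0)

    def stat(values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(values.T).T
        rv = stats.rankdata(values, axis=0)
        rv = rv - rv.mean(axis=0)
        sd = rv.std(axis=0)
        sd[sd == 0] = np.inf
        return (rv * ry[:, None]).mean(axis=0) / sd

    return stat


def envfit_r_statistic(scores: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized multiple correlation of each column against two axis scores."""
    X = scores - scores.mean(axis=0)
    Q, _ = np.linalg.qr(X)

    def stat(values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(values.T).T
        v = values - values.mean(axis=0)
        ss = (v**2).sum(axis=0)
        ss[ss == 0] = np.inf
        r2 = ((Q.T @ v) ** 2).sum(axis=0) / ss
        return np.sqrt(np.clip(r2, 0.0, 1.0))

    return stat


def modified_permutation_test(
    presence: pd.DataFrame,
    attribute: pd.Series,
    plot_statistic: Callable[[np.ndarray], np.ndarray],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permute a species attribute among species and rebuild plot-level means.

    ``presence`` is a plot x species boolean/abundance table, ``attribute`` a
    per-species value (NaN = unknown; the missingness pattern is held fixed and
    values are permuted among the scored species).  ``plot_statistic`` maps a
    (plots x B) array of plot-level attribute means to B statistic values; the
    test is two-sided on |T|.  Returns (p, observed T).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    attr = attribute.reindex(presence.columns)
    known = attr.notna().to_numpy()
    vals = attr.to_numpy(dtype=float)[known]
    if len(vals) < 2 or np.allclose(vals, vals[0]):
        raise ValueError("attribute constant or defined for fewer than two species")
    P = presence.to_numpy(dtype=float)[:, known]
    denom = P.sum(axis=1)
    keep = denom > 0
    if not np.all(keep):
        log.warning("%d plot(s) without scored species dropped from modified test", (~keep).sum())
        P, denom = P[keep], denom[keep]
    obs = P @ vals / denom
    t_obs = float(np.asarray(plot_statistic(obs[:, None]))[0])
    rng = np.random.default_rng(seed)
    A = rng.permuted(np.tile(vals, (n_perm, 1)), axis=1).T  # species x B
    t_null = np.asarray(plot_statistic(P @ A / denom[:, None]))
    p = float((1 + np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12)) / (n_perm + 1))
    return p, t_obs


def envfit_vectors(
    scores: pd.DataFrame,
    variables: pd.DataFrame,
    modes: Mapping[str, str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    modif: Mapping[str, tuple[pd.DataFrame, pd.Series]] | None = None,
) -> pd.DataFrame:
    """Passively fit plot-level variables onto the first two ordination axes.

    For each variable, least squares on the two axis-score columns gives the
    multiple correlation r and the unit direction of steepest increase in the
    ordination plane.  ``modes[name]`` is ``"topographic"`` (parametric p only)
    or ``"species-derived"`` (adds permutation and, when ``modif[name]``
    supplies the (presence, attribute) pair, modified-permutation p-values).
    """
    ax = scores.to_numpy(dtype=float)[:, :2]
    n = len(ax)
    modes = dict(modes or {})
    modif = dict(modif or {})
    rng = np.random.default_rng(seed)
    Xc = ax - ax.mean(axis=0)
    stat = envfit_r_statistic(ax)
    rows = []
    for name in variables.columns:
        v = variables[name].reindex(scores.index).to_numpy(dtype=float)
        if np.allclose(v, v[0]):
            raise ValueError(f"variable {name!r} is constant")
        mode = modes.get(name, "topographic")
        vc = v - v.mean()
        coef, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
        direction = coef / np.linalg.norm(coef)
        r = float(stat(v[:, None])[0])
        r2 = r**2
        f = (r2 / 2) / ((1 - r2) / (n - 3)) if r2 < 1 else np.inf
        p_par = float(stats.f.sf(f, 2, n - 3))
        p_perm = p_modif = np.nan
        if mode == "species-derived":
            perms = np.stack([rng.permutation(v) for _ in range(n_perm)], axis=1)
            r_null = stat(perms)
            p_perm = _perm_count_p(r_null, r, n_perm)
            if name in modif:
                presence, attribute = modif[name]
                p_modif, _ = modified_permutation_test(
                    presence.loc[scores.index],
                    attribute,
                    stat,
                    n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
        elif mode != "topographic":
            raise ValueError(f"unknown mode {mode!r} for variable {name!r}")
        rows.append(
            {
                "variable": name,
                "dx": float(direction[0]),
                "dy": float(direction[1]),
                "r": r,
                "p_par": p_par,
                "p_perm": p_perm,
                "p_modif": p_modif,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def spearman_table(
    spectra: pd.DataFrame,
    topography: pd.DataFrame,
    eiv_means: pd.DataFrame,
    presence: pd.DataFrame | None = None,
    onset: pd.Series | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spearman correlations of monthly flowering shares with topography and EIV.

    Topographic variables get the parametric p only; indicator-value means
    additionally get a plot-permutation p and a modified-permutation p (the
    onset months are permuted among species and the month share rebuilt, the
    indicator mean held fixed), when ``presence`` and ``onset`` are supplied.
    """
    rng = np.random.default_rng(seed)
    month_cols = [c for c in spectra.columns if not c.startswith("n_")]
    rows = []
    for month in month_cols:
        y = spectra[month].to_numpy(dtype=float)
        for kind, table in (("topographic", topography), ("species-derived", eiv_means)):
            for name in table.columns:
                if name.startswith("n_"):
                    continue
                v = table[name].reindex(spectra.index).to_numpy(dtype=float)
                r, p_par = _spearman_with_p(y, v)
                p_perm = p_modif = np.nan
                if kind == "species-derived" and np.isfinite(r):
                    stat = spearman_statistic(v)
                    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
                    null = np.abs(np.asarray(stat(perms)))
                    p_perm = _perm_count_p(null, abs(r), n_perm)
                    if presence is not None and onset is not None:
                        target = _month_number(month)
                        indicator = (onset == target).astype(float).where(onset.notna())
                        p_modif, _ = modified_permutation_test(
                            presence.loc[spectra.index],
                            indicator,
                            stat,
                            n_perm=n_perm,
                            seed=int(rng.integers(2**31)),
                        )
                rows.append(
                    {
                        "month": month,
                        "variable": name,
                        "r": r,
                        "p_par": p_par,
                        "p_perm": p_perm,
                        "p_modif": p_modif,
                    }
                )
    return pd.DataFrame(rows)


def _month_number(name: str) -> int:
    from .traits import MONTH_NAMES

    lookup = {v: k for k, v in MONTH_NAMES.items()}
    return lookup.get(name, int(name) if str(name).isdigit() else -1)


def _spearman_with_p(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    if np.allclose(y, y[0]) or np.allclose(v, v[0]):
        log.warning("zero-variance vector in Spearman correlation")
        return float("nan"), float("nan")
    res = stats.spearmanr(y, v)
    return float(res.statistic), float(res.pvalue)


def cca_ptv(
    matrix,
    variable: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    name: str = "constraint",
) -> CCAResult:
    """Single-constraint CCA: % of total inertia explained, pseudo-F, Monte Carlo p.

    The constraint is weighted-centered by the row masses; the constrained
    inertia is the squared norm of the chi-square residual matrix projected on
    it.  Significance is tested by unrestricted permutation of the constraint
    across plots, one-sided on F.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    arr = data.to_numpy(dtype=float)
    P, r, c, S = _chi_square_residuals(arr, data.index, data.columns)
    x = variable.reindex(data.index).to_numpy(dtype=float) if isinstance(variable, pd.Series) else np.asarray(variable, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constraining variable is constant")
    n = len(x)
    total = float((S**2).sum())

    def constrained_inertia(cols: np.ndarray) -> np.ndarray:
        z = np.sqrt(r)[:, None] * (cols - (r @ cols))
        norms = (z**2).sum(axis=0)
        return ((S.T @ z) ** 2).sum(axis=0) / norms

    con = float(constrained_inertia(x[:, None])[0])
    resid = total - con
    f_obs = con / (resid / (n - 2))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)], axis=1)
    con_null = constrained_inertia(perms)
    f_null = con_null / ((total - con_null) / (n - 2))
    p = _perm_count_p(f_null, f_obs, n_perm)
    return CCAResult(
        variable=name,
        ptv=100.0 * con / total,
        f_stat=float(f_obs),
        p_value=p,
        n_perm=n_perm,
        constrained_inertia=con,
        total_inertia=total,
    )
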