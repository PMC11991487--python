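"""Synthetic doline transects with known group structure and trait coupling.

The generator emulates the sampling design of a karst-doline vegetation survey:
~10 dolines of 2.45-21.74 m depth crossed by continuous transects of 2 m plots,
a smooth concave (cosine-bowl) depth profile per limb, a sky-view factor that
shrinks with depth, bare rock concentrated near the rims and on scattered
rock-crevice plots, and a species pool of six archetypes with unimodal
(Gaussian) responses along the depth gradient.  Crevice archetypes respond to
bare rock instead of depth.  Flowering onset and indicator values are coupled
to the archetype niche: deep-niche species flower early (March) and carry high
moisture/nutrient figures, shallow-niche species flower in June with high
light/temperature figures, crevice species flower last (August).

Observation noise: occurrences are Poisson-thinned and expected covers are
rounded through the ordinal cover scale (percent -> code -> midpoint), which
reproduces the sparsity real fidelity statistics consume.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import CommunityMatrix, CoverScale, DEFAULT_SCALE, validate_plot_meta

__all__ = ["SimulationConfig", "GroundTruth", "simulate_profile", "simulate_community", "ground_truth"]

#: (doline depth m, north limb length m, south limb length m) for ten dolines
DEFAULT_DOLINES: tuple[tuple[float, int, int], ...] = (
    (5.98, 14, 20),
    (7.51, 14, 24),
    (8.17, 18, 34),
    (2.45, 10, 22),
    (8.71, 22, 18),
    (13.28, 32, 36),
    (18.84, 34, 54),
    (21.74, 38, 46),
    (13.65, 30, 30),
    (15.4, 40, 34),
)

#: normalized-depth band edges separating archetypes 1|2, 2|3, 3|4, 4|5
DEFAULT_BAND_EDGES: tuple[float, float, float, float] = (0.55, 0.35, 0.20, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    dolines: tuple[tuple[float, int, int], ...] = DEFAULT_DOLINES
    spacing: float = 2.0
    band_edges: tuple[float, float, float, float] = DEFAULT_BAND_EDGES
    n_species_per_archetype: tuple[int, int, int, int, int, int] = (24, 20, 20, 24, 18, 16)
    n_generalists: int = 8
    niche_breadth_scale: float = 0.35  # niche SD as fraction of (terraced) band width
    terrace: float = 0.6  # 0 = smooth coenocline, 1 = fully discrete bands
    presence_intensity: float = 2.5  # Poisson rate at the niche optimum
    peak_cover_range: tuple[float, float] = (1.5, 35.0)  # % at the optimum
    cover_noise_sd: float = 0.3  # lognormal sd on realized cover
    rock_crevice_fraction: float = 0.085
    rock_crevice_range: tuple[float, float] = (55.0, 95.0)
    rock_base_max: float = 30.0  # rim-level bare rock on ordinary plots
    rock_noise_sd: float = 6.0
    rock_suppression: float = 1.5  # exponent damping soil flora on rocky plots
    svf_top: float = 0.95
    svf_slope: float = 0.75
    svf_noise_sd: float = 0.03
    onset_centers: tuple[int, int, int, int, int, int] = (3, 4, 5, 5, 6, 8)
    onset_coupling: float = 1.0  # 0 = onset independent of archetype
    eiv_slopes: tuple[float, ...] = (-4.5, -2.5, 4.0, 4.5, 0.0)  # L, T, M, N, R per unit depth
    eiv_coupling: float = 1.0
    eiv_noise_sd: float = 0.7
    eiv_missing_rate: float = 0.05
    onset_missing_rate: float = 0.03

    def __post_init__(self) -> None:
        if len(self.dolines) < 1:
            raise ValueError("need at least one doline")
        if any(d <= 0 for d, _, _ in self.dolines):
            raise ValueError("doline depths must be positive")
        for p in (self.onset_coupling, self.eiv_coupling, self.rock_crevice_fraction, self.terrace):
            if not 0 <= p <= 1:
                raise ValueError("coupling/fraction parameters must lie in [0, 1]")


@dataclass
class GroundTruth:
    labels: pd.Series  # plot -> true archetype 1..6
    species_params: pd.DataFrame  # archetype, niche_center, niche_sd, peak_cover
    config: SimulationConfig


_TRUTH_CACHE: dict[str, GroundTruth] = {}


def simulate_profile(
    depth_m: float,
    length_north_m: float,
    length_south_m: float,
    spacing: float = 2.0,
    transect: str = "T1",
    ref_depth: float | None = None,
    svf_top: float = 0.95,
    svf_slope: float = 0.75,
    rock_base_max: float = 30.0,
) -> pd.DataFrame:
    """Deterministic plot metadata for one doline transect.

    The transect runs rim -> bottom -> rim; each limb follows a cosine bowl,
    so rim plots sit at depth 0 and the bottom plot at ``depth_m``.  The SVF
    proxy decreases linearly with depth (relative to ``ref_depth``, default the
    doline's own depth) and bare rock is highest near the rims.
    """
    if depth_m <= 0:
        raise ValueError("doline depth must be positive")
    for L in (length_north_m, length_south_m):
        if L <= 0 or abs(L / spacing - round(L / spacing)) > 1e-9:
            raise ValueError(f"limb length {L} m is not a positive multiple of spacing {spacing} m")
    ref = ref_depth if ref_depth is not None else depth_m
    ln, ls = float(length_north_m), float(length_south_m)
    pos = np.arange(0.0, ln + ls + spacing / 2, spacing)
    depth = np.where(
        pos <= ln,
        depth_m * (1 - np.cos(np.pi * pos / ln)) / 2,
        depth_m * (1 - np.cos(np.pi * (ln + ls - pos) / ls)) / 2,
    )
    depth = np.round(depth, 10)  # exact zeros at the rims
    svf = np.clip(svf_top - svf_slope * depth / ref, 0.0, 1.0)
    rock = rock_base_max * (1 - depth / depth.max())
    meta = pd.DataFrame(
        {
            "transect": transect,
            "position": pos,
            "depth": depth,
            "svf": svf,
            "bare_rock": rock,
        },
        index=pd.Index([f"{transect}_p{int(p):03d}" for p in pos], name="plot"),
    )
    return validate_plot_meta(meta)


def _archetype_from_depth(d_norm: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    e1, e2, e3, e4 = edges
    out = np.full(len(d_norm), 5, dtype=int)
    out[d_norm >= e4] = 4
    out[d_norm >= e3] = 3
    out[d_norm >= e2] = 2
    out[d_norm >= e1] = 1
    return out


_BAND_LIMITS = {1: (0.55, 1.0), 2: (0.35, 0.55), 3: (0.20, 0.35), 4: (0.03, 0.20), 5: (0.0, 0.03)}


def _terrace_positions(d_norm: np.ndarray, edges: tuple[float, ...], terrace: float) -> np.ndarray:
    """Shrink gradient positions toward their band centre.

    Vegetation belts along doline slopes behave as discrete terraces with
    sharp boundaries rather than a perfectly smooth coenocline; ``terrace``
    interpolates between the two regimes (0 = smooth, 1 = fully discrete).
    """
    bands = _archetype_from_depth(d_norm, edges)
    centres = np.array([(_BAND_LIMITS[a][0] + _BAND_LIMITS[a][1]) / 2 for a in bands])
    return (1 - terrace) * d_norm + terrace * centres


def simulate_community(
    config: SimulationConfig, scale: CoverScale = DEFAULT_SCALE
) -> tuple[CommunityMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic survey: (community codes, plot meta, traits, truth)."""
    rng = np.random.default_rng(config.seed)
    ref_depth = max(d for d, _, _ in config.dolines)

    metas = []
    for i, (d, ln, ls) in enumerate(config.dolines, start=1):
        metas.append(
            simulate_profile(
                d,
                ln,
                ls,
                spacing=config.spacing,
                transect=f"T{i:02d}",
                ref_depth=ref_depth,
                svf_top=config.svf_top,
                svf_slope=config.svf_slope,
                rock_base_max=config.rock_base_max,
            )
        )
    meta = pd.concat(metas)
    n_plots = len(meta)
    meta["svf"] = np.clip(meta["svf"] + rng.normal(0, config.svf_noise_sd, n_plots), 0.0, 1.0)
    rock = np.clip(meta["bare_rock"] + rng.normal(0, config.rock_noise_sd, n_plots), 0.0, 45.0)
    crevice = rng.random(n_plots) < config.rock_crevice_fraction
    lo, hi = config.rock_crevice_range
    rock[crevice] = rng.uniform(lo, hi, int(crevice.sum()))
    meta["bare_rock"] = np.round(rock, 1)

    d_norm = (meta["depth"] / ref_depth).to_numpy()
    labels = _archetype_from_depth(d_norm, config.band_edges)
    labels[meta["bare_rock"].to_numpy() > 50.0] = 6

    # --- species pool ------------------------------------------------------
    counts = config.n_species_per_archetype
    if min(counts) < 1:
        raise ValueError("species pool too small: every archetype needs at least one species")
    species, arch, centers, sds, peaks = [], [], [], [], []
    for a in range(1, 6):
        lo_b, hi_b = _BAND_LIMITS[a]
        width = hi_b - lo_b
        eff_width = max(width * (1 - config.terrace), 0.04)
        for s in range(counts[a - 1]):
            species.append(f"sp_a{a}_{s:02d}")
            arch.append(a)
            raw_centre = rng.uniform(lo_b + 0.2 * width, hi_b - 0.2 * width)
            centers.append(float(_terrace_positions(np.array([raw_centre]), config.band_edges, config.terrace)[0]))
            sds.append(max(config.niche_breadth_scale * eff_width, 0.015) * rng.lognormal(0, 0.2))
            peaks.append(float(np.exp(rng.uniform(*np.log(config.peak_cover_range)))))
    for s in range(counts[5]):  # crevice flora: niche on the bare-rock axis (%)
        species.append(f"sp_a6_{s:02d}")
        arch.append(6)
        centers.append(rng.uniform(65.0, 90.0))
        sds.append(rng.uniform(12.0, 22.0))
        peaks.append(float(np.exp(rng.uniform(*np.log(config.peak_cover_range)))))
    for s in range(config.n_generalists):
        species.append(f"sp_gen_{s:02d}")
        arch.append(0)
        centers.append(rng.uniform(0.0, 1.0))
        sds.append(rng.uniform(0.3, 0.6))
        peaks.append(float(np.exp(rng.uniform(*np.log(config.peak_cover_range)))))
    arch = np.array(arch)
    centers = np.array(centers)
    sds = np.array(sds)
    peaks = np.array(peaks)
    n_sp = len(species)

    # --- abundances --------------------------------------------------------
    rock_arr = meta["bare_rock"].to_numpy()
    soil_damp = (1 - rock_arr / 100.0) ** config.rock_suppression
    d_eff = _terrace_positions(d_norm, config.band_edges, config.terrace)
    resp = np.empty((n_plots, n_sp))
    for j in range(n_sp):
        if arch[j] == 6:
            resp[:, j] = np.exp(-((rock_arr - centers[j]) ** 2) / (2 * sds[j] ** 2))
        else:
            resp[:, j] = np.exp(-((d_eff - centers[j]) ** 2) / (2 * sds[j] ** 2)) * soil_damp
    present = rng.poisson(config.presence_intensity * resp) > 0
    cover = peaks[None, :] * resp * rng.lognormal(0, config.cover_noise_sd, resp.shape)
    cover = np.where(present, np.minimum(cover, 95.0), 0.0)
    for i in np.flatnonzero(~present.any(axis=1)):  # no plot may stay empty
        j = int(np.argmax(resp[i]))
        cover[i, j] = scale.midpoints[1]
        present[i, j] = True

    codes = np.full(cover.shape, "", dtype=object)
    for i, j in zip(*np.nonzero(cover > 0)):
        codes[i, j] = scale.percent_to_code(cover[i, j])
    community = CommunityMatrix(
        pd.DataFrame(codes, index=meta.index, columns=pd.Index(species, name="species")),
        kind="codes",
        scale=scale,
    )

    # --- traits ------------------------------------------------------------
    onset_centers = np.array(config.onset_centers)
    pool_probs = np.bincount(arch[arch > 0], minlength=7)[1:7].astype(float)
    pool_probs /= pool_probs.sum()
    onset = np.empty(n_sp)
    for j in range(n_sp):
        a = arch[j] if arch[j] > 0 else int(rng.choice(6, p=pool_probs)) + 1
        if rng.random() < config.onset_coupling:
            m = onset_centers[a - 1]
        else:
            m = onset_centers[int(rng.choice(6, p=pool_probs))]
        m += rng.choice((-1, 0, 1), p=(0.2, 0.6, 0.2))
        # early/late tails exercise the raw 2..9 range (Feb and Sep onsets)
        if m <= 3 and rng.random() < 0.3:
            m = 2
        if m >= 8 and rng.random() < 0.3:
            m = 9
        onset[j] = np.clip(m, 2, 9)
    onset[rng.random(n_sp) < config.onset_missing_rate] = np.nan

    # effective gradient position driving the indicator values
    mu_eff = np.where(arch == 6, 0.05, np.where(arch == 0, centers, centers))
    intercepts = {"L": 7.6, "T": 7.0, "M": 3.2, "N": 2.8, "R": 6.8}
    traits = pd.DataFrame({"onset": onset}, index=pd.Index(species, name="species"))
    for col, slope in zip(("L", "T", "M", "N", "R"), config.eiv_slopes):
        vals = (
            intercepts[col]
            + config.eiv_coupling * slope * mu_eff
            + rng.normal(0, config.eiv_noise_sd, n_sp)
        )
        vals = np.clip(np.round(vals), 1, 9)
        vals[rng.random(n_sp) < config.eiv_missing_rate] = np.nan
        traits[col] = vals

    truth = GroundTruth(
        labels=pd.Series(labels, index=meta.index, name="archetype"),
        species_params=pd.DataFrame(
            {"archetype": arch, "niche_center": centers, "niche_sd": sds, "peak_cover": peaks},
            index=pd.Index(species, name="species"),
        ),
        config=config,
    )
    _TRUTH_CACHE[repr(config)] = truth
    return community, meta, traits, truth


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Ground truth of a configuration previously passed to simulate_community."""
    try:
        return _TRUTH_CACHE[repr(config)]
    except KeyError:
        raise KeyError("configuration has not been simulated yet") from None
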