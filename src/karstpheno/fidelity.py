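"""Diagnostic-species statistics: equalized phi fidelity, Fisher's exact test
and synoptic-table assembly.

Fidelity of a species to a plot group is the phi association coefficient of
the 2x2 presence table (inside/outside the group x present/absent), computed
*as if all groups had equal size*.  With k groups, per-group relative
frequencies f_g and F = sum_g f_g, the equalized phi for target group t is

    phi = (k f_t - F) / sqrt(F (k - 1) (k - F))

which equals the classical 2x2 phi evaluated on any equal-size replication of
the groups.  Species are diagnostic for a group when phi > 0.20 and the
one-sided Fisher exact test of concentration in that group has p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import Partition
from .core_io import CommunityMatrix, SynopticTable

__all__ = [
    "PresenceProfile",
    "presence_profiles",
    "equalized_phi",
    "fisher_presence",
    "build_synoptic",
]


@dataclass(frozen=True)
class PresenceProfile:
    """Per-group presence counts of one species."""

    species: str
    counts: tuple[int, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.sizes):
            raise ValueError("counts and sizes must align")
        for c, n in zip(self.counts, self.sizes):
            if not 0 <= c <= n:
                raise ValueError(f"count {c} outside [0, group size {n}]")

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / np.asarray(self.sizes, dtype=float)


def presence_profiles(matrix: CommunityMatrix, partition: Partition) -> dict[str, PresenceProfile]:
    """Species -> per-group presence counts under a partition."""
    pres = matrix.presence()
    labels = partition.labels.reindex(pres.index)
    if labels.isna().any():
        raise ValueError("partition missing labels for some plots")
    groups = sorted(labels.unique())
    sizes = tuple(int((labels == g).sum()) for g in groups)
    counts = pres.groupby(labels).sum().reindex(groups)
    return {
        sp: PresenceProfile(sp, tuple(int(c) for c in counts[sp]), sizes)
        for sp in pres.columns
    }


def equalized_phi(profile: PresenceProfile, target_group: int) -> float:
    """Phi fidelity of the species to ``target_group`` (0-based) with equalized groups.

    Raises for a species absent everywhere; a species present in every plot of
    every group has no concentration and returns 0 by convention.
    """
    f = profile.frequencies
    k = len(f)
    if k < 2:
        raise ValueError("fidelity requires at least two groups")
    F = float(f.sum())
    if F == 0:
        raise ValueError(f"species {profile.species!r} absent from all groups")
    if F >= k:  # present in every plot: no concentration anywhere
        return 0.0
    return float((k * f[target_group] - F) / np.sqrt(F * (k - 1) * (k - F)))


def fisher_presence(
    profile: PresenceProfile, target_group: int, alternative: str = "greater"
) -> float:
    """Fisher exact p for concentration of occurrences in the target group.

    One-sided toward over-representation by default (``alternative="greater"``,
    the vegetation-survey convention); ``"two-sided"`` is available.  Computed
    from the hypergeometric distribution of the 2x2 table
    [in-group present/absent vs out-group present/absent] with raw counts.
    """
    counts = np.asarray(profile.counts)
    sizes = np.asarray(profile.sizes)
    n_present = int(counts.sum())
    N = int(sizes.sum())
    if n_present == 0:
        raise ValueError(f"species {profile.species!r} absent: Fisher test degenerate")
    n_target = int(sizes[target_group])
    x = int(counts[target_group])
    # X ~ Hypergeom(N, n_present, n_target) under the null of no association
    if alternative == "greater":
        p = hypergeom.sf(x - 1, N, n_present, n_target)
    elif alternative == "two-sided":
        pmf_x = hypergeom.pmf(x, N, n_present, n_target)
        support = np.arange(max(0, n_present + n_target - N), min(n_present, n_target) + 1)
        pmf = hypergeom.pmf(support, N, n_present, n_target)
        p = pmf[pmf <= pmf_x * (1 + 1e-12)].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def build_synoptic(
    matrix: CommunityMatrix,
    partition: Partition,
    phi_threshold: float = 0.20,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> SynopticTable:
    """Assemble the species x group synoptic table.

    Each cell carries integer-rounded % presence and phi x 100 (1 decimal as
    written); species are flagged diagnostic for a group when phi exceeds the
    threshold and the Fisher test is significant.  Diagnostic species are
    blocked by group (within a block by declining phi); the remaining species
    follow, ordered by declining overall presence.
    """
    profiles = presence_profiles(matrix, partition)
    groups = sorted(partition.labels.unique())
    species = [sp for sp in matrix.species if sum(profiles[sp].counts) > 0]
    pres = pd.DataFrame(index=species, columns=groups, dtype=float)
    phi = pd.DataFrame(index=species, columns=groups, dtype=float)
    pval = pd.DataFrame(index=species, columns=groups, dtype=float)
    for sp in species:
        prof = profiles[sp]
        pres.loc[sp] = 100.0 * prof.frequencies
        for j, g in enumerate(groups):
            phi.loc[sp, g] = 100.0 * equalized_phi(prof, j)
            pval.loc[sp, g] = fisher_presence(prof, j, alternative=alternative)
    diag = (phi > 100.0 * phi_threshold) & (pval < alpha)

    order: list[str] = []
    for g in groups:
        block = diag.index[diag[g]].tolist()
        block = [sp for sp in block if sp not in order]
        block.sort(key=lambda sp: -phi.loc[sp, g])
        order.extend(block)
    rest = [sp for sp in species if sp not in order]
    total = {sp: sum(profiles[sp].counts) for sp in rest}
    rest.sort(key=lambda sp: -total[sp])
    order.extend(rest)

    sizes = pd.Series({g: int((partition.labels == g).sum()) for g in groups})
    return SynopticTable(
        presence_pct=pres.loc[order],
        phi100=phi.loc[order],
        fisher_p=pval.loc[order],
        diagnostic=diag.loc[order],
        group_sizes=sizes,
        phi_threshold=phi_threshold,
        alpha=alpha,
    )
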