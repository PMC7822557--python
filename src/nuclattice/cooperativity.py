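"""TF-site clustering and cooperative-binding energy bonuses.

Adjacent TFs can stabilise each other's binding.  This is modelled uniformly:
binding sites whose inter-motif gap is under a threshold (default 12 bp) are
chained into clusters, and every clustered site has its binding energy lowered
by a constant cooperativity strength (k_B*T).  Because the bonus lowers the
free energy of TF-containing states, the genome-average nucleosome occupancy
drops; the nucleosome's (c, gamma) should be re-fit after applying it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import LatticeSystem


@dataclass(frozen=True)
class BindingSite:
    """A candidate bound motif: owning factor, 0-based start, footprint, and
    a score (higher = better; conventionally minus the binding energy)."""

    factor: str
    start: int
    length: int
    score: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SiteCluster:
    """Two or more chained sites.  `span` is the inner distance between the
    two edge motifs (end of the first to start of the last, motif lengths
    excluded)."""

    sites: list[BindingSite]

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a cluster needs >= 2 sites")
        self.sites = sorted(self.sites, key=lambda s: s.start)

    @property
    def count(self) -> int:
        return len(self.sites)

    @property
    def span(self) -> int:
        return max(self.sites[-1].start - self.sites[0].end, 0)

    @property
    def start(self) -> int:
        return self.sites[0].start

    @property
    def end(self) -> int:
        return self.sites[-1].end


def sites_from_system(
    sys: LatticeSystem, exclude: tuple[str, ...] = ("nucleosome",)
) -> list[BindingSite]:
    """All bindable starts of every (non-nucleosome) factor as BindingSites,
    scored by minus the binding energy."""
    sites = []
    for f in sys.factors:
        if f.name in exclude:
            continue
        for s in np.flatnonzero(f.track.finite_mask()):
            sites.append(
                BindingSite(f.name, int(s), f.footprint, -float(f.track.energies[s]))
            )
    return sorted(sites, key=lambda s: (s.start, s.end))


def _prune_overlaps(sites: list[BindingSite]) -> list[BindingSite]:
    """Within each group of mutually overlapping motifs keep only the top two
    scores (two overlapping TFs may bind simultaneously in rare cases; more
    cannot)."""
    if not sites:
        return []
    groups: list[list[BindingSite]] = [[sites[0]]]
    reach = sites[0].end
    for s in sites[1:]:
        if s.start < reach:
            groups[-1].append(s)
        else:
            groups.append([s])
        reach = max(reach, s.end)
    kept: list[BindingSite] = []
    for g in groups:
        g = sorted(g, key=lambda s: s.score, reverse=True)[:2]
        kept.extend(g)
    return sorted(kept, key=lambda s: (s.start, s.end))


def find_clusters(sites: list[BindingSite], max_gap: int = 12) -> list[SiteCluster]:
    """Single-linkage chaining of sites whose inter-motif gap (bp between the
    end of one motif and the start of the next, motif lengths excluded) is
    strictly less than `max_gap`.  Overlapping motifs first pruned to the top
    two scores per overlap group.  Only clusters of >= 2 sites are returned."""
    sites = _prune_overlaps(sorted(sites, key=lambda s: (s.start, s.end)))
    return _chain(sites, max_gap)


def _chain(sites: list[BindingSite], max_gap: int) -> list[SiteCluster]:
    clusters: list[SiteCluster] = []
    chain: list[BindingSite] = []
    reach = -(10**12)
    for s in sites:
        if chain and s.start - reach < max_gap:
            chain.append(s)
        else:
            if len(chain) >= 2:
                clusters.append(SiteCluster(chain))
            chain = [s]
        reach = max(reach, s.end)
    if len(chain) >= 2:
        clusters.append(SiteCluster(chain))
    return clusters


def apply_cooperativity(
    sys: LatticeSystem,
    clusters: list[SiteCluster],
    strength: float,
    mode: str = "energy",
) -> LatticeSystem:
    """Return a system with the cooperativity bonus applied to every clustered
    site.

    mode='energy' (default): each clustered site's energy is lowered by
    `strength` k_B*T, i.e. its Boltzmann weight is multiplied by
    exp(gamma * strength).  mode='specificity': instead, the binding
    specificity gamma of every factor owning a clustered site is raised by
    `strength`.

    The returned system's tracks intentionally break the mean(exp(-E)) = 1
    convention at clustered sites; re-fit the nucleosome (c, gamma) before
    comparing occupancies to data.
    """
    if strength < 0:
        raise ValueError("cooperativity strength must be >= 0")
    out = sys.copy()
    if strength == 0 or not clusters:
        return out
    by_name = {f.name: f for f in out.factors}
    if mode == "energy":
        for cl in clusters:
            for s in cl.sites:
                by_name[s.factor].track.energies[s.start] -= strength
    elif mode == "specificity":
        for name in {s.factor for cl in clusters for s in cl.sites}:
            by_name[name].gamma += strength
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


__all__ = [
    "BindingSite",
    "SiteCluster",
    "sites_from_system",
    "find_clusters",
    "apply_cooperativity",
]
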