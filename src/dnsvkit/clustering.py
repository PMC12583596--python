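"""Breakpoint-junction clustering without a fixed distance cutoff.

Two junctions are candidates to belong to one rearrangement event when their
breakends lie improbably close under a uniform background.  With lambda =
(total breakends) / (genome length) the probability of observing a nearest
inter-breakend distance <= d by chance is ``p = 1 - exp(-2 * lambda * d)``
(the two-sided exponential nearest-neighbour law of a Poisson process).  All
candidate pairs are tested, Benjamini-Hochberg controls the FDR at
``fdr_alpha``, and significant pairs are merged transitively (single
linkage), so no fixed distance threshold is imposed: the same separation may
merge in a sparse genome and stay apart in a dense one.

Inter-chromosomal junctions take part through their breakends on each
partner chromosome; two junctions sharing no chromosome never pair directly
but may end up in one cluster through a chain of significant pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genome import GenomeMap
from .model import Junction


@dataclass
class SVCluster:
    cluster_id: str
    junctions: list[Junction]
    # minimal interval covering member breakends, per chromosome
    footprint: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_breakpoints(self) -> int:
        """Number of breakpoint junctions in the cluster (a junction is one
        rearrangement joint)."""
        return len(self.junctions)

    def compute_footprint(self) -> None:
        self.footprint = {}
        for j in self.junctions:
            for bnd in (j.bnd1, j.bnd2):
                lo, hi = self.footprint.get(bnd.chrom, (bnd.pos, bnd.pos))
                self.footprint[bnd.chrom] = (min(lo, bnd.pos), max(hi, bnd.pos))


def junction_distance(a: Junction, b: Junction) -> float:
    """Minimum distance between breakends of a and b on shared chromosomes;
    infinite when no chromosome is shared."""
    best = math.inf
    for x in (a.bnd1, a.bnd2):
        for y in (b.bnd1, b.bnd2):
            if x.chrom == y.chrom:
                best = min(best, abs(x.pos - y.pos))
    return best


def pair_p_value(d: float, lam: float) -> float:
    """P(nearest inter-breakend distance <= d) under a uniform Poisson
    breakend background of rate lam per bp."""
    if math.isinf(d):
        return 1.0
    return 1.0 - math.exp(-2.0 * lam * d)


def bh_threshold(p_values: list[float], alpha: float) -> float:
    """Largest Benjamini-Hochberg-significant p-value (-1.0 when none)."""
    m = len(p_values)
    if m == 0:
        return -1.0
    best = -1.0
    for rank, p in enumerate(sorted(p_values), start=1):
        if p <= alpha * rank / m:
            best = p
    return best


def cluster_junctions(
    junctions: list[Junction],
    genome: GenomeMap,
    fdr_alpha: float = 0.05,
) -> list[SVCluster]:
    """Partition junctions into event clusters.

    Deterministic: input order never matters; cluster ids are assigned in
    order of each cluster's lexicographically smallest member junction id.
    """
    if not junctions:
        return []
    junctions = sorted((j.canonical() for j in junctions), key=lambda j: j.id)
    n = len(junctions)
    lam = (2.0 * n) / genome.total_length

    pairs: list[tuple[float, int, int]] = []
    for i in range(n):
        for k in range(i + 1, n):
            d = junction_distance(junctions[i], junctions[k])
            pairs.append((pair_p_value(d, lam), i, k))

    p_star = bh_threshold([p for p, _, _ in pairs], fdr_alpha)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # merge in order of (p, id pair) for deterministic tie handling
    for p, i, k in sorted(pairs, key=lambda t: (t[0], junctions[t[1]].id, junctions[t[2]].id)):
        if p_star < 0 or p > p_star:
            break
        ri, rk = find(i), find(k)
        if ri != rk:
            parent[max(ri, rk)] = min(ri, rk)

    groups: dict[int, list[Junction]] = {}
    for i, j in enumerate(junctions):
        groups.setdefault(find(i), []).append(j)

    clusters = []
    ordered = sorted(groups.values(), key=lambda g: min(j.id for j in g))
    for idx, members in enumerate(ordered):
        c = SVCluster(cluster_id=f"cluster_{idx}", junctions=sorted(members, key=lambda j: j.id))
        c.compute_footprint()
        clusters.append(c)
    return clusters
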