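"""Cohort-level statistics for de novo SV analyses.

Implements the headline derived quantities: class fractions and per-genome
mutation rate, the two-tailed exact binomial test used for meiotic timing,
the two-sample Kolmogorov-Smirnov test for parental size bias, Fisher's
exact test for 2x2 contingency, telomere-distance binning with the
subtelomeric density ratio, a GAT-style permutation enrichment test over a
genomic workspace, and the array/WES detectability rule.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .genome import GenomeMap


# ---------------------------------------------------------------------------
# counting


def class_fractions(counts: dict[str, int]) -> pd.DataFrame:
    """Percentages (0.1% precision) of per-class counts."""
    total = sum(counts.values())
    rows = [
        {"sv_class": k, "count": v,
         "pct": round(100.0 * v / total, 1) if total else 0.0}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)


def dnsv_rate(n_events: int, n_genomes: int) -> float:
    """De novo SV rate per offspring genome per generation."""
    if n_genomes <= 0:
        raise ValueError("n_genomes must be positive")
    return n_events / n_genomes


# ---------------------------------------------------------------------------
# hypothesis tests


def binom_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Two-tailed exact binomial p-value (sum of outcomes no more probable
    than the observed one)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    return sps.binomtest(k, n, p0, alternative="two-sided").pvalue


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]]."""
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# telomere-distance analyses


@dataclass
class BinnedDensity:
    anchor: str  # "telomere" | "centromere"
    bin_edges: np.ndarray        # distance-to-anchor edges, bp
    events_per_bin: np.ndarray
    mb_per_bin: np.ndarray
    density_per_mb: np.ndarray

    @property
    def total_events(self) -> int:
        return int(self.events_per_bin.sum())


def _anchor_distance(genome: GenomeMap, anchor: str, chrom: str, pos: int) -> int:
    if anchor == "telomere":
        return genome.telomere_distance(chrom, pos)
    if anchor == "centromere":
        return genome.centromere_distance(chrom, pos)
    raise ValueError(f"unknown anchor {anchor!r}")


def telomere_binning(
    events: list[tuple[str, int]],
    genome: GenomeMap,
    bin_size: int = 5_000_000,
    anchor: str = "telomere",
) -> BinnedDensity:
    """Bin events by distance to the nearest telomere end (or centromere).

    ``events`` are (chrom, position) pairs; each event is a single
    representative position (the lower breakend).  Only chromosomes present
    in ``genome`` contribute; positions beyond a chromosome end raise.
    The amount of sequence per distance bin is computed from the same
    genome, so densities are per Mb of eligible sequence.
    """
    max_dist = max(
        (_anchor_distance(genome, anchor, c, p_extreme)
         for c in genome.chrom_names
         for p_extreme in (0, genome.chrom_lengths[c] // 2, genome.chrom_lengths[c])),
        default=0,
    )
    n_bins = max(1, -(-max_dist // bin_size))
    edges = np.arange(0, (n_bins + 1) * bin_size, bin_size)

    counts = np.zeros(n_bins, dtype=int)
    for chrom, pos in events:
        d = _anchor_distance(genome, anchor, chrom, pos)
        counts[min(d // bin_size, n_bins - 1)] += 1

    # bp of genome at each distance stratum (1 bp resolution, analytic)
    bp = np.zeros(n_bins)
    for chrom, length in genome.chrom_lengths.items():
        if anchor == "telomere":
            # distance d occupies 2 bp per chromosome for d < length/2
            half = length / 2
            for b in range(n_bins):
                lo, hi = b * bin_size, min((b + 1) * bin_size, half)
                if hi > lo:
                    bp[b] += 2 * (hi - lo)
        else:
            cen = genome.centromeres[chrom]
            for b in range(n_bins):
                lo, hi = b * bin_size, (b + 1) * bin_size
                left = max(0, min(cen - lo, cen) - max(cen - hi, 0))
                right = max(0, min(cen + hi, length) - min(cen + lo, length))
                bp[b] += left + right

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(bp > 0, counts / (bp / 1e6), 0.0)
    return BinnedDensity(anchor, edges, counts, bp / 1e6, density)


def subtelomeric_ratio(
    events: list[tuple[str, int]],
    genome: GenomeMap,
    cutoff: int = 15_000_000,
) -> float:
    """Density of events within ``cutoff`` of a telomere end, relative to
    the genome-wide average density."""
    n_sub = sum(
        1 for chrom, pos in events
        if genome.telomere_distance(chrom, pos) < cutoff
    )
    sub_mb = sum(
        min(2 * cutoff, length) for length in genome.chrom_lengths.values()
    ) / 1e6
    total_mb = genome.total_length / 1e6
    sub_density = n_sub / sub_mb
    overall_density = len(events) / total_mb
    return density_ratio(sub_density, overall_density)


def density_ratio(subtelomeric_per_mb: float, genomewide_per_mb: float) -> float:
    if genomewide_per_mb <= 0:
        raise ValueError("genome-wide density must be positive")
    return subtelomeric_per_mb / genomewide_per_mb


# ---------------------------------------------------------------------------
# permutation enrichment


@dataclass
class EnrichmentResult:
    observed: int          # bp overlap with targets
    expected: float        # mean over permutation samples
    ratio: float           # observed / expected
    p_value: float         # one-sided empirical, floor 1/(n_samples+1)
    n_samples: int
    window_bp: int


Interval = tuple[str, int, int]


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def _clip_to(intervals: list[Interval], workspace: list[Interval]) -> list[Interval]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in workspace:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    out = []
    for chrom, s, e in intervals:
        for iv in trees.get(chrom, IntervalTree()).overlap(s, e):
            out.append((chrom, max(s, iv.begin), min(e, iv.end)))
    return _merge(out)


def _overlap_bp(a: list[Interval], b: list[Interval]) -> int:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in b:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    total = 0
    for chrom, s, e in a:
        for iv in trees.get(chrom, IntervalTree()).overlap(s, e):
            total += min(e, iv.end) - max(s, iv.begin)
    return total


def permutation_enrichment(
    query: list[Interval],
    targets: list[Interval],
    workspace: list[Interval],
    n_samples: int = 1000,
    window: int = 0,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Observed-over-expected overlap of query intervals with targets.

    Query intervals are optionally extended by ``window`` bp on both sides,
    clipped to the workspace, and compared with length-preserving uniform
    random placements within the workspace.  The one-sided empirical p-value
    is ``(#{samples with overlap >= observed} + 1) / (n_samples + 1)``.
    """
    rng = rng or np.random.default_rng()
    workspace = _merge(workspace)
    targets = _clip_to(_merge(targets), workspace)
    extended = [(c, max(0, s - window), e + window) for c, s, e in query]
    placed = _clip_to(extended, workspace)
    observed = _overlap_bp(placed, targets)

    # random placements preserve the extended query lengths
    lengths = [e - s for _, s, e in extended]
    # valid start positions per workspace segment for each query length
    seg_list = workspace
    seg_lens = [e - s for _, s, e in seg_list]
    max_seg = max(seg_lens, default=0)
    for L in lengths:
        if L > max_seg:
            raise ValueError(
                f"query interval of {L} bp exceeds the longest workspace segment"
            )

    target_trees: dict[str, IntervalTree] = {}
    for chrom, s, e in targets:
        target_trees.setdefault(chrom, IntervalTree()).addi(s, e)

    # cumulative valid-start counts per distinct query length
    cums = {
        L: np.cumsum([max(0, sl - L + 1) for sl in seg_lens])
        for L in set(lengths)
    }
    sample_overlaps = np.zeros(n_samples)
    for si in range(n_samples):
        total = 0
        for L in lengths:
            cum = cums[L]
            u = rng.integers(0, cum[-1])
            idx = int(bisect_right(cum, u))
            chrom, seg_start, _ = seg_list[idx]
            offset = u - (cum[idx - 1] if idx else 0)
            s = seg_start + int(offset)
            e = s + L
            for iv in target_trees.get(chrom, IntervalTree()).overlap(s, e):
                total += min(e, iv.end) - max(s, iv.begin)
        sample_overlaps[si] = total

    expected = float(sample_overlaps.mean())
    n_ge = int((sample_overlaps >= observed).sum())
    p = (n_ge + 1) / (n_samples + 1)
    ratio = observed / expected if expected > 0 else float("inf")
    return EnrichmentResult(
        observed=observed, expected=expected, ratio=ratio,
        p_value=p, n_samples=n_samples, window_bp=window,
    )


# ---------------------------------------------------------------------------
# array/WES detectability


def detectability_class(
    sv_class: str,
    deletion_spans: list[Interval],
    exons: list[Interval],
    exon_cutoff: int = 3,
) -> str:
    """"array_wes_detectable" or "not_detectable".

    Balanced rearrangements (reciprocal inversion/translocation) are not
    detectable by array/WES; neither are events whose deletion components all
    span fewer than ``exon_cutoff`` exons of the canonical transcript.
    Events with no deletion component and no balanced-class label are
    considered detectable (their copy-number change is array-visible).
    """
    if sv_class in ("RECIPROCAL_INV", "RECIPROCAL_TRA"):
        return "not_detectable"
    if deletion_spans:
        trees: dict[str, IntervalTree] = {}
        for chrom, s, e in exons:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, (chrom, s, e))
        max_exons = 0
        for chrom, s, e in deletion_spans:
            hit = {iv.data for iv in trees.get(chrom, IntervalTree()).overlap(s, e)}
            max_exons = max(max_exons, len(hit))
        if max_exons < exon_cutoff:
            return "not_detectable"
    return "array_wes_detectable"
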