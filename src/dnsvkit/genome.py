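"""Genome coordinate frames: chromosome lengths and telomere/centromere anchors.

A :class:`GenomeMap` is the coordinate frame every other module validates
against.  The bundled GRCh38 map carries the primary-assembly autosome + X
lengths and approximate centromere midpoints (cytoband-derived, suitable for
Mb-scale distance binning, not base-pair-accurate annotation).  Synthetic
genomes of any size can be constructed for simulation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GenomeError(ValueError):
    """A coordinate or chromosome name inconsistent with the genome map."""


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome lengths plus telomere/centromere anchor positions.

    Telomere anchors are the chromosome ends (0 and length); the distance of a
    position to the nearest telomere is ``min(pos, length - pos)``.  Centromere
    anchors are single midpoint positions per chromosome.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise GenomeError(f"chromosome {chrom} has non-positive length {length}")
        for chrom, pos in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise GenomeError(f"centromere on unknown chromosome {chrom}")
            if not 0 <= pos <= self.chrom_lengths[chrom]:
                raise GenomeError(f"centromere position {pos} outside {chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check_position(self, chrom: str, pos: int) -> None:
        if chrom not in self.chrom_lengths:
            raise GenomeError(f"unknown chromosome: {chrom}")
        if not 0 <= pos <= self.chrom_lengths[chrom]:
            raise GenomeError(
                f"position {pos} outside {chrom} (length {self.chrom_lengths[chrom]})"
            )

    def telomere_distance(self, chrom: str, pos: int) -> int:
        """Distance (bp) from ``pos`` to the nearest chromosome end."""
        self.check_position(chrom, pos)
        return min(pos, self.chrom_lengths[chrom] - pos)

    def centromere_distance(self, chrom: str, pos: int) -> int:
        self.check_position(chrom, pos)
        if chrom not in self.centromeres:
            raise GenomeError(f"no centromere anchor for {chrom}")
        return abs(pos - self.centromeres[chrom])

    def autosomes(self) -> "GenomeMap":
        """Restrict to autosomes (chromosome names not ending in X or Y)."""
        keep = {
            c: l
            for c, l in self.chrom_lengths.items()
            if not c.rstrip().upper().endswith(("X", "Y"))
        }
        cen = {c: p for c, p in self.centromeres.items() if c in keep}
        return GenomeMap(keep, cen)


# GRCh38 primary-assembly chromosome lengths (autosomes + X).
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
}

# Approximate centromere midpoints (Mb-scale cytoband midpoints).
GRCH38_CENTROMERES: dict[str, int] = {
    "chr1": 123_400_000,
    "chr2": 93_900_000,
    "chr3": 90_900_000,
    "chr4": 50_000_000,
    "chr5": 48_800_000,
    "chr6": 59_800_000,
    "chr7": 60_100_000,
    "chr8": 45_200_000,
    "chr9": 43_000_000,
    "chr10": 39_800_000,
    "chr11": 53_400_000,
    "chr12": 35_500_000,
    "chr13": 17_700_000,
    "chr14": 17_200_000,
    "chr15": 19_000_000,
    "chr16": 36_800_000,
    "chr17": 25_100_000,
    "chr18": 18_500_000,
    "chr19": 26_200_000,
    "chr20": 28_100_000,
    "chr21": 12_000_000,
    "chr22": 15_000_000,
    "chrX": 60_500_000,
}


def grch38() -> GenomeMap:
    """The bundled GRCh38 autosome + X map."""
    return GenomeMap(dict(GRCH38_LENGTHS), dict(GRCH38_CENTROMERES))


def synthetic_genome(n_chroms: int = 2, chrom_length: int = 100_000_000) -> GenomeMap:
    """A uniform toy genome for simulation: chromosomes chr1..chrN."""
    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    cens = {c: chrom_length // 2 for c in lengths}
    return GenomeMap(lengths, cens)
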