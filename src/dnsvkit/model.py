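"""Domain types for trio structural-variant analysis.

Coordinate and orientation conventions
--------------------------------------
All positions are 0-based.  A breakend orientation of ``+`` means the sequence
to the LEFT of the position is retained into the junction; ``-`` means the
sequence to the RIGHT is retained.  Under this (BEDPE-style) convention a
deletion junction reads ``(+,-)``, a tandem duplication ``(-,+)`` and an
inversion contributes a ``(+,+)`` ("head") and/or a ``(-,-)`` ("tail")
junction.  Junctions are canonical: breakend 1 sorts at or before breakend 2
by (chromosome, position).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"
    INS = "INS"
    BND = "BND"


class Flag(str, enum.Enum):
    """Caller flags carried on a call.

    PASS: all caller filters passed.  MGE10kb: sub-10 kb call class retained
    despite non-PASS status.  IMPRECISE: breakpoints not base-pair resolved.
    COLOCALIZED_RD: an independent read-depth CNV segment co-locates with the
    junction call (the rescue signal for imprecise calls).
    """

    PASS = "PASS"
    MGE10kb = "MGE10kb"
    IMPRECISE = "IMPRECISE"
    COLOCALIZED_RD = "COLOCALIZED_RD"


class OrientationClass(str, enum.Enum):
    DEL_LIKE = "DEL_like"      # (+,-)
    DUP_LIKE = "DUP_like"      # (-,+)
    INV_HEAD = "INV_head"      # (+,+)
    INV_TAIL = "INV_tail"      # (-,-)
    INTERCHROM = "INTERCHROM"


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering: chr2 before chr10, X/Y after numbers."""
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


@dataclass(frozen=True, order=False)
class Breakend:
    chrom: str
    pos: int
    orient: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orient not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orient!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")

    @property
    def sort_key(self) -> tuple:
        return (*_chrom_sort_key(self.chrom), self.pos)


@dataclass(frozen=True)
class Junction:
    """A pair of oriented breakends fused by one rearrangement."""

    id: str
    bnd1: Breakend
    bnd2: Breakend
    imprecise: bool = False

    @staticmethod
    def make(id: str, bnd1: Breakend, bnd2: Breakend, imprecise: bool = False) -> "Junction":
        """Construct with canonical breakend order (idempotent)."""
        if bnd2.sort_key < bnd1.sort_key:
            bnd1, bnd2 = bnd2, bnd1
        return Junction(id, bnd1, bnd2, imprecise)

    @property
    def is_canonical(self) -> bool:
        return self.bnd1.sort_key <= self.bnd2.sort_key

    def canonical(self) -> "Junction":
        return Junction.make(self.id, self.bnd1, self.bnd2, self.imprecise)

    @property
    def intrachromosomal(self) -> bool:
        return self.bnd1.chrom == self.bnd2.chrom

    @property
    def size(self) -> int | None:
        """Span in bp, or None for inter-chromosomal junctions."""
        if not self.intrachromosomal:
            return None
        return abs(self.bnd2.pos - self.bnd1.pos)

    @property
    def chroms(self) -> set[str]:
        return {self.bnd1.chrom, self.bnd2.chrom}

    def orientation_class(self) -> OrientationClass:
        return junction_orientation_class(self)


def junction_orientation_class(j: Junction) -> OrientationClass:
    """Classify a canonical junction by its ordered orientation pair.

    Exactly one class applies to every junction: inter-chromosomal junctions
    map to INTERCHROM; intra-chromosomal ones map by (orient1, orient2) to
    DEL_like (+,-), DUP_like (-,+), INV_head (+,+) or INV_tail (-,-).
    """
    if not j.intrachromosomal:
        return OrientationClass.INTERCHROM
    pair = (j.bnd1.orient, j.bnd2.orient)
    return {
        ("+", "-"): OrientationClass.DEL_LIKE,
        ("-", "+"): OrientationClass.DUP_LIKE,
        ("+", "+"): OrientationClass.INV_HEAD,
        ("-", "-"): OrientationClass.INV_TAIL,
    }[pair]


@dataclass(frozen=True)
class EvidenceProfile:
    """Per-sample supporting evidence for one call."""

    caller_score: float = 0.0
    discordant_reads: int = 0
    clipped_reads_bnd1: int = 0
    clipped_reads_bnd2: int = 0
    vaf: float = 0.0
    flags: frozenset[Flag] = frozenset()

    def __post_init__(self) -> None:
        if min(self.discordant_reads, self.clipped_reads_bnd1, self.clipped_reads_bnd2) < 0:
            raise ValueError("read counts must be non-negative")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF must be in [0,1], got {self.vaf}")


PROBAND = "proband"
FATHER = "father"
MOTHER = "mother"


@dataclass(frozen=True)
class SVCall:
    """One caller record attached to a sample within a trio.

    ``evidence`` maps trio role ('proband', 'father', 'mother') to the
    evidence observed in that member's reads at this call's breakpoints.
    Simple calls carry one junction; reciprocal events carry two.
    """

    id: str
    junctions: tuple[Junction, ...]
    svtype: SVType
    sample_id: str
    family_id: str = ""
    evidence: dict[str, EvidenceProfile] = field(default_factory=dict)
    is_transduction: bool = False  # retrotransposon-mediated 3' transduction annotation

    @property
    def junction(self) -> Junction:
        return self.junctions[0]

    @property
    def size(self) -> int | None:
        return self.junction.size

    def canonical(self) -> "SVCall":
        return replace(self, junctions=tuple(j.canonical() for j in self.junctions))


@dataclass(frozen=True)
class CNSegment:
    """Integer copy-number state over a 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    copy_number: int
    sample_id: str = ""
    source: str = "read_depth"  # or "junction_inferred"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty CN segment [{self.start},{self.end})")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")


@dataclass(frozen=True)
class TrioRecord:
    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    sibling_ids: tuple[str, ...] = ()
    affected_status: str = "affected"
    disease_group: str = ""

    @property
    def member_ids(self) -> tuple[str, ...]:
        return (self.proband_id, self.father_id, self.mother_id, *self.sibling_ids)


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class SNPGenotypeRow:
    """One biallelic SNP site with trio genotypes and allele depths.

    ``genotypes`` and ``depths`` are keyed by trio role; depths are
    (ref_depth, alt_depth) pairs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    depths: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for role, (rd, ad) in self.depths.items():
            if rd < 0 or ad < 0:
                raise ValueError(f"negative allele depth for {role}")


@dataclass(frozen=True)
class AnalysisParams:
    """Every analysis threshold in one place.

    Defaults implement the candidate-to-high-confidence de novo cascade:
    minimum size 50 bp; a parental clipped-read veto (>=4 at either breakpoint
    or >=2 at both, in either parent); removal of junctions recurring in >=3
    samples; caller score > 30 with > 10 discordant reads among PASS/MGE10kb
    calls, with an IMPRECISE + colocalized-read-depth rescue; VAF >= 0.1.
    Phasing requires a winning-class site fraction > 0.9 with >= 3 supporting
    SNPs.  Genomic distance analyses use 5 Mb telomere bins and a 15 Mb
    subtelomere cutoff; enrichment uses 1000 permutation samples.
    """

    min_sv_len: int = 50
    max_parent_clip_either: int = 4
    max_parent_clip_both: int = 2
    recurrence_k: int = 3
    min_score: float = 30.0
    min_discordant: int = 10
    min_vaf: float = 0.1
    mge_len: int = 10_000
    timing_min_snps: int = 3
    timing_frac: float = 0.9
    telomere_bin: int = 5_000_000
    subtelomere_cutoff: int = 15_000_000
    enrich_windows: tuple[int, ...] = (5_000, 10_000, 25_000, 50_000, 500_000)
    enrich_samples: int = 1000
    detectability_exon_cutoff: int = 3
    # call matching (parent/child and cross-sample): same orientation class,
    # breakpoints within the window, and reciprocal overlap for intervals
    match_window: int = 200
    reciprocal_overlap: float = 0.5
    # clustering
    cluster_fdr_alpha: float = 0.05
    # classification geometry
    inv_span_tolerance: int = 1000        # reciprocal-inversion span agreement floor (bp)
    insertion_site_max_gap: int = 1000    # max site gap for an insertion-type event (bp)
    min_material_segment: int = 300       # profile segments below this are breakend-offset slivers
    rescue_window: int = 1_000_000        # breakpoint-rescue search radius (bp)
    # allele-fraction half-width for binning SNP support at CN=3 / CN=1 sites
    af_tolerance: float = 0.12
    exclude_chroms: tuple[str, ...] = ("chrY", "Y")

    def __post_init__(self) -> None:
        numeric = [
            self.min_sv_len, self.max_parent_clip_either, self.max_parent_clip_both,
            self.recurrence_k, self.min_score, self.min_discordant, self.min_vaf,
            self.mge_len, self.timing_min_snps, self.timing_frac, self.telomere_bin,
            self.subtelomere_cutoff, self.enrich_samples, self.detectability_exon_cutoff,
            self.match_window, self.cluster_fdr_alpha,
        ]
        if any(v <= 0 for v in numeric):
            raise ValueError("all analysis thresholds must be positive")
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0,1]")
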