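"""Synthetic trio cohorts with ground-truth de novo structural variants.

The generator emulates the observable layer of a short-read trio SV study:
per-call evidence profiles (caller score, discordant reads, parental
clipped reads, VAF, caller flags), true de novo events of every simple and
complex class, inherited SVs that reappear in a parent, recurrent artifact
junctions shared by unrelated samples, read-depth copy-number segments for
events large enough for a depth caller, and SNP allele balances over
duplicated/deleted regions consistent with parental origin and meiotic
timing.  It does not simulate reads; everything is generated at the
call/evidence level that the downstream pipeline consumes.

Default conditions mirror the study cohort: class weights follow the
observed counts of each resolvable class, parent of origin is paternal for
about two-thirds of events, 85% of maternal duplications arise at meiosis
II, and SNP allele depths are binomial at ~30x coverage.  Event sizes are
drawn log-uniformly per class within bounds scaled to the synthetic genome.

Everything is a pure function of the seed: the same configuration and seed
reproduce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as svio
from .genome import GenomeMap, synthetic_genome
from .classify import SVClass
from .model import (
    AnalysisParams,
    Breakend,
    CNSegment,
    EvidenceProfile,
    Flag,
    Genotype,
    Junction,
    SNPGenotypeRow,
    SVCall,
    SVType,
    TrioRecord,
)
from .phasing import Timing

# observed per-class event counts used as default class weights
DEFAULT_CLASS_WEIGHTS: dict[str, int] = {
    "DEL": 1377,
    "TANDEM_DUP": 245,
    "RECIPROCAL_INV": 49,
    "RECIPROCAL_TRA": 30,
    "TEMPLATED_INS": 6,
    "LOSS_LOSS": 18,
    "INV_LOSS": 14,
    "LOSS_INV_LOSS": 12,
    "LOSS_INVDUP": 14,
    "DUP_TRP_INV_DUP": 14,
    "DUP_NML_DUP": 7,
    "DUP_NML_DUP_NML_DUP": 3,
    "DELETION_BRIDGE": 7,
    "TRA_LOSS": 3,
    "DISPERSED_DUP": 8,
    "INVERTED_DUP": 2,
}

#: classes needing two chromosomes
INTERCHROM_CLASSES = {
    "RECIPROCAL_TRA", "TEMPLATED_INS", "DELETION_BRIDGE",
    "TRA_LOSS", "DISPERSED_DUP", "INVERTED_DUP",
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters; ``seed`` fully determines the output."""

    genome: GenomeMap = field(default_factory=lambda: synthetic_genome(3, 100_000_000))
    n_families: int = 20
    events_per_family: int = 1
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    # event-segment size bounds (log-uniform), bp
    min_segment: int = 5_000
    max_segment: int = 200_000
    min_simple_size: int = 5_000
    max_simple_size: int = 1_000_000
    # cohort contamination
    n_artifacts: int = 0                 # recurrent artifact junction groups
    artifact_recurrence: int = 3         # samples sharing each artifact
    inherited_per_family: int = 0
    # evidence model (true calls clear every threshold at default noise 0)
    score_range: tuple[float, float] = (40.0, 300.0)
    discordant_range: tuple[int, int] = (12, 60)
    vaf_range: tuple[float, float] = (0.3, 0.7)
    max_parent_clip_true: int = 1
    # SNP model for dosage regions
    snp_spacing: int = 2_000             # one SNP per this many bp
    depth: int = 30
    genotype_error_rate: float = 0.0
    maternal_fraction: float = 0.322     # ~67.8% paternal origin
    mii_fraction: float = 0.85           # maternal duplications from meiosis II
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_weights or min(self.class_weights.values()) < 0:
            raise ValueError("class weights must be non-negative and non-empty")
        if self.min_segment < 50:
            raise ValueError("segments must be >= 50 bp")


@dataclass(frozen=True)
class TruthRecord:
    event_id: str
    sample_id: str
    family_id: str
    true_class: str
    junctions: tuple[Junction, ...]
    cn_segments: tuple[CNSegment, ...]
    parent_of_origin: str = "none"       # maternal | paternal | none
    timing: str = Timing.NA.value        # MI | MII | NA
    is_denovo: bool = True
    is_artifact: bool = False
    is_inherited: bool = False

    def __post_init__(self) -> None:
        if sum([self.is_denovo, self.is_artifact, self.is_inherited]) != 1:
            raise ValueError("exactly one of denovo/artifact/inherited must hold")

    @property
    def gain_region(self) -> tuple[str, int, int] | None:
        for seg in self.cn_segments:
            if seg.copy_number > 2:
                return (seg.chrom, seg.start, seg.end)
        return None

    @property
    def loss_region(self) -> tuple[str, int, int] | None:
        for seg in self.cn_segments:
            if seg.copy_number < 2:
                return (seg.chrom, seg.start, seg.end)
        return None


@dataclass
class SimulatedCohort:
    config: SimConfig
    trios: list[TrioRecord]
    # proband candidate calls (true + inherited + artifacts), by sample id
    calls_by_proband: dict[str, list[SVCall]]
    # parental call sets keyed by proband id: (father calls, mother calls)
    parental_calls: dict[str, tuple[list[SVCall], list[SVCall]]]
    # read-depth CN segments per proband
    cn_by_proband: dict[str, list[CNSegment]]
    # SNP rows per family
    snps_by_family: dict[str, list[SNPGenotypeRow]]
    truth: list[TruthRecord]

    def truth_denovo_ids(self) -> set[str]:
        return {t.event_id for t in self.truth if t.is_denovo}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        svio.write_manifest(self.trios, outdir / "manifest.tsv")
        for trio in self.trios:
            pid = trio.proband_id
            svio.write_bedpe(self.calls_by_proband[pid], outdir / f"{pid}.bedpe")
            fa, mo = self.parental_calls[pid]
            svio.write_bedpe(fa, outdir / f"{trio.father_id}.bedpe")
            svio.write_bedpe(mo, outdir / f"{trio.mother_id}.bedpe")
            svio.write_cn_bed(self.cn_by_proband[pid], outdir / f"{pid}.cn.bed")
            svio.write_snp_table(
                self.snps_by_family[trio.family_id], outdir / f"{trio.family_id}.snps.tsv"
            )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "event_id\tsample_id\tfamily_id\ttrue_class\torigin\ttiming\t"
                "is_denovo\tis_artifact\tis_inherited\tjunctions\n"
            )
            for t in self.truth:
                jtxt = ";".join(
                    f"{j.bnd1.chrom}:{j.bnd1.pos}{j.bnd1.orient}-"
                    f"{j.bnd2.chrom}:{j.bnd2.pos}{j.bnd2.orient}"
                    for j in t.junctions
                )
                fh.write(
                    f"{t.event_id}\t{t.sample_id}\t{t.family_id}\t{t.true_class}\t"
                    f"{t.parent_of_origin}\t{t.timing}\t{int(t.is_denovo)}\t"
                    f"{int(t.is_artifact)}\t{int(t.is_inherited)}\t{jtxt}\n"
                )


def load_cohort(indir: str | Path, genome: GenomeMap | None = None) -> SimulatedCohort:
    """Load a cohort directory written by :meth:`SimulatedCohort.write`.

    Ground truth is loaded when a truth.tsv is present (junction geometry is
    not reconstructed from the truth file; ids and labels are)."""
    indir = Path(indir)
    trios = svio.read_manifest(indir / "manifest.tsv")
    config = SimConfig(genome=genome or synthetic_genome(3, 100_000_000),
                       n_families=len(trios))
    calls_by_proband: dict[str, list[SVCall]] = {}
    parental: dict[str, tuple[list[SVCall], list[SVCall]]] = {}
    cn_by_proband: dict[str, list[CNSegment]] = {}
    snps_by_family: dict[str, list[SNPGenotypeRow]] = {}
    for trio in trios:
        pid = trio.proband_id
        calls_by_proband[pid] = svio.read_bedpe(indir / f"{pid}.bedpe", sample_id=pid)
        fa = svio.read_bedpe(indir / f"{trio.father_id}.bedpe", sample_id=trio.father_id)
        mo = svio.read_bedpe(indir / f"{trio.mother_id}.bedpe", sample_id=trio.mother_id)
        parental[pid] = (fa, mo)
        cn_path = indir / f"{pid}.cn.bed"
        cn_by_proband[pid] = svio.read_cn_bed(cn_path) if cn_path.exists() else []
        snp_path = indir / f"{trio.family_id}.snps.tsv"
        snps_by_family[trio.family_id] = (
            svio.read_snp_table(snp_path) if snp_path.exists() else []
        )
    truth: list[TruthRecord] = []
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                truth.append(
                    TruthRecord(
                        event_id=f[0], sample_id=f[1], family_id=f[2], true_class=f[3],
                        parent_of_origin=f[4], timing=f[5], junctions=(), cn_segments=(),
                        is_denovo=f[6] == "1", is_artifact=f[7] == "1",
                        is_inherited=f[8] == "1",
                    )
                )
    return SimulatedCohort(
        config=config, trios=trios, calls_by_proband=calls_by_proband,
        parental_calls=parental, cn_by_proband=cn_by_proband,
        snps_by_family=snps_by_family, truth=truth,
    )


# ---------------------------------------------------------------------------
# event construction


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> int:
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_complex_event(
    subtype: str,
    locus: tuple[str, int],
    sizes: list[int],
    rng: np.random.Generator,
    event_id: str = "ev",
    second_chrom: tuple[str, int] | None = None,
) -> tuple[list[Junction], list[CNSegment]]:
    """Junctions and true CN segments for one event of ``subtype``.

    ``locus`` is (chrom, start) of the primary breakpoint region; ``sizes``
    supplies segment lengths (consumed left to right; missing entries are
    drawn 5-50 kb).  Inter-chromosomal subtypes take the donor/partner locus
    in ``second_chrom``.  The emitted junction orientation multiset and CN
    profile are the class's defining signature.
    """
    chrom, s = locus
    sizes = list(sizes)

    def nxt() -> int:
        return sizes.pop(0) if sizes else _log_uniform(rng, 5_000, 50_000)

    def jx(n: int, b1: Breakend, b2: Breakend) -> Junction:
        return Junction.make(f"{event_id}_j{n}", b1, b2)

    def cn(c: str, a: int, b: int, state: int) -> CNSegment:
        return CNSegment(c, a, b, state, source="read_depth")

    if subtype in INTERCHROM_CLASSES:
        if second_chrom is None:
            raise ValueError(f"{subtype} requires a second chromosome locus")
        chrom_b, t = second_chrom

    if subtype == "DEL":
        L = nxt()
        return [jx(1, Breakend(chrom, s, "+"), Breakend(chrom, s + L, "-"))], [
            cn(chrom, s, s + L, 1)
        ]
    if subtype == "TANDEM_DUP":
        L = nxt()
        return [jx(1, Breakend(chrom, s, "-"), Breakend(chrom, s + L, "+"))], [
            cn(chrom, s, s + L, 3)
        ]
    if subtype == "RECIPROCAL_INV":
        L = nxt()
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom, s + L, "+")),
            jx(2, Breakend(chrom, s, "-"), Breakend(chrom, s + L, "-")),
        ], []
    if subtype == "LOSS_LOSS":
        l1, gap, l2 = nxt(), nxt(), nxt()
        a, b = s, s + l1
        c, d = b + gap, b + gap + l2
        return [
            jx(1, Breakend(chrom, a, "+"), Breakend(chrom, b, "-")),
            jx(2, Breakend(chrom, c, "+"), Breakend(chrom, d, "-")),
        ], [cn(chrom, a, b, 1), cn(chrom, c, d, 1)]
    if subtype == "INV_LOSS":
        l1, l2 = nxt(), nxt()
        a, c, d = s, s + l1, s + l1 + l2
        return [
            jx(1, Breakend(chrom, a, "+"), Breakend(chrom, c, "+")),
            jx(2, Breakend(chrom, a, "-"), Breakend(chrom, d, "-")),
        ], [cn(chrom, c, d, 1)]
    if subtype == "LOSS_INV_LOSS":
        l1, l2, l3 = nxt(), nxt(), nxt()
        a, b, c, d = s, s + l1, s + l1 + l2, s + l1 + l2 + l3
        return [
            jx(1, Breakend(chrom, a, "+"), Breakend(chrom, c, "+")),
            jx(2, Breakend(chrom, b, "-"), Breakend(chrom, d, "-")),
        ], [cn(chrom, a, b, 1), cn(chrom, c, d, 1)]
    if subtype == "LOSS_INVDUP":
        l1, l2, l3 = nxt(), nxt(), nxt()
        a, b, c, d = s, s + l1, s + l1 + l2, s + l1 + l2 + l3
        return [
            jx(1, Breakend(chrom, a, "+"), Breakend(chrom, d, "+")),
            jx(2, Breakend(chrom, b, "-"), Breakend(chrom, c, "-")),
        ], [cn(chrom, a, b, 1), cn(chrom, c, d, 3)]
    if subtype == "DUP_TRP_INV_DUP":
        l1, l2, l3 = nxt(), nxt(), nxt()
        a, b, c, d = s, s + l1, s + l1 + l2, s + l1 + l2 + l3
        return [
            jx(1, Breakend(chrom, a, "-"), Breakend(chrom, b, "-")),
            jx(2, Breakend(chrom, c, "+"), Breakend(chrom, d, "+")),
        ], [cn(chrom, a, b, 3), cn(chrom, b, c, 4), cn(chrom, c, d, 3)]
    if subtype == "DUP_NML_DUP":
        l1, l2, l3 = nxt(), nxt(), nxt()
        a, b, c, d = s, s + l1, s + l1 + l2, s + l1 + l2 + l3
        return [
            jx(1, Breakend(chrom, a, "-"), Breakend(chrom, c, "-")),
            jx(2, Breakend(chrom, b, "+"), Breakend(chrom, d, "+")),
        ], [cn(chrom, a, b, 3), cn(chrom, c, d, 3)]
    if subtype == "DUP_NML_DUP_NML_DUP":
        l1, l2, l3, l4, l5 = (nxt() for _ in range(5))
        a = s
        b = a + l1
        c = b + l2
        d = c + l3
        e = d + l4
        f = e + l5
        return [
            jx(1, Breakend(chrom, a, "-"), Breakend(chrom, b, "+")),
            jx(2, Breakend(chrom, c, "-"), Breakend(chrom, e, "-")),
            jx(3, Breakend(chrom, d, "+"), Breakend(chrom, f, "+")),
        ], [cn(chrom, a, b, 3), cn(chrom, c, d, 3), cn(chrom, e, f, 3)]
    if subtype == "RECIPROCAL_TRA":
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t, "-")),
            jx(2, Breakend(chrom, s, "-"), Breakend(chrom_b, t, "+")),
        ], []
    if subtype == "TEMPLATED_INS":
        lt = sizes.pop(0) if sizes else int(rng.integers(500, 2_000))
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t, "-")),
            jx(2, Breakend(chrom, s, "-"), Breakend(chrom_b, t + lt, "+")),
        ], []
    if subtype == "DISPERSED_DUP":
        # donor must be visible to a read-depth caller (> 10 kb)
        lt = sizes.pop(0) if sizes else _log_uniform(rng, 20_000, 200_000)
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t, "-")),
            jx(2, Breakend(chrom, s, "-"), Breakend(chrom_b, t + lt, "+")),
        ], [cn(chrom_b, t, t + lt, 3)]
    if subtype == "INVERTED_DUP":
        lt = sizes.pop(0) if sizes else _log_uniform(rng, 20_000, 200_000)
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t + lt, "+")),
            jx(2, Breakend(chrom, s, "-"), Breakend(chrom_b, t, "-")),
        ], [cn(chrom_b, t, t + lt, 3)]
    if subtype == "DELETION_BRIDGE":
        la = nxt()
        lt = sizes.pop(0) if sizes else int(rng.integers(500, 2_000))
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t, "-")),
            jx(2, Breakend(chrom, s + la, "-"), Breakend(chrom_b, t + lt, "+")),
        ], [cn(chrom, s, s + la, 1)]
    if subtype == "TRA_LOSS":
        la, lb = nxt(), nxt()
        # losses on both chromosomes: '+' precedes '-' in position on each
        return [
            jx(1, Breakend(chrom, s, "+"), Breakend(chrom_b, t + lb, "-")),
            jx(2, Breakend(chrom, s + la, "-"), Breakend(chrom_b, t, "+")),
        ], [cn(chrom, s, s + la, 1), cn(chrom_b, t, t + lb, 1)]
    raise ValueError(f"unknown subtype {subtype!r}")


def event_extent(subtype: str, n_segments_hint: int = 6) -> int:
    """Conservative bp budget an event of ``subtype`` may occupy."""
    return 6 * 200_000


# ---------------------------------------------------------------------------
# SNP simulation


def simulate_duplication_snps(
    dup_region: tuple[str, int, int],
    origin: str,
    timing: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SNPGenotypeRow]:
    """Trio SNP rows over a CN=3 duplication, consistent with its origin and
    meiotic timing.

    Sites alternate between origin-informative configurations (parents are
    opposite homozygotes) and timing-informative ones (mother het, father
    hom).  Proband allele depths are binomial at the configured coverage
    around the dosage-expected allele fraction; with probability
    ``genotype_error_rate`` a site is drawn from the opposite class's
    expected fraction (a flipped support label).
    """
    return _simulate_region_snps(dup_region, "duplication", origin, timing, config, rng)


def simulate_deletion_snps(
    del_region: tuple[str, int, int],
    origin: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SNPGenotypeRow]:
    """Trio SNP rows over a hemizygous deletion (origin-informative only)."""
    return _simulate_region_snps(del_region, "deletion", origin, Timing.NA.value, config, rng)


def _depths(rng: np.random.Generator, frac: float, depth: int) -> tuple[int, int]:
    total = max(int(rng.poisson(depth)), 8)
    alt = int(rng.binomial(total, min(max(frac, 0.0), 1.0)))
    return (total - alt, alt)


def _simulate_region_snps(
    region: tuple[str, int, int],
    kind: str,
    origin: str,
    timing: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SNPGenotypeRow]:
    chrom, start, end = region
    positions = list(range(start + config.snp_spacing // 2, end, config.snp_spacing))
    rows: list[SNPGenotypeRow] = []
    err = config.genotype_error_rate
    for i, pos in enumerate(positions):
        flip = rng.random() < err
        if i % 2 == 0:
            # origin-informative: mother hom-alt, father hom-ref
            gt = {"mother": Genotype.HOM_ALT, "father": Genotype.HOM_REF}
            if kind == "duplication":
                frac = 2 / 3 if origin == "maternal" else 1 / 3
                if flip:
                    frac = 1.0 - frac
            else:  # deletion: surviving allele from the retained parent
                frac = 0.0 if origin == "maternal" else 1.0
                if flip:
                    frac = 1.0 - frac
            gt["proband"] = _gt_from_frac(frac)
            rows.append(
                SNPGenotypeRow(
                    chrom=chrom, pos=pos, ref="A", alt="B",
                    genotypes=gt,
                    depths={
                        "proband": _depths(rng, frac, config.depth),
                        "father": _depths(rng, 0.0, config.depth),
                        "mother": _depths(rng, 1.0, config.depth),
                    },
                )
            )
        else:
            if kind != "duplication":
                continue
            # timing-informative: mother het, father hom-ref
            gt = {"mother": Genotype.HET, "father": Genotype.HOM_REF}
            if origin == "maternal" and timing == Timing.MI.value:
                frac = 1 / 3
                if flip:
                    frac = float(rng.choice([0.0, 2 / 3]))
            elif origin == "maternal" and timing == Timing.MII.value:
                frac = float(rng.choice([0.0, 2 / 3]))
                if flip:
                    frac = 1 / 3
            else:
                # paternal duplication: maternal transmit A or B, father's A doubled
                frac = float(rng.choice([0.0, 1 / 3]))
            gt["proband"] = _gt_from_frac(frac)
            rows.append(
                SNPGenotypeRow(
                    chrom=chrom, pos=pos, ref="A", alt="B",
                    genotypes=gt,
                    depths={
                        "proband": _depths(rng, frac, config.depth),
                        "father": _depths(rng, 0.0, config.depth),
                        "mother": _depths(rng, 0.5, config.depth),
                    },
                )
            )
    return rows


def _gt_from_frac(frac: float) -> Genotype:
    if frac <= 0.05:
        return Genotype.HOM_REF
    if frac >= 0.95:
        return Genotype.HOM_ALT
    return Genotype.HET


# ---------------------------------------------------------------------------
# cohort assembly


def _true_evidence(config: SimConfig, rng: np.random.Generator) -> dict[str, EvidenceProfile]:
    flags = frozenset({Flag.PASS})
    return {
        "proband": EvidenceProfile(
            caller_score=round(float(rng.uniform(*config.score_range)), 1),
            discordant_reads=int(rng.integers(*config.discordant_range)),
            clipped_reads_bnd1=int(rng.integers(5, 30)),
            clipped_reads_bnd2=int(rng.integers(5, 30)),
            vaf=round(float(rng.uniform(*config.vaf_range)), 3),
            flags=flags,
        ),
        "father": EvidenceProfile(
            clipped_reads_bnd1=int(rng.integers(0, config.max_parent_clip_true + 1)),
            clipped_reads_bnd2=int(rng.integers(0, config.max_parent_clip_true + 1)),
        ),
        "mother": EvidenceProfile(
            clipped_reads_bnd1=int(rng.integers(0, config.max_parent_clip_true + 1)),
            clipped_reads_bnd2=int(rng.integers(0, config.max_parent_clip_true + 1)),
        ),
    }


def _svtype_for(subtype: str) -> SVType:
    return {
        "DEL": SVType.DEL,
        "TANDEM_DUP": SVType.DUP,
        "RECIPROCAL_INV": SVType.INV,
        "RECIPROCAL_TRA": SVType.TRA,
        "TEMPLATED_INS": SVType.INS,
    }.get(subtype, SVType.BND)


class _Placer:
    """Non-overlapping event placement on a genome, deterministic per rng."""

    def __init__(self, genome: GenomeMap, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
        self.chroms = sorted(genome.chrom_names)

    def place(self, extent: int, exclude_chrom: str | None = None) -> tuple[str, int]:
        candidates = [
            c for c in self.chroms
            if c != exclude_chrom and self.genome.chrom_lengths[c] > 2 * extent + 2_000_000
        ]
        if not candidates:
            raise ValueError(f"no chromosome can hold an event of extent {extent}")
        for _ in range(200):
            chrom = candidates[int(self.rng.integers(len(candidates)))]
            length = self.genome.chrom_lengths[chrom]
            start = int(self.rng.integers(1_000_000, length - extent - 1_000_000))
            span = (start - 50_000, start + extent + 50_000)
            if all(hi <= span[0] or lo >= span[1] for lo, hi in self.used[chrom]):
                self.used[chrom].append(span)
                return chrom, start
        raise ValueError("placement failed: genome too crowded for requested events")


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full trio cohort with ground truth.

    Every true de novo call carries parental evidence with 0-1 clipped
    reads; inherited calls reproduce the proband junction in one parent's
    call set with >= 4 clipped reads at a breakpoint; each artifact junction
    is emitted in at least ``artifact_recurrence`` unrelated probands.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    classes = sorted(config.class_weights)
    weights = np.array([config.class_weights[c] for c in classes], dtype=float)
    weights = weights / weights.sum()

    trios = [
        TrioRecord(
            family_id=f"F{i:04d}", proband_id=f"F{i:04d}_P",
            father_id=f"F{i:04d}_F", mother_id=f"F{i:04d}_M",
            disease_group="synthetic",
        )
        for i in range(config.n_families)
    ]

    placer = _Placer(genome, rng)
    calls_by_proband: dict[str, list[SVCall]] = {t.proband_id: [] for t in trios}
    parental: dict[str, tuple[list[SVCall], list[SVCall]]] = {
        t.proband_id: ([], []) for t in trios
    }
    cn_by_proband: dict[str, list[CNSegment]] = {t.proband_id: [] for t in trios}
    snps_by_family: dict[str, list[SNPGenotypeRow]] = {t.family_id: [] for t in trios}
    truth: list[TruthRecord] = []
    counter = 0

    for trio in trios:
        for _ in range(config.events_per_family):
            subtype = classes[int(rng.choice(len(classes), p=weights))]
            counter += 1
            event_id = f"dn{counter:05d}"
            truth.append(
                _emit_denovo(
                    subtype, event_id, trio, config, rng, placer,
                    calls_by_proband, cn_by_proband, snps_by_family,
                )
            )

        for k in range(config.inherited_per_family):
            counter += 1
            truth.append(
                _emit_inherited(
                    f"inh{counter:05d}", trio, config, rng, placer,
                    calls_by_proband, parental,
                )
            )

    # recurrent artifacts across unrelated probands
    for a in range(config.n_artifacts):
        counter += 1
        truth.append(
            _emit_artifact(
                f"art{counter:05d}", trios, config, rng, placer, calls_by_proband
            )
        )

    # deterministic per-sample ordering
    for pid in calls_by_proband:
        calls_by_proband[pid].sort(key=lambda c: c.id)
        cn_by_proband[pid].sort(key=lambda s: (s.chrom, s.start))

    return SimulatedCohort(
        config=config, trios=trios, calls_by_proband=calls_by_proband,
        parental_calls=parental, cn_by_proband=cn_by_proband,
        snps_by_family=snps_by_family, truth=truth,
    )


def simulate_filter_stress(
    n_calls: int,
    n_samples: int = 30,
    genome: GenomeMap | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[SVCall]], dict[str, tuple[list[SVCall], list[SVCall]]]]:
    """Candidate calls whose evidence straddles every filter threshold.

    Sizes hover around the 50 bp minimum, scores around 30, discordant reads
    around 10, clipped reads around the 2/4 parental rules, VAF around 0.1,
    flag sets are random subsets, a fraction of junctions recur across
    samples and a fraction match a planted parental call — so a filter
    implementation is exercised on both sides of every boundary.
    """
    rng = np.random.default_rng(seed)
    genome = genome or synthetic_genome(3, 100_000_000)
    chroms = sorted(genome.chrom_lengths) + ["chrY"]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    calls: dict[str, list[SVCall]] = {s: [] for s in samples}
    parental: dict[str, tuple[list[SVCall], list[SVCall]]] = {
        s: ([], []) for s in samples
    }

    # pool of junctions reused across samples to trip the recurrence rule
    shared = []
    for i in range(max(2, n_calls // 50)):
        pos = int(rng.integers(1_000_000, 50_000_000))
        size = int(rng.integers(5_000, 50_000))
        shared.append((f"chr{int(rng.integers(1, 3)) + 1}", pos, size))

    all_flags = [Flag.PASS, Flag.MGE10kb, Flag.IMPRECISE, Flag.COLOCALIZED_RD]
    for i in range(n_calls):
        sample = samples[int(rng.integers(n_samples))]
        if rng.random() < 0.15:
            chrom, pos, size = shared[int(rng.integers(len(shared)))]
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            if chrom == "chrY":
                chrom_len = 57_000_000
            else:
                chrom_len = genome.chrom_lengths[chrom]
            pos = int(rng.integers(1_000_000, chrom_len - 1_000_000))
            size = int(rng.integers(40, 60)) if rng.random() < 0.3 else int(
                rng.integers(60, 100_000)
            )
        j = Junction.make(
            f"q{i:05d}", Breakend(chrom, pos, "+"), Breakend(chrom, pos + size, "-")
        )
        flags = frozenset(
            f for f in all_flags if rng.random() < 0.5
        )
        ev = {
            "proband": EvidenceProfile(
                caller_score=float(rng.integers(25, 36)),
                discordant_reads=int(rng.integers(8, 14)),
                clipped_reads_bnd1=int(rng.integers(0, 30)),
                clipped_reads_bnd2=int(rng.integers(0, 30)),
                vaf=round(float(rng.uniform(0.05, 0.15)), 3),
                flags=flags,
            ),
            "father": EvidenceProfile(
                clipped_reads_bnd1=int(rng.integers(0, 6)),
                clipped_reads_bnd2=int(rng.integers(0, 6)),
            ),
            "mother": EvidenceProfile(
                clipped_reads_bnd1=int(rng.integers(0, 6)),
                clipped_reads_bnd2=int(rng.integers(0, 6)),
            ),
        }
        call = SVCall(
            id=j.id, junctions=(j,), svtype=SVType.DEL, sample_id=sample,
            evidence=ev, is_transduction=rng.random() < 0.03,
        )
        calls[sample].append(call)
        if rng.random() < 0.1 and chrom != "chrY":
            parent_call = SVCall(
                id=f"{j.id}_p", junctions=(j,), svtype=SVType.DEL,
                sample_id=f"{sample}_parent",
                evidence={"proband": ev["proband"]},
            )
            fa, mo = parental[sample]
            (fa if rng.random() < 0.5 else mo).append(parent_call)
    return calls, parental


def _emit_denovo(
    subtype: str,
    event_id: str,
    trio: TrioRecord,
    config: SimConfig,
    rng: np.random.Generator,
    placer: _Placer,
    calls_by_proband: dict[str, list[SVCall]],
    cn_by_proband: dict[str, list[CNSegment]],
    snps_by_family: dict[str, list[SNPGenotypeRow]],
) -> TruthRecord:
    extent = max(6 * config.max_segment, config.max_simple_size)
    chrom, start = placer.place(extent)
    second = None
    if subtype in INTERCHROM_CLASSES:
        c2, t2 = placer.place(extent, exclude_chrom=chrom)
        second = (c2, t2)
    sizes: list[int] = []
    if subtype in ("DEL", "TANDEM_DUP"):
        sizes = [_log_uniform(rng, config.min_simple_size, config.max_simple_size)]
        if sizes[0] > config.genome.chrom_lengths[chrom] // 4:
            sizes[0] = config.genome.chrom_lengths[chrom] // 4
    elif subtype in ("TEMPLATED_INS", "DISPERSED_DUP", "INVERTED_DUP"):
        sizes = []  # template/donor lengths have class-specific defaults
    elif subtype == "DELETION_BRIDGE":
        sizes = [_log_uniform(rng, config.min_segment, config.max_segment)]
    else:
        sizes = [
            _log_uniform(rng, config.min_segment, config.max_segment) for _ in range(6)
        ]
    junctions, cn_segs = make_complex_event(
        subtype, (chrom, start), sizes, rng, event_id=event_id, second_chrom=second
    )

    origin = "maternal" if rng.random() < config.maternal_fraction else "paternal"
    timing = Timing.NA.value
    cn_segs = tuple(replace(s, sample_id=trio.proband_id) for s in cn_segs)
    gain = next((s for s in cn_segs if s.copy_number > 2), None)
    loss = next((s for s in cn_segs if s.copy_number < 2), None)
    if gain is not None:
        if origin == "maternal":
            timing = (
                Timing.MII.value if rng.random() < config.mii_fraction else Timing.MI.value
            )
        snps_by_family[trio.family_id].extend(
            simulate_duplication_snps(
                (gain.chrom, gain.start, gain.end), origin, timing, config, rng
            )
        )
    elif loss is not None:
        snps_by_family[trio.family_id].extend(
            simulate_deletion_snps((loss.chrom, loss.start, loss.end), origin, config, rng)
        )

    for i, j in enumerate(junctions):
        size = j.size
        ev = _true_evidence(config, rng)
        if size is not None and size < AnalysisParams().mge_len:
            prof = ev["proband"]
            ev["proband"] = replace(prof, flags=frozenset({Flag.PASS, Flag.MGE10kb}))
        calls_by_proband[trio.proband_id].append(
            SVCall(
                id=j.id, junctions=(j,), svtype=_svtype_for(subtype),
                sample_id=trio.proband_id, family_id=trio.family_id, evidence=ev,
            )
        )
    # read-depth segments only where a depth caller would see them (>10 kb)
    cn_by_proband[trio.proband_id].extend(
        s for s in cn_segs if s.end - s.start > AnalysisParams().mge_len
    )
    return TruthRecord(
        event_id=event_id, sample_id=trio.proband_id, family_id=trio.family_id,
        true_class=subtype, junctions=tuple(junctions), cn_segments=cn_segs,
        parent_of_origin=origin, timing=timing,
        is_denovo=True, is_artifact=False, is_inherited=False,
    )


def _emit_inherited(
    event_id: str,
    trio: TrioRecord,
    config: SimConfig,
    rng: np.random.Generator,
    placer: _Placer,
    calls_by_proband: dict[str, list[SVCall]],
    parental: dict[str, tuple[list[SVCall], list[SVCall]]],
) -> TruthRecord:
    chrom, start = placer.place(2 * config.max_segment)
    size = _log_uniform(rng, config.min_simple_size, config.max_simple_size // 10)
    junctions, _ = make_complex_event("DEL", (chrom, start), [size], rng, event_id=event_id)
    j = junctions[0]
    carrier = "father" if rng.random() < 0.5 else "mother"
    ev = _true_evidence(config, rng)
    # the transmitting parent shows the junction in its own reads
    ev[carrier] = EvidenceProfile(
        clipped_reads_bnd1=int(rng.integers(4, 20)),
        clipped_reads_bnd2=int(rng.integers(0, 3)),
    )
    calls_by_proband[trio.proband_id].append(
        SVCall(
            id=j.id, junctions=(j,), svtype=SVType.DEL,
            sample_id=trio.proband_id, family_id=trio.family_id, evidence=ev,
        )
    )
    parent_call = SVCall(
        id=f"{event_id}_parent", junctions=(j,), svtype=SVType.DEL,
        sample_id=trio.father_id if carrier == "father" else trio.mother_id,
        family_id=trio.family_id,
        evidence={"proband": _true_evidence(config, rng)["proband"]},
    )
    fa, mo = parental[trio.proband_id]
    (fa if carrier == "father" else mo).append(parent_call)
    return TruthRecord(
        event_id=event_id, sample_id=trio.proband_id, family_id=trio.family_id,
        true_class="DEL", junctions=tuple(junctions), cn_segments=(),
        is_denovo=False, is_artifact=False, is_inherited=True,
    )


def _emit_artifact(
    event_id: str,
    trios: list[TrioRecord],
    config: SimConfig,
    rng: np.random.Generator,
    placer: _Placer,
    calls_by_proband: dict[str, list[SVCall]],
) -> TruthRecord:
    chrom, start = placer.place(2 * config.max_segment)
    size = _log_uniform(rng, config.min_simple_size, config.max_simple_size // 10)
    junctions, _ = make_complex_event("DEL", (chrom, start), [size], rng, event_id=event_id)
    j = junctions[0]
    k = min(max(config.artifact_recurrence, AnalysisParams().recurrence_k), len(trios))
    chosen = rng.choice(len(trios), size=k, replace=False)
    first_trio = trios[int(sorted(chosen)[0])]
    for idx in sorted(chosen):
        trio = trios[int(idx)]
        calls_by_proband[trio.proband_id].append(
            SVCall(
                id=f"{event_id}_{trio.proband_id}", junctions=(j,), svtype=SVType.DEL,
                sample_id=trio.proband_id, family_id=trio.family_id,
                evidence=_true_evidence(config, rng),
            )
        )
    return TruthRecord(
        event_id=event_id, sample_id=first_trio.proband_id,
        family_id=first_trio.family_id, true_class="DEL",
        junctions=tuple(junctions), cn_segments=(),
        is_denovo=False, is_artifact=True, is_inherited=False,
    )
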