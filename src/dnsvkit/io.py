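"""Readers and writers for the pipeline's text formats.

Formats
-------
* BEDPE (10 columns + key=value attribute column) for SV calls.  Breakend
  positions are the ``end`` coordinates of the two BEDPE intervals; strands
  follow the retained-side convention of :mod:`dnsvkit.model`.
* BED4(+2) for copy-number segments: chrom, start, end, copy_number
  [, sample_id, source].
* TSV manifest for trio cohorts: family_id, proband_id, father_id, mother_id,
  sibling_ids (comma-separated, may be empty), affected_status, disease_group.
* TSV SNP table: chrom, pos, ref, alt, then GT_<role> and AD_<role>
  (ref,alt) columns per trio role.

Attribute keys in the BEDPE extra column: SVTYPE, SCORE, DR, VAF, FLAGS and
CR1_/CR2_ clipped-read counts per trio role; absent keys default to zero /
empty.  All round-trips are lossless for the fields defined in the model.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from .genome import GenomeMap
from .model import (
    Breakend,
    CNSegment,
    EvidenceProfile,
    FATHER,
    Flag,
    Genotype,
    Junction,
    MOTHER,
    PROBAND,
    SNPGenotypeRow,
    SVCall,
    SVType,
    TrioRecord,
)

ROLES = (PROBAND, FATHER, MOTHER)


class FormatError(ValueError):
    """Malformed input; carries the offending file and line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _parse_attrs(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if field in (".", ""):
        return attrs
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"attribute {item!r} is not key=value")
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def _evidence_from_attrs(attrs: dict[str, str], role: str) -> EvidenceProfile:
    suffix = "" if role == PROBAND else f"_{role.upper()}"
    flags: frozenset[Flag] = frozenset()
    if attrs.get(f"FLAGS{suffix}"):
        flags = frozenset(Flag(f) for f in attrs[f"FLAGS{suffix}"].split(",") if f)
    return EvidenceProfile(
        caller_score=float(attrs.get(f"SCORE{suffix}", 0.0)),
        discordant_reads=int(attrs.get(f"DR{suffix}", 0)),
        clipped_reads_bnd1=int(attrs.get(f"CR1{suffix}", 0)),
        clipped_reads_bnd2=int(attrs.get(f"CR2{suffix}", 0)),
        vaf=float(attrs.get(f"VAF{suffix}", 0.0)),
        flags=flags,
    )


def _attrs_from_call(call: SVCall) -> str:
    items = [f"SVTYPE={call.svtype.value}"]
    for role in ROLES:
        if role not in call.evidence:
            continue
        ev = call.evidence[role]
        suffix = "" if role == PROBAND else f"_{role.upper()}"
        items.append(f"SCORE{suffix}={ev.caller_score:g}")
        items.append(f"DR{suffix}={ev.discordant_reads}")
        items.append(f"CR1{suffix}={ev.clipped_reads_bnd1}")
        items.append(f"CR2{suffix}={ev.clipped_reads_bnd2}")
        items.append(f"VAF{suffix}={ev.vaf:g}")
        if ev.flags:
            items.append(f"FLAGS{suffix}=" + ",".join(sorted(f.value for f in ev.flags)))
    if call.family_id:
        items.append(f"FAMILY={call.family_id}")
    if call.is_transduction:
        items.append("TRANSDUCTION=1")
    if call.junction.imprecise:
        items.append("IMPRECISE_J=1")
    return ";".join(items)


def read_bedpe(
    path: str | os.PathLike,
    sample_id: str = "",
    genome: GenomeMap | None = None,
    drop_chroms: Sequence[str] = (),
) -> list[SVCall]:
    """Read SV calls from a 10+ column BEDPE file.

    Each line yields one call with one canonical junction.  ``drop_chroms``
    removes calls touching the named chromosomes at load time (used for the
    chrY exclusion).  If ``genome`` is given, chromosome names and positions
    are validated against it.
    """
    calls: list[SVCall] = []
    drop = set(drop_chroms)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(path, lineno, f"expected >=10 columns, got {len(fields)}")
            try:
                c1, s1, e1, c2, s2, e2, name, _score, o1, o2 = fields[:10]
                pos1, pos2 = int(e1), int(e2)
                int(s1), int(s2)
                attrs = _parse_attrs(fields[10]) if len(fields) > 10 else {}
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if genome is not None:
                for chrom, pos in ((c1, pos1), (c2, pos2)):
                    if chrom not in genome.chrom_lengths:
                        raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
                    if pos > genome.chrom_lengths[chrom]:
                        raise FormatError(path, lineno, f"position {pos} beyond {chrom}")
            if c1 in drop or c2 in drop:
                continue
            try:
                junction = Junction.make(
                    name,
                    Breakend(c1, pos1, o1),
                    Breakend(c2, pos2, o2),
                    imprecise=attrs.get("IMPRECISE_J", "0") == "1",
                )
                svtype = SVType(attrs.get("SVTYPE", "BND"))
                evidence = {
                    role: _evidence_from_attrs(attrs, role)
                    for role in ROLES
                    if role == PROBAND or any(k.endswith(f"_{role.upper()}") for k in attrs)
                }
                calls.append(
                    SVCall(
                        id=name,
                        junctions=(junction,),
                        svtype=svtype,
                        sample_id=sample_id or attrs.get("SAMPLE", ""),
                        family_id=attrs.get("FAMILY", ""),
                        evidence=evidence,
                        is_transduction=attrs.get("TRANSDUCTION", "0") == "1",
                    )
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return calls


def write_bedpe(calls: Iterable[SVCall], path: str | os.PathLike) -> None:
    """Write calls as BEDPE (one line per junction-bearing call)."""
    with open(path, "w") as fh:
        for call in calls:
            j = call.junction.canonical()
            fh.write(
                "\t".join(
                    [
                        j.bnd1.chrom, str(max(j.bnd1.pos - 1, 0)), str(j.bnd1.pos),
                        j.bnd2.chrom, str(max(j.bnd2.pos - 1, 0)), str(j.bnd2.pos),
                        call.id, ".", j.bnd1.orient, j.bnd2.orient,
                        _attrs_from_call(call),
                    ]
                )
                + "\n"
            )


def read_cn_bed(path: str | os.PathLike) -> list[CNSegment]:
    """Read copy-number segments from BED4(+2); rejects overlapping segments
    within one sample."""
    segs: list[CNSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(path, lineno, f"expected >=4 columns, got {len(fields)}")
            try:
                seg = CNSegment(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    copy_number=int(fields[3]),
                    sample_id=fields[4] if len(fields) > 4 else "",
                    source=fields[5] if len(fields) > 5 else "read_depth",
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            segs.append(seg)
    _check_cn_disjoint(segs, path)
    return segs


def _check_cn_disjoint(segs: Sequence[CNSegment], path: str | os.PathLike) -> None:
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{path}: overlapping CN segments for sample {sample!r} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def write_cn_bed(segs: Iterable[CNSegment], path: str | os.PathLike) -> None:
    segs = list(segs)
    _check_cn_disjoint(segs, path)
    with open(path, "w") as fh:
        for s in segs:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\t{s.sample_id}\t{s.source}\n"
            )


MANIFEST_COLUMNS = [
    "family_id", "proband_id", "father_id", "mother_id",
    "sibling_ids", "affected_status", "disease_group",
]


def read_manifest(path: str | os.PathLike) -> list[TrioRecord]:
    """Read a trio cohort manifest TSV; sample ids must be cohort-unique."""
    trios: list[TrioRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(MANIFEST_COLUMNS)] != MANIFEST_COLUMNS:
            raise FormatError(path, 1, f"manifest header must start with {MANIFEST_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(MANIFEST_COLUMNS):
                raise FormatError(path, lineno, "short manifest row")
            sibs = tuple(s for s in fields[4].split(",") if s)
            trios.append(
                TrioRecord(
                    family_id=fields[0], proband_id=fields[1], father_id=fields[2],
                    mother_id=fields[3], sibling_ids=sibs,
                    affected_status=fields[5], disease_group=fields[6],
                )
            )
    seen: set[str] = set()
    for trio in trios:
        for member in trio.member_ids:
            if member in seen:
                raise ValueError(f"{path}: duplicate sample id {member!r} in manifest")
            seen.add(member)
    return trios


def write_manifest(trios: Iterable[TrioRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for t in trios:
            fh.write(
                "\t".join(
                    [
                        t.family_id, t.proband_id, t.father_id, t.mother_id,
                        ",".join(t.sibling_ids), t.affected_status, t.disease_group,
                    ]
                )
                + "\n"
            )


def read_snp_table(path: str | os.PathLike) -> list[SNPGenotypeRow]:
    """Read a trio SNP genotype/allele-depth TSV."""
    rows: list[SNPGenotypeRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["chrom", "pos", "ref", "alt"] + [
            f"{kind}_{role}" for role in ROLES for kind in ("GT", "AD")
        ]
        if header != expected:
            raise FormatError(path, 1, f"SNP table header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(expected):
                raise FormatError(path, lineno, "wrong column count")
            genotypes: dict[str, Genotype] = {}
            depths: dict[str, tuple[int, int]] = {}
            try:
                for i, role in enumerate(ROLES):
                    genotypes[role] = Genotype(f[4 + 2 * i])
                    rd, ad = f[5 + 2 * i].split(",")
                    depths[role] = (int(rd), int(ad))
                rows.append(
                    SNPGenotypeRow(
                        chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3],
                        genotypes=genotypes, depths=depths,
                    )
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return rows


def write_snp_table(rows: Iterable[SNPGenotypeRow], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt"] + [
            f"{kind}_{role}" for role in ROLES for kind in ("GT", "AD")
        ]
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fields = [r.chrom, str(r.pos), r.ref, r.alt]
            for role in ROLES:
                fields.append(r.genotypes[role].value)
                rd, ad = r.depths[role]
                fields.append(f"{rd},{ad}")
            fh.write("\t".join(fields) + "\n")
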