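"""Candidate-to-high-confidence de novo SV filter cascade.

Stages, in order:

1. size + proband-specific: drop calls < 50 bp and calls matching a parental
   call (same orientation class, breakpoints within the match window,
   reciprocal overlap for intrachromosomal spans);
2. chrY removal;
3. parental clipped-read veto: >=4 clipped reads at either breakpoint, or
   >=2 at both, in either parent;
4. cohort recurrence: junctions matching calls in >=3 distinct samples are
   alignment artifacts;
5. caller quality: PASS or MGE10kb flag, score > 30 and > 10 discordant
   reads — with IMPRECISE calls rescued when an independent read-depth CNV
   co-locates with them;
6. VAF >= 0.1 (removes mosaic candidates).

The clip/recurrence/VAF stages are independent per-call predicates; the
quality stage is the only one with a rescue path.  A FilterReport records
per-stage bookkeeping (n_in, n_removed, n_rescued, removed ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnalysisParams, Flag, Junction, OrientationClass, SVCall


@dataclass
class FilterStage:
    """Per-stage accounting.

    ``n_removed`` counts calls failing the stage's primary predicate;
    ``n_rescued`` counts the subset added back by a rescue path, so
    ``n_out = n_in - n_removed + n_rescued``.  ``removed_ids`` lists the
    permanently removed calls (length ``n_removed - n_rescued``).
    """

    name: str
    n_in: int
    n_removed: int
    n_rescued: int = 0
    removed_ids: list[str] = field(default_factory=list)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed + self.n_rescued


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)
    survivors: list[SVCall] = field(default_factory=list)
    # calls removed at the quality/VAF stages, eligible for breakpoint rescue
    rescue_pool: list[SVCall] = field(default_factory=list)

    def check_bookkeeping(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_in != prev.n_out:
                raise AssertionError(
                    f"stage {cur.name}: n_in {cur.n_in} != previous n_out {prev.n_out}"
                )


def _reciprocal_overlap(a: Junction, b: Junction) -> float:
    lo = max(a.bnd1.pos, b.bnd1.pos)
    hi = min(a.bnd2.pos, b.bnd2.pos)
    if hi <= lo:
        return 0.0
    span_a = max(a.size or 0, 1)
    span_b = max(b.size or 0, 1)
    return min((hi - lo) / span_a, (hi - lo) / span_b)


def junctions_match(a: Junction, b: Junction, params: AnalysisParams) -> bool:
    """True when two junctions represent the same breakpoint pair.

    Requires the same orientation class, both breakends within the match
    window, and (for intrachromosomal junctions) reciprocal span overlap.
    """
    a, b = a.canonical(), b.canonical()
    if a.orientation_class() != b.orientation_class():
        return False
    if a.bnd1.chrom != b.bnd1.chrom or a.bnd2.chrom != b.bnd2.chrom:
        return False
    if abs(a.bnd1.pos - b.bnd1.pos) > params.match_window:
        return False
    if abs(a.bnd2.pos - b.bnd2.pos) > params.match_window:
        return False
    if a.intrachromosomal and (a.size or 0) > 0 and (b.size or 0) > 0:
        if _reciprocal_overlap(a, b) < params.reciprocal_overlap:
            return False
    return True


def calls_match(a: SVCall, b: SVCall, params: AnalysisParams) -> bool:
    return junctions_match(a.junction, b.junction, params)


def proband_specific(
    proband_calls: list[SVCall],
    father_calls: list[SVCall],
    mother_calls: list[SVCall],
    params: AnalysisParams,
) -> list[SVCall]:
    """Keep proband calls >= min_sv_len not matching any parental call."""
    parental = father_calls + mother_calls
    out = []
    for call in proband_calls:
        size = call.size
        if size is not None and size < params.min_sv_len:
            continue
        if any(calls_match(call, p, params) for p in parental):
            continue
        out.append(call)
    return out


def parental_clip_filter(call: SVCall, params: AnalysisParams) -> bool:
    """True = keep.  Drops calls with parental clipped-read support.

    A parent vetoes the call if it shows >= max_parent_clip_either clipped
    reads at either breakpoint, or >= max_parent_clip_both at both.
    Raises if a parental evidence profile is missing: de novo status cannot
    be assessed without both parents.
    """
    for role in ("father", "mother"):
        if role not in call.evidence:
            raise ValueError(f"call {call.id}: missing {role} evidence profile")
        ev = call.evidence[role]
        c1, c2 = ev.clipped_reads_bnd1, ev.clipped_reads_bnd2
        if c1 >= params.max_parent_clip_either or c2 >= params.max_parent_clip_either:
            return False
        if c1 >= params.max_parent_clip_both and c2 >= params.max_parent_clip_both:
            return False
    return True


def cohort_recurrence_filter(
    calls_by_sample: dict[str, list[SVCall]],
    params: AnalysisParams,
    reference: dict[str, list[SVCall]] | None = None,
) -> dict[str, list[SVCall]]:
    """Remove calls whose junction recurs in >= recurrence_k distinct samples
    (counting the carrier itself, any role).

    Carriers are counted against ``reference`` (default: the input itself).
    Recurrence is a property of the candidate pool, so the cascade passes the
    pool as it stood before the per-call evidence filters; this keeps the
    clip/recurrence/VAF stages order-independent.
    """
    ref = reference if reference is not None else calls_by_sample
    flat_ref = [(sample, call) for sample, calls in ref.items() for call in calls]
    out: dict[str, list[SVCall]] = {s: [] for s in calls_by_sample}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            carriers = {
                other_sample
                for other_sample, other in flat_ref
                if calls_match(call, other, params)
            }
            if len(carriers) < params.recurrence_k:
                out[sample].append(call)
    return out


def quality_filter(call: SVCall, params: AnalysisParams) -> tuple[bool, bool]:
    """Returns (keep, rescued).

    Keep when the call is PASS or MGE10kb with score > min_score and
    discordant reads > min_discordant; or rescue an IMPRECISE call when an
    independent read-depth CNV co-locates with it.
    """
    ev = call.evidence.get("proband")
    if ev is None:
        return False, False
    primary = (
        bool(ev.flags & {Flag.PASS, Flag.MGE10kb})
        and ev.caller_score > params.min_score
        and ev.discordant_reads > params.min_discordant
    )
    if primary:
        return True, False
    if Flag.IMPRECISE in ev.flags and Flag.COLOCALIZED_RD in ev.flags:
        return True, True
    return False, False


def vaf_filter(call: SVCall, params: AnalysisParams) -> bool:
    """True = keep; drops mosaic candidates with VAF < min_vaf (VAF equal to
    the threshold is kept)."""
    ev = call.evidence.get("proband")
    return ev is not None and ev.vaf >= params.min_vaf


def _stage(report: FilterReport, name: str, before: list[SVCall],
           after: list[SVCall], n_rescued: int = 0) -> None:
    removed = [c.id for c in before if c not in after]
    report.stages.append(
        FilterStage(name=name, n_in=len(before), n_removed=len(removed),
                    n_rescued=n_rescued, removed_ids=removed)
    )


def run_cascade(
    calls_by_proband: dict[str, list[SVCall]],
    parental_calls: dict[str, tuple[list[SVCall], list[SVCall]]],
    params: AnalysisParams | None = None,
) -> FilterReport:
    """Apply the full cascade to a cohort.

    ``calls_by_proband`` maps proband sample id to its candidate calls;
    ``parental_calls`` maps proband id to (father_calls, mother_calls).
    Transduction-annotated translocations are removed with the quality stage
    inputs (annotation-driven; detection is upstream of this package).
    """
    params = params or AnalysisParams()
    report = FilterReport()

    # stage 1: size + proband-specific
    current: dict[str, list[SVCall]] = {}
    all_in = [c for calls in calls_by_proband.values() for c in calls]
    for proband, calls in calls_by_proband.items():
        fa, mo = parental_calls.get(proband, ([], []))
        current[proband] = proband_specific(calls, fa, mo, params)
    _stage(report, "size_proband_specific", all_in,
           [c for v in current.values() for c in v])

    # stage 2: chrY removal
    before = [c for v in current.values() for c in v]
    excl = set(params.exclude_chroms)
    current = {
        s: [c for c in calls if not (c.junction.chroms & excl)]
        for s, calls in current.items()
    }
    _stage(report, "chrY_removal", before, [c for v in current.values() for c in v])
    candidate_pool = {s: list(calls) for s, calls in current.items()}

    # stage 3: parental clipped reads
    before = [c for v in current.values() for c in v]
    current = {
        s: [c for c in calls if parental_clip_filter(c, params)]
        for s, calls in current.items()
    }
    _stage(report, "parental_clip", before, [c for v in current.values() for c in v])

    # stage 4: cohort recurrence
    before = [c for v in current.values() for c in v]
    current = cohort_recurrence_filter(current, params, reference=candidate_pool)
    _stage(report, "cohort_recurrence", before, [c for v in current.values() for c in v])

    # stage 5: flags/score/discordant with IMPRECISE rescue
    before = [c for v in current.values() for c in v]
    n_failed = 0
    n_rescued = 0
    removed_ids: list[str] = []
    nxt: dict[str, list[SVCall]] = {}
    for s, calls in current.items():
        kept = []
        for c in calls:
            if c.is_transduction:
                n_failed += 1
                removed_ids.append(c.id)
                report.rescue_pool.append(c)
                continue
            keep, rescued = quality_filter(c, params)
            if rescued:
                n_failed += 1
                n_rescued += 1
            if keep:
                kept.append(c)
            else:
                n_failed += 1
                removed_ids.append(c.id)
                report.rescue_pool.append(c)
        nxt[s] = kept
    current = nxt
    report.stages.append(
        FilterStage("quality_rescue", len(before), n_failed, n_rescued, removed_ids)
    )

    # stage 6: VAF
    before = [c for v in current.values() for c in v]
    nxt = {}
    for s, calls in current.items():
        kept = []
        for c in calls:
            if vaf_filter(c, params):
                kept.append(c)
            else:
                report.rescue_pool.append(c)
        nxt[s] = kept
    current = nxt
    _stage(report, "vaf", before, [c for v in current.values() for c in v])

    report.survivors = [c for v in current.values() for c in v]
    report.check_bookkeeping()
    return report
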