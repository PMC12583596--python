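"""Rule-based classification of junction clusters into SV classes.

Each cluster of breakpoint junctions is assigned a simple class or a complex
subtype from two signals: the multiset of junction orientation classes and
the copy-number profile implied by junction dosage algebra, corroborated by
read-depth segments when available.

Junction dosage algebra: walking left to right along a chromosome, crossing
a ``-`` breakend raises copy number by one and crossing a ``+`` breakend
lowers it by one, starting from the diploid baseline of 2.  This reproduces
the canonical profiles — a deletion junction gives (2,1,2), a tandem
duplication (2,3,2), a balanced inversion pair stays flat, and the
duplication–inverted-triplication–duplication configuration gives
(2,3,4,3,2).

Complex events are those with >= 2 clustered junctions, excepting the four
balanced/insertional simple configurations (reciprocal inversion, reciprocal
translocation, templated insertion, dispersed duplication).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import pandas as pd

from .clustering import SVCluster
from .model import AnalysisParams, CNSegment, Junction, OrientationClass

OC = OrientationClass


class SVClass(str, enum.Enum):
    DEL = "DEL"
    TANDEM_DUP = "TANDEM_DUP"
    RECIPROCAL_INV = "RECIPROCAL_INV"
    RECIPROCAL_TRA = "RECIPROCAL_TRA"
    TEMPLATED_INS = "TEMPLATED_INS"
    DISPERSED_DUP = "DISPERSED_DUP"
    INVERTED_DUP = "INVERTED_DUP"
    LOSS_LOSS = "LOSS_LOSS"
    INV_LOSS = "INV_LOSS"
    LOSS_INV_LOSS = "LOSS_INV_LOSS"
    LOSS_INVDUP = "LOSS_INVDUP"
    DUP_TRP_INV_DUP = "DUP_TRP_INV_DUP"
    DUP_NML_DUP = "DUP_NML_DUP"
    DUP_NML_DUP_NML_DUP = "DUP_NML_DUP_NML_DUP"
    DELETION_BRIDGE = "DELETION_BRIDGE"
    TRA_LOSS = "TRA_LOSS"
    UNCLASSIFIED = "UNCLASSIFIED"


#: classes exempt from the complex definition despite having two junctions
SIMPLE_MULTIJUNCTION = {
    SVClass.RECIPROCAL_INV,
    SVClass.RECIPROCAL_TRA,
    SVClass.TEMPLATED_INS,
    SVClass.DISPERSED_DUP,
}

SIMPLE_CLASSES = {SVClass.DEL, SVClass.TANDEM_DUP} | SIMPLE_MULTIJUNCTION


@dataclass(frozen=True)
class ProfileSegment:
    chrom: str
    start: int
    end: int
    copy_number: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNProfile:
    segments: list[ProfileSegment]
    discordant: bool = False

    def material(self, min_len: int) -> list[ProfileSegment]:
        """Segments long enough to carry signal (drops breakend-offset
        slivers shorter than ``min_len``)."""
        return [s for s in self.segments if s.length >= min_len]


@dataclass
class ComplexCall:
    cluster_id: str
    assigned_class: SVClass
    cn_profile: CNProfile
    junctions: list[Junction]
    rescue_used: bool = False

    @property
    def is_complex(self) -> bool:
        return len(self.junctions) >= 2 and self.assigned_class not in SIMPLE_MULTIJUNCTION


def cn_profile(
    cluster: SVCluster,
    rd_segments: list[CNSegment] | None = None,
    params: AnalysisParams | None = None,
) -> CNProfile:
    """Copy-number states over breakend-delimited segments of the cluster.

    Junction-derived states are cross-checked against overlapping read-depth
    segments (majority-overlap vote); a contradiction flags the profile
    discordant without changing the junction-derived states.
    """
    params = params or AnalysisParams()
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for j in cluster.junctions:
        jc = j.canonical()
        for bnd in (jc.bnd1, jc.bnd2):
            by_chrom.setdefault(bnd.chrom, []).append((bnd.pos, bnd.orient))

    segments: list[ProfileSegment] = []
    for chrom in sorted(by_chrom):
        bnds = sorted(by_chrom[chrom])
        cn = 2
        for (pos, orient), (nxt_pos, _) in zip(bnds, bnds[1:]):
            cn += 1 if orient == "-" else -1
            if nxt_pos > pos:
                segments.append(ProfileSegment(chrom, pos, nxt_pos, cn))

    discordant = False
    if rd_segments:
        min_len = params.min_material_segment
        for seg in segments:
            if seg.length < min_len or seg.copy_number == 2:
                continue
            rd_cn = _majority_rd_cn(seg, rd_segments)
            if rd_cn is not None and rd_cn != seg.copy_number:
                discordant = True
    return CNProfile(segments=segments, discordant=discordant)


def _majority_rd_cn(seg: ProfileSegment, rd_segments: list[CNSegment]) -> int | None:
    """Read-depth copy number covering the majority of ``seg``, if any."""
    cover: dict[int, int] = {}
    for rd in rd_segments:
        if rd.chrom != seg.chrom:
            continue
        ov = min(seg.end, rd.end) - max(seg.start, rd.start)
        if ov > 0:
            cover[rd.copy_number] = cover.get(rd.copy_number, 0) + ov
    if not cover:
        return None
    cn, bp = max(cover.items(), key=lambda kv: kv[1])
    return cn if bp > seg.length / 2 else None


def _rd_confirms_gain(seg: ProfileSegment, rd_segments: list[CNSegment] | None) -> bool:
    if not rd_segments:
        return False
    cn = _majority_rd_cn(seg, rd_segments)
    return cn is not None and cn > 2


def _spans_agree(a: Junction, b: Junction, params: AnalysisParams) -> bool:
    tol = max(params.inv_span_tolerance, int(0.1 * max(a.size or 0, b.size or 0)))
    return (
        abs(a.bnd1.pos - b.bnd1.pos) <= tol
        and abs(a.bnd2.pos - b.bnd2.pos) <= tol
    )


def classify_cluster(
    cluster: SVCluster,
    rd_segments: list[CNSegment] | None = None,
    params: AnalysisParams | None = None,
) -> ComplexCall:
    """Assign one class to a cluster; UNCLASSIFIED is the sink.

    Deterministic and insensitive to junction input order.  Balanced
    configurations are recognised before unbalanced ones, and copy-number
    corroborated labels before junction-only fallbacks.
    """
    params = params or AnalysisParams()
    js = sorted((j.canonical() for j in cluster.junctions), key=lambda j: j.id)
    profile = cn_profile(cluster, rd_segments, params)
    label = _decide(js, profile, rd_segments if not profile.discordant else None, params)
    return ComplexCall(
        cluster_id=cluster.cluster_id,
        assigned_class=label,
        cn_profile=profile,
        junctions=js,
    )


def _decide(
    js: list[Junction],
    profile: CNProfile,
    rd_segments: list[CNSegment] | None,
    params: AnalysisParams,
) -> SVClass:
    ocs = sorted(j.orientation_class().value for j in js)
    material = profile.material(params.min_material_segment)
    losses = [s for s in material if s.copy_number < 2]
    gains = [s for s in material if s.copy_number > 2]

    if len(js) == 1:
        oc = js[0].orientation_class()
        if oc == OC.DEL_LIKE:
            return SVClass.DEL
        if oc == OC.DUP_LIKE:
            return SVClass.TANDEM_DUP
        return SVClass.UNCLASSIFIED

    if len(js) == 2:
        a, b = js
        same_chrom_pair = a.chroms == b.chroms

        # two deletion-type junctions: adjacent independent losses
        if ocs == [OC.DEL_LIKE.value, OC.DEL_LIKE.value] and a.intrachromosomal:
            disjoint = a.bnd2.pos <= b.bnd1.pos or b.bnd2.pos <= a.bnd1.pos
            return SVClass.LOSS_LOSS if disjoint and same_chrom_pair else SVClass.UNCLASSIFIED

        # inversion pair (one head + one tail) on one chromosome
        if (
            ocs == sorted([OC.INV_HEAD.value, OC.INV_TAIL.value])
            and a.intrachromosomal
            and same_chrom_pair
        ):
            return _classify_inversion_pair(a, b, losses, gains, rd_segments, params)

        # direct-orientation local insertion of a distal segment (same chrom)
        if (
            ocs == sorted([OC.DEL_LIKE.value, OC.DUP_LIKE.value])
            and a.intrachromosomal
            and same_chrom_pair
        ):
            return _classify_insertional(losses, gains, rd_segments, params, inverted=False)

        # inter-chromosomal pair between one chromosome pair
        if not a.intrachromosomal and not b.intrachromosomal and same_chrom_pair:
            pats = {tuple(o for _, o in sorted(
                [(bnd.chrom, bnd.orient) for bnd in (j.bnd1, j.bnd2)])) for j in (a, b)}
            direct = pats == {("+", "-"), ("-", "+")}
            inverted = pats == {("+", "+"), ("-", "-")}
            if not (direct or inverted):
                return SVClass.UNCLASSIFIED
            if not losses and not gains:
                return SVClass.RECIPROCAL_TRA if direct else SVClass.UNCLASSIFIED
            return _classify_insertional(losses, gains, rd_segments, params,
                                         inverted=inverted)

        return SVClass.UNCLASSIFIED

    if len(js) == 3 and all(j.intrachromosomal for j in js) and len(
        {j.bnd1.chrom for j in js}
    ) == 1:
        # local chain of three rearrangements: alternating gain/normal profile
        cns = [s.copy_number for s in material]
        if not losses and len(gains) == 3 and cns == [3, 2, 3, 2, 3]:
            return SVClass.DUP_NML_DUP_NML_DUP
        return SVClass.UNCLASSIFIED

    return SVClass.UNCLASSIFIED


def _classify_inversion_pair(
    a: Junction,
    b: Junction,
    losses: list[ProfileSegment],
    gains: list[ProfileSegment],
    rd_segments: list[CNSegment] | None,
    params: AnalysisParams,
) -> SVClass:
    # triplication nested in duplication: .. 3,4,3 ..
    cns = [g.copy_number for g in gains]
    if any(c >= 4 for c in cns) and not losses:
        if cns == [3, 4, 3]:
            return SVClass.DUP_TRP_INV_DUP
        return SVClass.UNCLASSIFIED
    if not losses and not gains:
        return SVClass.RECIPROCAL_INV if _spans_agree(a, b, params) else SVClass.UNCLASSIFIED
    if len(losses) == 2 and not gains:
        return SVClass.LOSS_INV_LOSS
    if len(losses) == 1 and not gains:
        return SVClass.INV_LOSS
    if len(losses) == 1 and len(gains) == 1:
        return SVClass.LOSS_INVDUP
    if not losses and len(gains) == 2:
        return SVClass.DUP_NML_DUP
    if not losses and len(gains) == 1:
        # inverted insertion of one distal segment
        return _classify_insertional(losses, gains, rd_segments, params, inverted=True)
    return SVClass.UNCLASSIFIED


def _classify_insertional(
    losses: list[ProfileSegment],
    gains: list[ProfileSegment],
    rd_segments: list[CNSegment] | None,
    params: AnalysisParams,
    inverted: bool,
) -> SVClass:
    """Insertion-shaped pairs: a donor template linked to a distal site.

    Without loss at the site: a read-depth-confirmed donor gain is a
    dispersed (direct) or inverted duplication; otherwise a short template is
    a templated insertion.  With loss at the site: a short template bridging
    the loss is a deletion bridge; otherwise an unbalanced translocation
    with deletion.
    """
    donor = gains[0] if len(gains) == 1 else None
    if not losses:
        if donor is None:
            return SVClass.UNCLASSIFIED
        if _rd_confirms_gain(donor, rd_segments):
            return SVClass.INVERTED_DUP if inverted else SVClass.DISPERSED_DUP
        if donor.length <= params.mge_len:
            return SVClass.TEMPLATED_INS
        return SVClass.UNCLASSIFIED
    if donor is not None and donor.length <= params.mge_len:
        return SVClass.DELETION_BRIDGE
    return SVClass.TRA_LOSS


def rescue_breakpoints(
    cluster: SVCluster,
    filtered_pool: list[Junction],
    rd_segments: list[CNSegment] | None = None,
    params: AnalysisParams | None = None,
) -> ComplexCall:
    """Classify with a one-junction rescue pass for unresolved clusters.

    When the cluster is UNCLASSIFIED, junctions removed at the quality/VAF
    stages that fall within the cluster footprint (padded by the rescue
    window) are tried one at a time in id order; the first that resolves the
    cluster to a non-UNCLASSIFIED class is adopted.  At most one junction is
    rescued per cluster.
    """
    params = params or AnalysisParams()
    call = classify_cluster(cluster, rd_segments, params)
    if call.assigned_class != SVClass.UNCLASSIFIED or not filtered_pool:
        return call

    pad = params.rescue_window
    nearby = []
    for j in sorted((j.canonical() for j in filtered_pool), key=lambda j: j.id):
        for bnd in (j.bnd1, j.bnd2):
            span = cluster.footprint.get(bnd.chrom)
            if span and span[0] - pad <= bnd.pos <= span[1] + pad:
                nearby.append(j)
                break

    for candidate in nearby:
        augmented = SVCluster(
            cluster_id=cluster.cluster_id,
            junctions=[*cluster.junctions, candidate],
        )
        augmented.compute_footprint()
        trial = classify_cluster(augmented, rd_segments, params)
        if trial.assigned_class != SVClass.UNCLASSIFIED:
            return replace(trial, rescue_used=True)
    return call


def summarize_classes(calls: list[ComplexCall]) -> pd.DataFrame:
    """Per-class counts with percentages overall and within complex calls,
    reported to 0.1%."""
    if not calls:
        return pd.DataFrame(
            columns=["sv_class", "count", "pct_overall", "is_complex", "pct_within_complex"]
        )
    total = len(calls)
    n_complex = sum(c.is_complex for c in calls)
    rows = []
    for cls in SVClass:
        members = [c for c in calls if c.assigned_class == cls]
        if not members:
            continue
        is_complex = members[0].is_complex
        rows.append(
            {
                "sv_class": cls.value,
                "count": len(members),
                "pct_overall": round(100.0 * len(members) / total, 1),
                "is_complex": is_complex,
                "pct_within_complex": (
                    round(100.0 * len(members) / n_complex, 1)
                    if is_complex and n_complex
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
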