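"""End-to-end orchestration: filter -> cluster -> classify -> phase -> stats.

The pipeline consumes a cohort (simulated in memory or loaded from files),
applies the de novo filter cascade, clusters surviving junctions per
proband, classifies each cluster (with the one-junction rescue pass for
unresolved clusters), assigns parent of origin and meiotic timing from the
family SNP table, and assembles cohort-level summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import ComplexCall, SVClass, classify_cluster, rescue_breakpoints, summarize_classes
from .clustering import cluster_junctions
from .filtering import FilterReport, run_cascade
from .genome import GenomeMap
from .model import AnalysisParams
from .phasing import OriginTimingCall, Timing, call_origin_and_timing
from .simulate import SimulatedCohort
from .stats import binom_two_tailed, class_fractions, dnsv_rate


@dataclass
class RunReport:
    seed: int
    params: AnalysisParams
    filter_report: FilterReport
    classified: list[ComplexCall] = field(default_factory=list)
    # proband id per classified call, aligned with `classified`
    samples: list[str] = field(default_factory=list)
    origin_timing: list[OriginTimingCall] = field(default_factory=list)
    class_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    stats: dict = field(default_factory=dict)

    def stage_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name, "n_in": s.n_in, "n_removed": s.n_removed,
                    "n_rescued": s.n_rescued, "n_out": s.n_out,
                }
                for s in self.filter_report.stages
            ]
        )


def _event_region(call: ComplexCall) -> tuple[str, tuple[str, int, int]] | None:
    """(kind, region) of the dosage-altered interval to phase, if any.

    Duplicated (CN>2) regions take precedence over losses, mirroring the
    two-step duplication-timing design.
    """
    gains = [s for s in call.cn_profile.segments if s.copy_number > 2 and s.length >= 1000]
    losses = [s for s in call.cn_profile.segments if s.copy_number < 2 and s.length >= 1000]
    if gains:
        g = max(gains, key=lambda s: s.length)
        return "duplication", (g.chrom, g.start, g.end)
    if losses:
        l = max(losses, key=lambda s: s.length)
        return "deletion", (l.chrom, l.start, l.end)
    return None


def run_pipeline(
    cohort: SimulatedCohort,
    params: AnalysisParams | None = None,
    genome: GenomeMap | None = None,
) -> RunReport:
    params = params or AnalysisParams()
    genome = genome or cohort.config.genome

    report = run_cascade(cohort.calls_by_proband, cohort.parental_calls, params)

    by_sample: dict[str, list] = {}
    for call in report.survivors:
        by_sample.setdefault(call.sample_id, []).append(call)
    pool_by_sample: dict[str, list] = {}
    for call in report.rescue_pool:
        pool_by_sample.setdefault(call.sample_id, []).append(call.junction)

    run = RunReport(seed=cohort.config.seed, params=params, filter_report=report)
    family_of = {t.proband_id: t.family_id for t in cohort.trios}

    for sample in sorted(by_sample):
        junctions = [c.junction for c in by_sample[sample]]
        rd = cohort.cn_by_proband.get(sample, [])
        clusters = cluster_junctions(junctions, genome, params.cluster_fdr_alpha)
        pool = pool_by_sample.get(sample, [])
        for cluster in clusters:
            cluster.cluster_id = f"{sample}:{cluster.cluster_id}"
            call = rescue_breakpoints(cluster, pool, rd, params)
            run.classified.append(call)
            run.samples.append(sample)

            kind_region = _event_region(call)
            if kind_region is not None:
                kind, region = kind_region
                snps = cohort.snps_by_family.get(family_of.get(sample, ""), [])
                run.origin_timing.append(
                    call_origin_and_timing(call.cluster_id, kind, region, snps, params)
                )

    run.class_summary = summarize_classes(run.classified)
    run.stats = _cohort_stats(run, n_genomes=len(cohort.trios))
    return run


def _cohort_stats(run: RunReport, n_genomes: int) -> dict:
    counts: dict[str, int] = {}
    for call in run.classified:
        counts[call.assigned_class.value] = counts.get(call.assigned_class.value, 0) + 1
    out: dict = {
        "n_events": len(run.classified),
        "n_genomes": n_genomes,
        "dnsv_rate": dnsv_rate(len(run.classified), n_genomes) if n_genomes else float("nan"),
        "class_fractions": class_fractions(counts),
        "n_complex": sum(c.is_complex for c in run.classified),
    }
    n_mi = sum(t.timing == Timing.MI for t in run.origin_timing)
    n_mii = sum(t.timing == Timing.MII for t in run.origin_timing)
    out["n_timed_mi"] = n_mi
    out["n_timed_mii"] = n_mii
    if n_mi + n_mii > 0:
        out["mii_fraction"] = n_mii / (n_mi + n_mii)
        out["timing_binom_p"] = binom_two_tailed(n_mii, n_mi + n_mii, 0.5)
    n_mat = sum(t.origin == "maternal" for t in run.origin_timing)
    n_pat = sum(t.origin == "paternal" for t in run.origin_timing)
    out["n_maternal"] = n_mat
    out["n_paternal"] = n_pat
    return out


def truth_evaluation(cohort: SimulatedCohort, run: RunReport) -> dict:
    """Compare survivors and class labels against the simulation truth."""
    truth_junctions = {
        j.id: t for t in cohort.truth if t.is_denovo for j in t.junctions
    }
    survivor_ids = {c.id for c in run.filter_report.survivors}
    truth_ids = set(truth_junctions)
    class_by_event = {
        t.event_id: t.true_class for t in cohort.truth if t.is_denovo
    }
    correct = total = 0
    for call in run.classified:
        event_ids = {j.id.rsplit("_j", 1)[0] for j in call.junctions}
        if len(event_ids) != 1:
            total += 1
            continue
        event_id = event_ids.pop()
        if event_id in class_by_event:
            total += 1
            correct += call.assigned_class.value == class_by_event[event_id]
    return {
        "n_truth_denovo_junctions": len(truth_ids),
        "n_survivors": len(survivor_ids),
        "false_negatives": sorted(truth_ids - survivor_ids),
        "false_positives": sorted(survivor_ids - truth_ids),
        "survivors_equal_truth": survivor_ids == truth_ids,
        "n_events_classified": total,
        "n_events_correct_class": correct,
    }
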