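"""De novo filter cascade: per-stage rules, bookkeeping and oracle parity."""

import pytest

from dnsvkit.filtering import (
    cohort_recurrence_filter,
    parental_clip_filter,
    proband_specific,
    quality_filter,
    run_cascade,
    vaf_filter,
)
from dnsvkit.model import (
    AnalysisParams,
    Breakend,
    EvidenceProfile,
    Flag,
    Junction,
    SVCall,
    SVType,
)
from dnsvkit.simulate import simulate_filter_stress


def make_call(
    cid="c1",
    chrom="chr1",
    pos=1_000_000,
    size=5_000,
    sample="S1",
    score=100.0,
    dr=20,
    vaf=0.5,
    flags=(Flag.PASS,),
    father_clips=(0, 0),
    mother_clips=(0, 0),
    transduction=False,
):
    j = Junction.make(cid, Breakend(chrom, pos, "+"), Breakend(chrom, pos + size, "-"))
    return SVCall(
        id=cid,
        junctions=(j,),
        svtype=SVType.DEL,
        sample_id=sample,
        evidence={
            "proband": EvidenceProfile(score, dr, 10, 10, vaf, frozenset(flags)),
            "father": EvidenceProfile(clipped_reads_bnd1=father_clips[0],
                                      clipped_reads_bnd2=father_clips[1]),
            "mother": EvidenceProfile(clipped_reads_bnd1=mother_clips[0],
                                      clipped_reads_bnd2=mother_clips[1]),
        },
        is_transduction=transduction,
    )


class TestProbandSpecific:
    def test_call_identical_to_parent_removed(self, params):
        call = make_call()
        assert proband_specific([call], [make_call(cid="fa")], [], params) == []

    @pytest.mark.parametrize("size,kept", [(49, False), (50, True)])
    def test_minimum_size_boundary(self, params, size, kept):
        call = make_call(size=size)
        out = proband_specific([call], [], [], params)
        assert (call in out) == kept

    def test_distant_parental_call_does_not_match(self, params):
        call = make_call(pos=1_000_000)
        parent = make_call(cid="fa", pos=1_001_000)  # 1 kb away, window 200 bp
        assert proband_specific([call], [parent], [], params) == [call]

    def test_orientation_class_must_match(self, params):
        call = make_call()
        j = Junction.make("fa", Breakend("chr1", 1_000_000, "-"),
                          Breakend("chr1", 1_005_000, "+"))
        parent = SVCall(id="fa", junctions=(j,), svtype=SVType.DUP, sample_id="F",
                        evidence=call.evidence)
        assert proband_specific([call], [parent], [], params) == [call]


class TestParentalClipFilter:
    @pytest.mark.parametrize(
        "father,mother,keep",
        [
            ((4, 0), (0, 0), False),  # >=4 at either breakpoint
            ((0, 0), (2, 2), False),  # >=2 at both breakpoints
            ((1, 1), (1, 1), True),
            ((3, 1), (0, 0), True),
            ((0, 5), (0, 0), False),
        ],
    )
    def test_clip_rules(self, params, father, mother, keep):
        call = make_call(father_clips=father, mother_clips=mother)
        assert parental_clip_filter(call, params) is keep

    def test_missing_parent_profile_is_an_error(self, params):
        call = make_call()
        call = SVCall(id=call.id, junctions=call.junctions, svtype=call.svtype,
                      sample_id=call.sample_id,
                      evidence={"proband": call.evidence["proband"]})
        with pytest.raises(ValueError, match="missing father"):
            parental_clip_filter(call, params)


class TestQualityAndVaf:
    @pytest.mark.parametrize(
        "score,dr,flags,keep,rescued",
        [
            (31, 11, (Flag.PASS,), True, False),
            (30, 11, (Flag.PASS,), False, False),       # strict > 30
            (31, 10, (Flag.PASS,), False, False),       # strict > 10
            (31, 11, (Flag.MGE10kb,), True, False),
            (100, 50, (), False, False),                # no PASS/MGE10kb
            (5, 0, (Flag.IMPRECISE, Flag.COLOCALIZED_RD), True, True),
            (5, 0, (Flag.IMPRECISE,), False, False),
        ],
    )
    def test_quality_rules(self, params, score, dr, flags, keep, rescued):
        call = make_call(score=score, dr=dr, flags=flags)
        assert quality_filter(call, params) == (keep, rescued)

    @pytest.mark.parametrize("vaf,keep", [(0.09, False), (0.10, True), (0.5, True)])
    def test_vaf_boundary(self, params, vaf, keep):
        assert vaf_filter(make_call(vaf=vaf), params) is keep


class TestRecurrence:
    def _cohort(self, n_carriers):
        cohort = {}
        for i in range(max(n_carriers, 4)):
            sample = f"S{i}"
            if i < n_carriers:
                cohort[sample] = [make_call(cid=f"art_{sample}", sample=sample)]
            else:
                cohort[sample] = [
                    make_call(cid=f"own_{sample}", pos=10_000_000 + i * 5_000_000,
                              sample=sample)
                ]
        return cohort

    def test_three_carriers_all_removed(self, params):
        out = cohort_recurrence_filter(self._cohort(3), params)
        assert all("art" not in c.id for calls in out.values() for c in calls)

    def test_two_carriers_kept(self, params):
        out = cohort_recurrence_filter(self._cohort(2), params)
        kept = [c.id for calls in out.values() for c in calls]
        assert "art_S0" in kept and "art_S1" in kept


def brute_force_survivors(calls_by_proband, parental, params):
    """One-pass reference predicate, written independently of the cascade."""
    excl = set(params.exclude_chroms)

    def matches(a, b):
        ja, jb = a.junction.canonical(), b.junction.canonical()
        if ja.orientation_class() != jb.orientation_class():
            return False
        if (ja.bnd1.chrom, ja.bnd2.chrom) != (jb.bnd1.chrom, jb.bnd2.chrom):
            return False
        if abs(ja.bnd1.pos - jb.bnd1.pos) > params.match_window:
            return False
        if abs(ja.bnd2.pos - jb.bnd2.pos) > params.match_window:
            return False
        if ja.intrachromosomal and ja.size and jb.size:
            ov = min(ja.bnd2.pos, jb.bnd2.pos) - max(ja.bnd1.pos, jb.bnd1.pos)
            if ov / max(ja.size, jb.size) < params.reciprocal_overlap or \
               ov / max(min(ja.size, jb.size), 1) < params.reciprocal_overlap:
                return False
        return True

    # candidate pool after size/proband-specific/chrY (reference for recurrence)
    pool = {}
    for sample, calls in calls_by_proband.items():
        fa, mo = parental.get(sample, ([], []))
        pool[sample] = [
            c for c in calls
            if (c.size is None or c.size >= params.min_sv_len)
            and not any(matches(c, p) for p in fa + mo)
            and not (c.junction.chroms & excl)
        ]
    flat = [(s, c) for s, calls in pool.items() for c in calls]

    survivors = []
    for sample, call in flat:
        ok = True
        for role in ("father", "mother"):
            ev = call.evidence[role]
            if ev.clipped_reads_bnd1 >= 4 or ev.clipped_reads_bnd2 >= 4:
                ok = False
            if ev.clipped_reads_bnd1 >= 2 and ev.clipped_reads_bnd2 >= 2:
                ok = False
        carriers = {s for s, other in flat if matches(call, other)}
        if len(carriers) >= params.recurrence_k:
            ok = False
        ev = call.evidence["proband"]
        good_quality = (
            bool(ev.flags & {Flag.PASS, Flag.MGE10kb})
            and ev.caller_score > params.min_score
            and ev.discordant_reads > params.min_discordant
        )
        rescued = Flag.IMPRECISE in ev.flags and Flag.COLOCALIZED_RD in ev.flags
        if not (good_quality or rescued):
            ok = False
        if call.is_transduction:
            ok = False
        if ev.vaf < params.min_vaf:
            ok = False
        if ok:
            survivors.append(call.id)
    return sorted(survivors)


class TestCascade:
    def test_empty_input_empty_report(self, params):
        report = run_cascade({}, {}, params)
        assert report.survivors == []
        report.check_bookkeeping()

    def test_toy_fixture_hand_applied(self, params):
        """1 inherited + 3 recurrent + 1 low-VAF + 1 rescued + 2 clean -> 3 survive."""
        inherited = make_call(cid="inh", pos=1_000_000)
        recurrent = [
            make_call(cid=f"rec{i}", pos=5_000_000, sample=f"S{i}") for i in range(3)
        ]
        low_vaf = make_call(cid="lowvaf", pos=9_000_000, vaf=0.05)
        rescued = make_call(cid="resc", pos=13_000_000, score=5, dr=0,
                            flags=(Flag.IMPRECISE, Flag.COLOCALIZED_RD))
        clean = [make_call(cid=f"ok{i}", pos=17_000_000 + i * 4_000_000)
                 for i in range(2)]
        calls = {
            "S1": [inherited, low_vaf, rescued, *clean, recurrent[0]],
            "S2": [recurrent[1]],
            "S3": [recurrent[2]],
        }
        parental = {"S1": ([make_call(cid="fa", pos=1_000_000)], [])}
        report = run_cascade(calls, parental, params)
        assert sorted(c.id for c in report.survivors) == ["ok0", "ok1", "resc"]
        report.check_bookkeeping()

    def test_bookkeeping_identity_on_random_cohort(self, params):
        calls, parental = simulate_filter_stress(300, seed=11)
        report = run_cascade(calls, parental, params)
        report.check_bookkeeping()
        for prev, cur in zip(report.stages, report.stages[1:]):
            assert cur.n_in == prev.n_out

    def test_cascade_equals_brute_force_predicate(self, params):
        calls, parental = simulate_filter_stress(600, seed=5)
        report = run_cascade(calls, parental, params)
        assert sorted(c.id for c in report.survivors) == brute_force_survivors(
            calls, parental, params
        )

    def test_survivors_subset_of_input(self, params):
        calls, parental = simulate_filter_stress(200, seed=2)
        report = run_cascade(calls, parental, params)
        input_ids = {c.id for v in calls.values() for c in v}
        assert {c.id for c in report.survivors} <= input_ids

    def test_clip_recurrence_vaf_stage_order_invariance(self, params):
        """The three evidence predicates commute: any application order of
        clip/recurrence/VAF yields the same survivor set."""
        import itertools

        calls, parental = simulate_filter_stress(300, seed=7)
        # fix the non-permutable prefix: size/proband-specific + chrY + quality
        excl = set(params.exclude_chroms)
        base = {}
        for sample, sample_calls in calls.items():
            fa, mo = parental.get(sample, ([], []))
            base[sample] = [
                c for c in proband_specific(sample_calls, fa, mo, params)
                if not (c.junction.chroms & excl)
            ]
        reference = {s: list(v) for s, v in base.items()}

        def apply_clip(state):
            return {s: [c for c in v if parental_clip_filter(c, params)]
                    for s, v in state.items()}

        def apply_rec(state):
            return cohort_recurrence_filter(state, params, reference=reference)

        def apply_vaf(state):
            return {s: [c for c in v if vaf_filter(c, params)]
                    for s, v in state.items()}

        results = []
        for order in itertools.permutations([apply_clip, apply_rec, apply_vaf]):
            state = {s: list(v) for s, v in base.items()}
            for stage in order:
                state = stage(state)
            results.append(sorted(c.id for v in state.values() for c in v))
        assert all(r == results[0] for r in results)
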