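"""Artifact-filter cascade: junction support, intrapriming, ISM ends,
non-redundant merge, replicate filter, and threshold monotonicity."""

import numpy as np
import pytest

from helpers import make_tx, random_cascade_inputs
from isocall.classify import StructuralCall, classify_all
from isocall.filters import (
    FilterConfig,
    downstream_a_count,
    intrapriming_filter,
    ism_end_filter,
    junction_support_filter,
    merge_nonredundant,
    replicate_filter,
    run_filter_cascade,
)
from isocall.io import DictGenome
from isocall.models import JunctionSupportTable, ReferenceAnnotation


def call_for(model, category, **diag):
    return StructuralCall(
        transcript_id=model.transcript_id,
        category=category,
        matched_reference_transcript="R" if category in ("FSM", "ISM") else None,
        assigned_gene=None if category == "intergenic" else "G",
        diagnostics=diag,
    )


class TestJunctionSupportFilter:
    def test_one_unsupported_junction_fails(self):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30), (40, 50)])
        support = JunctionSupportTable()
        support.add("chr1", 10, 20, "+", 5)  # (30, 40) unsupported
        report = junction_support_filter([t], [call_for(t, "NIC")], support)
        assert not report.passed(t)
        assert report.status[report.key(t)] == "junction_support"

    def test_mono_exon_passes_vacuously(self):
        t = make_tx("t", "chr1", "+", [(0, 100)])
        report = junction_support_filter(
            [t], [call_for(t, "intergenic")], JunctionSupportTable()
        )
        assert report.passed(t)

    def test_all_junctions_at_threshold_pass(self):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30), (40, 50), (60, 70)])
        support = JunctionSupportTable()
        for d, a in [(10, 20), (30, 40), (50, 60)]:
            support.add("chr1", d, a, "+", 1)
        report = junction_support_filter([t], [call_for(t, "NIC")], support)
        assert report.passed(t)

    def test_missing_call_is_error(self):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30)])
        with pytest.raises(ValueError, match="no structural call"):
            junction_support_filter([t], [], JunctionSupportTable())


class TestIntraprimingFilter:
    def genome_with_tail(self, tail, left_pad=100, total=200):
        seq = "C" * left_pad + tail
        seq = seq + "G" * (total - len(seq))
        return DictGenome({"chr1": seq})

    def test_sixteen_adenines_fail_fifteen_pass(self):
        # transcript ends at 100 on + strand; window is [100, 120)
        t = make_tx("t", "chr1", "+", [(0, 50), (60, 100)])
        for n_a, expect_pass in [(15, True), (16, False), (20, False)]:
            genome = self.genome_with_tail("A" * n_a + "C" * (20 - n_a))
            report = intrapriming_filter([t], [call_for(t, "NIC")], genome)
            assert report.passed(t) is expect_pass, n_a

    def test_fsm_exempt_even_with_full_adenine_tract(self):
        t = make_tx("t", "chr1", "+", [(0, 50), (60, 100)])
        genome = self.genome_with_tail("A" * 20)
        report = intrapriming_filter([t], [call_for(t, "FSM")], genome)
        assert report.passed(t)

    def test_minus_strand_counts_adenines_on_transcript_strand(self):
        # minus-strand 3' end at genomic start 100; upstream window [80, 100)
        # of T's reads as A on the transcript strand
        t = make_tx("t", "chr1", "-", [(100, 150), (160, 199)])
        genome = DictGenome({"chr1": "C" * 80 + "T" * 20 + "G" * 100})
        report = intrapriming_filter([t], [call_for(t, "NNC")], genome)
        assert not report.passed(t)
        # and an A-tract on the plus strand upstream is harmless
        genome2 = DictGenome({"chr1": "C" * 80 + "A" * 20 + "G" * 100})
        report2 = intrapriming_filter([t], [call_for(t, "NNC")], genome2)
        assert report2.passed(t)

    def test_truncated_window_is_counted_and_flagged(self):
        t = make_tx("t", "chr1", "+", [(0, 50), (60, 90)])
        genome = DictGenome({"chr1": "C" * 90 + "A" * 10})  # only 10 bp left
        count, truncated = downstream_a_count(t, genome, 20)
        assert (count, truncated) == (10, True)
        report = intrapriming_filter([t], [call_for(t, "NIC")], genome)
        assert report.passed(t)
        assert report.flags[report.key(t)] == "truncated_window"


class TestIsmEndFilter:
    def test_three_prime_only_truncation_dropped(self):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30)])
        call = call_for(t, "ISM", missing_5p=False, missing_3p=True)
        report = ism_end_filter([t], [call])
        assert not report.passed(t)

    @pytest.mark.parametrize("m5,m3", [(True, False), (True, True)])
    def test_five_prime_truncation_kept(self, m5, m3):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30)])
        call = call_for(t, "ISM", missing_5p=m5, missing_3p=m3)
        assert ism_end_filter([t], [call]).passed(t)

    def test_disabled_by_config(self):
        t = make_tx("t", "chr1", "+", [(0, 10), (20, 30)])
        call = call_for(t, "ISM", missing_5p=False, missing_3p=True)
        cfg = FilterConfig(filter_ism_ends=False)
        assert ism_end_filter([t], [call], cfg).passed(t)


class TestMergeAndReplicates:
    def test_same_chain_merges_to_outermost_ends(self):
        a = make_tx("tA", "chr1", "+", [(100, 200), (300, 900)], sample="S1")
        b = make_tx("tB", "chr1", "+", [(120, 200), (300, 950)], sample="S2")
        merged, counts = merge_nonredundant({"S1": [a], "S2": [b]})
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end) == (100, 950)
        assert counts[m.transcript_id] == 2

    def test_different_chains_stay_separate(self):
        a = make_tx("tA", "chr1", "+", [(100, 200), (300, 900)])
        b = make_tx("tB", "chr1", "+", [(100, 200), (310, 900)])
        merged, _ = merge_nonredundant({"S1": [a, b]})
        assert len(merged) == 2

    def test_mono_exon_below_half_reciprocal_overlap_not_merged(self):
        a = make_tx("tA", "chr1", "+", [(0, 100)])
        b = make_tx("tB", "chr1", "+", [(60, 160)])  # 40/100 reciprocal
        merged, _ = merge_nonredundant({"S1": [a], "S2": [b]})
        assert len(merged) == 2

    def test_mono_exon_reciprocal_overlap_merges(self):
        a = make_tx("tA", "chr1", "+", [(0, 100)])
        b = make_tx("tB", "chr1", "+", [(40, 140)])  # 60/100 both ways
        merged, counts = merge_nonredundant({"S1": [a], "S2": [b]})
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 140)
        assert counts[merged[0].transcript_id] == 2

    def test_same_transcript_in_one_sample_counts_once(self):
        a = make_tx("tA", "chr1", "+", [(100, 200), (300, 900)])
        b = make_tx("tB", "chr1", "+", [(100, 200), (300, 910)])
        merged, counts = merge_nonredundant({"S1": [a, b]})
        assert counts[merged[0].transcript_id] == 1

    @pytest.mark.parametrize(
        "count,min_rep,kept", [(2, 2, True), (1, 2, False), (1, 1, True)]
    )
    def test_replicate_threshold(self, count, min_rep, kept):
        m = make_tx("t", "chr1", "+", [(0, 10), (20, 30)])
        out = replicate_filter([m], {"t": count}, FilterConfig(min_replicates=min_rep))
        assert (m in out) is kept


class TestCascade:
    def test_output_subset_of_input_each_stage(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            per_sample, ref, support, genome = random_cascade_inputs(rng)
            result = run_filter_cascade(per_sample, ref, support, genome)
            n_input = sum(len(v) for v in per_sample.values())
            assert len(result.final_models) <= len(result.merged) <= n_input

    def test_threshold_monotonicity(self):
        """Stricter thresholds never grow the pass set."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            per_sample, ref, support, genome = random_cascade_inputs(rng)

            def final_ids(**kw):
                cfg = FilterConfig(**kw)
                res = run_filter_cascade(per_sample, ref, support, genome, cfg)
                return {m.transcript_id for m in res.final_models}

            base = dict(min_junction_reads=1, polyA_min_A=16, min_replicates=1)
            prev = final_ids(**base)
            for reads in (2, 4):
                cur = final_ids(**{**base, "min_junction_reads": reads})
                assert cur <= prev
                prev = cur
            prev = final_ids(**base)
            for min_a in (10, 5):
                cur = final_ids(**{**base, "polyA_min_A": min_a})
                assert cur <= prev
                prev = cur
            prev = final_ids(**base)
            for reps in (2, 3):
                cur = final_ids(**{**base, "min_replicates": reps})
                assert cur <= prev
                prev = cur

    def test_planted_adenine_tracts_removed_unless_fsm(self, default_dataset):
        """On synthetic data every non-FSM model with >= 16 downstream A's is
        removed by the intrapriming rule, while FSM models are retained."""
        ds = default_dataset
        support = JunctionSupportTable()
        for table in ds.support_by_sample.values():
            support.update(table)
        result = run_filter_cascade(
            ds.queries_by_sample, ds.annotation, support, ds.genome,
            FilterConfig(min_replicates=1),
        )
        truth_cat = ds.truth.query_categories
        a_counts = ds.truth.downstream_a_counts
        final_ids = {m.transcript_id for m in result.final_models}
        for qid, cat in truth_cat.items():
            if a_counts[qid] >= 16 and cat not in ("FSM",):
                assert qid not in final_ids
        # FSM queries always survive intrapriming (they may still merge away)
        for sample, report in result.intrapriming_report.items():
            for (smp, tx), rule in report.status.items():
                if truth_cat.get(tx) == "FSM":
                    assert rule is None
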