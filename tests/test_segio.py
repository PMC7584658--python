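import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaps import (CNState, PipelineConfig, classify_segments, classify_state,
                   filter_gap_adjacent, merge_segments, read_genome_ref,
                   read_seg, write_seg)
from cnaps.segio import (DataError, GenomeRefError, SegFormatError,
                         SegRecordError, write_genome_ref)
from conftest import make_segment
from oracles import classify_oracle

CANONICAL = ("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n"
             "S1\tchr1\t100\t5000\t25\t-0.5\n"
             "S1\t2\t1\t900\t10\t0.1\n"
             "S2\t1\t50\t60\t3\t0.9\n")


class TestReadSeg:
    def test_reads_and_sorts_valid_rows(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(CANONICAL)
        records = read_seg(p, labels={"S1": "BRCA"})
        assert len(records) == 3
        assert [r.sample_id for r in records] == ["S1", "S1", "S2"]
        assert [r.chrom for r in records] == ["1", "2", "1"]  # chr stripped
        assert records[0].cancer_type == "BRCA"
        assert records[2].cancer_type == "NA"

    def test_dialect_and_column_order_equivalence(self, tmp_path):
        alt = ("seg.mean\tloc.end\tID\tnum.mark\tchrom\tloc.start\n"
               "-0.5\t5000\tS1\t25\tchr1\t100\n"
               "0.1\t900\tS1\t10\t2\t1\n"
               "0.9\t60\tS2\t3\t1\t50\n")
        p1, p2 = tmp_path / "a.seg", tmp_path / "b.seg"
        p1.write_text(CANONICAL)
        p2.write_text(alt)
        assert read_seg(p1) == read_seg(p2)

    def test_non_finite_seg_mean_dropped(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(CANONICAL + "S3\t1\t5\t9\t2\tNA\n")
        assert len(read_seg(p)) == 3

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text("Sample\tChromosome\tStart\tEnd\n" "S1\t1\t1\t2\n")
        with pytest.raises(SegFormatError, match="seg_mean"):
            read_seg(p)

    def test_start_after_end_reports_line(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n"
                     "S1\t1\t500\t100\t0.0\n")
        with pytest.raises(SegRecordError, match="line 2"):
            read_seg(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(CANONICAL)
        records = read_seg(p)
        q = tmp_path / "b.seg"
        write_seg(records, q)
        assert read_seg(q) == records


class TestClassifyState:
    @pytest.mark.parametrize("x,state", [
        (-1.5, CNState.HOMDEL),
        (-1.0, CNState.HEMIDEL),
        (-0.2, CNState.NEUTRAL),
        (0.0, CNState.NEUTRAL),
        (0.3, CNState.GAIN),
        (0.7, CNState.AMP),
        (3.0, CNState.AMP),
    ])
    def test_boundaries(self, x, state):
        assert classify_state(x) is state

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_state(float("nan"))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=-4, max_value=4, allow_nan=False))
    def test_total_and_agrees_with_inequality_oracle(self, x):
        assert classify_state(x).name == classify_oracle(x)

    def test_custom_thresholds(self):
        cfg = PipelineConfig(homdel_max=-2, hemidel_max=-1, neutral_max=1,
                             gain_max=2)
        assert classify_state(-1.5, cfg) is CNState.HEMIDEL


def _classified(specs, **kw):
    """specs: list of (start, end, seg_mean[, probes])."""
    return classify_segments([
        make_segment(s[0], s[1], s[2],
                     probes=s[3] if len(s) > 3 else None, **kw)
        for s in specs])


class TestMergeSegments:
    def test_same_state_small_gap_merges(self):
        segs = _classified([(1, 100_000, -0.5), (110_001, 300_000, -0.5)])
        merged = merge_segments(segs)
        assert len(merged) == 1
        assert (merged[0].segment.start, merged[0].segment.end) == (1, 300_000)

    def test_different_states_never_merge(self):
        segs = _classified([(1, 100_000, -0.5), (100_001, 200_000, 0.0)])
        assert merge_segments(segs) == segs

    def test_gap_at_threshold_blocks_merge(self):
        # gap of exactly merge_gap_max does not merge (strict <)
        segs = _classified([(1, 100_000, -0.5), (200_001, 300_000, -0.5)])
        assert len(merge_segments(segs)) == 2

    def test_transitive_three_way_merge(self):
        segs = _classified([(1, 100_000, 0.5), (100_001, 200_000, 0.5),
                            (250_001, 400_000, 0.5)])
        merged = merge_segments(segs)
        assert len(merged) == 1
        assert merged[0].segment.end == 400_000

    def test_probe_weighted_mean(self):
        segs = _classified([(1, 10, -0.4, 30), (20, 30, -0.6, 10)])
        merged = merge_segments(segs)
        assert merged[0].segment.seg_mean == pytest.approx(
            (30 * -0.4 + 10 * -0.6) / 40)
        assert merged[0].segment.num_probes == 40

    def test_unweighted_mean_without_probes(self):
        segs = _classified([(1, 10, -0.4), (20, 30, -0.6)])
        assert merge_segments(segs)[0].segment.seg_mean == pytest.approx(-0.5)

    def test_overlap_rejected(self):
        segs = _classified([(1, 100, 0.0), (50, 200, 0.0)])
        with pytest.raises(DataError, match="overlap"):
            merge_segments(segs)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 150_000),   # gap before segment
                              st.integers(1, 200_000),   # length
                              st.sampled_from([-2.0, -0.5, 0.0, 0.5, 1.0])),
                    max_size=12))
    def test_merge_idempotent_and_sound(self, spec):
        pos, segs = 1, []
        for gap, length, mean in spec:
            start = pos + gap
            segs.append(make_segment(start, start + length - 1, mean))
            pos = start + length
        classified = classify_segments(segs)
        merged = merge_segments(classified)
        assert merge_segments(merged) == merged
        cfg = PipelineConfig()
        for a, b in zip(merged, merged[1:]):
            gap = b.segment.start - a.segment.end - 1
            assert not (a.state == b.state and gap < cfg.merge_gap_max)


class TestFilterGapAdjacent:
    def test_large_gap_removes_both_flanks(self):
        segs = _classified([(1, 100_000, 0.0), (250_001, 400_000, 0.0),
                            (400_001, 500_000, -0.5)])
        kept = filter_gap_adjacent(segs)
        assert kept == segs[2:]

    def test_gap_exactly_threshold_retained(self):
        segs = _classified([(1, 100_000, 0.0), (200_001, 300_000, 0.0)])
        assert filter_gap_adjacent(segs) == segs

    def test_contiguous_tiling_is_identity(self):
        segs = _classified([(1, 100, 0.0), (101, 200, -0.5), (201, 300, 0.5)])
        assert filter_gap_adjacent(segs) == segs

    def test_output_is_subset_of_input(self):
        segs = _classified([(1, 10, 0.0), (300_000, 300_010, -0.5),
                            (700_000, 700_010, 0.5)])
        kept = filter_gap_adjacent(segs)
        assert all(k in segs for k in kept)
        assert kept == []  # every segment flanks a >100 kb gap


class TestGenomeRef:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chrom\tlength\tcen_start\tcen_end\n"
                     "1\t1000000\t400000\t500000\n"
                     "2\t2000000\t900000\t950000\n")
        genome = read_genome_ref(p)
        assert set(genome.chroms) == {"1", "2"}
        q = tmp_path / "h.tsv"
        write_genome_ref(genome, q)
        assert read_genome_ref(q) == genome

    def test_centromere_outside_chromosome_rejected(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chrom\tlength\tcen_start\tcen_end\n"
                     "1\t1000000\t900000\t1100000\n")
        with pytest.raises(GenomeRefError):
            read_genome_ref(p)

    def test_unknown_chromosome_named(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("chrom\tlength\tcen_start\tcen_end\n"
                     "1\t1000000\t400000\t500000\n")
        with pytest.raises(GenomeRefError, match="X"):
            read_genome_ref(p).require("X")
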