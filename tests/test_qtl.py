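"""Marker placement, QTL interval merging, gene membership, final report."""

import numpy as np
import pandas as pd
import pytest

from panheat.deg import CandidateSets
from panheat.io_formats import Contig, ContigSet, GeneModel, GenomicInterval
from panheat.qtl import (
    Marker,
    QtlInterval,
    build_intervals,
    candidate_counts,
    final_candidates,
    genes_in_qtls,
    markers_from_frame,
    place_markers,
)
from panheat.variants import revcomp


def _genome(seq, name="c1"):
    return ContigSet([Contig(name, seq)])


class TestPlaceMarkers:
    SEQ = "TTTTTACGTACGGTTCAGGCCATGCATTACGGAGACCATTGCCCTTGAGATCAGGTTACA"

    def test_unique_forward_hit(self):
        probe = self.SEQ[10:30]
        m = Marker("m1", "q1", sequence=probe)
        placed, log = place_markers([m], _genome(self.SEQ))
        assert placed[0].pos == 11 and placed[0].end == 30
        assert placed[0].strand == "+" and not log.ambiguous

    def test_reverse_complement_hit_forward_coordinates(self):
        probe = revcomp(self.SEQ[20:40])
        m = Marker("m1", "q1", sequence=probe)
        placed, _ = place_markers([m], _genome(self.SEQ))
        assert placed[0].pos == 21 and placed[0].end == 40
        assert placed[0].strand == "-"

    def test_absent_marker_unplaced(self):
        m = Marker("m1", "q1", sequence="A" * 20)
        placed, log = place_markers([m], _genome(self.SEQ))
        assert not placed and log.unplaced == ["m1"]

    def test_ambiguous_excluded_unless_kept(self):
        seq = self.SEQ + self.SEQ  # every probe occurs twice
        m = Marker("m1", "q1", sequence=self.SEQ[10:30])
        placed, log = place_markers([m], _genome(seq))
        assert not placed and log.ambiguous == ["m1"]
        placed, _ = place_markers(
            [Marker("m1", "q1", sequence=self.SEQ[10:30])], _genome(seq),
            keep_ambiguous=True,
        )
        assert placed[0].pos == 11  # first by position

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            place_markers([Marker("m1", "q1", sequence="ACGTACGT")], _genome(self.SEQ))


def _placed(marker_id, qtl_id, contig, start, end):
    return Marker(marker_id, qtl_id, contig=contig, pos=start, end=end)


class TestBuildIntervals:
    def test_flanking_markers_span(self):
        ms = [
            _placed("l", "q1", "c1", 100, 120),
            _placed("r", "q1", "c1", 4980, 5000),
        ]
        (q,) = build_intervals(ms)
        assert (q.interval.start, q.interval.end) == (100, 5000)

    def test_merge_overlapping(self):
        ms = [
            _placed("a", "q1", "c1", 100, 5000),
            _placed("b", "q2", "c1", 4000, 9000),
        ]
        (q,) = build_intervals(ms, merge=True)
        assert (q.interval.start, q.interval.end) == (100, 9000)
        assert set(q.qtl_ids) == {"q1", "q2"}

    def test_three_qtls_two_overlap(self):
        ms = [
            _placed("a", "q1", "c1", 100, 5000),
            _placed("b", "q2", "c1", 4000, 9000),
            _placed("c", "q3", "c1", 20000, 30000),
        ]
        out = build_intervals(ms, merge=True)
        assert len(out) == 2
        assert not build_intervals(ms, merge=False)[0].interval.start > 100

    def test_merged_disjoint_and_cover_union(self):
        rng = np.random.default_rng(0)
        ms = [
            _placed(f"m{i}", f"q{i}", "c1", int(s), int(s) + int(rng.integers(100, 5000)))
            for i, s in enumerate(rng.integers(1, 50_000, size=20))
        ]
        out = build_intervals(ms, merge=True)
        ivs = sorted((q.interval.start, q.interval.end) for q in out)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 < s2  # disjoint
        union_in = set()
        for m in ms:
            union_in.update(range(m.pos, m.end + 1))
        union_out = set()
        for s, e in ivs:
            union_out.update(range(s, e + 1))
        assert union_in == union_out

    def test_multi_contig_qtl_rejected(self):
        ms = [_placed("a", "q1", "c1", 1, 20), _placed("b", "q1", "c2", 1, 20)]
        with pytest.raises(ValueError, match="several contigs"):
            build_intervals(ms)

    def test_all_markers_unplaced_raises_when_expected(self):
        ms = [_placed("a", "q1", "c1", 1, 20)]
        with pytest.raises(ValueError, match="unplaced"):
            build_intervals(ms, expected_qtls={"q1", "q2"})


def _gene(gene_id, contig, start, end):
    return GeneModel(gene_id, contig, "+", start, end, exons=[(start, end)])


class TestGenesInQtls:
    def test_overlap_examples(self):
        genes = [_gene("in", "c1", 2000, 2500), _gene("out", "c1", 5001, 5600)]
        intervals = [QtlInterval(("q1",), GenomicInterval("c1", 100, 5000))]
        per_int, per_gene = genes_in_qtls(genes, intervals)
        assert per_int[("q1",)] == ["in"]
        assert "out" not in per_gene

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        genes = [
            _gene(f"g{i}", f"c{int(rng.integers(1, 3))}", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(1, 40_000, size=50))
        ]
        intervals = [
            QtlInterval(
                (f"q{i}",),
                GenomicInterval(f"c{int(rng.integers(1, 3))}", int(s), int(s) + 4000),
            )
            for i, s in enumerate(rng.integers(1, 40_000, size=10))
        ]
        per_int, per_gene = genes_in_qtls(genes, intervals)
        for q in intervals:
            expected = sorted(
                g.gene_id
                for g in genes
                if g.contig == q.interval.contig
                and g.start <= q.interval.end
                and q.interval.start <= g.end
            )
            assert per_int[q.qtl_ids] == expected


class TestFinalCandidates:
    def _cands(self, up, down, up_nonref=()):
        return CandidateSets(
            up=set(up), down=set(down),
            up_nonref=set(up_nonref), down_nonref=set(),
            evidence=pd.DataFrame(),
        )

    def test_restriction_and_counts(self):
        cands = self._cands({"g1", "g2"}, {"g3"}, up_nonref={"g2"})
        per_gene = {"g1": [("q1",)], "g2": [("q2",)]}
        report = final_candidates(cands, per_gene)
        assert report.up == {"g1", "g2"} and not report.down
        assert report.counts()["total"] == 2
        assert report.up_nonref == {"g2"}

    def test_no_overlap_empty(self):
        report = final_candidates(self._cands({"g1"}, set()), {})
        assert report.total == 0

    def test_shrinking_intervals_monotone(self, sim_study, sim_result):
        """Dropping intervals never adds candidates."""
        full = sim_result.report
        genes = sim_result.qtl_membership
        smaller = {g: v for g, v in genes.items() if len(v) > 1}
        shrunk = final_candidates(sim_result.candidates, smaller)
        assert shrunk.up <= full.up and shrunk.down <= full.down

    def test_totals_sum(self):
        assert candidate_counts(3, 4) == {"up": 3, "down": 4, "total": 7}
        assert candidate_counts({"a"}, {"b", "c"})["total"] == 3


def test_markers_from_frame_requires_placement_or_sequence():
    df = pd.DataFrame(
        [{"qtl_id": "q1", "marker_id": "m1", "sequence": "ACGTACGTACGTACGTACGT"}]
    )
    (m,) = markers_from_frame(df)
    assert m.sequence and not m.placed
    with pytest.raises(ValueError):
        Marker("m2", "q1")
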