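import numpy as np
import pytest

from seedmir._seq import gc_percent, revcomp
from seedmir.discovery import (Anchor, DiscoveryConfig, anchor_tags,
                               assign_canonical, detect_blocks,
                               evaluate_candidate, extract_windows, mfei,
                               Block, PrecursorCall)
from seedmir.folding import default_engine, hairpin_loops
from seedmir.preprocess import SmallReadTag
from seedmir.synthetic import generate_hairpin


def _anchor(seq, contig, start, strand="+", count=1):
    return Anchor(SmallReadTag(seq, count), contig, start, start + len(seq), strand)


class TestAnchorTags:
    def test_double_occurrence_reported_twice(self):
        tag = SmallReadTag("AACCGGAAUUCCGGAAUACC", 3)  # not its own revcomp
        contig = "U" * 10 + tag.sequence + "A" * 7 + tag.sequence + "U" * 5
        anchors = anchor_tags([tag], {"c": contig})
        assert [(a.start, a.strand) for a in anchors] == [(10, "+"), (37, "+")]
        for a in anchors:
            assert contig[a.start:a.end] == tag.sequence

    def test_minus_strand_only_match(self):
        tag = SmallReadTag("ACGGACGUACGUACGUACGU", 1)
        contig = "U" * 8 + revcomp(tag.sequence) + "A" * 8
        (a,) = anchor_tags([tag], {"c": contig})
        assert a.strand == "-"
        assert revcomp(contig[a.start:a.end]) == tag.sequence

    def test_planted_mature_anchors_inside_host(self, study):
        """Every planted canonical with clean reads anchors inside its host
        precursor span."""
        by_contig = {}
        for a in study.anchors:
            by_contig.setdefault((a.contig, a.tag.sequence), []).append(a)
        checked = 0
        for p in study.truth.precursors:
            if p.n_clean_reads < 10:
                continue
            hits = by_contig.get((p.contig, p.canonical), [])
            assert any(p.start <= a.start and a.end <= p.end for a in hits), p.id
            checked += 1
        assert checked > 10


class TestDetectBlocks:
    def test_two_block_clustering(self):
        seq = "ACGUACGUACGUACGUACGUA"
        anchors = [_anchor(seq, "c", s) for s in (100, 101, 102, 160, 161)]
        blocks, verdicts = detect_blocks(anchors, delta=3)
        assert len(blocks) == 2
        assert verdicts["+"] is True
        spans = sorted((b.start, b.end) for b in blocks)
        assert spans[0] == (100, 102 + 21)

    def test_dispersed_pattern_invalid(self):
        seq = "ACGUACGUACGUACGUACGUA"
        anchors = [_anchor(seq, "c", s) for s in range(100, 300, 5)]
        blocks, verdicts = detect_blocks(anchors, delta=3)
        assert len(blocks) > 2
        assert verdicts["+"] is False

    def test_strands_clustered_separately(self):
        seq = "ACGUACGUACGUACGUACGUA"
        anchors = [_anchor(seq, "c", 100, "+"), _anchor(seq, "c", 100, "-")]
        blocks, verdicts = detect_blocks(anchors)
        assert {b.strand for b in blocks} == {"+", "-"}
        assert verdicts == {"+": True, "-": True}

    def test_mixed_contigs_rejected(self):
        seq = "ACGUACGUACGUACGUACGUA"
        with pytest.raises(ValueError):
            detect_blocks([_anchor(seq, "a", 1), _anchor(seq, "b", 1)])


class TestExtractWindows:
    def _block(self, start, end, reads=10):
        seq = "ACGUACGUACGUACGUACGUA"
        return Block("c", "+", start, end,
                     [_anchor(seq, "c", start, count=reads)])

    def test_two_block_window_arithmetic(self):
        wins = extract_windows([self._block(100, 125), self._block(155, 180)],
                               contig_len=1000, flank=20)
        assert wins == [(80, 200)]

    def test_contig_edge_clipping(self):
        wins = extract_windows([self._block(5, 30), self._block(60, 85)],
                               contig_len=95, flank=20)
        assert wins == [(0, 95)]

    def test_one_block_two_windows(self):
        wins = extract_windows([self._block(400, 425)], contig_len=1000,
                               max_len=300, flank=20)
        assert wins == [(145, 445), (380, 680)]


class TestMfei:
    def test_arithmetic(self):
        assert mfei(-45, 100, 50) == pytest.approx(-0.90)
        assert mfei(0, 120, 40) == 0.0

    def test_monotone_in_mfe(self):
        vals = [mfei(m, 150, 45) for m in (-80, -60, -40)]
        assert vals == sorted(vals)

    def test_zero_gc_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mfei(-40, 100, 0)
        with pytest.raises(ValueError):
            mfei(-40, 0, 50)


@pytest.fixture(scope="module")
def toy_hairpin():
    rng = np.random.default_rng(42)
    seq, m5, m3, loop = generate_hairpin(rng, 120, 0.45, 21)
    return seq, m5, m3, loop


class TestEvaluateCandidate:
    CFG = DiscoveryConfig()

    def test_good_hairpin_accepted(self, toy_hairpin):
        seq, m5, m3, loop = toy_hairpin
        res = evaluate_candidate(seq, [(m5[0], m5[1], 15)], default_engine(), self.CFG)
        assert res["ok"], res
        assert res["arm"] == "5p"
        assert 40 <= abs(res["mfe"]) <= 100

    def test_nine_reads_rejected_min_reads(self, toy_hairpin):
        seq, m5, _, _ = toy_hairpin
        res = evaluate_candidate(seq, [(m5[0], m5[1], 9)], default_engine(), self.CFG)
        assert not res["ok"]
        assert "min_reads" in res["reasons"]

    def test_loop_centered_block_rejected(self, toy_hairpin):
        seq, _, _, loop = toy_hairpin
        mid = (loop[0] + loop[1]) // 2
        res = evaluate_candidate(seq, [(mid - 10, mid + 11, 15)],
                                 default_engine(), self.CFG)
        assert not res["ok"]
        assert "arm_overlap" in res["reasons"]


class TestAssignCanonical:
    def _call(self, seq, structure):
        return PrecursorCall(
            contig="c", strand="+", start=0, end=len(seq), sequence=seq,
            structure=structure, mfe=-50.0, gc_percent=gc_percent(seq),
            blocks=[], total_reads=530, verdict=True)

    def test_most_frequent_wins(self, toy_hairpin):
        seq, m5, m3, _ = toy_hairpin
        engine = default_engine()
        db, _ = engine.fold(seq)
        call = self._call(seq, db)
        a = _anchor(seq[m5[0]:m5[1]], "c", m5[0], count=500)
        b = _anchor(seq[m3[0]:m3[1]], "c", m3[0], count=30)
        call = assign_canonical(call, [a, b])
        assert call.canonical.sequence == seq[m5[0]:m5[1]]
        assert call.mature_arm == "5p"
        assert [(t.sequence, arm) for t, arm in call.isomirs] == \
               [(seq[m3[0]:m3[1]], "3p")]

    def test_tie_breaks_lexicographically(self, toy_hairpin):
        seq, m5, m3, _ = toy_hairpin
        db, _ = default_engine().fold(seq)
        call = self._call(seq, db)
        a = _anchor(seq[m5[0]:m5[1]], "c", m5[0], count=100)
        b = _anchor(seq[m3[0]:m3[1]], "c", m3[0], count=100)
        call = assign_canonical(call, [a, b])
        expected = min(seq[m5[0]:m5[1]], seq[m3[0]:m3[1]])
        assert call.canonical.sequence == expected


class TestFixtureRecovery:
    def test_known_vs_novel_labels_match_truth(self, study):
        truth_by_contig = {p.contig: p for p in study.truth.precursors}
        n = 0
        for call in study.accepted:
            p = truth_by_contig.get(call.contig)
            if p is None or call.canonical is None:
                continue
            if call.canonical.sequence == p.canonical:
                assert call.known == p.known, call.contig
                n += 1
        assert n >= 0.5 * len(study.accepted)

    def test_canonical_recovers_planted_mature(self, study):
        """The most frequent anchored tag equals the planted mature sequence
        for at least 95% of accepted precursors."""
        truth_by_contig = {p.contig: p for p in study.truth.precursors}
        good = total = 0
        for call in study.accepted:
            p = truth_by_contig.get(call.contig)
            if p is None:
                continue
            total += 1
            good += (call.canonical is not None
                     and call.canonical.sequence == p.canonical)
        assert total > 0
        assert good / total >= 0.95

    def test_canonical_count_dominates_isomirs(self, study):
        for call in study.accepted:
            if call.canonical is None:
                continue
            for tag, _arm in call.isomirs:
                assert call.canonical.count >= tag.count

    def test_accepted_flags_recheck(self, study):
        """Accepted calls re-validate independently: re-fold the reported
        candidate sequence, recompute MFE/MFEI and re-count anchored reads."""
        engine = default_engine()
        cfg = DiscoveryConfig()
        for call in study.accepted[:12]:
            db, mfe = engine.fold(call.sequence)
            assert db == call.structure
            assert mfe == pytest.approx(call.mfe, abs=1e-6)
            assert cfg.mfe_min <= abs(mfe) <= cfg.mfe_max
            assert abs(mfei(mfe, call.length, call.gc_percent)) > cfg.mfei_min
            assert len(hairpin_loops(db)) == 1
            inside = [a for a in study.anchors
                      if a.contig == call.contig and a.strand == call.strand
                      and a.start >= call.start and a.end <= call.end]
            assert sum(a.count for a in inside) >= cfg.min_reads
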