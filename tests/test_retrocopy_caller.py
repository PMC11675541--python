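"""Identification pipeline: stage rules on crafted inputs, end-to-end
recovery of planted events on the shared noiseless bundle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from retrokit import retrocopy_caller as rc
from retrokit import synthetic_data as sd
from retrokit.alignment_engine import ProteinHit, align_protein_to_target
from retrokit.io_formats import GeneModel, GenomeSequence, GenomicInterval, \
    RepeatFeature

from conftest import match_truth


def _hit(identity=0.9, coverage=0.9, aligned=100, contig="c", strand="+",
         start=0, end=300, qid="q", score=200):
    return ProteinHit(
        query_id=qid, contig_id=contig, strand=strand, t_start=start,
        t_end=end, q_start=0, q_end=aligned, score=score, identity=identity,
        coverage=coverage, aligned_length=aligned, query_length=aligned,
        n_frameshifts=0, net_frameshift=0,
    )


class TestFilterHits:
    @pytest.mark.parametrize("identity,coverage,aligned,kept", [
        (0.49, 0.9, 80, False),    # identity at/below the strict bound
        (0.50, 0.9, 80, False),
        (0.51, 0.9, 80, True),
        (0.8, 0.50, 80, False),    # coverage strict
        (0.8, 0.8, 50, False),     # length strict
        (0.8, 0.8, 51, True),
    ])
    def test_strict_boundaries(self, identity, coverage, aligned, kept):
        hits = rc.filter_candidate_hits(
            [_hit(identity=identity, coverage=coverage, aligned=aligned)])
        assert bool(hits) is kept


class TestMerge:
    def test_39bp_gap_merges_40_does_not(self):
        a = _hit(start=0, end=300)
        for gap, n in [(39, 1), (40, 2)]:
            b = _hit(start=300 + gap, end=600 + gap)
            loci = rc.merge_candidates([a, b])
            assert len(loci) == n
        merged = rc.merge_candidates([a, _hit(start=339, end=600)])[0]
        assert (merged.start, merged.end) == (0, 600)
        assert merged.merged_from == 2

    def test_opposite_strands_never_merge(self):
        a = _hit(start=0, end=300, strand="+")
        b = _hit(start=310, end=600, strand="-")
        assert len(rc.merge_candidates([a, b])) == 2

    def test_different_queries_never_merge(self):
        a = _hit(start=0, end=300, qid="q1")
        b = _hit(start=310, end=600, qid="q2")
        assert len(rc.merge_candidates([a, b])) == 2

    def test_transitive_and_order_invariant(self):
        hits = [_hit(start=s, end=s + 100) for s in (0, 130, 260)]
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            loci = rc.merge_candidates([hits[i] for i in perm])
            assert len(loci) == 1
            assert (loci[0].start, loci[0].end) == (0, 360)


class TestRetention:
    @pytest.mark.parametrize("n,lengths,kept", [
        (2, [60, 20], True),
        (2, [50, 40], False),      # strict > 50 on the longest lost intron
        (1, [500], False),
        (3, [51, 10, 10], True),
        (0, [], False),
    ])
    def test_rule(self, n, lengths, kept):
        r = rc.RetrocopyRecord("r", "s", "c", 0, 100, "+", "p",
                               introns_lost=n, lost_intron_lengths=lengths)
        assert bool(rc.apply_retention_rule([r])) is kept


class TestFanout:
    def _records(self, parent, n):
        return [rc.RetrocopyRecord(f"r{i}", "s", "c", i * 1000, i * 1000 + 100,
                                   "+", parent) for i in range(n)]

    def test_eleven_removed_ten_kept(self):
        assert rc.filter_parent_fanout(self._records("p", 11)) == []
        assert len(rc.filter_parent_fanout(self._records("p", 10))) == 10

    def test_empty_input(self):
        assert rc.filter_parent_fanout([]) == []

    def test_other_parents_unaffected(self):
        recs = self._records("p", 11) + self._records("q", 2)
        out = rc.filter_parent_fanout(recs)
        assert {r.parent_gene_id for r in out} == {"q"}


class TestCountLostIntrons:
    def _parent_and_hit(self, bundle, records):
        for r in records:
            t = match_truth(r, bundle.truth)
            if t and t.disruption == "none" and not t.fused_host:
                return bundle.genes[r.parent_gene_id], r
        raise AssertionError("no clean record in bundle")

    def test_full_length_copy_loses_all_introns(self, noiseless_bundle,
                                                noiseless_records):
        parent, r = self._parent_and_hit(noiseless_bundle, noiseless_records)
        expected = [l for _, l in parent.cds_intron_protein_positions()]
        assert r.introns_lost == len(expected)
        assert sorted(r.lost_intron_lengths) == sorted(expected)

    def test_truncated_alignment_counts_only_spanned_introns(self):
        # synthetic alignment covering the first half of a 4-exon parent
        genome = {"c": GenomeSequence("c", "A" * 4000)}
        parent = GeneModel(
            "p", "p.t", "c", "+",
            exons=[(0, 300), (500, 800), (1100, 1190), (1500, 1800)],
            cds=[(0, 300), (500, 800), (1100, 1190), (1500, 1800)],
            protein="M" * 329,
        )
        positions = parent.cds_intron_protein_positions()
        assert [int(p) for p, _ in positions] == [100, 200, 230]
        assert [l for _, l in positions] == [200, 300, 310]
        hit = _hit(aligned=150)
        hit.q_start, hit.q_end = 0, 150   # spans only the first intron
        n, lengths = rc.count_lost_introns(hit, parent)
        assert (n, lengths) == (1, [200])

    def test_retained_intron_suppressed_by_insertion(self):
        parent = GeneModel(
            "p", "p.t", "c", "+",
            exons=[(0, 300), (500, 800), (1100, 1400)],
            cds=[(0, 300), (500, 800), (1100, 1400)],
            protein="M" * 299,
        )
        hit = _hit(aligned=299)
        hit.q_start, hit.q_end = 0, 299
        hit.columns = [(2, -1, 0, 150)]        # fabricated gap structure
        # place a 150-nt insertion at protein position 100 (intron 1 is 200 bp)
        hit.gap_structure = lambda: [(100, 150)]
        n, lengths = rc.count_lost_introns(hit, parent)
        assert n == 1 and lengths == [300]     # only intron 2 counted lost

    def test_intronless_parent_errors(self):
        parent = GeneModel("p", "p.t", "c", "+", exons=[(0, 300)],
                           cds=[(0, 300)], protein="M" * 99)
        with pytest.raises(ValueError, match="cannot be a parent"):
            rc.count_lost_introns(_hit(), parent)


class TestDnaDuplicateFilter:
    def _genome_with_copies(self, n_copies, seed=0):
        rng = np.random.default_rng(seed)
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        backbone = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        seq = backbone
        positions = []
        for k in range(n_copies):
            pos = 2000 + k * 5000
            seq = seq[:pos] + unit + seq[pos + 400:]
            positions.append(pos)
        return {"c": GenomeSequence("c", seq)}, positions

    def _record(self, pos):
        return rc.RetrocopyRecord("r1", "s", "c", pos, pos + 400, "+", "p")

    def test_unique_record_kept(self):
        genome, pos = self._genome_with_copies(1)
        kept = rc.filter_dna_duplicates([self._record(pos[0])], genome, {})
        assert len(kept) == 1

    def test_two_copies_kept_three_removed(self):
        genome, pos = self._genome_with_copies(2)
        assert rc.filter_dna_duplicates([self._record(pos[0])], genome, {})
        genome, pos = self._genome_with_copies(3)
        assert rc.filter_dna_duplicates([self._record(pos[0])], genome, {}) == []


class TestClassification:
    def test_classes_match_planted_truth(self, noiseless_bundle,
                                         noiseless_records):
        for r in noiseless_records:
            t = match_truth(r, noiseless_bundle.truth)
            assert t is not None
            assert r.retro_class == t.expected_class
            assert (r.disruption != "none") == \
                   (t.expected_class == "retropseudogene")

    def test_chimeric_records_report_their_host(self, noiseless_bundle,
                                                noiseless_records):
        for r in noiseless_records:
            t = match_truth(r, noiseless_bundle.truth)
            if t.expected_class == "chimeric":
                assert r.overlaps_annotation
                host = noiseless_bundle.genes[r.host_gene_id]
                assert host.n_exons >= 2

    def test_class_invariants(self, noiseless_records):
        for r in noiseless_records:
            if r.retro_class in ("retrogene", "chimeric"):
                assert r.overlaps_annotation
            assert (r.retro_class == "retropseudogene") == \
                   (r.disruption != "none")


class TestEndToEnd:
    def test_noiseless_recovery_is_exact(self, noiseless_bundle,
                                         noiseless_records):
        truth = [t for t in noiseless_bundle.truth if t.kind == "retro"]
        matched = set()
        for r in noiseless_records:
            t = match_truth(r, noiseless_bundle.truth)
            assert t is not None, f"false positive at {r.contig_id}:{r.start}"
            assert t.event_id not in matched, "duplicate call"
            matched.add(t.event_id)
            assert r.parent_gene_id == t.parent_gene_id
        assert matched == {t.event_id for t in truth}

    def test_dna_duplications_never_called(self, noiseless_bundle,
                                           noiseless_records):
        for r in noiseless_records:
            for t in noiseless_bundle.truth:
                if t.kind == "dna_dup":
                    overlap = (t.contig_id == r.contig_id
                               and min(t.end, r.end) > max(t.start, r.start))
                    assert not overlap

    def test_dna_duplication_only_genome_yields_no_records(self):
        cfg = sd.SimulationConfig(
            n_contigs=2, contig_length=60_000, n_genes=8, n_retro_events=0,
            n_dna_duplications=5, substitution_probability=0.0, seed=13)
        bundle = sd.generate_bundle(cfg, with_expression=False)
        records = rc.call_retrocopies(bundle.genome, bundle.genes)
        assert records == []

    def test_kaks_zero_on_noiseless_copies(self, noiseless_records):
        with_kaks = [r for r in noiseless_records if r.ks is not None]
        assert with_kaks
        for r in with_kaks:
            assert r.ks == pytest.approx(0.0, abs=1e-9)
            assert r.age_class == "young"

    def test_raising_identity_threshold_never_adds_records(
            self, noiseless_bundle, noiseless_records):
        params = rc.CallerParams(min_identity=0.95)
        stricter = rc.call_retrocopies(noiseless_bundle.genome,
                                       noiseless_bundle.genes, params)
        assert len(stricter) <= len(noiseless_records)
        assert {(r.contig_id, r.start) for r in stricter} <= \
               {(r.contig_id, r.start) for r in noiseless_records}


class TestSummaries:
    def test_summary_from_published_style_counts(self):
        out = rc.summary_from_counts(1993, 1208, 1904, 541, 1133)
        assert out["retrocopies_per_parent"] == 1.65
        assert out["intact_pct"] == 95.5
        assert out["retrogene_chimeric_pct_of_intact"] == 87.9

    def test_summarize_called_catalog(self, noiseless_bundle,
                                      noiseless_records):
        out = rc.summarize_catalog(noiseless_records)
        assert sum(out["class_counts"].values()) == len(noiseless_records)
        n_pseudo = out["class_counts"].get("retropseudogene", 0)
        expected_intact_pct = round(
            100 * (1 - n_pseudo / len(noiseless_records)), 1)
        assert out["intact_pct"] == expected_intact_pct


class TestFlankProfile:
    def _record(self, start=50_000, end=51_000):
        return rc.RetrocopyRecord("r1", "s", "c", start, end, "+", "p")

    def test_no_repeats_all_zero(self):
        p = rc.flank_repeat_profile(self._record(), [])
        assert all(v == 0.0 for v in p.proportions.values())
        assert p.flank_span == 20_000

    def test_single_line_inside_one_flank(self):
        rep = RepeatFeature(GenomicInterval("c", 52_000, 54_000), "LINE")
        p = rc.flank_repeat_profile(self._record(), [rep])
        assert p.proportions["LINE"] == pytest.approx(2000 / 20_000)
        assert p.proportions["SINE"] == 0.0

    def test_contig_start_clips_denominator(self):
        r = self._record(start=2_000, end=3_000)
        p = rc.flank_repeat_profile(r, [])
        assert p.flank_span == 12_000

    def test_contig_end_clips_denominator(self):
        r = self._record(start=50_000, end=51_000)
        p = rc.flank_repeat_profile(r, [], contig_length=55_000)
        assert p.flank_span == 14_000

    def test_repeat_straddling_locus_counts_flank_part_only(self):
        rep = RepeatFeature(GenomicInterval("c", 49_500, 50_500), "SINE")
        p = rc.flank_repeat_profile(self._record(), [rep])
        assert p.proportions["SINE"] == pytest.approx(500 / 20_000)
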