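import numpy as np
import pytest

from cottonprx import alt_splicing as asx
from cottonprx import synthetic_data as sd
from cottonprx.io_formats import GeneModel, ModelConsistencyError


class TestOrfAndTranslate:
    @pytest.mark.parametrize(
        "seq,want",
        [
            ("ATGTGA", (3, 1)),
            ("ATGAAATAA", (6, 2)),
            ("CCCCCC", (0, 0)),       # no start
            ("ATGAAACCC", (0, 0)),    # start but no stop
            ("AAATGGCATGAAAGGGTGA", (9, 3)),  # longest ORF wins
        ],
    )
    def test_examples(self, seq, want):
        assert asx.orf_and_translate(seq) == want

    def test_tie_goes_to_most_five_prime_start(self):
        seq = "ATGAAATAGATGCCCTAG"  # two ORFs of 6 bp
        assert asx.orf_and_translate(seq) == (6, 2)

    def test_reported_length_excludes_stop(self):
        orf_bp, aa = asx.orf_and_translate("ATG" + "GGG" * 10 + "TAA")
        assert orf_bp == 33 and aa == 11


class TestFixtureArithmetic:
    def test_reference_orf(self, prx14_locus):
        seq = asx.transcript_sequence(
            prx14_locus.genome, prx14_locus.transcripts["ref"]
        )
        assert asx.orf_and_translate(seq) == (597, 199)

    def test_in_frame_retention_adds_fifteen(self, prx14_locus):
        seq = asx.transcript_sequence(
            prx14_locus.genome, prx14_locus.transcripts["leaf_AS2"]
        )
        assert asx.orf_and_translate(seq) == (612, 204)
        assert 597 + 15 == 612 == 3 * 204

    def test_exon_skipping_variant(self, prx14_locus):
        seq = asx.transcript_sequence(
            prx14_locus.genome, prx14_locus.transcripts["root_AS3"]
        )
        assert asx.orf_and_translate(seq) == (327, 109)
        assert 327 == 3 * 109

    def test_retention_reported_as_partial_ir(self, prx14_locus):
        events = asx.classify_events(
            prx14_locus.gene, prx14_locus.transcripts["leaf_AS2"]
        )
        (ev,) = events
        assert ev.type == "A3SS"
        assert ev.paper_label == "partial-IR"
        assert ev.length_bp == 15
        assert ev.ref_introns == (1,)

    def test_skipping_variant_has_es_and_a3ss(self, prx14_locus):
        events = asx.classify_events(
            prx14_locus.gene, prx14_locus.transcripts["root_AS3"]
        )
        types = {(e.type, e.length_bp) for e in events}
        es = next(e for e in events if e.type == "ES")
        assert es.ref_exons == (2, 3, 4)
        assert ("A3SS", 14) in types


class TestClassifyEvents:
    def test_identity_gives_empty_list(self, prx14_locus):
        assert asx.classify_events(
            prx14_locus.gene, prx14_locus.transcripts["ref"]
        ) == []

    def test_contig_mismatch_is_error(self, prx14_locus):
        alt = asx.TranscriptModel(
            "x", "g", "otherChr", "+", prx14_locus.gene.exons
        )
        with pytest.raises(ModelConsistencyError):
            asx.classify_events(prx14_locus.gene, alt)

    def test_all_six_event_types_round_trip(self):
        for seed in range(10):
            config = sd.SimulationConfig(seed=seed)
            _, gene, transcripts, truth = sd.gen_as_locus(config)
            for row in truth.itertuples():
                events = asx.classify_events(gene, transcripts[row.transcript])
                match = [e for e in events if e.type == row.event]
                assert len(match) == 1, (seed, row.transcript, events)
                ev = match[0]
                assert ev.length_bp == row.length_bp
                indices = ev.ref_exons if row.event in ("ES", "AFE", "ALE") \
                    else ev.ref_introns
                assert row.index in indices

    def test_ir_length_consistency(self):
        config = sd.SimulationConfig(seed=3)
        genome, gene, transcripts, truth = sd.gen_as_locus(config)
        ir = transcripts["IR"]
        events = asx.classify_events(gene, ir)
        retained = sum(e.length_bp for e in events if e.type == "IR")
        ref_len = sum(e - s for s, e in gene.exons)
        alt_len = sum(e - s for s, e in ir.exons)
        assert alt_len == ref_len + retained

    def test_invariance_under_coordinate_translation(self):
        config = sd.SimulationConfig(seed=4)
        _, gene, transcripts, truth = sd.gen_as_locus(config)
        shift = 10_000

        def moved_gene(m):
            return GeneModel(
                m.gene_id, m.contig, m.strand,
                [(s + shift, e + shift) for s, e in m.exons],
                [(s + shift, e + shift) for s, e in m.cds],
            )

        for row in truth.itertuples():
            t = transcripts[row.transcript]
            moved_t = asx.TranscriptModel(
                t.transcript_id, t.gene_id, t.contig, t.strand,
                [(s + shift, e + shift) for s, e in t.exons],
            )
            a = asx.classify_events(gene, t)
            b = asx.classify_events(moved_gene(gene), moved_t)
            assert [(e.type, e.length_bp, e.ref_introns, e.ref_exons)
                    for e in a] == [
                (e.type, e.length_bp, e.ref_introns, e.ref_exons) for e in b
            ]

    def test_minus_strand_locus_same_truth(self):
        plus = sd.gen_prx14_locus()
        minus = sd.gen_prx14_locus(strand="-")
        for name in ("leaf_AS2", "root_AS3"):
            a = asx.classify_events(plus.gene, plus.transcripts[name])
            b = asx.classify_events(minus.gene, minus.transcripts[name])
            assert [(e.type, e.length_bp, e.ref_introns, e.ref_exons)
                    for e in a] == [
                (e.type, e.length_bp, e.ref_introns, e.ref_exons) for e in b
            ]


class TestBoundaryDinucleotides:
    def test_canonical_intron(self):
        contig = "AAAA" + "GTAAGTTTCAG" + "CCCC"
        d, a, canonical = asx.boundary_dinucleotides(contig, (4, 15), "+")
        assert (d, a, canonical) == ("GT", "AG", True)

    def test_too_short_intron_is_error(self):
        with pytest.raises(ValueError):
            asx.boundary_dinucleotides("ACGTACGT", (2, 5), "+")

    def test_used_retention_boundary_noncanonical(self, prx14_locus):
        events = asx.classify_events(
            prx14_locus.gene, prx14_locus.transcripts["leaf_AS2"]
        )
        asx.annotate_boundaries(events, prx14_locus.genome, prx14_locus.gene)
        (ev,) = events
        # the 15-bp retention junction uses an AA acceptor: not GT..AG
        assert ev.donor == "GT" and ev.acceptor == "AA"
        assert ev.canonical is False

    def test_reference_introns_canonical_except_planted(self, prx14_locus):
        contig = prx14_locus.genome["simChr1"]
        flags = [
            asx.boundary_dinucleotides(contig, intron, "+")[2]
            for intron in prx14_locus.gene.introns
        ]
        assert flags == [True, True, True, True]

    def test_minus_strand_matches_plus_oracle(self):
        plus = sd.gen_prx14_locus()
        minus = sd.gen_prx14_locus(strand="-")
        for i, intron in enumerate(plus.gene.introns):
            d1, a1, c1 = asx.boundary_dinucleotides(
                plus.genome["simChr1"], intron, "+"
            )
            d2, a2, c2 = asx.boundary_dinucleotides(
                minus.genome["simChr1"], minus.gene.introns[i], "-"
            )
            assert (d1, a1, c1) == (d2, a2, c2)
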