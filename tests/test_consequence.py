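"""Transcript reconstruction: cryptic exons, frame, PTC and NMD logic."""

import pytest

from splicescan.consequence import (ConsequenceError, SpliceEvent, apply_event,
                                    build_cryptic_exon)
from splicescan.core_io import GenomicInterval, TranscriptModel
from splicescan.effects import SpliceScoringModel
from splicescan.simulate import SimConfig, simulate_genome

from splicescan.examples import CRYPTIC_EXON, build_cryptic_donor_locus as build_locus

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_translate(model, seqs):
    """Independent oracle: transcript position of the first in-frame stop."""
    cdna = model.spliced_sequence(seqs)
    start_g = model.cds[0] if model.strand == "+" else model.cds[1]
    start_t = model.transcript_coord(start_g)
    for k in range(start_t - 1, len(cdna) - 2, 3):
        if cdna[k : k + 3] in STOPS:
            return k + 1
    return None


class TestBuildCrypticExon:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_engineered_38nt_exon(self, strand):
        loc = build_locus(strand)
        exon = build_cryptic_exon(loc.model, loc.seqs, loc.new_donor_gpos)
        assert len(exon) == len(CRYPTIC_EXON) == 38

    def test_donor_outside_intron_is_error(self):
        loc = build_locus("+")
        with pytest.raises(ConsequenceError):
            build_cryptic_exon(loc.model, loc.seqs, loc.model.exons[0][0] + 5)

    def test_no_acceptor_in_range_is_error(self):
        loc = build_locus("+")
        with pytest.raises(ConsequenceError, match="no qualifying acceptor"):
            build_cryptic_exon(loc.model, loc.seqs, loc.new_donor_gpos,
                               acceptor_search_range=10)

    def test_adjacent_acceptor_empty_exon_is_error(self):
        """An acceptor AG immediately before the donor defines a 0-nt exon."""
        ppt = "TTTTCTTTTCCTTTCT"
        intron = "GTGAGT" + "CACACACA" + ppt + "AG" + "GTAAGT" + ppt + "AG"
        e1, e2 = "ATG" + "C" * 17, "G" * 17 + "TAA"
        seq = "A" * 8 + e1 + intron + e2 + "T" * 8
        ex1 = (9, 8 + len(e1))
        ex2 = (ex1[1] + len(intron) + 1, ex1[1] + len(intron) + len(e2))
        m = TranscriptModel("t", "chrZ", "+", [ex1, ex2], cds=(ex1[0], ex2[1]))
        seqs = {"chrZ": seq}
        donor_gpos = ex1[1] + 6 + 8 + len(ppt) + 2 + 1  # G right after the planted AG
        assert seq[donor_gpos - 1] == "G" and seq[donor_gpos - 3 : donor_gpos - 1] == "AG"
        with pytest.raises(ConsequenceError, match="empty cryptic exon"):
            build_cryptic_exon(m, seqs, donor_gpos, acceptor_search_range=5)

    def test_nearest_of_two_acceptors_chosen(self):
        loc = build_locus("+")
        # widen the search so the canonical intron-1 acceptor region (further
        # upstream) is also reachable; the nearest qualifying AG must win
        exon = build_cryptic_exon(loc.model, loc.seqs, loc.new_donor_gpos,
                                  acceptor_search_range=500)
        assert len(exon) == 38


class TestApplyEvent:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cryptic_inclusion_frameshifts_and_creates_ptc(self, strand):
        loc = build_locus(strand)
        exon = build_cryptic_exon(loc.model, loc.seqs, loc.new_donor_gpos)
        novel, rep = apply_event(
            loc.model, SpliceEvent("cryptic_exon_inclusion", new_exon=exon), loc.seqs
        )
        assert rep.frame_preserved is False  # 38 mod 3 == 2
        assert rep.ptc_offset is not None
        # oracle agreement: a stop exists and precedes the transcript's end
        stop_t = brute_force_translate(novel, loc.seqs)
        assert stop_t is not None and stop_t < len(novel.spliced_sequence(loc.seqs)) - 2

    def test_skip_of_3nt_exon_shortens_protein_by_one(self):
        """Skipping a 3-nt internal exon keeps frame and drops one residue."""
        # exon1 ATG + 9nt, exon2 3nt, exon3 with terminal stop
        ppt = "TTTTCTTTTCCTTTCT"
        i1 = "GTAAGT" + "CCCCAACC" + ppt + "AG"
        i2 = "GTAAGT" + "AAAACCAA" + ppt + "AG"
        e1, e2, e3 = "ATG" + "GCAGCTGCA", "GCC", "GGAGGCGGA" + "TAA"
        seq = "AAAA" + e1 + i1 + e2 + i2 + e3 + "TTTT"
        s1 = 5
        ex1 = (s1, s1 + len(e1) - 1)
        ex2 = (ex1[1] + len(i1) + 1, ex1[1] + len(i1) + len(e2))
        ex3 = (ex2[1] + len(i2) + 1, ex2[1] + len(i2) + len(e3))
        m = TranscriptModel("t", "c", "+", [ex1, ex2, ex3], cds=(ex1[0], ex3[1]))
        seqs = {"c": seq}
        assert m.spliced_sequence(seqs) == e1 + e2 + e3
        novel, rep = apply_event(m, SpliceEvent("exon_skip", skipped_exons=frozenset({2})), seqs)
        assert rep.frame_preserved is True
        assert rep.nmd_predicted is False
        ref_protein = (len(e1 + e2 + e3) - 3) // 3 - 1  # residues after ATG... whole protein incl Met
        assert rep.novel_protein_length == (len(e1 + e2 + e3)) // 3 - 1 - 1

    def test_skipping_terminal_exons_rejected(self):
        loc = build_locus("+")
        with pytest.raises(ConsequenceError):
            apply_event(loc.model, SpliceEvent("exon_skip", skipped_exons=frozenset({1})),
                        loc.seqs)

    def test_event_removing_start_codon_is_error(self):
        """A cryptic exon is fine, but a skip that drops the ATG exon must
        fail; here we fake it by skipping the internal exon of a model whose
        CDS starts there."""
        loc = build_locus("+")
        m = loc.model
        three = TranscriptModel("t3", m.chrom, "+",
                                [m.exons[0], m.exons[1], (m.tx_end + 50, m.tx_end + 70)],
                                cds=(m.exons[1][0], m.exons[1][1]))
        with pytest.raises(ConsequenceError, match="no ORF"):
            apply_event(three, SpliceEvent("exon_skip", skipped_exons=frozenset({2})),
                        loc.seqs)

    def test_untouched_exons_unchanged(self, small_sim):
        _, seqs, models, _, _ = small_sim
        m = next(m for m in models if m.n_exons >= 4)
        novel, _ = apply_event(m, SpliceEvent("exon_skip", skipped_exons=frozenset({2})), seqs)
        assert novel.exons == [ex for i, ex in enumerate(m.exons, 1) if i != 2]

    def test_frame_rule_matches_skipped_length_mod3(self, small_sim):
        """For every single internal-exon skip of the simulated models,
        frame_preserved <=> skipped exon length mod 3 == 0."""
        _, seqs, models, _, _ = small_sim
        for m in models:
            for i in range(2, m.n_exons):
                ex = m.exons[i - 1]
                _, rep = apply_event(m, SpliceEvent("exon_skip", skipped_exons=frozenset({i})), seqs)
                assert rep.frame_preserved == ((max(ex) - min(ex) + 1) % 3 == 0)

    def test_ptc_near_last_junction_never_nmd(self, small_sim):
        """No PTC, or a PTC within 50 nt of the final junction (or in the
        last exon), never predicts NMD."""
        _, seqs, models, _, _ = small_sim
        for m in models:
            for i in range(2, m.n_exons):
                _, rep = apply_event(
                    m, SpliceEvent("exon_skip", skipped_exons=frozenset({i})), seqs)
                if rep.ptc_offset is None:
                    assert rep.nmd_predicted is False
                elif rep.ptc_distance_to_last_junction is None or \
                        rep.ptc_distance_to_last_junction <= 50:
                    assert rep.nmd_predicted is False

    def test_nmd_set_for_deep_frameshift(self):
        """The engineered cryptic exon in a transcript with a distal final
        junction triggers the 50-nt rule."""
        loc = build_locus("+")
        m = loc.model
        # append a third exon far downstream so the last junction is distal
        ext_start = m.tx_end + 101
        seqs = {m.chrom: loc.seqs[m.chrom] + "C" * 400}
        three = TranscriptModel("t3", m.chrom, "+",
                                [m.exons[0], m.exons[1], (ext_start, ext_start + 99)],
                                cds=m.cds)
        exon = build_cryptic_exon(three, seqs, loc.new_donor_gpos)
        _, rep = apply_event(three, SpliceEvent("cryptic_exon_inclusion", new_exon=exon), seqs)
        assert rep.ptc_offset is not None
        assert rep.ptc_distance_to_last_junction > 50
        assert rep.nmd_predicted is True
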