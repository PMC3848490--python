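"""PWM scoring and the splice-effect rule engine on engineered loci."""

import numpy as np
import pytest

from splicescan.annotation import classify_location
from splicescan.core_io import Variant
from splicescan.effects import (SpliceEffectCall, SpliceScoringModel,
                                classify_effect, load_pwm, prioritise, score_site)

from splicescan.examples import build_cryptic_donor_locus as build_locus


@pytest.fixture(scope="module")
def scoring():
    return SpliceScoringModel()


def consensus(pwm):
    return "".join("ACGT"[int(r.argmax())] for r in pwm)


class TestScoreSite:
    def test_consensus_scores_100_anticonsensus_0(self, scoring):
        for pwm in (scoring.donor_pwm, scoring.acceptor_pwm):
            assert score_site(consensus(pwm), pwm) == pytest.approx(100.0)
            anti = "".join("ACGT"[int(r.argmin())] for r in pwm)
            assert score_site(anti, pwm) == pytest.approx(0.0)

    def test_single_mismatch_drops_by_position_contribution(self, scoring):
        pwm = scoring.donor_pwm
        cons = consensus(pwm)
        spans = pwm.max(axis=1) - pwm.min(axis=1)
        i = 5
        worst_base = "ACGT"[int(pwm[i].argmin())]
        mutated = cons[:i] + worst_base + cons[i + 1:]
        expected = 100.0 - 100.0 * spans[i] / spans.sum()
        assert score_site(mutated, pwm) == pytest.approx(expected)

    def test_monotone_toward_consensus(self, scoring):
        """Mutating any position toward the consensus base never lowers the score."""
        rng = np.random.default_rng(0)
        pwm = scoring.donor_pwm
        cons = consensus(pwm)
        for _ in range(200):
            w = "".join(rng.choice(list("ACGT"), size=pwm.shape[0]))
            i = int(rng.integers(pwm.shape[0]))
            improved = w[:i] + cons[i] + w[i + 1:]
            assert score_site(improved, pwm) >= score_site(w, pwm) - 1e-12

    def test_length_mismatch_is_error(self, scoring):
        with pytest.raises(ValueError):
            score_site("ACGT", scoring.donor_pwm)

    def test_ambiguous_base_skipped(self, scoring):
        cons = consensus(scoring.donor_pwm)
        assert score_site("N" + cons[1:], scoring.donor_pwm) == pytest.approx(100.0)


class TestClassifyEffect:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_acceptor_ablation_predicts_exon_skip(self, scoring, strand):
        loc_fix = build_locus(strand)
        m, seqs = loc_fix.model, loc_fix.seqs
        a_pos = loc_fix.acceptor_a_gpos
        ref = seqs[m.chrom][a_pos - 1]
        alt = "G" if ref != "G" else "C"
        v = Variant("rs_acc", m.chrom, a_pos, ref, alt, 0.1)
        loc = classify_location(v, m)
        assert loc.cls == "essential_splice_site" and loc.site_kind == "acceptor"
        call = classify_effect(v, m, scoring, loc, seqs)
        assert call.category == "acceptor_destroyed"
        assert call.predicted_event == "exon_skip"
        assert call.event_ordinal == 2  # skip of the exon following intron 1

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cryptic_donor_creation_with_upstream_acceptor(self, scoring, strand):
        loc_fix = build_locus(strand)
        v, m, seqs = loc_fix.cryptic_variant, loc_fix.model, loc_fix.seqs
        loc = classify_location(v, m)
        call = classify_effect(v, m, scoring, loc, seqs)
        assert call.category == "cryptic_donor_created"
        assert call.predicted_event == "cryptic_exon_inclusion"
        assert call.alt_score >= scoring.cryptic_threshold > call.ref_score

    def test_ppt_interruption_called_for_t_to_c(self, scoring):
        """A T>C in the polypyrimidine tract weakens the tract even though
        both bases are pyrimidines (T outweighs C)."""
        loc_fix = build_locus("+")
        m, seqs = loc_fix.model, loc_fix.seqs
        ilo, ihi = m.introns()[0]
        pos = ihi - 6  # inside the planted tract, outside the acceptor PWM...
        # ensure we sit on a T within the ppt window but beyond offset -15
        pos = ihi - 15
        assert seqs[m.chrom][pos - 1] == "T"
        v = Variant("rs_ppt", m.chrom, pos, "T", "C", 0.1)
        loc = classify_location(v, m)
        call = classify_effect(v, m, scoring, loc, seqs)
        assert call.category == "ppt_weakened"
        assert "polypyrimidine" in call.evidence

    def test_exonic_variant_far_from_boundaries_no_effect(self, scoring):
        loc_fix = build_locus("+")
        m, seqs = loc_fix.model, loc_fix.seqs
        pos = m.exons[0][0] + 20
        ref = seqs[m.chrom][pos - 1]
        alt = "T" if ref != "T" else "A"
        v = Variant("rs_mid", m.chrom, pos, ref, alt, 0.1)
        call = classify_effect(v, m, scoring, classify_location(v, m), seqs)
        assert call.category == "no_effect"

    def test_site_score_changed_near_donor(self, scoring):
        """An exonic variant 1 bp from the GT that flips the -1 G away from
        consensus changes the canonical donor score."""
        loc_fix = build_locus("+")
        m, seqs = loc_fix.model, loc_fix.seqs
        pos = m.exons[0][1]  # last exonic nt (the G of ...CAG)
        assert seqs[m.chrom][pos - 1] == "G"
        v = Variant("rs_near", m.chrom, pos, "G", "T", 0.1)
        loc = classify_location(v, m)
        assert loc.cls == "splice_region"
        call = classify_effect(v, m, scoring, loc, seqs)
        assert call.category == "site_score_changed"
        assert abs(call.score_delta) >= scoring.score_delta

    def test_simulated_essential_ablations_all_called(self, small_sim, scoring):
        """Recall 1 on constructions: every engineered GT/AG ablation is
        called donor/acceptor_destroyed."""
        _, seqs, models, _, _ = small_sim
        for m in models[:6]:
            for i, (ilo, ihi) in enumerate(m.introns(), 1):
                for gpos, kind in ((ilo if m.strand == "+" else ihi, "donor"),
                                   (ihi - 1 if m.strand == "+" else ilo + 1, "acceptor")):
                    ref = seqs[m.chrom][gpos - 1]
                    alt = "A" if ref != "A" else "C"
                    v = Variant("v", m.chrom, gpos, ref, alt, 0.1)
                    loc = classify_location(v, m)
                    assert loc.cls == "essential_splice_site"
                    call = classify_effect(v, m, scoring, loc, seqs)
                    assert call.category == f"{kind}_destroyed"


class TestPrioritise:
    def test_effect_calls_rank_above_no_effect(self):
        calls = [
            SpliceEffectCall("rs1", "t", "ppt_weakened"),
            SpliceEffectCall("rs2", "t", "no_effect"),
            SpliceEffectCall("rs3", "t", "acceptor_destroyed", 90, 40),
        ]
        ranked = prioritise(calls)
        assert [c.variant_id for c in ranked] == ["rs3", "rs1", "rs2"]

    def test_tie_break_is_id_lexicographic(self):
        a = SpliceEffectCall("rsB", "t", "ppt_weakened")
        b = SpliceEffectCall("rsA", "t", "ppt_weakened")
        assert [c.variant_id for c in prioritise([a, b])] == ["rsA", "rsB"]

    def test_empty_input(self):
        assert prioritise([]) == []
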