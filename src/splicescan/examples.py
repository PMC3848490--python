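"""A hand-built demonstration locus: a two-exon gene whose first intron
carries an engineerable cryptic donor site.

A single C>T inside the intron completes a GT donor dinucleotide in a
consensus-grade context; a qualifying acceptor AG sits 38 nt sense-upstream
of the new boundary, so activating the donor defines a 38-nt cryptic exon
whose inclusion frameshifts the transcript (38 mod 3 = 2) and introduces a
premature termination codon.  The locus can be built on either strand,
which makes it a convenient check that all splice geometry is
strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import TranscriptModel, Variant

_RC = str.maketrans("ACGT", "TGCA")

# sense-strand building blocks
EXON1 = "ATG" + "GCTGCA" * 9 + "CAG"  # 60 nt, multiple of 3, donor-friendly end
PPT = "TTTTCTTTTCCTTTCT"  # polypyrimidine tract
#: the 38-nt cryptic exon; the leading TAAATAAATAA places a stop codon in
#: every reading frame so a PTC is guaranteed on inclusion
CRYPTIC_EXON = ("TAAATAAATAA" + "GCCGCAGCTGCAGCTGCAGCTGCAGCA")[:38]
PRE = "GTGAGT" + "CACACACACACACACACACA"  # canonical donor end of intron 1
INTRON1 = PRE + PPT + "AG" + CRYPTIC_EXON + "GC" + "GAGT" + "CAAACAAACA" + PPT + "AG"
EXON2 = "GGA" * 20 + "TAA"  # 63 nt, terminal stop
FLANK = "AAAACCCC"


@dataclass
class CrypticDonorLocus:
    seqs: dict[str, str]
    model: TranscriptModel
    #: genomic position of the G that precedes the engineered GT (the first
    #: intron-retained base once the variant creates the donor)
    new_donor_gpos: int
    #: the C>T substitution (sense strand) that creates the cryptic donor
    cryptic_variant: Variant
    #: genomic position of the A of intron 1's essential acceptor AG
    acceptor_a_gpos: int
    strand: str


def build_cryptic_donor_locus(strand: str = "+", chrom: str = "chrT") -> CrypticDonorLocus:
    sense = FLANK + EXON1 + INTRON1 + EXON2 + FLANK
    L = len(sense)
    off = len(FLANK)
    e1_s = (off + 1, off + len(EXON1))
    i1_s = (e1_s[1] + 1, e1_s[1] + len(INTRON1))
    e2_s = (i1_s[1] + 1, i1_s[1] + len(EXON2))
    g_sense = i1_s[0] + len(PRE) + len(PPT) + 2 + len(CRYPTIC_EXON)
    c_sense = g_sense + 1
    assert sense[g_sense - 1] == "G" and sense[c_sense - 1] == "C"
    acceptor_a_sense = i1_s[1] - 1
    assert sense[acceptor_a_sense - 1 : i1_s[1]] == "AG"

    if strand == "+":
        genome = sense
        conv = lambda p: p
        ref, alt = "C", "T"
    else:
        genome = sense[::-1].translate(_RC)
        conv = lambda p: L - p + 1
        ref, alt = "G", "A"  # complement of the sense-strand C>T

    exons = [tuple(sorted((conv(a), conv(b)))) for a, b in (e1_s, e2_s)]
    lo = min(min(ex) for ex in exons)
    hi = max(max(ex) for ex in exons)
    model = TranscriptModel("txA", chrom, strand, exons, cds=(lo, hi))
    return CrypticDonorLocus(
        seqs={chrom: genome},
        model=model,
        new_donor_gpos=conv(g_sense),
        cryptic_variant=Variant("rs_cryptic", chrom, conv(c_sense), ref, alt, 0.2),
        acceptor_a_gpos=conv(acceptor_a_sense),
        strand=strand,
    )
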