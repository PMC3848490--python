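"""Transcript-consequence reconstruction for predicted splice events.

Given a transcript model, its genomic sequence and a splice event (internal
exon skip or cryptic-exon inclusion), this module rebuilds the novel mRNA,
re-translates the CDS from the annotated start codon, and reports reading
frame, premature-termination-codon (PTC) position, and predicted
nonsense-mediated-decay (NMD) status under the 50-nt rule: a PTC more than
50 nt upstream of the final exon-exon junction marks the transcript as an
NMD substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import GenomicInterval, TranscriptModel
from .effects import SpliceScoringModel, find_upstream_acceptor

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ConsequenceError(ValueError):
    """The event is invalid for the model (no acceptor, no ORF, ...)."""


@dataclass(frozen=True)
class SpliceEvent:
    """An exon skip (internal exon ordinals) or a cryptic-exon inclusion
    (a new exon strictly inside one intron)."""

    kind: str  # exon_skip | cryptic_exon_inclusion
    skipped_exons: frozenset[int] = frozenset()
    new_exon: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.kind == "exon_skip":
            if not self.skipped_exons:
                raise ValueError("exon_skip requires skipped_exons")
        elif self.kind == "cryptic_exon_inclusion":
            if self.new_exon is None:
                raise ValueError("cryptic_exon_inclusion requires new_exon")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class ConsequenceReport:
    novel_cdna_length: int
    frame_preserved: bool
    ptc_offset: int | None  # nt from the event's 5' edge to the PTC start
    ptc_distance_to_last_junction: int | None
    nmd_predicted: bool
    novel_protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.nmd_predicted and self.ptc_offset is None:
            raise ValueError("nmd_predicted requires a PTC")


def build_cryptic_exon(
    model: TranscriptModel,
    seqs: dict[str, str],
    donor_pos: int,
    scoring: SpliceScoringModel | None = None,
    acceptor_search_range: int = 200,
) -> GenomicInterval:
    """The cryptic exon defined by a variant-created donor boundary.

    ``donor_pos`` is the genomic position of the G of the new donor GT (the
    first base spliced out downstream of the cryptic exon); it must lie
    inside an intron.  The exon runs from the first base after the nearest
    qualifying upstream acceptor AG to the last base before the new donor;
    its length is the sense distance between the two boundaries minus one.
    """
    scoring = scoring or SpliceScoringModel()
    if not any(lo <= donor_pos <= hi for lo, hi in model.introns()):
        raise ConsequenceError(f"donor position {donor_pos} is not intronic in "
                               f"{model.transcript_id}")
    hit = find_upstream_acceptor(seqs, model, donor_pos, scoring,
                                 search_range=acceptor_search_range, min_distance=1)
    if hit is None:
        raise ConsequenceError(
            f"no qualifying acceptor within {acceptor_search_range} nt upstream "
            f"of donor at {donor_pos}"
        )
    g_pos, _score = hit
    if abs(donor_pos - g_pos) == 1:
        raise ConsequenceError("acceptor immediately adjacent to donor: empty cryptic exon")
    if model.strand == "+":
        lo, hi = g_pos + 1, donor_pos - 1
    else:
        lo, hi = donor_pos + 1, g_pos - 1
    return GenomicInterval(model.chrom, lo, hi, model.strand)


def _insert_exon(model: TranscriptModel, new_exon: GenomicInterval) -> list[tuple[int, int]]:
    for i, (ilo, ihi) in enumerate(model.introns(), start=1):
        if ilo <= new_exon.start and new_exon.end <= ihi:
            exons = list(model.exons)
            exons.insert(i, (new_exon.start, new_exon.end))
            return exons
    raise ConsequenceError(
        f"new exon {new_exon.start}-{new_exon.end} is not strictly inside an "
        f"intron of {model.transcript_id}"
    )


def _first_stop(cdna: str, start_t: int) -> int | None:
    """Transcript coordinate (1-based) of the first in-frame stop codon at or
    after ``start_t``, or None."""
    for k in range(start_t - 1, len(cdna) - 2, 3):
        if cdna[k : k + 3] in STOP_CODONS:
            return k + 1
    return None


def _cds_start_gpos(model: TranscriptModel) -> int:
    if model.cds is None:
        raise ConsequenceError(f"{model.transcript_id} has no annotated CDS")
    return model.cds[0] if model.strand == "+" else model.cds[1]


def apply_event(
    model: TranscriptModel,
    event: SpliceEvent,
    seqs: dict[str, str],
    nmd_junction_threshold: int = 50,
) -> tuple[TranscriptModel, ConsequenceReport]:
    """Rebuild the mRNA implied by ``event`` and report its consequence.

    frame_preserved is (inserted - deleted coding length) mod 3 == 0; a PTC
    is an in-frame stop whose genomic position differs from the reference
    transcript's stop codon; NMD is predicted when the PTC starts more than
    ``nmd_junction_threshold`` nt upstream of the last exon-exon junction.
    """
    n = model.n_exons
    if event.kind == "exon_skip":
        bad = [i for i in event.skipped_exons if i <= 1 or i >= n]
        if bad:
            raise ConsequenceError(f"can only skip internal exons, got {sorted(bad)}")
        new_exons = [ex for i, ex in enumerate(model.exons, 1) if i not in event.skipped_exons]
    else:
        new_exons = _insert_exon(model, event.new_exon)

    novel = TranscriptModel(
        transcript_id=model.transcript_id + ".novel",
        chrom=model.chrom,
        strand=model.strand,
        exons=new_exons,
        cds=model.cds,
        gene_id=model.gene_id,
    )

    cdna = novel.spliced_sequence(seqs)
    report_kwargs = dict(novel_cdna_length=len(cdna))

    # coding-length change of the event
    if model.cds is not None:
        cds_lo, cds_hi = model.cds
        if event.kind == "exon_skip":
            deleted = sum(
                max(0, min(max(ex), cds_hi) - max(min(ex), cds_lo) + 1)
                for i, ex in enumerate(model.exons, 1)
                if i in event.skipped_exons
            )
            inserted = 0
        else:
            deleted = 0
            # the inclusion is coding iff its intron lies within the CDS span
            inside_cds = cds_lo <= event.new_exon.start and event.new_exon.end <= cds_hi
            inserted = len(event.new_exon) if inside_cds else 0
        frame_preserved = (inserted - deleted) % 3 == 0
    else:
        frame_preserved = True

    if model.cds is None:
        return novel, ConsequenceReport(
            novel_cdna_length=len(cdna), frame_preserved=True, ptc_offset=None,
            ptc_distance_to_last_junction=None, nmd_predicted=False,
        )

    start_g = _cds_start_gpos(model)
    start_t = novel.transcript_coord(start_g)
    if start_t is None:
        raise ConsequenceError("no ORF: event removes the annotated start codon")
    if cdna[start_t - 1 : start_t + 2] != "ATG":
        raise ConsequenceError("no ORF: annotated start codon is not ATG in the novel transcript")

    stop_t = _first_stop(cdna, start_t)

    # genomic identity of the reference stop codon's first base
    ref_cdna = model.spliced_sequence(seqs)
    ref_start_t = model.transcript_coord(start_g)
    ref_stop_t = _first_stop(ref_cdna, ref_start_t) if ref_start_t else None
    ref_stop_g = model.genomic_coord(ref_stop_t) if ref_stop_t else None

    ptc_offset = None
    ptc_dist = None
    nmd = False
    protein_len = None
    if stop_t is not None:
        protein_len = (stop_t - start_t) // 3
        stop_g = novel.genomic_coord(stop_t)
        is_ptc = ref_stop_g is None or stop_g != ref_stop_g
        if is_ptc:
            # event's 5' edge in novel-transcript coordinates
            if event.kind == "exon_skip":
                first_skipped = min(event.skipped_exons)
                kept_before = sum(
                    max(ex) - min(ex) + 1
                    for i, ex in enumerate(model.exons, 1)
                    if i < first_skipped
                )
                edge_t = kept_before + 1
            else:
                edge_t = novel.transcript_coord(
                    event.new_exon.start if model.strand == "+" else event.new_exon.end
                )
            ptc_offset = stop_t - edge_t
            if novel.n_exons > 1:
                last_junction_t = sum(
                    max(ex) - min(ex) + 1 for ex in novel.exons[:-1]
                )
                ptc_dist = last_junction_t - stop_t
                nmd = ptc_dist > nmd_junction_threshold
    return novel, ConsequenceReport(
        novel_cdna_length=len(cdna),
        frame_preserved=frame_preserved,
        ptc_offset=ptc_offset,
        ptc_distance_to_last_junction=ptc_dist,
        nmd_predicted=nmd,
        novel_protein_length=protein_len,
    )
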