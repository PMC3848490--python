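"""Domain types and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 1-based inclusive (the VCF/GFF3 convention);
BED's 0-based half-open coordinates are converted only at the file boundary.
Splice-site sequence logic elsewhere in the package operates on the
transcript (sense) strand; minus-strand sequences are reverse-complemented
at extraction time.

Chromosome names are compared verbatim — no "chr" prefix normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """A file or record violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with 1-based position and minor-allele frequency."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float = 0.0

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single nucleotides: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) for {self.id}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf {self.maf} outside [0, 0.5] for {self.id}")


@dataclass
class TranscriptModel:
    """A stranded exon structure with an optional CDS over a genomic sequence.

    ``exons`` is stored in transcript (5'->3') orientation: ascending genomic
    coordinates on '+', descending on '-'.  ``cds`` is the genomic interval
    (start <= end) spanned by the coding sequence, or None for non-coding
    models.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        # normalize to transcript orientation
        self.exons = by_start if self.strand == "+" else by_start[::-1]
        if not self.gene_id:
            self.gene_id = self.transcript_id

    @property
    def tx_start(self) -> int:
        """Leftmost genomic coordinate of the transcript."""
        return min(s for s, _ in self.exons)

    @property
    def tx_end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Introns in transcript orientation, each as a genomic (lo, hi) pair
        ordered (start<=end) regardless of strand."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out

    def exon_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons]

    def spliced_sequence(self, seqs: dict[str, str]) -> str:
        """The mature (exon-joined) transcript sequence, sense strand."""
        return "".join(
            extract_sequence(seqs, GenomicInterval(self.chrom, s, e, self.strand))
            for s, e in self.exons
        )

    def transcript_coord(self, gpos: int) -> int | None:
        """1-based position of a genomic (exonic) base in the mature
        transcript, or None if the base is not exonic."""
        offset = 0
        for s, e in self.exons:
            lo, hi = min(s, e), max(s, e)
            if lo <= gpos <= hi:
                within = (gpos - lo) if self.strand == "+" else (hi - gpos)
                return offset + within + 1
            offset += hi - lo + 1
        return None

    def genomic_coord(self, tpos: int) -> int:
        """Genomic position of 1-based transcript coordinate ``tpos``."""
        offset = 0
        for s, e in self.exons:
            lo, hi = min(s, e), max(s, e)
            n = hi - lo + 1
            if tpos <= offset + n:
                within = tpos - offset - 1
                return lo + within if self.strand == "+" else hi - within
            offset += n
        raise IndexError(f"transcript coordinate {tpos} beyond {self.transcript_id}")


# ---------------------------------------------------------------------------
# sequence handling


def extract_sequence(seqs: dict[str, str], interval: GenomicInterval) -> str:
    """Sense-strand sequence of ``interval`` from a chrom -> sequence dict."""
    chrom_seq = seqs[interval.chrom]
    sub = chrom_seq[interval.start - 1 : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# variants


def read_variants(path: str | Path, format: str = "vcf") -> list[Variant]:
    """Read biallelic SNVs from a VCF 4.x file.

    Multiallelic and indel records are skipped; a summary count of skipped
    records is logged.  MAF is taken from the AF INFO field when present
    (folded to the minor allele), else 0.
    """
    if format != "vcf":
        raise ValueError(f"unsupported variant format {format!r}")
    from cyvcf2 import VCF

    out: list[Variant] = []
    n_skipped = 0
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            n_skipped += 1
            continue
        af = rec.INFO.get("AF")
        maf = 0.0
        if af is not None:
            af = float(af[0] if isinstance(af, tuple) else af)
            maf = min(af, 1.0 - af)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        try:
            out.append(Variant(vid, rec.CHROM, rec.POS, ref, alt, maf))
        except ValueError as exc:
            log.warning("skipping malformed record %s: %s", vid, exc)
            n_skipped += 1
    if n_skipped:
        log.info("read_variants: skipped %d non-SNV/malformed records", n_skipped)
    return out


def write_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    genotypes=None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variants as VCF 4.2; ``genotypes`` is an optional (n_haplotypes,
    n_variants) 0/1 array written as phased diploid GT columns (haplotypes
    2i, 2i+1 form sample i)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        if contig_lengths:
            for chrom, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        n_samples = 0
        if genotypes is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            n_samples = genotypes.shape[0] // 2
            cols += ["FORMAT"] + [f"S{i}" for i in range(n_samples)]
        fh.write("\t".join(cols) + "\n")
        for j, v in enumerate(variants):
            if genotypes is not None:
                af = float(genotypes[:, j].mean())
            else:
                af = v.maf
            row = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", f"AF={af:.6g}"]
            if genotypes is not None:
                row.append("GT")
                col = genotypes[:, j]
                row += [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "gff3") -> list[TranscriptModel]:
    """Read transcript models from GFF3 or BED12, normalized to 1-based
    inclusive coordinates with exons in transcript orientation."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unsupported gene-model format {format!r}")


def _read_gff3(path: str | Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
        cds_feats = [(c.start, c.end) for c in db.children(tx, featuretype="CDS")]
        cds = None
        if cds_feats:
            cds = (min(s for s, _ in cds_feats), max(e for _, e in cds_feats))
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.id
        models.append(
            TranscriptModel(tx.id, tx.seqid, tx.strand, exons, cds=cds, gene_id=gene_id)
        )
    return models


def _read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"BED12 line has {len(f)} fields: {line[:80]}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            cds = (thick_start + 1, thick_end) if thick_end > thick_start else None
            models.append(TranscriptModel(name, chrom, strand, exons, cds=cds))
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs_gene = f"ID=gene:{m.gene_id}"
            fh.write(
                f"{m.chrom}\tsplicescan\tgene\t{m.tx_start}\t{m.tx_end}\t.\t{m.strand}\t.\t{attrs_gene}\n"
            )
            fh.write(
                f"{m.chrom}\tsplicescan\tmRNA\t{m.tx_start}\t{m.tx_end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent=gene:{m.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), 1):
                fh.write(
                    f"{m.chrom}\tsplicescan\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            if m.cds is not None:
                lo, hi = m.cds
                for s, e in sorted(m.exons):
                    cs, ce = max(s, lo), min(e, hi)
                    if cs <= ce:
                        fh.write(
                            f"{m.chrom}\tsplicescan\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t"
                            f"ID={m.transcript_id}.cds;Parent={m.transcript_id}\n"
                        )


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exons = sorted(m.exons)
            chrom_start = exons[0][0] - 1
            chrom_end = exons[-1][1]
            if m.cds is not None:
                thick_start, thick_end = m.cds[0] - 1, m.cds[1]
            else:
                thick_start = thick_end = chrom_start
            sizes = ",".join(str(e - s + 1) for s, e in exons)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(chrom_start), str(chrom_end), m.transcript_id,
                        "0", m.strand, str(thick_start), str(thick_end), "0",
                        str(len(exons)), sizes, starts,
                    ]
                )
                + "\n"
            )
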