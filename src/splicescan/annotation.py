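"""Splice-location classification of variants against transcript models.

Windows follow the Ensembl-style terms the field's annotators use:

* essential_splice_site — the two invariant intronic nt adjacent to an exon
  (the donor GT at intronic offsets +1/+2, the acceptor AG at -2/-1);
* splice_region — the first/last ``exonic_window`` (default 3) nt of an exon
  at a spliced boundary, or intronic offsets +3..+8 (donor side) /
  -8..-3 (acceptor side);
* otherwise exonic / intronic / intergenic by containment.

All offsets are in transcript (sense) orientation: positive into the intron
from a donor, negative upstream from an acceptor; exonic positions carry the
mirrored sign (last exonic nt before a donor = -1, first exonic nt after an
acceptor = +1).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import TranscriptModel, Variant

#: most splice-proximal first
SEVERITY_ORDER = ("essential_splice_site", "splice_region", "exonic", "intronic", "intergenic")
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

SPLICE_CLASSES = frozenset({"essential_splice_site", "splice_region"})


@dataclass(frozen=True)
class SpliceWindows:
    """Window sizes (nt) defining the splice-region zone; config-overridable."""

    exonic: int = 3
    intronic_min: int = 3
    intronic_max: int = 8
    essential: int = 2


@dataclass(frozen=True)
class SpliceLocation:
    variant_id: str
    transcript_id: str
    cls: str
    site_kind: str = "none"  # donor | acceptor | none
    intron_or_exon_number: int = 0  # 1-based ordinal in transcript orientation
    offset: int = 0  # signed nt from the nearest exon-intron boundary

    def __post_init__(self) -> None:
        if self.cls not in _SEVERITY_RANK:
            raise ValueError(f"unknown class {self.cls!r}")
        if self.cls == "essential_splice_site" and self.site_kind == "none":
            raise ValueError("essential_splice_site requires a donor/acceptor site_kind")


def _donor_exon_offset(model: TranscriptModel, exon: tuple[int, int], pos: int) -> int:
    """1-based distance from pos to the exon's 3' (donor-side) end, sense strand."""
    lo, hi = min(exon), max(exon)
    return (hi - pos + 1) if model.strand == "+" else (pos - lo + 1)


def _acceptor_exon_offset(model: TranscriptModel, exon: tuple[int, int], pos: int) -> int:
    """1-based distance from pos to the exon's 5' (acceptor-side) start."""
    lo, hi = min(exon), max(exon)
    return (pos - lo + 1) if model.strand == "+" else (hi - pos + 1)


def classify_location(
    variant: Variant, model: TranscriptModel, windows: SpliceWindows = SpliceWindows()
) -> SpliceLocation:
    """Classify one variant against one transcript model."""
    pos = variant.pos
    if variant.chrom != model.chrom or not (model.tx_start <= pos <= model.tx_end):
        return SpliceLocation(variant.id, model.transcript_id, "intergenic")

    w = windows
    n = model.n_exons
    for i, exon in enumerate(model.exons, start=1):  # transcript order
        lo, hi = min(exon), max(exon)
        if lo <= pos <= hi:
            d_don = _donor_exon_offset(model, exon, pos)  # 1 = last exonic nt
            d_acc = _acceptor_exon_offset(model, exon, pos)
            if i < n and d_don <= w.exonic:
                return SpliceLocation(variant.id, model.transcript_id,
                                      "splice_region", "donor", i, -d_don)
            if i > 1 and d_acc <= w.exonic:
                return SpliceLocation(variant.id, model.transcript_id,
                                      "splice_region", "acceptor", i, d_acc)
            off = -d_don if d_don <= d_acc else d_acc
            return SpliceLocation(variant.id, model.transcript_id, "exonic", "none", i, off)

    for i, (ilo, ihi) in enumerate(model.introns(), start=1):
        if not (ilo <= pos <= ihi):
            continue
        # sense-strand offsets: +1 = first intron base after the donor exon,
        # -1 = last intron base before the acceptor exon
        if model.strand == "+":
            off_d = pos - ilo + 1
            off_a = pos - ihi - 1
        else:
            off_d = ihi - pos + 1
            off_a = ilo - pos - 1
        if off_d <= w.essential:
            return SpliceLocation(variant.id, model.transcript_id,
                                  "essential_splice_site", "donor", i, off_d)
        if off_a >= -w.essential:
            return SpliceLocation(variant.id, model.transcript_id,
                                  "essential_splice_site", "acceptor", i, off_a)
        if off_d <= w.intronic_max:
            return SpliceLocation(variant.id, model.transcript_id,
                                  "splice_region", "donor", i, off_d)
        if off_a >= -w.intronic_max:
            return SpliceLocation(variant.id, model.transcript_id,
                                  "splice_region", "acceptor", i, off_a)
        off = off_d if off_d <= -off_a else off_a
        return SpliceLocation(variant.id, model.transcript_id, "intronic", "none", i, off)

    # inside the transcript span but between exons/introns cannot happen;
    # defensive fallback
    return SpliceLocation(variant.id, model.transcript_id, "intergenic")


@dataclass
class AnnotationSummary:
    n_variants: int
    n_splice: int

    @property
    def splice_percentage(self) -> float:
        return 100.0 * self.n_splice / self.n_variants if self.n_variants else 0.0


class _ModelIndex:
    """Per-chromosome lookup of transcripts overlapping a position."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self._by_chrom: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
        for m in models:
            self._by_chrom.setdefault(m.chrom, []).append((m.tx_start, m.tx_end, m))
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: t[0])

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        lst = self._by_chrom.get(chrom, [])
        starts = [s for s, _, _ in lst]
        k = bisect_right(starts, pos)
        return [m for s, e, m in lst[:k] if e >= pos]


def worst_class(classes: Iterable[str]) -> str:
    return min(classes, key=_SEVERITY_RANK.get, default="intergenic")


def annotate_set(
    variants: Sequence[Variant],
    models: Sequence[TranscriptModel],
    windows: SpliceWindows = SpliceWindows(),
) -> tuple[list[SpliceLocation], dict[str, str], AnnotationSummary]:
    """Annotate a variant set against all overlapping transcripts.

    Returns per-(variant, transcript) records, the variant-level class
    (the most splice-proximal across transcripts), and a summary counting
    unique variant ids with a splice class.
    """
    index = _ModelIndex(models)
    records: list[SpliceLocation] = []
    variant_cls: dict[str, str] = {}
    for v in variants:
        hits = index.overlapping(v.chrom, v.pos)
        if not hits:
            locs = [SpliceLocation(v.id, "", "intergenic")]
        else:
            locs = [classify_location(v, m, windows) for m in hits]
        records.extend(locs)
        cls = worst_class(loc.cls for loc in locs)
        prev = variant_cls.get(v.id)
        if prev is None or _SEVERITY_RANK[cls] < _SEVERITY_RANK[prev]:
            variant_cls[v.id] = cls
    n_total = len(variant_cls)
    n_splice = sum(1 for c in variant_cls.values() if c in SPLICE_CLASSES)
    return records, variant_cls, AnnotationSummary(n_total, n_splice)


def locations_to_dataframe(records: Sequence[SpliceLocation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "transcript_id": r.transcript_id,
                "class": r.cls,
                "site_kind": r.site_kind,
                "ordinal": r.intron_or_exon_number,
                "offset": r.offset,
            }
            for r in records
        ]
    )
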