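"""Rule-based prediction of splice-site effects of variants.

A position-weight-matrix scorer over packaged donor/acceptor frequency
matrices stands in for the web-based splice-site predictors commonly used
for this kind of triage.  Scores are normalized Shapiro–Senapathy style:

    score = 100 * (sum w - sum w_min) / (sum w_max - sum w_min)

so the consensus sequence scores 100 and the anti-consensus 0.

``classify_effect`` applies rules in priority order: essential GT/AG
ablation, cryptic-site creation, cryptic-acceptor ablation, polypyrimidine
tract weakening, and canonical site score change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import SpliceLocation
from .core_io import TranscriptModel, Variant

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: donor PWM layout: 3 exonic nt then 6 intronic nt; index of the intron's
#: first base (the G of GT) within the 9-nt window
DONOR_SPAN = 9
DONOR_INTRON_START = 3
#: acceptor PWM layout: 14 intronic nt then 1 exonic nt; index of the exon's
#: first base within the 15-nt window
ACCEPTOR_SPAN = 15
ACCEPTOR_EXON_START = 14

CATEGORY_SEVERITY = (
    "acceptor_destroyed",
    "donor_destroyed",
    "cryptic_donor_created",
    "cryptic_acceptor_created",
    "cryptic_acceptor_destroyed",
    "ppt_weakened",
    "site_score_changed",
    "no_effect",
)
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_SEVERITY)}


def load_pwm(which: str, path: str | Path | None = None) -> np.ndarray:
    """Load a PWM as an (n_positions, 4) array over A,C,G,T.

    ``which`` is "donor" or "acceptor"; with no path the packaged matrix is
    used.  PWM files are TSV with columns pos, A, C, G, T.
    """
    if path is None:
        name = {"donor": "donor_pwm.tsv", "acceptor": "acceptor_pwm.tsv"}[which]
        with resources.files("splicescan.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("pos") if which == "acceptor" else df.sort_values("pos")
    return df[["A", "C", "G", "T"]].to_numpy(dtype=float)


@dataclass
class SpliceScoringModel:
    """PWMs plus the thresholds of the rule engine.

    cryptic_threshold and score_delta are on the 0-100 score scale;
    ppt_window gives the intronic acceptor offsets scanned for the
    polypyrimidine tract (negative, upstream of the AG).
    """

    donor_pwm: np.ndarray = field(default_factory=lambda: load_pwm("donor"))
    acceptor_pwm: np.ndarray = field(default_factory=lambda: load_pwm("acceptor"))
    cryptic_threshold: float = 70.0
    score_delta: float = 10.0
    ppt_window: tuple[int, int] = (-40, -5)
    ppt_weights: dict[str, float] = field(
        default_factory=lambda: {"T": 1.0, "C": 0.5, "A": 0.0, "G": 0.0}
    )
    acceptor_search_range: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.cryptic_threshold < 100:
            raise ValueError("cryptic_threshold must be in (0, 100)")
        if self.donor_pwm.shape != (DONOR_SPAN, 4):
            raise ValueError(f"donor PWM must span {DONOR_SPAN} positions")
        if self.acceptor_pwm.shape != (ACCEPTOR_SPAN, 4):
            raise ValueError(f"acceptor PWM must span {ACCEPTOR_SPAN} positions")


@dataclass(frozen=True)
class SpliceEffectCall:
    variant_id: str
    transcript_id: str
    category: str
    ref_score: float = 0.0
    alt_score: float = 0.0
    predicted_event: str = "none"  # exon_skip | cryptic_exon_inclusion | intron_retention | none
    event_ordinal: int = 0  # affected exon/intron ordinal (transcript orientation)
    evidence: str = ""

    @property
    def score_delta(self) -> float:
        return self.alt_score - self.ref_score


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def score_site(window: str, pwm: np.ndarray) -> float:
    """Normalized 0-100 PWM score of a sense-strand window.

    Ambiguous bases are skipped (that position contributes to neither the
    numerator nor the normalization) with a warning.
    """
    window = window.upper()
    if len(window) != pwm.shape[0]:
        raise ValueError(f"window length {len(window)} != PWM span {pwm.shape[0]}")
    total = lo = hi = 0.0
    for i, base in enumerate(window):
        j = _BASE_INDEX.get(base)
        if j is None:
            log.warning("ambiguous base %r at PWM position %d skipped", base, i)
            continue
        row = pwm[i]
        total += row[j]
        lo += row.min()
        hi += row.max()
    if hi == lo:
        return 0.0
    return 100.0 * (total - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# sense-strand sequence access


def _sense_base(seqs: dict[str, str], chrom: str, strand: str, gpos: int,
                variant: Variant | None = None, use_alt: bool = False) -> str:
    if variant is not None and gpos == variant.pos:
        base = variant.alt if use_alt else variant.ref
    else:
        base = seqs[chrom][gpos - 1]
    return base.translate(_COMPLEMENT) if strand == "-" else base


def sense_window(
    seqs: dict[str, str], chrom: str, strand: str, start_gpos: int, length: int,
    variant: Variant | None = None, use_alt: bool = False,
) -> str:
    """Sense-strand window of ``length`` nt beginning at genomic position
    ``start_gpos`` (the window extends 3'-ward in transcript orientation),
    with the variant's ref or alt allele substituted at its position."""
    step = 1 if strand == "+" else -1
    return "".join(
        _sense_base(seqs, chrom, strand, start_gpos + step * k, variant, use_alt)
        for k in range(length)
    )


def _donor_window_start(model: TranscriptModel, intron_ordinal: int) -> int:
    """Genomic position of the sense-first base of the canonical donor window
    of intron ``intron_ordinal`` (1-based): 3 exonic nt before the boundary."""
    exon = model.exons[intron_ordinal - 1]
    lo, hi = min(exon), max(exon)
    return hi - 2 if model.strand == "+" else lo + 2


def _acceptor_window_start(model: TranscriptModel, intron_ordinal: int) -> int:
    """Genomic position of the sense-first base of the canonical acceptor
    window of intron ``intron_ordinal``: 14 intronic nt before the 3' exon."""
    ilo, ihi = model.introns()[intron_ordinal - 1]
    return ihi - 13 if model.strand == "+" else ilo + 13


def find_upstream_acceptor(
    seqs: dict[str, str],
    model: TranscriptModel,
    donor_gpos: int,
    scoring: SpliceScoringModel,
    search_range: int | None = None,
    min_distance: int = 2,
) -> tuple[int, float] | None:
    """Scan sense-upstream of a (putative) donor boundary for a qualifying
    acceptor AG.

    ``donor_gpos`` is the genomic position of the first base retained in the
    intron (the G of the new GT).  Returns (genomic position of the AG's G,
    acceptor score) for the nearest AG whose acceptor-PWM score reaches the
    cryptic threshold; None if no AG qualifies within ``search_range``
    sense-nt.
    """
    rng = scoring.acceptor_search_range if search_range is None else search_range
    step = 1 if model.strand == "+" else -1
    # d = sense distance from the AG's G to the donor boundary; the new exon
    # spans the (d-1) nt between them, so d >= 2 for a nonempty exon
    for d in range(min_distance, rng + 1):
        g_pos = donor_gpos - step * d
        win_start = g_pos - step * (ACCEPTOR_SPAN - 2)
        try:
            win = sense_window(seqs, model.chrom, model.strand, win_start, ACCEPTOR_SPAN)
        except (IndexError, KeyError):
            break
        if win[12:14] != "AG":
            continue
        score = score_site(win, scoring.acceptor_pwm)
        if score >= scoring.cryptic_threshold:
            return (g_pos, score)
    return None


# ---------------------------------------------------------------------------
# the rule engine


def _canonical_boundaries(model: TranscriptModel) -> tuple[set[int], set[int]]:
    """Genomic positions of the sense-first bases of canonical donor and
    acceptor windows, used to exclude annotated sites from cryptic scans."""
    donors, acceptors = set(), set()
    for i in range(1, model.n_exons):
        donors.add(_donor_window_start(model, i))
        acceptors.add(_acceptor_window_start(model, i))
    return donors, acceptors


def _essential_positions(model: TranscriptModel) -> set[int]:
    """Genomic positions of all essential GT/AG dinucleotide bases.  A
    putative cryptic site whose implied boundary lands here would splice at
    an annotated boundary and is not a separate site."""
    out: set[int] = set()
    for ilo, ihi in model.introns():
        out.update((ilo, ilo + 1, ihi - 1, ihi))
    return out


def _acceptor_offset(model: TranscriptModel, pos: int) -> tuple[int, int] | None:
    """(intron ordinal, negative sense offset from the intron's 3' end) if
    ``pos`` is intronic, else None."""
    for i, (ilo, ihi) in enumerate(model.introns(), start=1):
        if ilo <= pos <= ihi:
            off = pos - ihi - 1 if model.strand == "+" else ilo - pos - 1
            return i, off
    return None


def classify_effect(
    variant: Variant,
    model: TranscriptModel,
    scoring: SpliceScoringModel,
    location: SpliceLocation,
    seqs: dict[str, str],
) -> SpliceEffectCall:
    """Apply the splice-effect rules, most severe first."""
    vid, tid = variant.id, model.transcript_id

    # rule 1: ablation of an essential GT/AG dinucleotide
    if location.cls == "essential_splice_site":
        i = location.intron_or_exon_number
        if location.site_kind == "donor":
            start = _donor_window_start(model, i)
            ref = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                          DONOR_SPAN, variant, use_alt=False),
                             scoring.donor_pwm)
            alt = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                          DONOR_SPAN, variant, use_alt=True),
                             scoring.donor_pwm)
            return SpliceEffectCall(
                vid, tid, "donor_destroyed", ref, alt, "exon_skip", i,
                evidence=f"destroys GT of donor splice site intron {i}",
            )
        start = _acceptor_window_start(model, i)
        ref = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                      ACCEPTOR_SPAN, variant, use_alt=False),
                         scoring.acceptor_pwm)
        alt = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                      ACCEPTOR_SPAN, variant, use_alt=True),
                         scoring.acceptor_pwm)
        return SpliceEffectCall(
            vid, tid, "acceptor_destroyed", ref, alt, "exon_skip", i + 1,
            evidence=f"destroys AG of acceptor splice site intron {i}: "
                     f"predicted skip of exon {i + 1}",
        )

    donors, acceptors = _canonical_boundaries(model)
    essential = _essential_positions(model)
    step = 1 if model.strand == "+" else -1
    thr = scoring.cryptic_threshold

    # rule 2: cryptic site creation (alt crosses the threshold, ref below)
    best_created: SpliceEffectCall | None = None
    for k in range(DONOR_SPAN):
        start = variant.pos - step * k
        if start in donors or (start + step * DONOR_INTRON_START) in essential:
            continue
        try:
            w_ref = sense_window(seqs, model.chrom, model.strand, start, DONOR_SPAN,
                                 variant, use_alt=False)
            w_alt = sense_window(seqs, model.chrom, model.strand, start, DONOR_SPAN,
                                 variant, use_alt=True)
        except (IndexError, KeyError):
            continue
        if w_alt[DONOR_INTRON_START:DONOR_INTRON_START + 2] != "GT":
            continue
        s_ref, s_alt = score_site(w_ref, scoring.donor_pwm), score_site(w_alt, scoring.donor_pwm)
        # a functional donor needs the obligatory GT AND an above-threshold
        # score; creation = alt functional, ref not
        ref_functional = (
            w_ref[DONOR_INTRON_START:DONOR_INTRON_START + 2] == "GT" and s_ref >= thr
        )
        if s_alt >= thr and not ref_functional and (
            best_created is None or s_alt > best_created.alt_score
        ):
            donor_gpos = start + step * DONOR_INTRON_START  # first base lost to the intron
            loc = _acceptor_offset(model, variant.pos)
            ordinal = loc[0] if loc else location.intron_or_exon_number
            event, ev = "none", f"introduces cryptic donor splice site (score {s_ref:.0f}->{s_alt:.0f})"
            upstream = find_upstream_acceptor(seqs, model, donor_gpos, scoring)
            if upstream is not None:
                event = "cryptic_exon_inclusion"
                ev += f"; qualifying acceptor {abs(donor_gpos - upstream[0]) - 1} nt upstream"
            best_created = SpliceEffectCall(
                vid, tid, "cryptic_donor_created", s_ref, s_alt, event, ordinal, ev
            )
    if best_created is not None:
        return best_created
    for k in range(ACCEPTOR_SPAN):
        start = variant.pos - step * k
        if start in acceptors or (start + step * ACCEPTOR_EXON_START) in essential:
            continue
        try:
            w_ref = sense_window(seqs, model.chrom, model.strand, start, ACCEPTOR_SPAN,
                                 variant, use_alt=False)
            w_alt = sense_window(seqs, model.chrom, model.strand, start, ACCEPTOR_SPAN,
                                 variant, use_alt=True)
        except (IndexError, KeyError):
            continue
        if w_alt[12:14] != "AG":
            continue
        s_ref, s_alt = score_site(w_ref, scoring.acceptor_pwm), score_site(w_alt, scoring.acceptor_pwm)
        ref_functional = w_ref[12:14] == "AG" and s_ref >= thr
        if s_alt >= thr and not ref_functional and (
            best_created is None or s_alt > best_created.alt_score
        ):
            best_created = SpliceEffectCall(
                vid, tid, "cryptic_acceptor_created", s_ref, s_alt, "none",
                location.intron_or_exon_number,
                f"introduces cryptic acceptor splice site (score {s_ref:.0f}->{s_alt:.0f})",
            )
    if best_created is not None:
        return best_created

    # rule 3: ablation of an existing above-threshold non-canonical acceptor
    for k in range(ACCEPTOR_SPAN):
        start = variant.pos - step * k
        if start in acceptors or (start + step * ACCEPTOR_EXON_START) in essential:
            continue
        try:
            w_ref = sense_window(seqs, model.chrom, model.strand, start, ACCEPTOR_SPAN,
                                 variant, use_alt=False)
            w_alt = sense_window(seqs, model.chrom, model.strand, start, ACCEPTOR_SPAN,
                                 variant, use_alt=True)
        except (IndexError, KeyError):
            continue
        if w_ref[12:14] != "AG":
            continue
        s_ref, s_alt = score_site(w_ref, scoring.acceptor_pwm), score_site(w_alt, scoring.acceptor_pwm)
        if s_ref >= thr and (s_alt < thr or w_alt[12:14] != "AG"):
            return SpliceEffectCall(
                vid, tid, "cryptic_acceptor_destroyed", s_ref, s_alt, "none",
                location.intron_or_exon_number,
                f"destroys cryptic acceptor splice site (score {s_ref:.0f}->{s_alt:.0f})",
            )

    # rule 4: polypyrimidine tract weakening
    acc = _acceptor_offset(model, variant.pos)
    if acc is not None:
        ordinal, off = acc
        lo, hi = scoring.ppt_window
        if lo <= off <= hi:
            ref_sense = _sense_base(seqs, model.chrom, model.strand, variant.pos,
                                    variant, use_alt=False)
            alt_sense = _sense_base(seqs, model.chrom, model.strand, variant.pos,
                                    variant, use_alt=True)
            w_ref = scoring.ppt_weights.get(ref_sense, 0.0)
            w_alt = scoring.ppt_weights.get(alt_sense, 0.0)
            if w_alt < w_ref:
                return SpliceEffectCall(
                    vid, tid, "ppt_weakened", 0.0, 0.0, "none", ordinal,
                    f"may interrupt polypyrimidine tract intron {ordinal} "
                    f"({ref_sense}>{alt_sense} at acceptor offset {off})",
                )

    # rule 5: score change at a canonical site
    for i in range(1, model.n_exons):
        for which, start, span, pwm in (
            ("donor", _donor_window_start(model, i), DONOR_SPAN, scoring.donor_pwm),
            ("acceptor", _acceptor_window_start(model, i), ACCEPTOR_SPAN, scoring.acceptor_pwm),
        ):
            offsets = [start + step * k for k in range(span)]
            if variant.pos not in offsets:
                continue
            s_ref = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                            span, variant, use_alt=False), pwm)
            s_alt = score_site(sense_window(seqs, model.chrom, model.strand, start,
                                            span, variant, use_alt=True), pwm)
            if abs(s_alt - s_ref) >= scoring.score_delta:
                return SpliceEffectCall(
                    vid, tid, "site_score_changed", s_ref, s_alt, "none", i,
                    f"alters {which} splice site score of intron {i} "
                    f"({s_ref:.0f}->{s_alt:.0f})",
                )

    return SpliceEffectCall(vid, tid, "no_effect")


def prioritise(calls: list[SpliceEffectCall]) -> list[SpliceEffectCall]:
    """Rank calls by category severity then |score delta|; no_effect calls
    sink to the bottom; ties broken by variant id lexicographically."""
    return sorted(
        calls,
        key=lambda c: (
            c.category == "no_effect",
            _CATEGORY_RANK[c.category],
            -abs(c.score_delta),
            c.variant_id,
        ),
    )


def calls_to_dataframe(calls: list[SpliceEffectCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "transcript_id": c.transcript_id,
                "category": c.category,
                "ref_score": c.ref_score,
                "alt_score": c.alt_score,
                "predicted_event": c.predicted_event,
                "event_ordinal": c.event_ordinal,
                "evidence": c.evidence,
            }
            for c in calls
        ]
    )
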