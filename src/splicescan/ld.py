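"""Pairwise linkage disequilibrium from phased haplotypes and proxy-SNP search.

LD is computed by direct haplotype counting (the panel is phased), not by EM
from unphased genotypes.  With haplotype frequency p_AB for the alt alleles
of two variants and marginals p_A, p_B:

    D  = p_AB - p_A * p_B
    r² = D² / (p_A (1-p_A) p_B (1-p_B))
    D' = |D| / D_max,
    D_max = min(p_A (1-p_B), (1-p_A) p_B)        if D > 0
          = min(p_A p_B, (1-p_A)(1-p_B))         if D < 0

A proxy search retains every panel variant within a physical window of an
index SNP whose r² with it strictly exceeds a threshold (the index SNP
itself is always its own proxy at r² = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import Variant


class LdError(ValueError):
    """LD is undefined for the requested pair (e.g. a monomorphic variant)."""


@dataclass(frozen=True)
class LdStats:
    r2: float
    d_prime: float
    n_haplotypes: int


@dataclass
class HaplotypePanel:
    """Phased binary alleles: ``alleles[h, j]`` is 0 (ref) or 1 (alt) for
    haplotype h at the panel's j-th variant."""

    variants: list[Variant]
    alleles: np.ndarray  # (n_haplotypes, n_variants) uint8

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.variants):
            raise ValueError("alleles must be (n_haplotypes, n_variants)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0/1")
        self._index = {v.id: j for j, v in enumerate(self.variants)}

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.alleles[:, self.index_of(variant_id)]

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise LdError(f"variant {variant_id!r} not in panel") from None

    def alt_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


def panel_from_vcf(path) -> HaplotypePanel:
    """Build a phased haplotype panel from a VCF with GT fields.

    Only biallelic SNVs are used; haplotypes 2i and 2i+1 are the two phased
    alleles of sample i.
    """
    from cyvcf2 import VCF

    from .core_io import NUCLEOTIDES

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            continue
        gts = np.asarray(rec.genotypes, dtype=int)  # (n_samples, 3): a0, a1, phased
        col = gts[:, :2].reshape(-1)
        if (col < 0).any():  # missing genotypes unsupported in panels
            continue
        f = col.mean()
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{ref}:{alt}"
        variants.append(Variant(vid, rec.CHROM, rec.POS, ref, alt, maf=min(f, 1 - f)))
        columns.append(col.astype(np.uint8))
    if not variants:
        raise ValueError(f"no usable biallelic SNVs in {path}")
    return HaplotypePanel(variants, np.stack(columns, axis=1))


def _ld_from_columns(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n = a.shape[0]
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LdError("LD undefined for a monomorphic variant")
    p_ab = np.logical_and(a, b).mean()
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0, 0.0
    return float(r2), float(abs(d) / d_max)


def compute_ld(panel: HaplotypePanel, a: str, b: str) -> LdStats:
    """r² and D' between two panel variants by haplotype counting."""
    col_a = panel.column(a)
    col_b = panel.column(b)
    r2, d_prime = _ld_from_columns(col_a, col_b)
    return LdStats(r2=r2, d_prime=d_prime, n_haplotypes=panel.n_haplotypes)


def r2_against(panel: HaplotypePanel, j: int, candidates: np.ndarray) -> np.ndarray:
    """Vectorized r² between panel column j and each candidate column index.

    Monomorphic candidates get r² = NaN.
    """
    a = panel.alleles[:, j].astype(np.float64)
    B = panel.alleles[:, candidates].astype(np.float64)
    p_a = a.mean()
    p_b = B.mean(axis=0)
    p_ab = (a[:, None] * B).mean(axis=0)
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return r2


def find_proxies(
    panel: HaplotypePanel,
    index_snp: str,
    r2_threshold: float = 0.8,
    window: int = 500_000,
) -> list[tuple[Variant, LdStats]]:
    """All panel variants within ``window`` nt (center-to-center, inclusive)
    of the index SNP with r² strictly above ``r2_threshold``, sorted by
    descending r².  Includes the index SNP itself (r² = 1)."""
    j = panel.index_of(index_snp)
    idx_var = panel.variants[j]
    pos = np.array([v.pos for v in panel.variants])
    same_chrom = np.array([v.chrom == idx_var.chrom for v in panel.variants])
    in_window = same_chrom & (np.abs(pos - idx_var.pos) <= window)
    cand = np.flatnonzero(in_window)
    r2 = r2_against(panel, j, cand)
    out: list[tuple[Variant, LdStats]] = []
    for k, r2_k in zip(cand, r2):
        if k == j:
            out.append((idx_var, LdStats(1.0, 1.0, panel.n_haplotypes)))
            continue
        if np.isnan(r2_k) or r2_k <= r2_threshold:
            continue
        out.append((panel.variants[k], compute_ld(panel, index_snp, panel.variants[k].id)))
    out.sort(key=lambda t: (-t[1].r2, t[0].id))
    return out
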