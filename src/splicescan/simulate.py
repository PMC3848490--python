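"""Synthetic inputs for every pipeline stage: genomes with spliceable gene
models, phased haplotype panels with block LD, GWAS catalogues with a
controllable excess of disease SNPs in splice regions, and qPCR Ct tables
with genotype-dependent shifts.

The generator is deliberately structural rather than population-genetic:
LD comes from founder-copying blocks (adjacent variants copy a per-block
founder haplotype with per-haplotype copy noise; blocks are independent),
which gives tunable r² structure without coalescent machinery.  One global
seed drives a fixed per-generator seed hierarchy, so each generator is
deterministic and independently re-runnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import SPLICE_CLASSES, SpliceWindows, annotate_set
from .core_io import TranscriptModel, Variant
from .ld import HaplotypePanel

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")  # ordered: rng.choice must be reproducible
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS and c != "ATG"]

# fixed stream indices for the hierarchical per-generator seeds
_STREAM_GENOME, _STREAM_PANEL, _STREAM_CATALOG, _STREAM_CT = 0, 1, 2, 3


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Lengths are nt, rates are probabilities; ``ct_effect`` maps genotype
    label -> mean target-Ct shift in cycles (negative = higher expression);
    ``splice_enrichment_factor`` multiplies the background probability that
    a disease index SNP falls in a splice region.
    """

    seed: int = 0
    n_haplotypes: int = 400
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (30, 150)
    intron_len: tuple[int, int] = (80, 400)
    intergenic_len: tuple[int, int] = (500, 2000)
    snp_density: float = 10.0  # variants per kb
    ld_block_len: int = 2000
    recomb_rate: float = 0.01  # per-haplotype copy noise within a block
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_disease_snps: int = 338
    splice_enrichment_factor: float = 1.0
    ct_effect: dict = field(default_factory=dict)
    ct_sd: float = 0.25
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for name in ("n_haplotypes", "n_genes", "n_disease_snps", "ld_block_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be even (phased diploids)")
        if self.splice_enrichment_factor < 1:
            raise ConfigError("splice_enrichment_factor must be >= 1")
        if self.ct_sd < 0:
            raise ConfigError("ct_sd must be >= 0")
        if not 0 <= self.recomb_rate <= 1:
            raise ConfigError("recomb_rate must be a probability")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.exon_len[0] < 10 or self.exon_len[0] > self.exon_len[1]:
            raise ConfigError("exon_len range infeasible (min 10 nt)")
        if self.intron_len[0] < 40 or self.intron_len[0] > self.intron_len[1]:
            raise ConfigError("intron_len range infeasible (min 40 nt)")
        if self.exons_per_gene[0] < 2 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ConfigError("exons_per_gene range infeasible (min 2)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _coding_seq(rng: np.random.Generator, n: int) -> str:
    """ATG + non-stop codons + a stop codon; n must be a multiple of 3 >= 9."""
    n_mid = n // 3 - 2
    mid = "".join(rng.choice(_SENSE_CODONS, size=n_mid))
    stop = rng.choice(_STOPS)
    return "ATG" + mid + stop


def _intron_seq(rng: np.random.Generator, n: int) -> str:
    """GT ... polypyrimidine tract ... AG on the sense strand."""
    ppt_len = min(18, n - 10)
    body = _random_seq(rng, n - 4 - ppt_len)
    ppt = "".join(rng.choice(["T", "C"], p=[0.65, 0.35], size=ppt_len))
    return "GT" + body + ppt + "AG"


_RC = str.maketrans("ACGT", "TGCA")


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Generate one chromosome with ``n_genes`` multi-exon protein-coding
    genes on random strands.  Every intron starts GT and ends AG on the
    sense strand; every CDS is ATG..stop with length a multiple of 3."""
    rng = config.rng(_STREAM_GENOME)
    chrom_parts: list[str] = []
    models: list[TranscriptModel] = []
    cursor = 0
    for g in range(config.n_genes):
        spacer = int(rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1))
        chrom_parts.append(_random_seq(rng, spacer))
        cursor += spacer

        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            for _ in range(n_ex)
        ]
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3  # CDS length a multiple of 3
        intron_lens = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_ex - 1)
        ]
        cds = _coding_seq(rng, sum(exon_lens))

        # assemble the sense-strand gene sequence and sense exon offsets
        gene_parts: list[str] = []
        sense_exons: list[tuple[int, int]] = []  # 0-based sense offsets
        pos = 0
        taken = 0
        for i, el in enumerate(exon_lens):
            gene_parts.append(cds[taken : taken + el])
            sense_exons.append((pos, pos + el - 1))
            taken += el
            pos += el
            if i < n_ex - 1:
                gene_parts.append(_intron_seq(rng, intron_lens[i]))
                pos += intron_lens[i]
        gene_seq = "".join(gene_parts)
        gene_len = len(gene_seq)
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = cursor  # 0-based offset of the gene in the chromosome
        if strand == "+":
            exons = [(gstart + a + 1, gstart + b + 1) for a, b in sense_exons]
            chrom_parts.append(gene_seq)
        else:
            exons = [
                (gstart + gene_len - b, gstart + gene_len - a)
                for a, b in sense_exons
            ]
            chrom_parts.append(gene_seq[::-1].translate(_RC))
        cursor += gene_len
        tx_id = f"tx{g + 1:03d}"
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                chrom=config.chrom,
                strand=strand,
                exons=exons,
                cds=(min(s for s, _ in exons), max(e for _, e in exons)),
                gene_id=f"gene{g + 1:03d}",
            )
        )
    chrom_parts.append(_random_seq(rng, int(rng.integers(*config.intergenic_len))))
    return {config.chrom: "".join(chrom_parts)}, models


def simulate_panel(
    config: SimConfig, models: list[TranscriptModel], seqs: dict[str, str] | None = None
) -> tuple[HaplotypePanel, list[Variant]]:
    """Phased haplotype panel with founder-copy block LD.

    Variant sites are placed uniformly along the chromosome at
    ``snp_density`` per kb.  Within an ``ld_block_len`` block every variant
    copies the block's founder haplotype; each haplotype independently
    deviates to a fresh draw with probability ``recomb_rate``, so r² decays
    with that rate while staying 1 at rate 0.  Blocks are independent.
    """
    if seqs is None:
        raise ConfigError("simulate_panel needs the genome sequence (simulate_genome first)")
    rng = config.rng(_STREAM_PANEL)
    chrom_seq = seqs[config.chrom]
    L = len(chrom_seq)
    n_var = max(2, int(round(L / 1000.0 * config.snp_density)))
    positions = np.sort(
        rng.choice(np.arange(1, L + 1), size=min(n_var, L), replace=False)
    )
    n_hap = config.n_haplotypes
    alleles = np.zeros((n_hap, len(positions)), dtype=np.uint8)

    block_ids = positions // config.ld_block_len
    lo, hi = config.maf_range
    for block in np.unique(block_ids):
        cols = np.flatnonzero(block_ids == block)
        p = rng.uniform(lo, hi)
        founder = (rng.random(n_hap) < p).astype(np.uint8)
        for j in cols:
            noise = rng.random(n_hap) < config.recomb_rate
            fresh = (rng.random(n_hap) < p).astype(np.uint8)
            col = np.where(noise, fresh, founder)
            if col.min() == col.max():  # keep every variant polymorphic
                col = col.copy()
                col[rng.integers(n_hap)] ^= 1
            alleles[:, j] = col

    variants = []
    for j, pos in enumerate(positions):
        ref = chrom_seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        f = float(alleles[:, j].mean())
        variants.append(
            Variant(f"snp{j + 1:05d}", config.chrom, int(pos), ref, alt,
                    maf=min(f, 1.0 - f))
        )
    return HaplotypePanel(variants, alleles), variants


_DEFAULT_TRAITS = (
    "Ulcerative colitis", "Crohn's disease", "Type 1 diabetes",
    "Multiple sclerosis", "Psoriasis", "Asthma", "Primary biliary cirrhosis",
    "Rheumatoid arthritis",
)


def simulate_catalog(
    config: SimConfig,
    variants: list[Variant],
    models: list[TranscriptModel],
    windows: SpliceWindows = SpliceWindows(),
) -> pd.DataFrame:
    """A GWAS association table of ``n_disease_snps`` index SNPs whose
    probability of lying in a splice region is the background proportion
    times ``splice_enrichment_factor`` (capped at 1).  Index p-values are
    log-uniform in [1e-15, 5e-8); proxies carry no p-value by design — only
    index SNPs are significance-filtered downstream."""
    rng = config.rng(_STREAM_CATALOG)
    _, variant_cls, summary = annotate_set(variants, models, windows)
    splice_ids = [v.id for v in variants if variant_cls[v.id] in SPLICE_CLASSES]
    other_ids = [v.id for v in variants if variant_cls[v.id] not in SPLICE_CLASSES]
    q = summary.n_splice / summary.n_variants if summary.n_variants else 0.0
    p_target = min(q * config.splice_enrichment_factor, 1.0)
    if config.n_disease_snps > len(variants):
        raise ConfigError("n_disease_snps exceeds the variant pool")
    expected_splice = p_target * config.n_disease_snps
    if expected_splice > 0 and not splice_ids:
        raise ConfigError(
            "requested splice enrichment unattainable: no splice-region "
            "variants exist in the annotation landscape"
        )

    chosen: list[str] = []
    splice_pool, other_pool = list(splice_ids), list(other_ids)
    rng.shuffle(splice_pool)
    rng.shuffle(other_pool)
    for _ in range(config.n_disease_snps):
        want_splice = rng.random() < p_target
        pool = splice_pool if want_splice else other_pool
        backup = other_pool if want_splice else splice_pool
        if pool:
            chosen.append(pool.pop())
        elif backup:
            if want_splice:
                raise ConfigError(
                    "requested splice enrichment unattainable: splice-region "
                    "variant pool exhausted"
                )
            chosen.append(backup.pop())
        else:
            raise ConfigError("variant pool exhausted")

    by_id = {v.id: v for v in variants}
    log_lo, log_hi = np.log10(1e-15), np.log10(5e-8)
    rows = []
    for k, vid in enumerate(chosen):
        v = by_id[vid]
        p = 10.0 ** rng.uniform(log_lo, log_hi)
        rows.append(
            {
                "snp": vid,
                "trait": _DEFAULT_TRAITS[k % len(_DEFAULT_TRAITS)],
                "p_value": p,
                "risk_allele": v.alt,
                "pubmed_id": str(20000000 + k),
            }
        )
    return pd.DataFrame(rows)


def simulate_ct_table(
    config: SimConfig,
    genotype_groups: list[str],
    n_per_group: list[int],
    target_baseline: float = 25.0,
    control_baseline: float = 20.0,
) -> pd.DataFrame:
    """Per-sample target/control Ct values: baseline + per-genotype shift
    (``ct_effect``) + Gaussian noise of scale ``ct_sd`` cycles."""
    if len(genotype_groups) != len(n_per_group):
        raise ConfigError("genotype_groups and n_per_group must align")
    if any(n < 1 for n in n_per_group):
        raise ConfigError("group sizes must be >= 1")
    rng = config.rng(_STREAM_CT)
    rows = []
    k = 0
    for geno, n in zip(genotype_groups, n_per_group):
        shift = float(config.ct_effect.get(geno, 0.0))
        for _ in range(n):
            k += 1
            rows.append(
                {
                    "sample": f"S{k:03d}",
                    "genotype": geno,
                    "target_ct": target_baseline + shift + rng.normal(0, config.ct_sd),
                    "control_ct": control_baseline + rng.normal(0, config.ct_sd),
                }
            )
    return pd.DataFrame(rows)
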