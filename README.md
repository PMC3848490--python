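# splicescan

Most GWAS hits for autoimmune and inflammatory disease land in non-coding
sequence, and one recurring mechanism behind them is altered pre-mRNA
splicing: an associated variant (or something in linkage disequilibrium
with it) damages a splice site, creates a cryptic one, or weakens the
polypyrimidine tract, changing which transcript isoforms a gene produces.
`splicescan` is a tested, reusable implementation of the classic in-silico
triage for finding such variants, aimed at statistical geneticists and
molecular biologists who want to go from an association table to a short,
ranked list of splice-site SNPs worth validating at the bench — plus the
downstream analyses that validation produces (transcript consequences,
genotype-stratified qPCR).

## What it computes

**Catalogue filtering.** Associations are restricted to a configurable
autoimmune/inflammatory trait whitelist at genome-wide significance
(p ≤ 5×10⁻⁸; the comparison is inclusive because published tables round
p-values).

**LD proxy expansion.** From a phased haplotype panel, with haplotype
frequencies p_AB, p_A, p_B counted directly:

    D  = p_AB − p_A·p_B
    r² = D² / (p_A(1−p_A) p_B(1−p_B))
    D′ = |D| / D_max

Proxies are panel variants within 500 kb of an index SNP with r²
strictly > 0.8.

**Splice annotation.** Each variant is classified against transcript
models: *essential splice site* (the invariant intronic GT/AG
dinucleotides), *splice region* (first/last 3 exonic nt at a spliced
boundary, intronic offsets +3..+8 / −8..−3), else exonic / intronic /
intergenic, with the most splice-proximal class across transcripts
reported per variant.

**Effect prediction.** A Shapiro–Senapathy-style position-weight-matrix
scorer (score = 100·(Σw − Σw_min)/(Σw_max − Σw_min), so consensus = 100)
drives a prioritised rule set: essential GT/AG ablation (predicted exon
skip), cryptic donor/acceptor creation (with upstream-acceptor search for
cryptic-exon inclusion), cryptic acceptor ablation, polypyrimidine-tract
weakening, and canonical site score change.

**Enrichment test.** Is the disease set (index SNPs ∪ proxies) enriched
for splice-class variants?  The null is 1000 random SNP sets matched on
minor allele frequency (±0.05) and distance to the nearest gene (±10 kb),
LD-expanded identically.  Both a one-sample one-tailed t-test against the
observed percentage and the add-one empirical p,
(#null ≥ observed + 1)/(n_sets + 1), are reported.

**Transcript consequence.** For a predicted exon skip or cryptic-exon
inclusion, the novel mRNA is rebuilt, the CDS re-translated, frame
preservation decided by the mod-3 rule, and nonsense-mediated decay
predicted when a premature termination codon sits > 50 nt upstream of the
final exon–exon junction.

**Expression analysis.** Genotype-stratified qPCR via the comparative-Ct
method (ΔCt = target − control; fold change = 2^−ΔΔCt against a calibrator
genotype) with the Kruskal–Wallis H test across genotype groups.

A synthetic-data module generates every input — genomes with canonical
GT/AG gene models, phased panels with block LD, catalogues with a
controllable splice-region enrichment factor, and Ct tables — so the whole
pipeline is testable without downloads.

## Worked example

```python
from splicescan import SimConfig, simulate_genome, simulate_panel, simulate_catalog
from splicescan import MatchCriteria, run_enrichment, compute_ld

# 1. generate a synthetic study: genome, phased panel, enriched GWAS catalogue
cfg = SimConfig(seed=1, n_genes=35, n_haplotypes=200, snp_density=10,
                exon_len=(30, 60), intron_len=(80, 150), ld_block_len=1000,
                n_disease_snps=40, splice_enrichment_factor=10.0)
seqs, models = simulate_genome(cfg)
panel, variants = simulate_panel(cfg, models, seqs)
catalog = simulate_catalog(cfg, variants, models)

# 2. pairwise LD between the first two catalogued SNPs
ld = compute_ld(panel, catalog.snp[0], catalog.snp[1])
print(f"LD between {catalog.snp[0]} and {catalog.snp[1]}: "
      f"r2 = {ld.r2:.3f}, D' = {ld.d_prime:.3f}")

# 3. matched-SNP splice-region enrichment test
by_id = {v.id: v for v in variants}
index = [by_id[s] for s in catalog.snp]
result = run_enrichment(index, variants, panel, models,
                        MatchCriteria(n_sets=200), seed=2)
print(result.summary())
```

prints

```
LD between snp00061 and snp00602: r2 = 0.004, D' = 0.144
splice-region enrichment: observed 10.2% (LD-expanded set of 293), null mean 5.45% over 200 matched sets of 40; one-tailed t p = 3.22e-133, empirical p = 0.00498
```

The two catalogued SNPs sit in different LD blocks, so their r² is near
zero.  The ten-fold enriched catalogue yields an observed splice-class
percentage roughly double the matched-null mean; with 200 null sets the
empirical p bottoms out at 1/201 ≈ 0.005.  (The t-test p is far smaller
because the null percentages are tightly concentrated — the empirical p is
the honest summary here, and both are always reported.)

The same stages are available from the shell:

```bash
splicescan simulate --seed 7 --out-dir sim
splicescan run-all config.yaml          # catalogue -> proxies -> annotation
                                        # -> effects -> prioritisation
splicescan expression sim/ct_table.tsv --calibrator AG
```

`run-all` writes per-stage TSVs plus a `manifest.json` recording the seed,
parameters, record counts per stage and output checksums; reruns with the
same config are byte-identical.

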