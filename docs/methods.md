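# Methods

This note documents the models, conventions and numerical choices behind
`splicescan`, in the spirit of the methods documentation shipped by
simulation and statistics packages: what is computed, under which
assumptions, which knobs matter, and what the synthetic data do and do not
establish about real data.

## Coordinate and strand conventions

All internal coordinates are 1-based inclusive, the VCF/GFF3 convention;
BED12's 0-based half-open coordinates are converted only when reading or
writing BED files.  The pipeline is variant-centric and VCF-first, so this
avoids repeated off-by-one conversions in the splice-geometry code.
Chromosome names are compared verbatim — no "chr" normalization — so a
panel/annotation mismatch surfaces as an obvious empty result rather than a
silent half-match.

All splice-site sequence logic operates on the transcript (sense) strand.
Minus-strand windows are reverse-complemented at extraction time, and
intron offsets are sense offsets: +1 is the first intronic base after a
donor, −1 the last intronic base before an acceptor.  Exon lists are stored
in transcript orientation (rightmost genomic exon first on the minus
strand).

## Splice-location classes

* **essential_splice_site** — the two invariant intronic nt adjacent to an
  exon: donor GT at offsets +1/+2, acceptor AG at −2/−1.
* **splice_region** — the first/last 3 exonic nt of an exon at a spliced
  boundary, or intronic offsets +3..+8 (donor side) / −8..−3 (acceptor
  side).  These window sizes follow the Ensembl-style `splice_region`
  definition used by standard annotators and are overridable via
  `SpliceWindows`.
* otherwise **exonic / intronic / intergenic** by containment.

Transcript ends are not spliced boundaries: the first base of the first
exon and the last base of the last exon get no splice-region window.  A
variant overlapping several transcripts is summarised by its most
splice-proximal class (severity order essential > region > exonic >
intronic > intergenic), mirroring worst-consequence reporting in standard
variant annotators; per-transcript records are retained.  Percentages count
unique variant ids, so an index SNP that is its own proxy is counted once.

## LD

r² and D′ are computed by direct haplotype counting — the panels this
package consumes (and simulates) are phased, so no EM from genotypes is
needed or implemented.  The proxy-search threshold is strict (r² > 0.8
excludes the boundary value) and the 500 kb window is center-to-center and
boundary-inclusive.  Inside the enrichment test, all pairwise r² values are
obtained from one Pearson-correlation matrix of the 0/1 allele indicators
(identical to the haplotype-counting formula), which is the right
time/memory trade-off at simulation panel sizes (≲ a few thousand
variants); `compute_ld` remains the reference implementation for single
pairs.

## PWM splice-site scoring

The donor matrix spans 3 exonic + 6 intronic nt around the GT; the acceptor
matrix spans 14 intronic + 1 exonic nt around the AG, covering the
polypyrimidine tract.  Both are packaged human frequency matrices in the
Shapiro–Senapathy tradition and are fully replaceable via TSV files.  The
score normalizes the summed position weights so the consensus scores 100
and the anti-consensus 0; it is therefore monotone position-by-position
toward consensus.  This scorer is a declared stand-in for the proprietary
or web-based splice predictors commonly used in this kind of triage; no
attempt is made to reproduce any particular tool's numbers.

Two thresholds matter (both on the 0–100 scale, both free parameters
surfaced in config):

* `cryptic_threshold` = 70 — minimum score for a window to count as a
  functional site.  A site additionally *requires* its obligatory GT/AG:
  a near-consensus window lacking the dinucleotide is not a site however
  well it scores.
* `score_delta` = 10 — minimum |alt − ref| at a canonical site for a
  `site_score_changed` call.

Defaults were chosen so engineered constructions (consensus-grade created
sites vs. random background) separate cleanly; they are not calibrated
against any external tool.  One further geometric guard: a putative
cryptic site whose implied novel boundary falls inside an annotated
essential dinucleotide is discarded — such a "site" would splice at an
already-annotated boundary and is an artifact of window scanning, not a
separate signal.

Rules are applied in severity order: essential GT/AG ablation (predicted
skip of the adjacent exon), cryptic donor/acceptor creation, cryptic
acceptor ablation, polypyrimidine-tract weakening, canonical score change.
Tract weakening uses per-base weights T = 1.0, C = 0.5, A = G = 0 over
acceptor offsets −40..−5: any weight decrease counts, so a T>C change is a
(mild) interruption even though both bases are pyrimidines.  Prioritisation
sorts by category severity, then |score delta|, then variant id — the last
purely to make output deterministic.

## The enrichment test

The observed statistic is the splice-class percentage of the disease set
(index SNPs plus all r² > 0.8 proxies, deduplicated).  The null is built
from `n_sets` (default 1000) random sets matched per index SNP on minor
allele frequency (±0.05 absolute — the conventional reading of "±5%") and
on distance to the nearest gene boundary (±10 kb; 0 inside a gene), drawn
uniformly among eligible pool SNPs without replacement within a set, then
LD-expanded identically to the disease set.  Matched sets exclude the true
index SNPs; reuse across sets is allowed since sets are independent draws.

Two p-values are reported.  The one-tailed one-sample t-test asks whether
the null percentages' mean lies below the observed value (df = n_sets − 1);
it is the test traditionally quoted for this design but is fragile when the
null distribution is discrete or nearly degenerate (its p can be extreme
when the null variance collapses).  The add-one empirical p,
(#null ≥ observed + 1)/(n_sets + 1), is exchangeable-valid and is the
recommended summary; it is floored at 1/(n_sets + 1).  When every variant
is intergenic the result degenerates gracefully: observed = null mean = 0,
t-test p = 1, empirical p = 1.

## Transcript consequence

Events are the two kinds observed in practice for this triage: internal
exon skips and cryptic-exon inclusions (a new exon strictly inside one
intron); multi-event combinations are out of scope.  The novel exon chain
is re-spliced, the CDS re-translated from the annotated start codon, and:

* **frame_preserved** ⇔ (inserted − deleted coding length) mod 3 = 0;
* a **PTC** is an in-frame stop whose genomic position differs from the
  reference transcript's stop;
* **NMD** is predicted when the PTC starts more than 50 nt upstream of the
  final exon–exon junction (the 50-nt rule; threshold configurable).  A
  PTC in the last exon therefore never predicts NMD.

`build_cryptic_exon` scans sense-upstream of a variant-created donor
boundary for the nearest AG whose acceptor-PWM score reaches the cryptic
threshold; the exon runs from the base after that AG to the base before
the new GT.  An AG immediately adjacent to the donor defines an empty exon
and is a defined error.

## Comparative-Ct expression analysis

ΔCt = target Ct − endogenous-control Ct per sample; group fold change is
2^−ΔΔCt with ΔΔCt taken between group-mean ΔCt values (the standard
convention; per-sample folds averaged afterwards would differ under noise,
and nothing here depends on that choice at the noise levels simulated).
No amplification-efficiency correction is applied — the plain 2^−ΔΔCt
model.  Group differences use the tie-corrected Kruskal–Wallis H with the
chi-square approximation, the appropriate non-parametric choice at the
5–10 samples per genotype typical of these panels; an all-tied input
returns H = 0 with a warning rather than an error.  The implementation
delegates to scipy's tie-corrected statistic; the test suite checks it
against an explicit rank-table oracle.

## The synthetic-data generators

The generators produce structure, not population-genetic realism:

* **Genomes** — multi-exon protein-coding genes on random strands, exons
  30–150 nt, introns 80–400 nt with canonical GT…AG and an 18-nt
  pyrimidine-rich tract before each acceptor, CDS = ATG…stop with length a
  multiple of 3 and no internal stop.  Intron minima keep all annotation
  windows disjoint, which is what makes the analytic window-fraction check
  exact.
* **Panels** — variant sites placed uniformly at 10/kb; within an LD block
  (2 kb default) every variant copies a per-block founder haplotype, each
  haplotype deviating to a fresh draw with probability `recomb_rate`
  (0.01 default), so r² is 1 at rate 0 and decays with the rate; blocks
  are independent.  Founder frequencies are uniform on the configured MAF
  range (0.05–0.5).  This founder-copying model was chosen over a
  coalescent deliberately: the enrichment procedure needs tunable r²
  structure, not realistic genealogies.
* **Catalogues** — 338 index SNPs by default, sampled so the probability
  of a splice-class placement is the background proportion times the
  enrichment factor (capped at 1); at factor 1 this reduces exactly to a
  uniform draw, which is what makes the null-calibration study valid.
  Index p-values are log-uniform on [10⁻¹⁵, 5×10⁻⁸); proxies carry no
  p-value, since only index SNPs are significance-filtered.
* **Ct tables** — per-sample target/control Ct = baseline + per-genotype
  shift + Gaussian noise (0.25 cycles default).

One global seed drives a fixed per-generator seed hierarchy
(`default_rng([seed, stream])`), so each generator is deterministic and
independently re-runnable.

What passing tests on these data show — and what they do not: the geometry,
bookkeeping and statistical calibration of every stage are exercised
end-to-end, but nothing here validates PWM thresholds against experimental
splicing outcomes, models realistic human LD or allele-frequency spectra,
or captures tissue-specific expression; conclusions about any real locus
still require the bench.

## Problem sizes used in the automated checks

The calibration studies run at deliberately small scale chosen for tight
replicate loops: genomes of 25–35 genes with short exons/introns
(30–60 / 80–150 nt, giving a splice-dense landscape where null percentages
sit well away from the zero-count discreteness floor), 200-haplotype
panels, 40-SNP catalogues, 200 null sets per test, with 200 null-replicates
(type-I error) and 100 enriched replicates (power).  The acceptance script
uses the same sizes with 100 and 50 replicates.  Full-scale defaults
(338 index SNPs, 1000 null sets) remain the package defaults.

## Known limitations

* The PWM scorer is a stand-in; its thresholds are validated only on
  engineered constructions, and ESE/ESS hexamer motifs are not scored
  (the effect-call evidence field is reserved for a future motif scorer).
* No branch-point model and no RNA secondary-structure scoring.
* No unphased-genotype LD (EM), no structural variants, no liftover.
* The matched-null design matches on MAF and gene proximity only; gene
  density or chromosome are not covariates.
* `run_enrichment` materialises a full r² matrix; for panels far beyond
  simulation scale a windowed implementation would be needed.
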