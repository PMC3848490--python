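"""Synthetic-data generators: determinism, construction rules, LD structure."""

import numpy as np
import pytest

from splicescan.core_io import GenomicInterval, extract_sequence
from splicescan.ld import compute_ld
from splicescan.simulate import (ConfigError, SimConfig, simulate_catalog,
                                 simulate_ct_table, simulate_genome, simulate_panel)


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(splice_enrichment_factor=0.5)
        with pytest.raises(ConfigError):
            SimConfig(ct_sd=-1)
        with pytest.raises(ConfigError):
            SimConfig(maf_range=(0.0, 0.6))
        with pytest.raises(ConfigError):
            SimConfig(intron_len=(10, 20))
        with pytest.raises(ConfigError):
            SimConfig(n_haplotypes=201)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42, n_genes=4)
        s1, m1 = simulate_genome(cfg)
        s2, m2 = simulate_genome(cfg)
        assert s1 == s2
        assert [(m.exons, m.strand) for m in m1] == [(m.exons, m.strand) for m in m2]

    def test_gene_count(self):
        _, models = simulate_genome(SimConfig(seed=1, n_genes=3))
        assert len(models) == 3

    def test_introns_start_gt_end_ag(self, small_sim):
        _, seqs, models, _, _ = small_sim
        for m in models:
            for ilo, ihi in m.introns():
                s = extract_sequence(seqs, GenomicInterval(m.chrom, ilo, ihi, m.strand))
                assert s.startswith("GT") and s.endswith("AG")

    def test_cds_is_complete_orf(self, small_sim):
        _, seqs, models, _, _ = small_sim
        for m in models:
            cdna = m.spliced_sequence(seqs)
            assert cdna.startswith("ATG")
            assert len(cdna) % 3 == 0
            assert cdna[-3:] in ("TAA", "TAG", "TGA")
            # no internal in-frame stop
            assert all(cdna[k:k + 3] not in ("TAA", "TAG", "TGA")
                       for k in range(0, len(cdna) - 3, 3))


class TestSimulatePanel:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=9, n_genes=3, n_haplotypes=50)
        seqs, models = simulate_genome(cfg)
        p1, v1 = simulate_panel(cfg, models, seqs)
        p2, v2 = simulate_panel(cfg, models, seqs)
        assert (p1.alleles == p2.alleles).all()
        assert v1 == v2

    def test_zero_recomb_gives_perfect_intra_block_ld(self):
        cfg = SimConfig(seed=2, n_genes=3, n_haplotypes=100, recomb_rate=0.0,
                        ld_block_len=10**9)
        seqs, models = simulate_genome(cfg)
        panel, variants = simulate_panel(cfg, models, seqs)
        for j in range(1, min(8, panel.n_variants)):
            st = compute_ld(panel, variants[0].id, variants[j].id)
            assert st.r2 == pytest.approx(1.0)

    def test_cross_block_independence(self):
        """Across blocks alleles are independent: mean r2 below 0.05 at
        n_haplotypes = 2000."""
        cfg = SimConfig(seed=3, n_genes=4, n_haplotypes=2000, ld_block_len=500)
        seqs, models = simulate_genome(cfg)
        panel, variants = simulate_panel(cfg, models, seqs)
        blocks = np.array([v.pos // cfg.ld_block_len for v in variants])
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(300):
            i, j = rng.integers(0, len(variants), 2)
            if blocks[i] != blocks[j]:
                r2s.append(compute_ld(panel, variants[i].id, variants[j].id).r2)
        assert len(r2s) > 50
        assert np.mean(r2s) < 0.05

    def test_realized_mafs_match_configuration(self):
        """Realized allele frequencies track the configured MAF range within
        3 binomial SE at n >= 500 haplotypes."""
        cfg = SimConfig(seed=4, n_genes=3, n_haplotypes=500)
        seqs, models = simulate_genome(cfg)
        panel, variants = simulate_panel(cfg, models, seqs)
        lo, hi = cfg.maf_range
        se = 3 * np.sqrt(0.25 / cfg.n_haplotypes)
        for v in variants:
            assert lo - se <= v.maf <= hi + se

    def test_no_monomorphic_variants(self, small_sim):
        *_, panel, _ = small_sim
        freqs = panel.alt_frequencies()
        assert ((freqs > 0) & (freqs < 1)).all()


class TestSimulateCatalog:
    @pytest.fixture(scope="class")
    def default_sim(self):
        """Default-size conditions: the catalogue holds 338 index SNPs."""
        cfg = SimConfig(seed=13)
        seqs, models = simulate_genome(cfg)
        _, variants = simulate_panel(cfg, models, seqs)
        return cfg, models, variants

    def test_row_count_matches_n_disease_snps(self, default_sim):
        cfg, models, variants = default_sim
        cat = simulate_catalog(cfg, variants, models)
        assert len(cat) == cfg.n_disease_snps == 338

    def test_index_p_values_genome_wide_significant(self, default_sim):
        cfg, models, variants = default_sim
        cat = simulate_catalog(cfg, variants, models)
        assert (cat["p_value"] < 5e-8).all()
        assert (cat["p_value"] >= 1e-15).all()

    def test_deterministic_under_seed(self, default_sim):
        cfg, models, variants = default_sim
        c1 = simulate_catalog(cfg, variants, models)
        c2 = simulate_catalog(cfg, variants, models)
        assert c1.equals(c2)

    def test_unattainable_enrichment_is_config_error(self):
        cfg = SimConfig(seed=5, n_genes=2, n_haplotypes=50, n_disease_snps=30,
                        splice_enrichment_factor=50.0, snp_density=3)
        seqs, models = simulate_genome(cfg)
        _, variants = simulate_panel(cfg, models, seqs)
        with pytest.raises(ConfigError):
            simulate_catalog(cfg, variants, models)


class TestSimulateCtTable:
    def test_noise_free_shift_gives_exact_fold_change(self):
        """A -1 cycle target shift doubles expression downstream."""
        from splicescan.expression import CtRecord, comparative_ct

        cfg = SimConfig(seed=6, ct_effect={"TT": -1.0, "CC": 0.0}, ct_sd=0.0)
        df = simulate_ct_table(cfg, ["CC", "TT"], [5, 5])
        recs = [CtRecord(r[0], r[1], r[2], r[3]) for r in df.itertuples(index=False)]
        out = {g.genotype: g.rel_expression for g in comparative_ct(recs, "CC")}
        assert out["TT"] == pytest.approx(2.0)
        assert out["CC"] == pytest.approx(1.0)

    def test_zero_shifts_give_unit_folds(self):
        from splicescan.expression import CtRecord, comparative_ct

        cfg = SimConfig(seed=6, ct_sd=0.0)
        df = simulate_ct_table(cfg, ["AA", "AG", "GG"], [4, 4, 4])
        recs = [CtRecord(r[0], r[1], r[2], r[3]) for r in df.itertuples(index=False)]
        assert all(g.rel_expression == pytest.approx(1.0)
                   for g in comparative_ct(recs, "AG"))

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=8, ct_sd=0.5)
        assert simulate_ct_table(cfg, ["AA"], [6]).equals(simulate_ct_table(cfg, ["AA"], [6]))

    def test_bad_group_sizes_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ct_table(SimConfig(seed=1), ["AA"], [0])
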