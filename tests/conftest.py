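"""Shared fixtures: the packaged engineered cryptic-donor locus (on either
strand) and a small simulated dataset."""

from __future__ import annotations

import pytest

from splicescan.examples import CRYPTIC_EXON, CrypticDonorLocus, build_cryptic_donor_locus
from splicescan.simulate import SimConfig, simulate_genome, simulate_panel

# re-exported for tests that build their own constructions
build_locus = build_cryptic_donor_locus
Locus = CrypticDonorLocus


@pytest.fixture(params=["+", "-"], ids=["plus", "minus"])
def locus(request) -> CrypticDonorLocus:
    return build_cryptic_donor_locus(request.param)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome + panel shared across tests."""
    cfg = SimConfig(seed=11, n_genes=12, n_haplotypes=200, snp_density=8)
    seqs, models = simulate_genome(cfg)
    panel, variants = simulate_panel(cfg, models, seqs)
    return cfg, seqs, models, panel, variants
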