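"""End-to-end orchestration: catalogue filter -> LD proxies -> splice
annotation -> effect prediction -> prioritisation, with optional enrichment,
driven by a YAML config and written to a run directory with a provenance
manifest (parameters, seed, stage record counts, output checksums)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import SPLICE_CLASSES, SpliceWindows, annotate_set, locations_to_dataframe
from .catalog import (filter_significant, load_trait_list, read_associations,
                      select_traits, unique_index_snps)
from .core_io import read_fasta, read_gene_models
from .effects import (SpliceScoringModel, calls_to_dataframe, classify_effect,
                      load_pwm, prioritise)
from .enrichment import MatchCriteria, run_enrichment
from .ld import find_proxies, panel_from_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters; every referenced path must exist."""

    catalog: str
    vcf: str
    gff3: str
    fasta: str
    out_dir: str = "splicescan_run"
    traits: str | None = None  # YAML whitelist; None = packaged default
    p_threshold: float = 5e-8
    r2_threshold: float = 0.8
    ld_window: int = 500_000
    cryptic_threshold: float = 70.0
    score_delta: float = 10.0
    donor_pwm: str | None = None
    acceptor_pwm: str | None = None
    run_enrichment: bool = False
    n_sets: int = 1000
    maf_tolerance: float = 0.05
    gene_proximity_tolerance: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("catalog", "vcf", "gff3", "fasta"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the pipeline; returns the run directory.

    Outputs: index_snps.tsv, proxies.tsv, annotation.tsv, effects.tsv,
    prioritised.tsv, optional enrichment.json/null_props.tsv, and
    manifest.json.  Reruns with the same config are byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # stage 1: catalogue filter
    assoc = read_associations(config.catalog)
    counts["associations"] = len(assoc)
    assoc = select_traits(assoc, load_trait_list(config.traits))
    assoc = filter_significant(assoc, config.p_threshold)
    counts["significant_associations"] = len(assoc)
    index_ids = unique_index_snps(assoc)
    counts["index_snps"] = len(index_ids)
    pd.DataFrame({"snp": index_ids}).to_csv(out / "index_snps.tsv", sep="\t", index=False)
    log.info("catalogue filter: %d associations -> %d index SNPs",
             counts["associations"], counts["index_snps"])

    # stage 2: LD proxies
    panel = panel_from_vcf(config.vcf)
    in_panel = [i for i in index_ids if i in {v.id for v in panel.variants}]
    proxy_rows = []
    by_id = {v.id: v for v in panel.variants}
    proxy_variants: dict[str, object] = {}
    for idx in in_panel:
        for v, st in find_proxies(panel, idx, config.r2_threshold, config.ld_window):
            proxy_rows.append(
                {"index_snp": idx, "proxy": v.id, "r2": st.r2, "d_prime": st.d_prime,
                 "distance": abs(v.pos - by_id[idx].pos)}
            )
            proxy_variants[v.id] = v
    pd.DataFrame(proxy_rows).to_csv(out / "proxies.tsv", sep="\t", index=False)
    counts["proxies"] = len(proxy_variants)
    log.info("LD expansion: %d index SNPs -> %d unique variants",
             len(in_panel), counts["proxies"])

    # stage 3: splice annotation
    models = read_gene_models(config.gff3, "gff3")
    variants = list(proxy_variants.values())
    records, variant_cls, summary = annotate_set(variants, models)
    locations_to_dataframe(records).to_csv(out / "annotation.tsv", sep="\t", index=False)
    counts["splice_class_variants"] = summary.n_splice
    log.info("annotation: %d/%d variants in splice classes (%.3g%%)",
             summary.n_splice, summary.n_variants, summary.splice_percentage)

    # stage 4: effect prediction on splice-located variants
    seqs = read_fasta(config.fasta)
    scoring = SpliceScoringModel(
        donor_pwm=load_pwm("donor", config.donor_pwm),
        acceptor_pwm=load_pwm("acceptor", config.acceptor_pwm),
        cryptic_threshold=config.cryptic_threshold,
        score_delta=config.score_delta,
    )
    model_of = {m.transcript_id: m for m in models}
    calls = []
    for rec in records:
        if rec.cls in SPLICE_CLASSES and rec.transcript_id in model_of:
            calls.append(
                classify_effect(by_id[rec.variant_id], model_of[rec.transcript_id],
                                scoring, rec, seqs)
            )
    calls_to_dataframe(calls).to_csv(out / "effects.tsv", sep="\t", index=False)
    counts["effect_calls"] = len(calls)

    # stage 5: prioritisation
    ranked = prioritise(calls)
    ranked_df = calls_to_dataframe([c for c in ranked if c.category != "no_effect"])
    ranked_df.to_csv(out / "prioritised.tsv", sep="\t", index=False)
    counts["prioritised_variants"] = ranked_df["variant_id"].nunique() if len(ranked_df) else 0
    log.info("prioritisation: %d calls, %d unique prioritised variants",
             len(ranked), counts["prioritised_variants"])

    # optional stage 6: enrichment
    if config.run_enrichment:
        criteria = MatchCriteria(
            maf_tolerance=config.maf_tolerance,
            gene_proximity_tolerance=config.gene_proximity_tolerance,
            n_sets=config.n_sets,
            r2_threshold=config.r2_threshold,
            ld_window=config.ld_window,
        )
        index_variants = [by_id[i] for i in in_panel]
        result = run_enrichment(index_variants, panel.variants, panel, models,
                                criteria, seed=config.seed)
        (out / "enrichment.json").write_text(json.dumps(result.to_dict(), indent=2) + "\n")
        pd.DataFrame({"null_prop": result.null_props}).to_csv(
            out / "null_props.tsv", sep="\t", index=False
        )
        log.info("%s", result.summary())

    manifest = {
        "splicescan_version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stage_counts": counts,
        "checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
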