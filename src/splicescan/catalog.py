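"""GWAS-catalogue filtering: index SNPs for chosen traits at genome-wide
significance, the first stage of the pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5e-8

REQUIRED_COLUMNS = ("snp", "trait", "p_value", "risk_allele", "pubmed_id")


@dataclass(frozen=True)
class GwasAssociation:
    index_snp: str
    trait: str
    p_value: float
    risk_allele: str = "?"
    pubmed_id: str = ""

    def __post_init__(self) -> None:
        if not self.index_snp:
            raise ValueError("index_snp must be nonempty")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def read_associations(path: str | Path) -> list[GwasAssociation]:
    """Read a TSV association table (columns snp, trait, p_value,
    risk_allele, pubmed_id); rows with a non-numeric p-value are excluded
    with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            p = float(row["p_value"])
        except (TypeError, ValueError):
            log.warning("excluding %s: non-numeric p-value %r", row["snp"], row["p_value"])
            continue
        out.append(
            GwasAssociation(
                index_snp=str(row["snp"]),
                trait=str(row["trait"]),
                p_value=p,
                risk_allele=str(row.get("risk_allele", "?")),
                pubmed_id=str(row.get("pubmed_id", "")),
            )
        )
    return out


def filter_significant(
    associations: list[GwasAssociation], threshold: float = GENOME_WIDE_SIGNIFICANCE
) -> list[GwasAssociation]:
    """Associations at or below the significance threshold, input order kept.

    The comparison is inclusive (p <= threshold): published tables round
    p-values to one significant figure, so a printed 5e-8 is treated as
    genome-wide significant.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return [a for a in associations if a.p_value <= threshold]


def _norm_trait(t: str) -> str:
    return " ".join(t.split()).lower()


def select_traits(
    associations: list[GwasAssociation], whitelist: set[str]
) -> list[GwasAssociation]:
    """Case-insensitive exact trait match after whitespace normalization."""
    if not whitelist:
        raise ValueError("trait whitelist must be nonempty")
    wanted = {_norm_trait(t) for t in whitelist}
    return [a for a in associations if _norm_trait(a.trait) in wanted]


def load_trait_list(path: str | Path | None = None) -> set[str]:
    """Load a trait whitelist from YAML (a list under key ``traits`` or a
    bare list); with no path, the packaged autoimmune/inflammatory default."""
    if path is None:
        text = resources.files("splicescan.data").joinpath("autoimmune_traits.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data["traits"]
    return set(map(str, data))


def unique_index_snps(associations: list[GwasAssociation]) -> list[str]:
    """Deduplicated index SNP ids in first-appearance order.  Both the raw
    and deduplicated counts are logged: a SNP associated with several traits
    is one variant."""
    seen: dict[str, None] = {}
    for a in associations:
        seen.setdefault(a.index_snp, None)
    log.info(
        "associations: %d rows, %d unique index SNPs", len(associations), len(seen)
    )
    return list(seen)
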