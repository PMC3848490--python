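"""Genotype-stratified relative expression from qPCR cycle thresholds.

Relative quantification uses the comparative-Ct (2^-ddCt) method: per sample
dCt = target Ct - endogenous-control Ct; per genotype group
ddCt = mean(dCt) - mean(dCt of the calibrator group); relative expression
= 2^-ddCt, so the calibrator group is 1 by construction.  Group differences
are assessed with the Kruskal-Wallis H test (tie-corrected, chi-square
approximation), the appropriate choice for the small, non-normal sample
sizes typical of genotype-stratified qPCR panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    genotype: str
    target_ct: float
    control_ct: float

    def __post_init__(self) -> None:
        for name, v in (("target_ct", self.target_ct), ("control_ct", self.control_ct)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.control_ct


@dataclass(frozen=True)
class GroupExpression:
    genotype: str
    n: int
    delta_ct_mean: float
    rel_expression: float
    kw_H: float
    kw_p: float


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """TSV with columns sample, genotype, target_ct, control_ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "genotype", "target_ct", "control_ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return [
        CtRecord(str(r["sample"]), str(r["genotype"]),
                 float(r["target_ct"]), float(r["control_ct"]))
        for _, r in df.iterrows()
    ]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate all-tied input returns (0.0, 1.0) with a warning rather than
    an error.
    """
    if len(groups) < 2 or sum(1 for g in groups if len(g)) < 2:
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    if np.all(pooled == pooled[0]):
        log.warning("all observations tied; H defined as 0")
        return 0.0, 1.0
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def comparative_ct(
    records: Sequence[CtRecord], calibrator: str
) -> list[GroupExpression]:
    """Per-genotype relative expression by the comparative-Ct method.

    Fold changes are computed from group-mean dCt (the standard convention),
    relative to the ``calibrator`` genotype.  The Kruskal-Wallis test runs
    on the per-sample dCt values across all groups and its (H, p) is
    attached to every group row.
    """
    by_geno: dict[str, list[float]] = {}
    order: list[str] = []
    for r in records:
        if r.genotype not in by_geno:
            order.append(r.genotype)
        by_geno.setdefault(r.genotype, []).append(r.delta_ct)
    if calibrator not in by_geno or not by_geno[calibrator]:
        raise ValueError(f"calibrator group {calibrator!r} is empty or absent")
    cal_mean = float(np.mean(by_geno[calibrator]))
    if len(by_geno) >= 2 and sum(len(v) for v in by_geno.values()) >= 3:
        kw_h, kw_p = kruskal_wallis(list(by_geno.values()))
    else:
        kw_h, kw_p = float("nan"), float("nan")
    out = []
    for geno in order:
        vals = by_geno[geno]
        mean_dct = float(np.mean(vals))
        ddct = mean_dct - cal_mean
        out.append(
            GroupExpression(
                genotype=geno,
                n=len(vals),
                delta_ct_mean=mean_dct,
                rel_expression=float(2.0 ** (-ddct)),
                kw_H=kw_h,
                kw_p=kw_p,
            )
        )
    return out


def expression_to_dataframe(groups: Sequence[GroupExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genotype": g.genotype,
                "n": g.n,
                "delta_ct_mean": g.delta_ct_mean,
                "rel_expression": g.rel_expression,
                "kw_H": g.kw_H,
                "kw_p": g.kw_p,
            }
            for g in groups
        ]
    )
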