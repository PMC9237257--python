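"""Relative qPCR quantification (2^-ddCt) and RNA-seq concordance.

Per group, dCt = mean Ct(target) - mean Ct(reference); between a test and a
calibrator group, ddCt = dCt(test) - dCt(calibrator) and the relative
expression is 2^-ddCt (log2 fold-change = -ddCt).  Replicate Ct values are
averaged before dCt by default; amplification efficiency is fixed at 2, the
assumption built into the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QpcrPanel", "RelQuant", "ConcordanceResult", "delta_delta_ct", "concordance"]


@dataclass
class QpcrPanel:
    """Long-format Ct table (gene_id, sample_id, ct) with a reference gene."""

    ct: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "ct"}
        missing = required - set(self.ct.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns {sorted(missing)}")
        if (self.ct["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.reference_gene not in set(self.ct["gene_id"]):
            raise ValueError(f"reference gene {self.reference_gene!r} not in panel")

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.ct["gene_id"]) - {self.reference_gene})

    @classmethod
    def read_tsv(cls, path, reference_gene: str) -> "QpcrPanel":
        return cls(pd.read_csv(path, sep="\t", comment="#"), reference_gene)

    def to_tsv(self, path) -> None:
        self.ct.to_csv(path, sep="\t", index=False)


class RelQuant(NamedTuple):
    gene_id: str
    test_group: str
    calibrator_group: str
    ddct: float
    fold_change: float       # 2 ** -ddct
    log2_fold_change: float  # -ddct


def _mean_ct(panel: QpcrPanel, gene: str, samples: list[str]) -> float:
    sub = panel.ct[(panel.ct["gene_id"] == gene) & (panel.ct["sample_id"].isin(samples))]
    found = set(sub["sample_id"])
    missing = set(samples) - found
    if missing:
        raise ValueError(
            f"gene {gene!r} missing Ct in sample(s) {sorted(missing)}"
        )
    return float(sub["ct"].mean())


def delta_delta_ct(
    panel: QpcrPanel,
    design: pd.DataFrame,
    target_gene: str,
    test_group: str,
    calibrator_group: str,
) -> RelQuant:
    """2^-ddCt relative expression of ``target_gene`` in test vs calibrator."""
    groups = {g: list(sub["sample_id"]) for g, sub in design.groupby("group")}
    for g in (test_group, calibrator_group):
        if g not in groups:
            raise ValueError(f"group {g!r} not in design")
    dct = {}
    for g in (test_group, calibrator_group):
        samples = groups[g]
        dct[g] = _mean_ct(panel, target_gene, samples) - _mean_ct(
            panel, panel.reference_gene, samples
        )
    ddct = dct[test_group] - dct[calibrator_group]
    return RelQuant(
        gene_id=target_gene,
        test_group=test_group,
        calibrator_group=calibrator_group,
        ddct=ddct,
        fold_change=float(2.0 ** -ddct),
        log2_fold_change=-ddct,
    )


class ConcordanceResult(NamedTuple):
    r: float
    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def concordance(qpcr_log2fc: pd.Series, rnaseq_log2fc: pd.Series) -> ConcordanceResult:
    """Pearson correlation and least-squares line between the paired
    log2 fold-changes (qPCR on y, RNA-seq on x).

    Requires >= 3 paired finite values; a constant vector makes the
    correlation undefined and returns NaN statistics.
    """
    paired = pd.DataFrame({"qpcr": qpcr_log2fc, "rnaseq": rnaseq_log2fc}).dropna()
    if len(paired) < 3:
        raise ValueError("concordance needs >= 3 paired genes")
    x = paired["rnaseq"].to_numpy(dtype=float)
    y = paired["qpcr"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return ConcordanceResult(np.nan, np.nan, np.nan, np.nan, np.nan, len(paired))
    fit = stats.linregress(x, y)
    return ConcordanceResult(
        r=float(fit.rvalue),
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pvalue=float(fit.pvalue),
        n=len(paired),
    )
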