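"""Model/Results interface for the two-factor transcriptome comparison.

``TwoFactorTranscriptomeModel`` is built from a count matrix and the 2x2
factorial sample sheet; ``fit()`` quantifies FPKM, runs the four paired
contrasts, calls DEGs under the three criteria and attributes shared DEGs
to transgene, environment, or interaction effects by directional agreement.
The returned results object carries the per-contrast tables, the DEG sets,
the attribution and the co-expression Venn, and prints a compact summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import attribution as attribution_mod
from . import degtest, expression
from .attribution import EffectClassification
from .degtest import ContrastResult, DegSet
from .expression import CountMatrix, FpkmMatrix, VennCounts

__all__ = ["TwoFactorTranscriptomeModel", "TwoFactorResults"]


class TwoFactorTranscriptomeModel:
    """Two-factor (genotype x environment) differential expression model.

    Parameters
    ----------
    counts : CountMatrix
        Gene x sample integer counts with gene lengths.
    design : DataFrame
        Validated 2x2 sample sheet (see :func:`gxetx.expression.validate_design`).
    fpkm_threshold, lfc_threshold, alpha :
        The three DEG criteria (all boundaries inclusive).
    test : {"exact-binomial", "nb-moments"}
        Per-contrast count test.
    adjust : {"bh", "bonferroni"}
        Multiple-testing adjustment over filtered genes.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: pd.DataFrame,
        *,
        fpkm_threshold: float = 1.0,
        lfc_threshold: float = 1.0,
        alpha: float = 0.05,
        test: str = "exact-binomial",
        adjust: str = "bh",
        pseudocount: float = degtest.DEFAULT_PSEUDOCOUNT,
    ) -> None:
        self.counts = counts
        self.design = expression.validate_design(design.reset_index(drop=True))
        self.fpkm_threshold = fpkm_threshold
        self.lfc_threshold = lfc_threshold
        self.alpha = alpha
        self.test = test
        self.adjust = adjust
        self.pseudocount = pseudocount
        self.contrasts = expression.standard_contrasts(self.design)

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "TwoFactorTranscriptomeModel":
        return cls(
            CountMatrix.read_tsv(counts_path), pd.read_csv(samples_path, sep="\t"), **kwargs
        )

    def fit(self) -> "TwoFactorResults":
        fpkm = expression.compute_fpkm(self.counts)
        expressed = expression.expressed_sets(fpkm, self.design, self.fpkm_threshold)
        venn = expression.coexpression_venn(expressed)
        correlation = expression.replicate_correlation(fpkm, self.design)

        contrast_results: dict[str, ContrastResult] = {}
        deg_sets: dict[str, DegSet] = {}
        for cid, (ga, gb) in self.contrasts.items():
            res = degtest.test_contrast(
                self.counts,
                self.design,
                ga,
                gb,
                fpkm=fpkm,
                fpkm_threshold=self.fpkm_threshold,
                pseudocount=self.pseudocount,
                test=self.test,
                adjust=self.adjust,
            )
            contrast_results[cid] = res
            deg_sets[cid] = degtest.call_degs(res, self.lfc_threshold, self.alpha)

        cids = list(self.contrasts)
        classification = attribution_mod.classify_effects(
            deg_sets[cids[0]], deg_sets[cids[1]], deg_sets[cids[2]], deg_sets[cids[3]]
        )
        return TwoFactorResults(
            model=self,
            fpkm=fpkm,
            expressed_sets=expressed,
            venn=venn,
            replicate_correlation=correlation,
            contrast_results=contrast_results,
            deg_sets=deg_sets,
            classification=classification,
        )


@dataclass
class TwoFactorResults:
    """Fitted results of the two-factor comparison."""

    model: TwoFactorTranscriptomeModel
    fpkm: FpkmMatrix
    expressed_sets: dict[str, set[str]]
    venn: VennCounts
    replicate_correlation: pd.DataFrame
    contrast_results: dict[str, ContrastResult]
    deg_sets: dict[str, DegSet]
    classification: EffectClassification
    _summaries: list[dict] = field(default_factory=list, repr=False)

    @property
    def log2fc(self) -> dict[str, pd.Series]:
        return {cid: res.table["log2fc"] for cid, res in self.contrast_results.items()}

    def contrast_summaries(self) -> pd.DataFrame:
        rows = [
            degtest.summarize_contrast(
                self.deg_sets[cid], self.contrast_results[cid].n_coexpressed
            )
            for cid in self.contrast_results
        ]
        return pd.DataFrame(rows)

    def attribution_counts(self) -> dict:
        return attribution_mod.attribution_counts(self.classification)

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = ["Two-factor transcriptome comparison", "=" * 36]
        n_genes = len(self.fpkm.gene_ids)
        lines.append(f"genes: {n_genes}, samples: {len(self.model.design)}")
        lines.append(
            "expressed per group (mean FPKM >= "
            f"{self.model.fpkm_threshold:g}): "
            + ", ".join(f"{g}={len(s)}" for g, s in sorted(self.expressed_sets.items()))
        )
        four_way = self.venn.regions[frozenset(self.venn.set_names)]
        lines.append(
            f"co-expressed in all four groups: {four_way} "
            f"of {self.venn.union_size} expressed anywhere"
        )
        lines.append("")
        lines.append("contrast            total    up  down  co-expr   pct")
        for row in self.contrast_summaries().itertuples():
            lines.append(
                f"{row.contrast_id:<18} {row.total:>6} {row.up:>5} {row.down:>5} "
                f"{row.n_coexpressed:>8}  {row.pct_formatted:>6}"
            )
        lines.append("")
        counts = self.attribution_counts()
        lines.append(
            "effect attribution: "
            f"transgene={counts['transgene']['total']} "
            f"(up {counts['transgene']['up']}, down {counts['transgene']['down']}), "
            f"environment={counts['environment']['total']} "
            f"(up {counts['environment']['up']}, down {counts['environment']['down']}), "
            f"interaction={counts['interaction']['total']} "
            f"({counts['interaction_genotype']['total']} genotype-pair + "
            f"{counts['interaction_environment']['total']} site-pair)"
        )
        return "\n".join(lines)
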