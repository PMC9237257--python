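"""Per-contrast differential expression testing and DEG calling.

A gene is a DEG in a two-group contrast when all three criteria hold:

1. expression filter — group-mean FPKM >= 1 in at least one of the two
   groups;
2. effect size — |log2 fold-change| >= 1, with
   log2FC = log2((meanFPKM_A + eps) / (meanFPKM_B + eps));
3. significance — adjusted p <= 0.05.

All boundary comparisons are inclusive.  The default test is the exact
conditional (binomial) test on pooled per-group counts given the library
size totals: conditional on the pooled total ``t = xA + xB``, under the null
``xA ~ Binomial(t, N_A / (N_A + N_B))``, and the two-sided p-value sums the
probability of all outcomes no more likely than the observed one.  An
overdispersion-aware negative-binomial z-test with method-of-moments
dispersion is available via ``test="nb-moments"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._formatting import format_pct, pct_round_half_up
from .expression import CountMatrix, FpkmMatrix, compute_fpkm

__all__ = [
    "ContrastResult",
    "DegSet",
    "test_contrast",
    "adjust_pvalues",
    "call_degs",
    "summarize_contrast",
]

DEFAULT_PSEUDOCOUNT = 0.01  # FPKM units, guards one-group zeros in log2FC


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group comparison.

    ``table`` columns: mean_fpkm_a, mean_fpkm_b, log2fc, pvalue, padj,
    expressed (filter state).  Genes failing the expression filter carry
    NaN p-values and never become DEGs.
    """

    contrast_id: str
    group_a: str
    group_b: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_coexpressed(self) -> int:
        """Genes expressed (group-mean FPKM >= threshold) in *both* groups."""
        return int(self.table["coexpressed"].sum())

    def to_tsv(self, path, directions: pd.Series | None = None) -> None:
        out = self.table.copy()
        if directions is not None:
            out["direction"] = directions.reindex(out.index).fillna("none")
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class DegSet:
    """Directional DEG calls for one contrast: gene -> +1 (up) / -1 (down)."""

    contrast_id: str
    directions: dict[str, int]
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (-1, 1)}
        if bad:
            raise ValueError(f"directions must be +/-1, got {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    @property
    def up(self) -> set[str]:
        return {g for g, d in self.directions.items() if d == 1}

    @property
    def down(self) -> set[str]:
        return {g for g, d in self.directions.items() if d == -1}

    def __len__(self) -> int:
        return len(self.directions)


def _exact_binomial_pvalues(xa: np.ndarray, xb: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided exact conditional p per gene; pooled total 0 -> p = 1."""
    pvals = np.ones(len(xa))
    totals = xa + xb
    for i, (k, t) in enumerate(zip(xa, totals)):
        if t > 0:
            pvals[i] = stats.binomtest(int(k), int(t), p0).pvalue
    return pvals


def _nb_moments_pvalues(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: np.ndarray,
    size_factors_b: np.ndarray,
) -> np.ndarray:
    """Wald z-test on normalised group means with NB moment variance.

    Counts are scaled to a common depth; a single method-of-moments
    dispersion ``alpha = median((s2 - m) / m^2)`` over genes (floored at 0)
    plugs into var = m + alpha m^2.
    """
    na = counts_a / size_factors_a[np.newaxis, :]
    nb = counts_b / size_factors_b[np.newaxis, :]
    pooled = np.hstack([na, nb])
    m = pooled.mean(axis=1)
    s2 = pooled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = (s2 - m) / m**2
    per_gene = per_gene[np.isfinite(per_gene) & (m > 0)]
    alpha = max(0.0, float(np.median(per_gene))) if len(per_gene) else 0.0

    ma, mb = na.mean(axis=1), nb.mean(axis=1)
    va = (ma + alpha * ma**2) / na.shape[1]
    vb = (mb + alpha * mb**2) / nb.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ma - mb) / np.sqrt(va + vb)
    z = np.where(np.isfinite(z), z, 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up (default) or Bonferroni, clipped to [0,1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return np.clip(multipletests(p, method=key)[1], 0.0, 1.0)


def test_contrast(
    counts: CountMatrix,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    fpkm: FpkmMatrix | None = None,
    fpkm_threshold: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    test: str = "exact-binomial",
    adjust: str = "bh",
) -> ContrastResult:
    """Differential expression statistics for ``group_a`` vs ``group_b``.

    The expression filter (group-mean FPKM >= ``fpkm_threshold`` in either
    group) selects the genes that are tested; the multiple-testing
    adjustment runs over exactly those genes.
    """
    for g in (group_a, group_b):
        if g not in set(design["group"]):
            raise ValueError(f"group {g!r} not present in design")
    samples_a = list(design.loc[design["group"] == group_a, "sample_id"])
    samples_b = list(design.loc[design["group"] == group_b, "sample_id"])
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 replicates")

    if fpkm is None:
        fpkm = compute_fpkm(counts)
    mean_a = fpkm.values[samples_a].mean(axis=1)
    mean_b = fpkm.values[samples_b].mean(axis=1)
    expressed = (mean_a >= fpkm_threshold) | (mean_b >= fpkm_threshold)
    coexpressed = (mean_a >= fpkm_threshold) & (mean_b >= fpkm_threshold)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    ca = counts.counts[samples_a].to_numpy(dtype=float)
    cb = counts.counts[samples_b].to_numpy(dtype=float)
    lib_a = counts.library_sizes[samples_a].to_numpy(dtype=float)
    lib_b = counts.library_sizes[samples_b].to_numpy(dtype=float)
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("a group has zero total counts")

    idx = counts.gene_ids
    mask = expressed.to_numpy()
    pvalues = np.full(len(idx), np.nan)
    if test == "exact-binomial":
        xa = ca.sum(axis=1)[mask]
        xb = cb.sum(axis=1)[mask]
        p0 = lib_a.sum() / (lib_a.sum() + lib_b.sum())
        pvalues[mask] = _exact_binomial_pvalues(xa, xb, p0)
    elif test == "nb-moments":
        mean_lib = np.hstack([lib_a, lib_b]).mean()
        pvalues[mask] = _nb_moments_pvalues(
            ca[mask], cb[mask], lib_a / mean_lib, lib_b / mean_lib
        )
    else:
        raise ValueError(f"unknown test {test!r}")

    padj = np.full(len(idx), np.nan)
    padj[mask] = adjust_pvalues(pvalues[mask], method=adjust)

    table = pd.DataFrame(
        {
            "mean_fpkm_a": mean_a,
            "mean_fpkm_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvalues,
            "padj": padj,
            "expressed": mask,
            "coexpressed": coexpressed.to_numpy(),
        },
        index=idx,
    )
    return ContrastResult(
        contrast_id=f"{group_a}-vs-{group_b}",
        group_a=group_a,
        group_b=group_b,
        table=table,
        metadata={
            "test": test,
            "adjust": adjust,
            "fpkm_threshold": fpkm_threshold,
            "pseudocount": pseudocount,
        },
    )


def call_degs(
    result: ContrastResult, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> DegSet:
    """Apply the three DEG criteria; both thresholds are inclusive."""
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    ok = t["expressed"] & (t["padj"] <= alpha)
    up = ok & (t["log2fc"] >= lfc_threshold)
    down = ok & (t["log2fc"] <= -lfc_threshold)
    directions = {g: 1 for g in t.index[up]}
    directions.update({g: -1 for g in t.index[down]})
    return DegSet(
        contrast_id=result.contrast_id,
        directions=directions,
        lfc_threshold=lfc_threshold,
        alpha=alpha,
    )


def summarize_contrast(degs: DegSet, n_coexpressed: int) -> dict:
    """Contrast summary with the report-style percentage of co-expressed genes.

    e.g. 258 DEGs over 19,719 co-expressed genes -> ``"1.31%"``.
    """
    total = len(degs)
    if n_coexpressed <= 0:
        raise ValueError("n_coexpressed must be positive")
    if n_coexpressed < total:
        raise ValueError("n_coexpressed smaller than the DEG count")
    return {
        "contrast_id": degs.contrast_id,
        "total": total,
        "up": len(degs.up),
        "down": len(degs.down),
        "n_coexpressed": n_coexpressed,
        "pct": pct_round_half_up(total, n_coexpressed),
        "pct_formatted": format_pct(total, n_coexpressed),
    }
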