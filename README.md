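# gxetx

**Two-factor (genotype × environment) transcriptome comparison**: a tested,
reusable implementation of the analysis used to ask whether transcriptional
differences in a transgenic tree line are caused by the introduced gene, by
the growing environment, or by their interaction.

The motivating setting is a transgenic poplar line expressing an AP2/ERF
(jasmonate/ethylene-responsive) transcription factor, grown alongside its
non-transgenic progenitor at a saline and a non-saline site, with bud
transcriptomes sequenced in three biological replicates per group (a 2 × 2 × 3
design: two genotypes × two sites). The package is for molecular ecologists
and tree biotechnologists who have such a factorial count matrix and want the
complete downstream analysis with a ground-truth simulator to validate it.

## What it computes

Starting from a gene × sample integer count matrix with gene lengths:

1. **FPKM quantification** — FPKM = 10⁹·C/(N·L) for fragment count C, library
   size N and gene length L; genes are *expressed* in a group when the group
   mean FPKM ≥ 1, and the four expressed-gene sets feed a four-way
   co-expression Venn plus replicate-correlation QC on log₁₀(FPKM+1).
2. **DEG calling** — for each of the four paired contrasts (genotype within
   each site, site within each genotype) a gene is differentially expressed
   when (i) mean FPKM ≥ 1 in either group, (ii) |log₂FC| ≥ 1 with
   log₂FC = log₂((m_A+ε)/(m_B+ε)), and (iii) adjusted p ≤ 0.05. The default
   test is the exact conditional binomial test on pooled per-group counts
   given library-size totals (x_A ~ Bin(x_A+x_B, N_A/(N_A+N_B)) under the
   null); Benjamini–Hochberg adjustment by default, an overdispersion-aware
   negative-binomial variant and Bonferroni behind switches.
3. **Effect attribution** — a DEG shared by both genotype contrasts with the
   same fold-change sign is attributed to the **transgene**; shared by both
   site contrasts with the same sign, to the **environment**; shared with
   opposite signs in either pairing, to the **genotype × environment
   interaction**. Sign, not magnitude, defines agreement.
4. **Promoter cis-element scan** — strand-aware 2-kb promoter windows
   upstream of each TSS are scanned (both strands, overlapping hits
   reported) for the transcription factor's target cores as IUPAC patterns:
   GCC-box `GCCGCC`, DREB `CCGAC`, ABRE `YACGTGKC`; summarised per DEG
   direction as a counts-and-percentages table.
5. **Enrichment** — hypergeometric upper-tail test of term annotations
   against the co-expressed background with Bonferroni correction, plus
   level-2 ontology binning (root at level 0).
6. **qPCR validation** — 2^−ΔΔCt relative quantification against a reference
   gene and Pearson concordance (r, R², slope) of qPCR vs RNA-seq log₂
   fold-changes.

A synthetic-data module generates the full 2×2 factorial dataset with known
ground truth — negative-binomial counts with planted effect classes,
promoters with planted (and background-screened) element cores, annotations
with planted enrichment, and a Ct panel consistent with the simulated fold
changes — so every stage is testable end to end.

## Worked example

```python
from gxetx import SimConfig, TwoFactorTranscriptomeModel
from gxetx.simulate import simulate_counts, evaluate_recovery

cfg = SimConfig(n_genes=2000, seed=5)          # 2x2x3 design, effects of 2 log2 units
counts, design, truth = simulate_counts(cfg)
fit = TwoFactorTranscriptomeModel(counts, design).fit()
print(fit.summary())
```

prints

```
Two-factor transcriptome comparison
====================================
genes: 2000, samples: 12
expressed per group (mean FPKM >= 1): DA=2000, DB=2000, QA=2000, QB=2000
co-expressed in all four groups: 2000 of 2000 expressed anywhere

contrast            total    up  down  co-expr   pct
DA-vs-DB               69    32    37     2000   3.45%
QA-vs-QB               49    19    30     2000   2.45%
DA-vs-QA              140    70    70     2000   7.00%
DB-vs-QB              117    56    61     2000   5.85%

effect attribution: transgene=19 (up 6, down 13), environment=88 (up 45, down 43), interaction=39 (23 genotype-pair + 16 site-pair)
```

Group codes: D/Q = saline/non-saline site, A/B = transgenic/progenitor, so
`DA-vs-DB` is the genotype contrast at the saline site. Each contrast row
reports the DEGs (total, up, down) and their percentage of that contrast's
co-expressed genes; the attribution line splits shared DEGs into the three
effect classes. Against the planted truth,

```python
print(evaluate_recovery(fit.classification, truth))
# {'transgene_recovery': 0.95, 'environment_recovery': 0.978,
#  'interaction_recovery': 0.975, 'null_contamination': 0.0}
```

95–98% of planted effect genes land in the correct class and no null gene is
attributed to any class.

The CLI mirrors the stages: `gxetx simulate`, `gxetx deg --counts counts.tsv
--samples samples.tsv --contrast DA:DB`, `gxetx scan`, `gxetx enrich`,
`gxetx qpcr`, and `gxetx run-all --config run.yaml` for the full pipeline
with a reproducibility manifest.

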