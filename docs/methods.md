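# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Design and notation

The design is a complete 2 × 2 factorial: genotype ∈ {transgenic (A),
progenitor (B)} × site ∈ {saline (D), non-saline (Q)}, with r ≥ 2 biological
replicates per group (default 3). The four analysis contrasts are the paired
one-factor comparisons: DA–DB and QA–QB (genotype within site), DA–QA and
DB–QB (site within genotype).

## Quantification and filtering

FPKM_gs = 10⁹ · C_gs / (N_s · L_g), with N_s the per-sample library size
(column sum unless an explicit mapped-fragment total is supplied) and L_g
the gene length in bp. A gene is *expressed* in a group when its group-mean
FPKM ≥ 1 (boundary inclusive). The group mean — rather than an
any-replicate rule — is the default because a replicated design reports one
expressed-gene count per group; an "any replicate" mode is available.
Replicate QC computes Pearson correlation on log₁₀(FPKM+1): the log
transform guards the correlation against domination by a handful of very
highly expressed genes, and is recorded in the output metadata since
correlations on raw FPKM would be systematically higher. Constant samples
have undefined correlation and are reported as missing with a warning.

## The DEG test

A gene is a DEG in a contrast when all three hold (all bounds inclusive):
mean FPKM ≥ 1 in at least one group; |log₂FC| ≥ 1 with a pseudocount of
ε = 0.01 FPKM guarding one-group zeros; adjusted p ≤ 0.05.

The default test is the **exact conditional binomial test** on pooled
per-group counts. Conditional on the pooled total t = x_A + x_B, under the
null of equal concentration x_A ~ Binomial(t, N_A/(N_A+N_B)); the two-sided
p-value sums the probability of every outcome no more likely than the one
observed. This test is fully specified, cheap, and verifiable against
enumeration, which is why it is the default: it treats replicates as pooled
sequencing depth and is therefore anti-conservative under biological
overdispersion, but the |log₂FC| ≥ 1 gate absorbs most of that (a null gene
must show a two-fold mean difference before significance matters — the
all-null false-call fraction measured by the acceptance script is ≈ 0.4%).
An overdispersion-aware alternative (`test="nb-moments"`) uses a Wald z on
depth-normalised group means with a single method-of-moments negative
binomial dispersion (variance μ + αμ², α = median of (s²−m)/m² over genes,
floored at 0).

Multiple testing runs over exactly the genes passing the expression filter;
Benjamini–Hochberg step-up is the default for DEG calling (Bonferroni
available), and Bonferroni is the default for enrichment, where conservative
control is conventional.

Percentages in all report tables are computed round-half-up at two decimals
in decimal arithmetic (258/19,719 → 1.31%). This is the single formatting
rule used everywhere.

## Effect attribution

Attribution is set-algebraic, not model-based: a DEG present in both
contrasts of a pairing is attributed by the agreement of its fold-change
*signs* — same sign in the genotype pairing ⇒ transgene effect; same sign in
the site pairing ⇒ environment effect; opposite sign in either pairing ⇒
genotype × environment interaction (reported separately per pairing, since a
gene can legitimately hold a class in both pairings). Magnitudes are
deliberately ignored: the shared direction is the claim being made. A formal
two-factor interaction model (e.g. a GLM with a genotype×site term) would be
more powerful but answers a different question; the set-algebraic procedure
is reproduced as such.

## Promoter scanning

Promoters are the 2,000 bp upstream of the TSS: for a + strand gene the
forward-strand window [TSS−2000, TSS−1]; for a − strand gene the reverse
complement of [TSS+1, TSS+2000]; windows truncate at contig boundaries with
a warning. Coordinates are 1-based closed throughout.

Element cores are IUPAC patterns — GCC-box `GCCGCC`, DREB `CCGAC`, ABRE
`YACGTGKC` (reading the (C/T)ACGTG(T/G)C consensus; definitions are
user-overridable because the ABRE consensus admits alternative parses). The
scan reports every exact match including overlaps; `N` in the sequence
matches nothing. Both strands are scanned by default (these boxes function
in either orientation), with reverse-strand hits mapped to forward
coordinates; a single-strand mode exists, and the synthetic generator plants
consistently with the both-strand default. In the summary table an element
"counts" for a gene if it has ≥ 1 match, and the "2 elements"/"3 elements"
columns count genes by the number of *distinct element types* present.

## Enrichment

For a DEG list of size n from a background of N genes, K of them annotated
to a term, p = Σ_{i=k..min(n,K)} C(K,i)·C(N−K,n−i)/C(N,n) (upper tail).
Terms annotating no background gene are excluded from testing and from the
Bonferroni m. The default background is the contrast's co-expressed gene
set (union-ed with the DEG list so the precondition DEG ⊆ background always
holds); a whole-annotation background is a config switch. Because practice
varies on whether the 0.05 threshold applies to corrected or raw p, both
flags are emitted (`significant` = Bonferroni-corrected ≤ 0.05,
`significant_raw` = raw ≤ 0.05).

Level-2 binning puts each namespace root at level 0, so level-2 terms are
two parent edges below the root — stated explicitly because ontology tooling
conventions differ. A gene contributes once to every level-2 ancestor of
every term it carries; terms with no path to a root are skipped with a
warning, cycles are an error.

## qPCR

ΔCt = mean Ct(target) − mean Ct(reference) per group (replicates averaged
before ΔCt; a per-replicate mode is available), ΔΔCt = ΔCt(test) −
ΔCt(calibrator), relative expression 2^−ΔΔCt. Amplification efficiency is
fixed at 2, the assumption built into the method; the calibrator group is a
required input. Concordance with RNA-seq is Pearson r/R² plus the
least-squares line on paired log₂ fold-changes.

## The synthetic generator

Counts are negative binomial with variance μ + αμ², constant dispersion
α = 0.05 by default (a moderate bulk-RNA-seq value; configurable, with a
Poisson limit below α = 10⁻¹²). Baseline log₂ means are Normal(6, 1.5) —
median ≈ 64 expected counts with a realistic dynamic range — and gene
lengths are log-uniform on [500, 5000] bp so the FPKM length term is
exercised. Planted effects shift log₂ means by ±2 by default (twice the DEG
threshold): transgene genes shift the transgenic groups identically at both
sites; environment genes shift the saline groups identically in both
genotypes; interaction genes shift with opposite sign across their contrast
pair, split evenly between the genotype and environment pairings. Effect
fractions default to null 0.925 / transgene 0.010 / environment 0.045 /
interaction 0.020 — environment-driven genes most frequent, transgene-driven
rare, interactions in between, the ordering such comparisons report. Library
sizes are roughly equal because all samples draw from the same baseline
distribution.

Promoters are uniform A/C/G/T with chosen cores overwritten at random
non-overlapping offsets (per-element planting probabilities differ between
effect-class and null genes; defaults give ~40% of effect genes at least one
element, DREB most common). The background is screened by rejection
resampling so that no *unplanted* core occurs on either strand, and a
placement is accepted only if a full two-strand scan recovers exactly the
planted instances — so Table-style fractions have exact ground truth. The
screen can be switched off for realism tests.

Annotations give each namespace (BP/CC/MF/pathway) a root, two level-1 and
four level-2 terms, with annotated leaves one edge below level 2. One leaf
per effect class covers 90% of that class plus a 1% null leak (the planted
enrichment truth); remaining leaves annotate random gene sets. The qPCR
panel simulates Ct = 40 − log₂(expression) + N(0, σ) with σ = 0.2 cycles by
default, and a reference gene with constant expression; built from the
expected group means this inverts exactly at σ = 0.

All randomness descends from one seed through spawned child generators, so
a seed reproduces the dataset byte for byte.

**What the generator does not emulate:** GC/length biases and other
technical covariates, per-gene dispersion trends, correlated genes or
co-regulated modules, isoforms, unbalanced library sizes, batch effects,
real promoter base composition (background is uniform, and screening makes
element ground truth cleaner than nature), realistic ontology topology
(the DAG is a small tree), or qPCR efficiency ≠ 2. Passing the recovery
tests therefore shows the pipeline's logic is correct under its stated
model, not that the exact conditional test is optimal for heavily
overdispersed field data — for that, the NB variant or a dedicated DE
package is the appropriate comparison.

## Problem sizes and numerical conventions

Defaults were chosen so a full synthetic run is quick on a laptop: 2,000
genes × 12 samples for the end-to-end recovery analysis, 20 × 1,000 genes
for the all-null calibration, 1,000 2-kb sequences for the scanner oracle
and a dense N ≤ 60 grid for the hypergeometric oracle. Ties and boundaries:
all DEG thresholds inclusive; the two-sided exact p sums outcomes with
probability ≤ the observed outcome's; BH/Bonferroni outputs clipped to
[0, 1]; percentages round half-up at 2 decimals; promoter coordinates
1-based closed; a term reachable from several roots keeps its smallest
depth. Degenerate inputs (zero-total groups, constant correlation vectors,
DEGs missing promoter records, orphan ontology terms) raise errors or
produce flagged missing values as documented in each function.
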