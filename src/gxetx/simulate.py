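"""Synthetic 2x2 factorial transcriptome dataset with known ground truth.

The generator emulates the statistical structure of a two-genotype
(transgenic vs progenitor), two-site (saline vs nonsaline), replicated bud
transcriptome study:

* negative-binomial counts over a 2 x 2 x replicates design, with genes
  planted in four effect classes — ``null`` (no effect), ``transgene``
  (genotype shift of the same sign at both sites), ``environment`` (site
  shift of the same sign in both genotypes) and ``interaction`` (a shift
  whose sign flips across the paired contrasts);
* promoter sequences with cis-element cores (GCC-box / ABRE / DREB)
  planted at controlled per-class frequencies, over a background screened
  so that no unplanted core occurs on either strand;
* term annotations with terms preferentially covering chosen effect
  classes, plus a small parent-edge table giving every term a path to a
  namespace root (so level-2 ancestors are well defined);
* a qPCR Ct panel consistent with the simulated fold-changes plus
  Gaussian noise.

All randomness flows from a single seed through spawned child generators,
so an identical seed reproduces the dataset exactly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import AnnotationMap
from .expression import CountMatrix, validate_design
from .motifs import (
    DEFAULT_ELEMENTS,
    CisElementDef,
    expand_iupac,
    reverse_complement,
)
from .qpcr import QpcrPanel

__all__ = [
    "SimConfig",
    "TruthLabels",
    "SimulatedDataset",
    "simulate_counts",
    "simulate_promoters",
    "simulate_annotations",
    "simulate_qpcr",
    "simulate_dataset",
    "true_mean_expression",
    "evaluate_recovery",
    "write_dataset",
]

GROUPS = ("DA", "DB", "QA", "QB")  # D/Q = saline/nonsaline site, A/B = transgenic/progenitor
EFFECT_CLASSES = ("transgene", "environment", "interaction")

# per-element planting probability, for effect-class vs null genes; the
# effect-class values give roughly 30-50% of DEGs at least one element with
# DREB the most frequent, the structure seen in field promoter surveys
DEFAULT_PLANT_PROB: dict[str, dict[str, float]] = {
    "effect": {"GCC-box": 0.08, "ABRE": 0.10, "DREB": 0.30},
    "null": {"GCC-box": 0.04, "ABRE": 0.05, "DREB": 0.15},
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults encode the simulated study: 2,000 genes, 3 replicates per
    group, planted effects of 2 log2 units (comfortably past the DEG
    fold-change threshold of 1), log-normal baseline expression
    (log2 mean 6, sd 1.5 — median ~64 expected counts) and a constant NB
    dispersion of 0.05.  Effect fractions keep environment-driven genes
    most frequent, transgene-driven genes rare and interactions in
    between, mirroring the ordering such comparisons report.
    """

    n_genes: int = 2000
    replicates_per_group: int = 3
    effect_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.925,
            "transgene": 0.010,
            "environment": 0.045,
            "interaction": 0.020,
        }
    )
    effect_size_log2: float = 2.0
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 1.5
    dispersion: float = 0.05
    promoter_length: int = 2000
    motif_plant_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PLANT_PROB.items()}
    )
    screen_background: bool = True
    n_terms: int = 50
    annotation_cover_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        fracs = dict(self.effect_fractions)
        unknown = set(fracs) - {"null", *EFFECT_CLASSES}
        if unknown:
            raise ValueError(f"unknown effect classes {sorted(unknown)}")
        if any(f < 0 for f in fracs.values()):
            raise ValueError("effect fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("effect fractions must sum to 1")
        if self.effect_size_log2 < 0:
            raise ValueError("effect size must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.baseline_sd_log2 < 0:
            raise ValueError("baseline sd must be non-negative")
        if self.promoter_length <= 0:
            raise ValueError("promoter length must be positive")
        for side, probs in self.motif_plant_prob.items():
            if side not in ("effect", "null"):
                raise ValueError(f"motif_plant_prob keys must be effect/null, got {side!r}")
            for name, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"plant probability {name}={p} outside [0,1]")
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator for one simulation stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


@dataclass
class TruthLabels:
    """Ground-truth effect class and structure per gene.

    ``table`` is indexed by gene id with columns: klass, sign_genotype,
    sign_site, interaction_pairing ("genotype"/"environment" for
    interaction genes, "" otherwise), the four expected group mean counts
    (mu_DA..mu_QB) and planted_elements (comma-joined element names, filled
    in by the promoter simulator).
    """

    table: pd.DataFrame

    def genes_of(self, klass: str, pairing: str | None = None) -> set[str]:
        sel = self.table["klass"] == klass
        if pairing is not None:
            sel &= self.table["interaction_pairing"] == pairing
        return set(self.table.index[sel])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path) -> "TruthLabels":
        # keep_default_na off so the class label "null" survives the round trip
        table = pd.read_csv(
            path, sep="\t", comment="#", index_col="gene_id", keep_default_na=False
        )
        for col in ("mu_DA", "mu_DB", "mu_QA", "mu_QB"):
            if col in table.columns:
                table[col] = table[col].astype(float)
        return cls(table)


def _allocate_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic per-class gene counts (round(n * fraction), null takes
    the remainder), assigned to randomly permuted gene indices."""
    n = config.n_genes
    counts = {k: round(n * config.effect_fractions.get(k, 0.0)) for k in EFFECT_CLASSES}
    n_null = n - sum(counts.values())
    if n_null < 0:
        raise ValueError("effect fractions allocate more genes than n_genes")
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    order = rng.permutation(n)
    klass = np.array(["null"] * n, dtype=object)
    pos = 0
    for k in EFFECT_CLASSES:
        klass[order[pos : pos + counts[k]]] = k
        pos += counts[k]
    table = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    table["klass"] = klass
    return table


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, TruthLabels]:
    """Draw the NB count matrix, the sample sheet and the truth labels.

    Group mean model (log2 scale, e = effect size, s = random sign):
    transgene genes shift the transgenic groups by ``e*s`` at both sites;
    environment genes shift the saline groups by ``e*s`` in both genotypes;
    interaction genes shift with opposite sign across their contrast pair
    (genotype pairing: DA by ``+e*s``, QA by ``-e*s``; environment pairing:
    DA by ``+e*s``, DB by ``-e*s``); null genes are flat.
    """
    rng = config.rng(0)
    truth = _allocate_classes(config, rng)
    n = config.n_genes

    base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
    sign_genotype = np.zeros(n, dtype=int)
    sign_site = np.zeros(n, dtype=int)
    pairing = np.array([""] * n, dtype=object)

    klass = truth["klass"].to_numpy()
    e = config.effect_size_log2
    log2mu = {g: base.copy() for g in GROUPS}

    idx_t = np.flatnonzero(klass == "transgene")
    s = rng.choice([-1, 1], size=len(idx_t))
    sign_genotype[idx_t] = s
    log2mu["DA"][idx_t] += e * s
    log2mu["QA"][idx_t] += e * s

    idx_e = np.flatnonzero(klass == "environment")
    s = rng.choice([-1, 1], size=len(idx_e))
    sign_site[idx_e] = s
    log2mu["DA"][idx_e] += e * s
    log2mu["DB"][idx_e] += e * s

    idx_i = np.flatnonzero(klass == "interaction")
    which = rng.random(len(idx_i)) < 0.5  # split between the two pairings
    s = rng.choice([-1, 1], size=len(idx_i))
    for j, (gi, is_geno, sg) in enumerate(zip(idx_i, which, s)):
        if is_geno:
            pairing[gi] = "genotype"
            sign_genotype[gi] = sg
            log2mu["DA"][gi] += e * sg
            log2mu["QA"][gi] -= e * sg
        else:
            pairing[gi] = "environment"
            sign_site[gi] = sg
            log2mu["DA"][gi] += e * sg
            log2mu["DB"][gi] -= e * sg

    truth["sign_genotype"] = sign_genotype
    truth["sign_site"] = sign_site
    truth["interaction_pairing"] = pairing
    mu = {g: np.exp2(v) for g, v in log2mu.items()}
    for g in GROUPS:
        truth[f"mu_{g}"] = mu[g]
    truth["planted_elements"] = ""

    # gene lengths log-uniform over realistic mRNA lengths
    lengths = np.exp(rng.uniform(math.log(500), math.log(5000), size=n)).round()

    # NB draws: var = mu + dispersion * mu^2
    alpha = config.dispersion
    columns = {}
    samples = []
    for g in GROUPS:
        for r in range(1, config.replicates_per_group + 1):
            sid = f"{g}_{r}"
            samples.append(sid)
            m = mu[g]
            if alpha < 1e-12:
                draws = rng.poisson(m)
            else:
                nb_n = 1.0 / alpha
                draws = rng.negative_binomial(nb_n, nb_n / (nb_n + m))
            columns[sid] = draws.astype(np.int64)

    counts = pd.DataFrame(columns, index=truth.index)
    cm = CountMatrix(counts=counts, lengths=pd.Series(lengths, index=truth.index))

    design = pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": ["transgenic" if s.split("_")[0][1] == "A" else "progenitor" for s in samples],
            "site": ["saline" if s[0] == "D" else "nonsaline" for s in samples],
            "replicate": [int(s.split("_")[1]) for s in samples],
            "group": [s.split("_")[0] for s in samples],
        }
    )
    return cm, validate_design(design), TruthLabels(truth)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _forbidden_strings(elements: Sequence[CisElementDef]) -> list[str]:
    seen: set[str] = set()
    for el in elements:
        for s in expand_iupac(el.pattern):
            seen.add(s)
            seen.add(reverse_complement(s))
    return sorted(seen)


def _screen_sequence(
    seq: np.ndarray, forbidden: re.Pattern, rng: np.random.Generator, max_rounds: int = 200
) -> np.ndarray:
    """Redraw windows containing forbidden strings until the sequence is clean."""
    bases = np.array(list("ACGT"))
    for _ in range(max_rounds):
        text = "".join(seq)
        m = forbidden.search(text)
        if m is None:
            return seq
        span = slice(m.start(), m.start() + len(m.group(1)))
        seq[span] = rng.choice(bases, size=span.stop - span.start)
    raise RuntimeError("failed to screen promoter background")


def simulate_promoters(
    labels: TruthLabels,
    config: SimConfig,
    elements: Sequence[CisElementDef] = DEFAULT_ELEMENTS,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with planted element cores; records the plant map.

    Returns (promoter sequences by gene, planting table with columns
    gene_id, element, start (1-based), strand, sequence) and fills the
    ``planted_elements`` truth column.  With background screening on
    (default) an exact scan of the promoter set recovers exactly the
    planted instances on either strand.
    """
    rng = config.rng(1)
    length = config.promoter_length
    bases = np.array(list("ACGT"))
    forbidden = re.compile(
        "(?=(" + "|".join(_forbidden_strings(elements)) + "))"
    )
    probs = {k: dict(v) for k, v in config.motif_plant_prob.items()}

    promoters: dict[str, str] = {}
    plant_rows: list[dict] = []
    planted_col: dict[str, str] = {}

    for gene_id, row in labels.table.iterrows():
        side = "null" if row["klass"] == "null" else "effect"
        chosen = [
            el for el in elements if rng.random() < probs[side].get(el.name, 0.0)
        ]
        total_core = sum(len(el.pattern) for el in chosen)
        if total_core > length:
            raise ValueError(
                f"promoter_length {length} too short for planted cores of {gene_id}"
            )

        for _attempt in range(50):
            seq = rng.choice(bases, size=length)
            if config.screen_background:
                seq = _screen_sequence(seq, forbidden, rng)
            # non-overlapping random offsets for the chosen cores
            placements: list[tuple[CisElementDef, int, str]] = []
            occupied: list[tuple[int, int]] = []
            ok = True
            for el in chosen:
                w = len(el.pattern)
                concrete = expand_iupac(el.pattern)
                inst = concrete[rng.integers(len(concrete))]
                for _try in range(200):
                    start = int(rng.integers(0, length - w + 1))
                    if all(start + w <= a or start >= b for a, b in occupied):
                        occupied.append((start, start + w))
                        placements.append((el, start, inst))
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            for el, start, inst in placements:
                seq[start : start + len(inst)] = list(inst)
            text = "".join(seq)
            if config.screen_background:
                # planting can collide with flanks; accept only if the scan
                # would recover exactly the planted instances
                found = {
                    (m.start()) for m in forbidden.finditer(text)
                }
                expected = {start for _, start, _ in placements}
                if found != expected:
                    continue
            else:
                if any(text[s : s + len(i)] != i for _, s, i in placements):
                    continue
            promoters[gene_id] = text
            for el, start, inst in placements:
                plant_rows.append(
                    {
                        "gene_id": gene_id,
                        "element": el.name,
                        "start": start + 1,
                        "strand": "+",
                        "sequence": inst,
                    }
                )
            planted_col[gene_id] = ",".join(sorted({el.name for el, _, _ in placements}))
            break
        else:
            raise RuntimeError(f"could not place promoter elements for {gene_id}")

    labels.table["planted_elements"] = [
        planted_col.get(g, "") for g in labels.table.index
    ]
    planting = pd.DataFrame(
        plant_rows, columns=["gene_id", "element", "start", "strand", "sequence"]
    )
    return promoters, planting


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

NAMESPACES = ("BP", "CC", "MF", "pathway")


def simulate_annotations(
    labels: TruthLabels, config: SimConfig
) -> tuple[AnnotationMap, dict[str, str]]:
    """Term annotations with planted class enrichment and a rooted hierarchy.

    Each namespace gets a root (level 0), two level-1 branches and four
    level-2 terms; annotated leaf terms hang one edge below a level-2 term.
    One leaf per effect class preferentially covers that class
    (``annotation_cover_fraction`` of its genes plus a 1% null leak);
    remaining leaves annotate random gene sets.  Returns the annotation map
    and the planted term -> class mapping.
    """
    rng = config.rng(2)
    genes = list(labels.table.index)
    n_leaves = config.n_terms
    # spread leaves over namespaces, BP-heavy as in real annotation sets
    weights = {"BP": 0.5, "CC": 0.15, "MF": 0.15, "pathway": 0.2}
    leaf_alloc = {ns: max(1, int(round(n_leaves * w))) for ns, w in weights.items()}

    edges: list[dict] = []
    meta: list[dict] = []
    terms: dict[str, set[str]] = {}
    leaf_ids: list[str] = []
    for ns in NAMESPACES:
        root = f"{ns}:root"
        meta.append({"term_id": root, "name": f"{ns} root", "namespace": ns})
        l1 = [f"{ns}:L1.{i}" for i in range(1, 3)]
        l2 = [f"{ns}:L2.{i}" for i in range(1, 5)]
        for t in l1:
            edges.append({"child": t, "parent": root})
            meta.append({"term_id": t, "name": t, "namespace": ns})
        for i, t in enumerate(l2):
            edges.append({"child": t, "parent": l1[i % len(l1)]})
            meta.append({"term_id": t, "name": t, "namespace": ns})
        for i in range(leaf_alloc[ns]):
            leaf = f"{ns}:T{i + 1:03d}"
            edges.append({"child": leaf, "parent": l2[i % len(l2)]})
            meta.append({"term_id": leaf, "name": leaf, "namespace": ns})
            leaf_ids.append(leaf)

    planted: dict[str, str] = {}
    null_genes = labels.genes_of("null")
    usable = [lf for lf in leaf_ids if lf.startswith("BP:")]
    for klass, leaf in zip(EFFECT_CLASSES, usable):
        members = sorted(labels.genes_of(klass))
        keep = rng.random(len(members)) < config.annotation_cover_fraction
        chosen = {g for g, k in zip(members, keep) if k}
        leak_pool = sorted(null_genes)
        leak = rng.random(len(leak_pool)) < 0.01
        chosen |= {g for g, k in zip(leak_pool, leak) if k}
        terms[leaf] = chosen
        planted[leaf] = klass

    for leaf in leaf_ids:
        if leaf in terms:
            continue
        size = int(rng.integers(5, max(6, config.n_genes // 20)))
        terms[leaf] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))

    ann = AnnotationMap(
        terms=terms, meta=pd.DataFrame(meta), edges=pd.DataFrame(edges)
    )
    return ann, planted


# ---------------------------------------------------------------------------
# qPCR panel
# ---------------------------------------------------------------------------

def simulate_qpcr(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    panel_genes: Sequence[str],
    reference_gene: str = "REF",
    noise_sd: float = 0.2,
    intercept: float = 40.0,
    rng: np.random.Generator | None = None,
    reference_expression: float = 100.0,
) -> QpcrPanel:
    """Ct values consistent with an expression matrix: Ct = a - log2(expr) + noise.

    ``expression`` holds per-sample expression (FPKM or expected means) for
    at least the panel genes.  The reference gene is taken from the matrix
    when present, otherwise synthesised with a constant (group-free)
    expression level.  Zero or negative expression in a panel gene is an
    error.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    samples = list(design["sample_id"])
    rows: list[dict] = []
    gene_rows = {}
    for g in panel_genes:
        if g not in expression.index:
            raise ValueError(f"panel gene {g!r} not in expression matrix")
        vals = expression.loc[g, samples]
        if (vals <= 0).any():
            raise ValueError(f"panel gene {g!r} has non-positive expression")
        gene_rows[g] = vals.to_numpy(dtype=float)
    if reference_gene in expression.index:
        ref_vals = expression.loc[reference_gene, samples].to_numpy(dtype=float)
        if (ref_vals <= 0).any():
            raise ValueError("reference gene has non-positive expression")
    else:
        ref_vals = np.full(len(samples), reference_expression)
    gene_rows[reference_gene] = ref_vals

    for g, vals in gene_rows.items():
        noise = rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
        ct = intercept - np.log2(vals) + noise
        for sid, c in zip(samples, np.atleast_1d(ct + np.zeros(len(samples)))):
            rows.append({"gene_id": g, "sample_id": sid, "ct": float(c)})
    return QpcrPanel(ct=pd.DataFrame(rows), reference_gene=reference_gene)


def true_mean_expression(truth: TruthLabels, design: pd.DataFrame) -> pd.DataFrame:
    """Expected (noise-free) expression per sample from the truth means."""
    cols = {
        row["sample_id"]: truth.table[f"mu_{row['group']}"]
        for _, row in design.iterrows()
    }
    return pd.DataFrame(cols, index=truth.table.index)


# ---------------------------------------------------------------------------
# bundle, recovery metric, writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    counts: CountMatrix
    design: pd.DataFrame
    truth: TruthLabels
    promoters: dict[str, str]
    planting: pd.DataFrame
    annotation: AnnotationMap
    planted_terms: dict[str, str]
    qpcr: QpcrPanel


def simulate_dataset(
    config: SimConfig,
    n_qpcr_genes: int = 20,
    qpcr_noise_sd: float = 0.2,
) -> SimulatedDataset:
    """Full dataset: counts, promoters, annotations and a qPCR panel.

    The qPCR panel samples effect-class genes (falling back to null genes if
    too few) and simulates Ct from the expected group means plus noise.
    """
    counts, design, truth = simulate_counts(config)
    promoters, planting = simulate_promoters(truth, config)
    annotation, planted_terms = simulate_annotations(truth, config)

    rng = config.rng(3)
    effect_genes = sorted(set(truth.table.index[truth.table["klass"] != "null"]))
    null_genes = sorted(set(truth.table.index) - set(effect_genes))
    if len(effect_genes) >= n_qpcr_genes:
        panel = sorted(rng.choice(effect_genes, size=n_qpcr_genes, replace=False))
    else:  # all effect genes, topped up with null genes
        fill = rng.choice(
            null_genes, size=min(n_qpcr_genes - len(effect_genes), len(null_genes)),
            replace=False,
        )
        panel = sorted(effect_genes + list(fill))
    expr = true_mean_expression(truth, design)
    qpcr = simulate_qpcr(
        expr, design, panel, reference_gene="REF", noise_sd=qpcr_noise_sd, rng=rng
    )
    return SimulatedDataset(
        config=config,
        counts=counts,
        design=design,
        truth=truth,
        promoters=promoters,
        planting=planting,
        annotation=annotation,
        planted_terms=planted_terms,
        qpcr=qpcr,
    )


def evaluate_recovery(classification, truth: TruthLabels) -> dict:
    """Recovery of planted classes by the effect attribution.

    Returns per-class recovery fractions (planted genes attributed to the
    correct class, interactions matched to their pairing) and the null
    contamination (null genes attributed to any class).
    """
    table = classification.table
    out: dict = {}
    planted_t = truth.genes_of("transgene")
    planted_e = truth.genes_of("environment")
    got_t = set(table.loc[table["klass"] == "transgene", "gene_id"])
    got_e = set(table.loc[table["klass"] == "environment", "gene_id"])
    out["transgene_recovery"] = len(planted_t & got_t) / len(planted_t) if planted_t else np.nan
    out["environment_recovery"] = len(planted_e & got_e) / len(planted_e) if planted_e else np.nan

    planted_ig = truth.genes_of("interaction", pairing="genotype")
    planted_ie = truth.genes_of("interaction", pairing="environment")
    got_ig = set(table.loc[table["klass"] == "interaction_genotype", "gene_id"])
    got_ie = set(table.loc[table["klass"] == "interaction_environment", "gene_id"])
    n_planted_i = len(planted_ig) + len(planted_ie)
    n_hit = len(planted_ig & got_ig) + len(planted_ie & got_ie)
    out["interaction_recovery"] = n_hit / n_planted_i if n_planted_i else np.nan

    null_genes = truth.genes_of("null")
    attributed = set(table["gene_id"])
    out["null_contamination"] = (
        len(null_genes & attributed) / len(null_genes) if null_genes else np.nan
    )
    return out


def write_dataset(dataset: SimulatedDataset, outdir, write_genome: bool = False) -> dict:
    """Write the dataset as the flat-file bundle the pipeline reads.

    counts.tsv, samples.tsv, promoters.fasta, genes.tsv, annotations.tsv,
    ontology_edges.tsv, qpcr.tsv, truth.tsv (and optionally genome.fasta
    with per-gene contigs embedding each promoter, half the genes on the
    minus strand, for exercising coordinate-based promoter extraction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["counts"] = outdir / "counts.tsv"
    dataset.counts.to_tsv(paths["counts"])
    paths["samples"] = outdir / "samples.tsv"
    dataset.design.reset_index(drop=True).to_csv(paths["samples"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    dataset.truth.to_tsv(paths["truth"])

    paths["promoters"] = outdir / "promoters.fasta"
    with open(paths["promoters"], "w") as fh:
        for gene_id, seq in dataset.promoters.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    # gene models on per-gene contigs; with a genome these exercise the
    # strand-aware promoter extraction
    rng = dataset.config.rng(4)
    models = []
    genome: dict[str, str] = {}
    bases = "ACGT"
    for i, (gene_id, seq) in enumerate(dataset.promoters.items()):
        strand = "+" if i % 2 == 0 else "-"
        body = "".join(rng.choice(list(bases), size=50))
        contig = f"contig_{gene_id}"
        if strand == "+":
            genome[contig] = seq + body
            tss = len(seq) + 1
        else:
            genome[contig] = body + reverse_complement(seq)
            tss = len(body)
        models.append(
            {"gene_id": gene_id, "contig": contig, "strand": strand, "tss": tss}
        )
    paths["genes"] = outdir / "genes.tsv"
    pd.DataFrame(models).to_csv(paths["genes"], sep="\t", index=False)
    if write_genome:
        paths["genome"] = outdir / "genome.fasta"
        with open(paths["genome"], "w") as fh:
            for contig, seq in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    ann_rows = []
    for term_id, term_genes in dataset.annotation.terms.items():
        ns = dataset.annotation.namespace_of(term_id)
        for g in sorted(term_genes):
            ann_rows.append({"term_id": term_id, "namespace": ns, "gene_id": g})
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)
    paths["ontology_edges"] = outdir / "ontology_edges.tsv"
    dataset.annotation.edges.to_csv(paths["ontology_edges"], sep="\t", index=False)

    paths["qpcr"] = outdir / "qpcr.tsv"
    dataset.qpcr.to_tsv(paths["qpcr"])
    return paths
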