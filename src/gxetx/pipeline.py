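"""End-to-end pipeline: simulate or load a dataset, run every analysis
stage and write the report bundle.

Stages run in the order quantification -> DEG calling (four contrasts) ->
effect attribution -> promoter cis-element scan -> term enrichment ->
qPCR concordance.  All tables are TSV with a header line; a JSON manifest
records the configuration hash, package version, seed and collected
warnings, which suffices to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .degtest import summarize_contrast
from .enrich import AnnotationMap, hypergeometric_enrichment, level2_classify
from .expression import CountMatrix, read_design
from .model import TwoFactorTranscriptomeModel
from .motifs import DEFAULT_ELEMENTS, CisElementDef, scan_promoters
from .qpcr import QpcrPanel, concordance, delta_delta_ct
from .simulate import SimConfig, TruthLabels, evaluate_recovery, simulate_dataset, write_dataset

log = logging.getLogger("gxetx")

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-loadable)."""

    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    promoters: str = "promoters.fasta"
    annotations: str = "annotations.tsv"
    ontology_edges: str = "ontology_edges.tsv"
    qpcr: str = "qpcr.tsv"
    qpcr_reference: str = "REF"
    truth: str | None = None

    fpkm_threshold: float = 1.0
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    test: str = "exact-binomial"
    adjust: str = "bh"
    elements: dict = field(
        default_factory=lambda: {el.name: el.pattern for el in DEFAULT_ELEMENTS}
    )
    scan_both_strands: bool = True
    enrichment_background: str = "expressed"  # or "annotation"
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("fpkm_threshold", self.fpkm_threshold),
            ("lfc_threshold", self.lfc_threshold),
            ("alpha", self.alpha),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.enrichment_background not in ("expressed", "annotation"):
            raise ValueError("enrichment_background must be 'expressed' or 'annotation'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def simulate_inputs(config: SimConfig, outdir, write_genome: bool = False) -> dict:
    """Generate and write a synthetic dataset bundle; returns file paths."""
    dataset = simulate_dataset(config)
    return write_dataset(dataset, outdir, write_genome=write_genome)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns key results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[str] = []

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            results = _run_stages(config, outdir)
        collected_warnings = [str(w.message) for w in caught]
    except Exception as exc:  # annotate which stage failed
        stage = getattr(exc, "_stage", "unknown")
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "warnings": collected_warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                exc._stage = name
                raise

        return wrapper

    return deco


def _run_stages(config: RunConfig, outdir: Path) -> dict:
    results: dict = {}

    counts = CountMatrix.read_tsv(config.counts)
    design = read_design(config.samples)

    model = TwoFactorTranscriptomeModel(
        counts,
        design,
        fpkm_threshold=config.fpkm_threshold,
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        test=config.test,
        adjust=config.adjust,
    )
    fit = _stage("quantify+deg+attribute")(model.fit)()
    results["fit"] = fit

    # --- quantification outputs
    fit.fpkm.values.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id")
    fit.replicate_correlation.to_csv(outdir / "correlation.tsv", sep="\t", index_label="sample_id")
    fit.venn.to_frame().to_csv(outdir / "venn.tsv", sep="\t", index=False)

    # --- contrasts
    summaries = fit.contrast_summaries()
    summaries.to_csv(outdir / "contrast_summary.tsv", sep="\t", index=False)
    for cid, res in fit.contrast_results.items():
        degs = fit.deg_sets[cid]
        directions = pd.Series(
            {g: ("up" if d == 1 else "down") for g, d in degs.directions.items()}
        )
        res.to_tsv(outdir / f"contrast_{cid}.tsv", directions=directions)

    # --- attribution
    fit.classification.to_tsv(outdir / "attribution.tsv", lfc=fit.log2fc)
    results["attribution_counts"] = fit.attribution_counts()

    # --- promoter scan of genotype-contrast DEGs
    scan = _stage("scan")(_scan_stage)(config, fit, outdir)
    results["cis_summary"] = scan

    # --- enrichment per contrast
    results["enrichment"] = _stage("enrich")(_enrich_stage)(config, fit, outdir)

    # --- qPCR concordance
    results["concordance"] = _stage("qpcr")(_qpcr_stage)(config, fit, outdir)

    # --- recovery against truth, when provided
    if config.truth:
        truth = TruthLabels.read_tsv(config.truth)
        recovery = evaluate_recovery(fit.classification, truth)
        results["recovery"] = recovery
        pd.DataFrame([recovery]).to_csv(outdir / "recovery.tsv", sep="\t", index=False)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(fit.summary() + "\n")
    return results


def _scan_stage(config: RunConfig, fit, outdir: Path) -> pd.DataFrame:
    promoters = _read_fasta(config.promoters)
    elements = [CisElementDef(n, p) for n, p in config.elements.items()]
    scans = scan_promoters(promoters, elements, both_strands=config.scan_both_strands)
    scans.attrs["scanned_gene_ids"] = list(promoters)
    scans.to_csv(outdir / "scan.tsv", sep="\t", index=False)

    from .motifs import summarize_cis_elements

    site_of = {cid: cid.split("-vs-")[0][0] for cid in fit.deg_sets}
    frames = []
    for cid, degs in fit.deg_sets.items():
        pair = fit.classification.contrast_pairs["genotype"]
        if cid not in pair:
            continue  # the cis summary targets genotype-contrast DEGs
        label = "saline" if site_of[cid] == "D" else "nonsaline"
        frames.append(summarize_cis_elements(degs, scans, elements, label=label))
    summary = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    summary.to_csv(outdir / "cis_summary.tsv", sep="\t", index=False)
    return summary


def _enrich_stage(config: RunConfig, fit, outdir: Path) -> dict:
    annotation = AnnotationMap.read_tsv(config.annotations, config.ontology_edges)
    all_annotated = set().union(*annotation.terms.values())
    out = {}
    for cid, degs in fit.deg_sets.items():
        if not len(degs):
            continue
        table = fit.contrast_results[cid].table
        if config.enrichment_background == "expressed":
            background = set(table.index[table["coexpressed"]]) | degs.genes
        else:
            background = all_annotated | degs.genes
        enr = hypergeometric_enrichment(degs.genes, background, annotation, config.alpha)
        enr.to_csv(outdir / f"enrichment_{cid}.tsv", sep="\t", index=False)
        level2 = level2_classify({"up": degs.up, "down": degs.down}, annotation)
        level2.to_csv(outdir / f"level2_{cid}.tsv", sep="\t", index=False)
        out[cid] = enr
    return out


def _qpcr_stage(config: RunConfig, fit, outdir: Path) -> dict:
    panel = QpcrPanel.read_tsv(config.qpcr, reference_gene=config.qpcr_reference)
    design = fit.model.design
    rel_rows = []
    qpcr_lfc: dict[tuple[str, str], float] = {}
    for cid, (ga, gb) in fit.model.contrasts.items():
        for gene in panel.target_genes:
            try:
                rq = delta_delta_ct(panel, design, gene, ga, gb)
            except ValueError:
                continue
            rel_rows.append({"contrast_id": cid, **rq._asdict()})
            qpcr_lfc[(cid, gene)] = rq.log2_fold_change
    rel = pd.DataFrame(rel_rows)
    rel.to_csv(outdir / "relquant.tsv", sep="\t", index=False)

    pairs = []
    for (cid, gene), q in qpcr_lfc.items():
        r = fit.contrast_results[cid].table["log2fc"].get(gene)
        if r is not None and pd.notna(r):
            pairs.append({"contrast_id": cid, "gene_id": gene, "qpcr": q, "rnaseq": r})
    pairs = pd.DataFrame(pairs)
    conc = concordance(pairs["qpcr"], pairs["rnaseq"]) if len(pairs) >= 3 else None
    out_rows = []
    if conc is not None:
        out_rows.append({"scope": "all", **conc._asdict()})
    pd.DataFrame(out_rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    pairs.to_csv(outdir / "concordance_pairs.tsv", sep="\t", index=False)
    return {"concordance": conc, "pairs": pairs}
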