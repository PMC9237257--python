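"""Ground-truth structure of the synthetic 2x2 factorial generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxetx.enrich import hypergeometric_enrichment
from gxetx.simulate import (
    GROUPS,
    SimConfig,
    simulate_annotations,
    simulate_counts,
    simulate_dataset,
    simulate_promoters,
)


class TestConfig:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(effect_fractions={"null": 0.5, "transgene": 0.1})

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimConfig(dispersion=0.0)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            SimConfig(motif_plant_prob={"effect": {"DREB": 1.5}})

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            SimConfig(replicates_per_group=1)


class TestCounts:
    def test_all_null_config_yields_only_null_labels(self):
        cfg = SimConfig(n_genes=100, effect_fractions={"null": 1.0}, seed=3)
        _, _, truth = simulate_counts(cfg)
        assert set(truth.table["klass"]) == {"null"}

    def test_deterministic_class_allocation(self):
        cfg = SimConfig(
            n_genes=1000,
            effect_fractions={"null": 0.99, "transgene": 0.01},
            seed=9,
        )
        _, _, truth = simulate_counts(cfg)
        assert (truth.table["klass"] == "transgene").sum() == 10

    def test_matrix_shape_and_dtype(self):
        cfg = SimConfig(n_genes=50, replicates_per_group=4, seed=0)
        cm, design, _ = simulate_counts(cfg)
        assert cm.counts.shape == (50, 16)
        assert (cm.counts.to_numpy() >= 0).all()
        assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)
        assert len(design) == 16
        assert set(design["group"]) == set(GROUPS)

    def test_identical_seed_identical_dataset(self):
        a = simulate_counts(SimConfig(n_genes=80, seed=13))
        b = simulate_counts(SimConfig(n_genes=80, seed=13))
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[2].table, b[2].table)

    def test_planted_ratio_approaches_effect_size(self):
        """At tiny dispersion the group mean-count ratio of a transgene gene
        approaches 2^effect (Monte-Carlo over >= 1e4 draws)."""
        cfg = SimConfig(
            n_genes=40,
            replicates_per_group=250,  # 40 x 250 columns ~ 1e4 draws per group
            effect_fractions={"null": 0.5, "transgene": 0.5},
            effect_size_log2=2.0,
            dispersion=1e-13,
            seed=17,
        )
        cm, design, truth = simulate_counts(cfg)
        t = truth.table
        gene = t.index[(t["klass"] == "transgene") & (t["sign_genotype"] == 1)][0]
        da = cm.counts.loc[gene, [s for s in cm.sample_ids if s.startswith("DA")]]
        db = cm.counts.loc[gene, [s for s in cm.sample_ids if s.startswith("DB")]]
        assert da.mean() / db.mean() == pytest.approx(4.0, rel=0.05)

    def test_all_null_group_means_equal_in_expectation(self):
        cfg = SimConfig(
            n_genes=30, replicates_per_group=300,
            effect_fractions={"null": 1.0}, seed=23,
        )
        cm, design, truth = simulate_counts(cfg)
        for g in truth.table.index[:5]:
            means = [
                cm.counts.loc[g, [s for s in cm.sample_ids if s.startswith(grp)]].mean()
                for grp in GROUPS
            ]
            assert max(means) / max(min(means), 1e-9) < 1.25

    def test_nb_dispersion_inflates_variance(self):
        cfg = SimConfig(
            n_genes=60, replicates_per_group=300,
            effect_fractions={"null": 1.0}, dispersion=0.2, seed=29,
            baseline_sd_log2=0.0,
        )
        cm, _, _ = simulate_counts(cfg)
        da = cm.counts[[s for s in cm.sample_ids if s.startswith("DA")]].to_numpy()
        m = da.mean(axis=1)
        v = da.var(axis=1, ddof=1)
        # pooled over genes, variance tracks mu + 0.2 mu^2, far above Poisson
        assert np.median(v / m) > 2.0


class TestPromoters:
    def test_no_planting_and_screening_yields_zero_hits(self):
        from gxetx.motifs import scan_promoters

        cfg = SimConfig(
            n_genes=40, promoter_length=500,
            motif_plant_prob={"effect": {}, "null": {}}, seed=31,
        )
        _, _, truth = simulate_counts(cfg)
        promoters, planting = simulate_promoters(truth, cfg)
        assert len(planting) == 0
        assert len(scan_promoters(promoters)) == 0

    def test_planted_core_at_recorded_offset(self, small_dataset):
        planting = small_dataset.planting
        dreb = planting[planting["element"] == "DREB"]
        assert len(dreb) > 0
        for row in dreb.head(20).itertuples():
            seq = small_dataset.promoters[row.gene_id]
            assert seq[row.start - 1 : row.start - 1 + 5] == "CCGAC"

    def test_truth_column_matches_planting_table(self, small_dataset):
        planting = small_dataset.planting
        by_gene = planting.groupby("gene_id")["element"].agg(
            lambda s: ",".join(sorted(set(s)))
        )
        truth_col = small_dataset.truth.table["planted_elements"]
        for gene, elements in by_gene.items():
            assert truth_col[gene] == elements
        unplanted = set(truth_col.index) - set(by_gene.index)
        assert (truth_col[list(unplanted)] == "").all()

    def test_plant_fraction_within_binomial_ci(self):
        """With DREB plant probability 0.4 over 1,000 genes the planted
        fraction lands inside the binomial 99% CI."""
        cfg = SimConfig(
            n_genes=1000, promoter_length=120,
            effect_fractions={"null": 1.0},
            motif_plant_prob={"effect": {}, "null": {"DREB": 0.4}},
            seed=37,
        )
        _, _, truth = simulate_counts(cfg)
        _, planting = simulate_promoters(truth, cfg)
        n_planted = planting["gene_id"].nunique()
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.4)
        assert lo <= n_planted <= hi

    def test_promoter_too_short_rejected(self):
        cfg = SimConfig(
            n_genes=5, promoter_length=4,
            effect_fractions={"null": 1.0},
            motif_plant_prob={"effect": {}, "null": {"ABRE": 1.0}},
            seed=41,
        )
        _, _, truth = simulate_counts(cfg)
        with pytest.raises(ValueError, match="too short"):
            simulate_promoters(truth, cfg)


class TestAnnotations:
    def test_planted_term_matches_closed_form_tail(self):
        """A term covering all transgene genes and nothing else: testing the
        perfect DEG list gives the closed-form hypergeometric tail."""
        import math

        cfg = SimConfig(
            n_genes=200,
            effect_fractions={"null": 0.9, "transgene": 0.1},
            annotation_cover_fraction=1.0,
            seed=43,
        )
        _, _, truth = simulate_counts(cfg)
        ann, planted = simulate_annotations(truth, cfg)
        term = next(t for t, k in planted.items() if k == "transgene")
        # restrict the planted term to exactly the transgene genes
        transgene = truth.genes_of("transgene")
        ann.terms[term] = set(transgene)
        background = list(truth.table.index)
        res = hypergeometric_enrichment(sorted(transgene), background, ann)
        row = res[res["term_id"] == term].iloc[0]
        K = n = k = len(transgene)
        expected = math.comb(200 - K, n - k) * math.comb(K, k) / math.comb(200, n)
        assert row["p"] == pytest.approx(expected, rel=1e-9)
        assert row["k"] == k and row["K"] == K

    def test_every_term_reaches_a_root(self, small_dataset):
        import networkx as nx

        edges = small_dataset.annotation.edges
        graph = nx.DiGraph([(r.parent, r.child) for r in edges.itertuples()])
        roots = {t for t in graph.nodes if graph.in_degree(t) == 0}
        for term in small_dataset.annotation.terms:
            assert any(nx.has_path(graph, r, term) for r in roots)

    def test_planted_terms_enriched_in_their_class(self, small_dataset):
        truth = small_dataset.truth
        ann = small_dataset.annotation
        background = list(truth.table.index)
        for term, klass in small_dataset.planted_terms.items():
            genes = truth.genes_of(klass)
            if not genes:
                continue
            res = hypergeometric_enrichment(sorted(genes), background, ann)
            row = res[res["term_id"] == term].iloc[0]
            assert row["p"] < 1e-4


class TestDatasetBundle:
    def test_write_and_reload_round_trip(self, small_dataset, tmp_path):
        from gxetx.expression import CountMatrix, read_design
        from gxetx.simulate import TruthLabels, write_dataset

        paths = write_dataset(small_dataset, tmp_path, write_genome=True)
        cm = CountMatrix.read_tsv(paths["counts"])
        pd.testing.assert_frame_equal(cm.counts, small_dataset.counts.counts)
        design = read_design(paths["samples"])
        assert list(design["sample_id"]) == list(small_dataset.design["sample_id"])
        truth = TruthLabels.read_tsv(paths["truth"])
        assert (truth.table["klass"] == small_dataset.truth.table["klass"]).all()

    def test_genome_models_reproduce_promoters(self, small_dataset, tmp_path):
        """Extracting promoters from the generated contigs with the recorded
        strand-aware TSS reproduces the promoter FASTA."""
        from Bio import SeqIO

        from gxetx.motifs import GeneModel, extract_promoter
        from gxetx.simulate import write_dataset

        paths = write_dataset(small_dataset, tmp_path, write_genome=True)
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["genome"]), "fasta")}
        models = pd.read_csv(paths["genes"], sep="\t")
        L = small_dataset.config.promoter_length
        for row in models.head(30).itertuples():
            model = GeneModel(row.gene_id, row.contig, row.strand, row.tss)
            assert extract_promoter(model, genome, L) == small_dataset.promoters[row.gene_id]
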