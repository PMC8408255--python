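"""Generator contracts: determinism, file validity, truth/emission consistency,
and the statistical properties of the planted signals."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from homoevol.simdata import (SimConfig, SimConfigError, jc_mutate, mutate_cds,
                              random_cds, random_dna, simulate_counts,
                              simulate_dataset, simulate_ltr_elements,
                              simulate_sv_table)
from homoevol.synteny import parse_annotation


class TestConfigValidation:
    def test_bias_fractions_must_sum_to_one(self):
        with pytest.raises(SimConfigError, match="sum to 1"):
            SimConfig(bias_fractions=(0.5, 0.2, 0.2, 0.2))

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(SimConfigError, match="mu"):
            SimConfig(mu=0.0)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(SimConfigError, match="dispersion"):
            SimConfig(nb_dispersion=-1.0)

    def test_effect_sizes_must_respect_category_bands(self):
        with pytest.raises(SimConfigError, match="lower"):
            SimConfig(bias_log2_effects=(0.0, 1.5, 2.0, 3.5))
        with pytest.raises(SimConfigError, match="higher"):
            SimConfig(bias_log2_effects=(0.0, 0.8, 2.0, 2.5))

    def test_too_short_chromosome_names_the_constraint(self):
        with pytest.raises(SimConfigError, match="chromosome too short"):
            SimConfig(chrom_length=50_000, genes_per_chrom=200)

    def test_default_design_has_thirty_samples(self):
        cfg = SimConfig()
        assert cfg.n_samples == 30
        assert len(cfg.sample_table()) == 30


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = SimConfig(n_chrom_pairs=1, genes_per_chrom=40,
                        chrom_length=300_000, ltr_class_counts=(3, 4, 2),
                        seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, str(d1))
        simulate_dataset(cfg, str(d2))
        files = sorted(p.name for p in d1.iterdir())
        assert files
        for name in files:
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_different_seeds_differ(self):
        c1 = SimConfig(n_chrom_pairs=1, genes_per_chrom=40,
                       chrom_length=300_000, seed=1)
        c2 = SimConfig(n_chrom_pairs=1, genes_per_chrom=40,
                       chrom_length=300_000, seed=2)
        _, t1 = simulate_dataset(c1, None)
        _, t2 = simulate_dataset(c2, None)
        assert t1.gene_base_mean != t2.gene_base_mean


class TestEmittedFiles:
    def test_gff3_parses_and_matches_truth(self, small_bundle):
        bundle, truth = small_bundle
        genes, ranks = parse_annotation(str(bundle.gff3))
        parsed_ids = {g.gene_id for g in genes}
        assert set(truth.gene_info) == parsed_ids
        for g in genes:
            info = truth.gene_info[g.gene_id]
            assert (g.start, g.end) == (info["start"], info["end"])
            assert g.exon_count == len(info["exons"])

    def test_intervals_inside_chromosome_bounds(self, small_bundle, small_config):
        bundle, truth = small_bundle
        te = pd.read_csv(bundle.te_bed, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score",
                                "strand"])
        assert (te["start"] >= 0).all()
        assert (te["end"] <= small_config.chrom_length).all()
        assert (te["start"] < te["end"]).all()
        sv = pd.read_csv(bundle.sv_tsv, sep="\t")
        assert (sv["start"] >= 0).all()
        assert (sv["end"] <= small_config.chrom_length).all()

    def test_counts_table_shape_and_design(self, small_bundle, small_config):
        bundle, truth = small_bundle
        counts = pd.read_csv(bundle.counts_tsv, sep="\t", index_col=0)
        assert counts.shape == (len(truth.gene_info), 30)
        design = pd.read_csv(bundle.design_tsv, sep="\t", index_col=0)
        assert list(design.index) == list(counts.columns)
        assert set(design["tissue"]) == set(small_config.tissues)
        assert set(design["variety"]) == set(small_config.varieties)

    def test_truth_json_resolves_against_files(self, small_bundle):
        bundle, truth = small_bundle
        payload = json.loads(bundle.truth_json.read_text())
        assert payload["version"] == "1"
        assert payload["config"]["seed"] == truth.config.seed
        emitted_genes = set(payload["gene_info"])
        for rec in payload["homoeolog_pairs"]:
            assert rec["gene_a"] in emitted_genes
            assert rec["gene_b"] in emitted_genes
        for g in payload["te_suppressed_genes"]:
            assert g in emitted_genes

    def test_genome_fasta_contains_cds_with_planted_divergence(self, small_bundle,
                                                               small_config):
        from homoevol.pipeline import extract_cds, _read_fasta
        from homoevol.seqevol import align_cds_pair, kaks_ng86

        bundle, truth = small_bundle
        genome = _read_fasta(bundle.genome_fasta)
        ks_vals = []
        for p in truth.homoeolog_pairs[:40]:
            ca = extract_cds(genome, truth.gene_info[p.gene_a])
            cb = extract_cds(genome, truth.gene_info[p.gene_b])
            res = kaks_ng86(align_cds_pair(ca, cb))
            if res.ks is not None:
                ks_vals.append(res.ks)
        # planted synonymous divergence near the configured Ks scale
        assert np.median(ks_vals) == pytest.approx(small_config.ks_mean, rel=0.5)


class TestPlantedCategories:
    def test_category_counts_within_three_binomial_sds(self):
        cfg = SimConfig(n_chrom_pairs=4, genes_per_chrom=313,
                        chrom_length=1_500_000,
                        bias_fractions=(0.55, 0.20, 0.15, 0.10), seed=5)
        _, truth = simulate_dataset(cfg, None)
        cats = [p.category for p in truth.homoeolog_pairs]
        n = len(cats)
        assert n >= 900
        for frac, cat in zip(cfg.bias_fractions,
                             ("no_difference", "lower", "medium", "higher")):
            got = sum(c == cat for c in cats)
            assert abs(got - n * frac) <= 3 * np.sqrt(n * frac * (1 - frac))


class TestCounts:
    def test_null_pair_mean_ratio_converges_to_one(self):
        """log2FC = 0 pairs: empirical mean ratio within 2% over many draws."""
        rng = np.random.default_rng(0)
        mu, alpha, n = 200.0, 0.05, 10_000
        r = 1 / alpha
        a = rng.negative_binomial(r, r / (r + mu), n)
        b = rng.negative_binomial(r, r / (r + mu), n)
        assert a.mean() / b.mean() == pytest.approx(1.0, abs=0.02)

    def test_te_suppression_halves_the_mean(self, small_config, small_truth,
                                            small_counts):
        """Re-simulating with suppression removed doubles suppressed genes."""
        import copy

        sup = sorted(small_truth.te_suppressed_genes)
        unsup_truth = copy.copy(small_truth)
        unsup_truth.te_suppressed_genes = set()
        unsup_counts = simulate_counts(unsup_truth, small_config)
        ratio = (small_counts.loc[sup].to_numpy().mean()
                 / unsup_counts.loc[sup].to_numpy().mean())
        assert ratio == pytest.approx(small_config.te_suppression_factor,
                                      rel=0.05)

    def test_nonpositive_dispersion_is_an_error(self, small_truth, small_config):
        import dataclasses
        with pytest.raises(SimConfigError):
            bad = dataclasses.replace(small_config, nb_dispersion=0.0)

    def test_all_zero_means_disallowed(self, small_truth, small_config):
        import copy
        truth = copy.copy(small_truth)
        truth.gene_base_mean = {g: 0.0 for g in small_truth.gene_base_mean}
        with pytest.raises(SimConfigError, match="zero"):
            simulate_counts(truth, small_config)


class TestLTRSimulation:
    def test_age_zero_gives_identical_ltrs(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 500)
        assert jc_mutate(rng, seq, 0.0) == seq

    def test_expected_raw_divergence_at_one_myr(self):
        """2 mu T = 0.026 expected substitutions/site at T = 1 Myr."""
        rng = np.random.default_rng(2)
        mu, T = 1.3e-8, 1.0e6
        d = 2 * mu * T
        p_expected = 0.75 * (1 - np.exp(-4 * d / 3))
        diffs = []
        for _ in range(500):
            s = random_dna(rng, 400)
            m = jc_mutate(rng, s, d)
            diffs.append(sum(a != b for a, b in zip(s, m)) / len(s))
        assert np.mean(diffs) == pytest.approx(p_expected, rel=0.10)
        assert d == pytest.approx(0.026)

    def test_requested_class_mix_is_emitted_exactly(self):
        cfg = SimConfig(ltr_class_counts=(10, 30, 10), seed=3)
        cands, recs, _ = simulate_ltr_elements(cfg)
        classes = [r["structural_class"] for r in recs]
        assert classes.count("intact") == 10
        assert classes.count("solo") == 30
        assert classes.count("truncated") == 10
        assert len(cands) == 50

    def test_solo_elements_lack_gagpol_and_3ltr(self):
        cfg = SimConfig(ltr_class_counts=(2, 3, 2), seed=4)
        cands, recs, gagpol = simulate_ltr_elements(cfg)
        for cand, rec in zip(cands, recs):
            if rec["structural_class"] == "solo":
                assert cand.ltr3_seq is None


class TestSVSimulation:
    def test_unknown_sv_type_is_an_error(self):
        with pytest.raises(SimConfigError, match="unknown SV type"):
            cfg = SimConfig(sv_counts_per_type={"deletion": 5})
            _, truth = simulate_dataset(
                SimConfig(n_chrom_pairs=1, genes_per_chrom=40,
                          chrom_length=300_000), None)
            simulate_sv_table(truth, cfg, pd.DataFrame(
                {"chrom": [], "start": [], "end": [], "name": []}))

    def test_type_counts_honored_exactly(self, small_truth, small_config):
        sv = pd.DataFrame(small_truth.sv_truth)
        got = sv["type"].value_counts().to_dict()
        assert got == small_config.sv_counts_per_type

    def test_extreme_enrichment_puts_all_breakpoints_near_tes(self):
        import dataclasses
        cfg = dataclasses.replace(
            SimConfig(n_chrom_pairs=1, genes_per_chrom=40, chrom_length=300_000,
                      seed=6),
            sv_breakpoint_te_enrichment=1e6)
        _, truth = simulate_dataset(cfg, None)
        assert all(rec["te_adjacent"] for rec in truth.sv_truth)

    def test_uniform_placement_matches_coverage_expectation(self):
        """With enrichment 1.0 the near-TE fraction follows TE coverage."""
        import dataclasses
        cfg = dataclasses.replace(
            SimConfig(n_chrom_pairs=2, genes_per_chrom=60, chrom_length=500_000,
                      seed=7, te_suppression_fraction=0.0,
                      sv_counts_per_type={"duplication": 250,
                                          "inversion": 250}),
            sv_breakpoint_te_enrichment=1.0)
        _, truth = simulate_dataset(cfg, None)
        # geometric expectation: fraction of positions within 2 kb of a TE
        from homoevol.simdata import _simulate_tes, _layout_genomes, _assign_modules
        chrom_pairs, genes, pairs, biased = _layout_genomes(cfg)
        te_bed, _ = _simulate_tes(cfg, genes, biased, pairs)
        L = cfg.chrom_length
        covered = 0
        for chrom, sub in te_bed.groupby("chrom"):
            mask = np.zeros(L, dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                mask[max(s - 2000, 0):min(e + 2000, L)] = True
            covered += mask.sum()
        p_near = covered / (4 * L)
        near = np.mean([rec["te_adjacent"] for rec in truth.sv_truth])
        # each SV contributes two breakpoints; P(adjacent) = 1-(1-p)^2 approx
        p_adj = 1 - (1 - p_near) ** 2
        sd = np.sqrt(p_adj * (1 - p_adj) / len(truth.sv_truth))
        assert abs(near - p_adj) <= 4 * sd + 0.02
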