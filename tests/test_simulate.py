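"""Determinism and planted-truth properties of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from hybridvigor import phenotypes as pheno
from hybridvigor.simulate import (
    CROSSES,
    GROUPS,
    PARENTS,
    ExprSimConfig,
    GenomeSimConfig,
    NetworkSimConfig,
    PhenoSimConfig,
    simulate_annotation,
    simulate_coexpression,
    simulate_counts,
    simulate_phenotypes,
)


class TestDeterminism:
    def test_same_seed_identical_different_seed_not(self):
        a, _ = simulate_phenotypes(PhenoSimConfig(seed=7, n_per_group=10))
        b, _ = simulate_phenotypes(PhenoSimConfig(seed=7, n_per_group=10))
        c, _ = simulate_phenotypes(PhenoSimConfig(seed=8, n_per_group=10))
        assert a.equals(b)
        assert not a.equals(c)

    def test_counts_byte_identical_across_calls(self):
        cfg = ExprSimConfig(seed=3, n_genes=50)
        c1, m1, t1 = simulate_counts(cfg)
        c2, m2, t2 = simulate_counts(ExprSimConfig(seed=3, n_genes=50))
        assert c1.equals(c2) and m1.equals(m2) and t1.equals(t2)

    def test_coexpression_and_annotation_reproducible(self):
        e1, tr1, l1 = simulate_coexpression(NetworkSimConfig(seed=4))
        e2, tr2, l2 = simulate_coexpression(NetworkSimConfig(seed=4))
        assert e1.equals(e2) and tr1.equals(tr2) and l1.equals(l2)
        g1, ln1, p1 = simulate_annotation(GenomeSimConfig(seed=4))
        g2, ln2, p2 = simulate_annotation(GenomeSimConfig(seed=4))
        assert g1.equals(g2) and ln1.equals(ln2) and p1.equals(p2)

    def test_truth_bins_do_not_depend_on_seed(self):
        assignment = {"gene_00001": 3, "gene_00002": 7}
        t1 = simulate_counts(ExprSimConfig(seed=1, n_genes=5, bin_assignment=assignment))[2]
        t2 = simulate_counts(ExprSimConfig(seed=9, n_genes=5, bin_assignment=assignment))[2]
        assert t1.equals(t2)


class TestPhenotypes:
    def test_zero_noise_zero_sd_means_are_exact(self):
        cfg = PhenoSimConfig(seed=0, n_per_group=20, noise_sd=0.0)
        for g in GROUPS:
            cfg.trait_sds[g] = {k: 0.0 for k in cfg.trait_sds[g]}
        raw, truth = simulate_phenotypes(cfg)
        tbl = pheno.derive_traits(raw)
        for g in GROUPS:
            sub = tbl[tbl["group"] == g]
            for trait, col in (("dfc", "dfc"), ("dem", "dem"), ("bwg", "bwg")):
                assert sub[col].mean() == pytest.approx(truth["trait_means"][g][trait], abs=1e-9)
            bw = (sub["bw_start"] + sub["bw_end"]) / 2
            assert bw.mean() == pytest.approx(truth["trait_means"][g]["bw"], abs=1e-6)

    def test_large_sample_means_near_planted(self):
        raw, truth = simulate_phenotypes(PhenoSimConfig(seed=12, n_per_group=400))
        tbl = pheno.derive_traits(raw)
        for g in GROUPS:
            sub = tbl[tbl["group"] == g]
            se = 14.0 / np.sqrt(len(sub))
            assert abs(sub["dfc"].mean() - truth["trait_means"][g]["dfc"]) < 4 * se

    def test_rfi_betas_recovered_from_structure(self):
        cfg = PhenoSimConfig(seed=5, n_per_group=300, noise_sd=0.0)
        raw, truth = simulate_phenotypes(cfg)
        tbl = pheno.derive_traits(raw)
        _, fit = pheno.compute_rfi(tbl)
        # a pooled single-intercept fit absorbs small between-group mean
        # differences into the slopes, so recovery is close but not exact
        assert fit.params["mbw"] == pytest.approx(truth["rfi_betas"][0], abs=0.05)
        assert fit.params["bwg"] == pytest.approx(truth["rfi_betas"][1], abs=0.05)
        assert fit.params["dem"] == pytest.approx(truth["rfi_betas"][2], abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError, match=">= 2"):
            simulate_phenotypes(PhenoSimConfig(n_per_group=1))
        cfg = PhenoSimConfig(noise_sd=-1.0)
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_phenotypes(cfg)


class TestCounts:
    def test_counts_are_nonnegative_integers_with_expected_shape(self):
        cfg = ExprSimConfig(seed=2, n_genes=30, n_lncrna=5, n_per_group=4)
        counts, meta, truth = simulate_counts(cfg)
        assert counts.shape == (35, 16)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)
        assert list(meta["group"].unique()) == list(GROUPS)
        assert len(truth) == 35 and (truth.drop(truth.index[:0]) != "").all()

    def test_zero_genes_gives_empty_matrix(self):
        counts, meta, truth = simulate_counts(ExprSimConfig(seed=0, n_genes=0))
        assert counts.shape == (0, 32) and truth.empty

    def test_unknown_bin_rejected(self):
        cfg = ExprSimConfig(bin_assignment={"gene_00001": 13})
        with pytest.raises(ValueError, match="unknown bin"):
            simulate_counts(cfg)

    def test_planted_bin_moves_group_means_as_specified(self):
        # bin 3 (dominant high, P2 high): WL baseline, YY and crosses elevated
        cfg = ExprSimConfig(
            seed=6, n_genes=1, n_per_group=200, bin_assignment={"gene_00001": 3},
            dispersion=1e-9, effect_log2fc=2.0, baseline_mean=1000.0,
        )
        counts, meta, _ = simulate_counts(cfg)
        m = counts.iloc[0].groupby(meta["group"]).mean()
        assert m["WL"] == pytest.approx(1000, rel=0.05)
        for g in ("YY", "WY", "YW"):
            assert m[g] == pytest.approx(4000, rel=0.05)

    def test_additive_bin_puts_cross_at_arithmetic_mid(self):
        cfg = ExprSimConfig(
            seed=7, n_genes=1, n_per_group=200, bin_assignment={"gene_00001": 4},
            dispersion=1e-9, effect_log2fc=2.0, baseline_mean=1000.0,
        )
        counts, meta, _ = simulate_counts(cfg)
        m = counts.iloc[0].groupby(meta["group"]).mean()
        assert m["WL"] == pytest.approx(1000, rel=0.05)
        assert m["YY"] == pytest.approx(4000, rel=0.05)
        mid = (m["WL"] + m["YY"]) / 2
        for cross in CROSSES:
            assert m[cross] == pytest.approx(mid, rel=0.05)


class TestCoexpression:
    def test_shapes_and_labels(self):
        cfg = NetworkSimConfig(seed=1, n_modules=2, genes_per_module=30, n_background=10,
                               n_samples=12)
        expr, trait, labels = simulate_coexpression(cfg)
        assert expr.shape == (70, 12) and len(trait) == 12
        assert labels.value_counts().to_dict() == {1: 30, 2: 30, 0: 10}

    def test_noise_free_trait_tracks_module_factor(self):
        cfg = NetworkSimConfig(seed=2, trait_noise_sd=0.0, gene_noise_sd=0.0)
        expr, trait, labels = simulate_coexpression(cfg)
        # any module-0 gene is loading * factor exactly -> |r| = 1 with trait
        g = expr.loc[labels[labels == 1].index[0]]
        assert abs(np.corrcoef(g, trait)[0, 1]) == pytest.approx(1.0)

    def test_within_module_correlation_exceeds_between(self):
        expr, _, labels = simulate_coexpression(NetworkSimConfig(seed=3))
        corr = np.corrcoef(expr.to_numpy())
        same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
        in_mod = (labels.to_numpy() != 0)[:, None] & (labels.to_numpy() != 0)[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        within = np.abs(corr[same & in_mod & off]).mean()
        between = np.abs(corr[~same & in_mod & off]).mean()
        assert within > 0.5 > between

    def test_bad_trait_module_index(self):
        with pytest.raises(ValueError, match="out of range"):
            simulate_coexpression(NetworkSimConfig(n_modules=2, trait_module_index=2))


class TestAnnotation:
    def test_coordinates_within_chromosomes_and_one_based(self):
        cfg = GenomeSimConfig(seed=10)
        genes, lncs, truth = simulate_annotation(cfg)
        for df in (genes, lncs):
            assert (df["start"] >= 1).all()
            assert (df["start"] <= df["end"]).all()
            for c, ln in cfg.chrom_lengths.items():
                assert (df.loc[df["chrom"] == c, "end"] <= ln).all()

    def test_truth_obeys_window_and_chromosome(self):
        cfg = GenomeSimConfig(seed=11)
        genes, lncs, truth = simulate_annotation(cfg)
        assert (truth["distance"] <= cfg.window).all()
        for _, row in truth.iterrows():
            assert lncs.loc[row["lncrna"], "chrom"] == genes.loc[row["gene"], "chrom"]

    def test_window_zero_keeps_only_touching_pairs(self):
        cfg = GenomeSimConfig(seed=12, window=0)
        _, _, truth = simulate_annotation(cfg)
        assert (truth["distance"] == 0).all()

    def test_single_chromosome_everything_is_candidate(self):
        cfg = GenomeSimConfig(
            seed=13, chrom_lengths={"chrA": 200_000}, n_genes=5, n_lncrna=3,
            window=10**9,
        )
        _, _, truth = simulate_annotation(cfg)
        assert len(truth) == 15  # every pair within the huge window

    def test_cis_fraction_bounds(self):
        with pytest.raises(ValueError, match="cis_fraction"):
            simulate_annotation(GenomeSimConfig(cis_fraction=1.5))
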