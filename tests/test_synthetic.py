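"""The synthetic-data generator: Mendelian transmission, variance targets,
design structure and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from treegs.pedigree import build_A, status_number
from treegs.synthetic_data import (
    SimulationConfig,
    assign_qtl_effects,
    build_study_bundle,
    build_two_cluster_bundle,
    drop_genes,
    simulate_founders,
    simulate_phenotypes,
    true_breeding_values,
)


class TestFounders:
    def test_fixed_maf_half_gives_mean_count_one(self):
        cfg = SimulationConfig(n_founders=400, n_markers=50, n_qtl=10,
                               maf_range=(0.5, 0.5))
        H, freqs = simulate_founders(cfg, np.random.default_rng(0))
        counts = H.sum(axis=2)
        se = np.sqrt(0.5 / (2 * 400))
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_maf_floor_keeps_monomorphism_rare(self):
        cfg = SimulationConfig(n_founders=30, n_markers=400, n_qtl=10)
        H, freqs = simulate_founders(cfg, np.random.default_rng(1))
        counts = H.sum(axis=2)
        mono = np.mean([len(set(counts[:, j])) == 1 for j in range(counts.shape[1])])
        # worst case MAF=0.05: P(all 60 alleles same) ~ 0.95^60 ~ 4.6%
        assert mono < 0.05

    def test_same_seed_reproducible(self):
        cfg = SimulationConfig(n_markers=60, n_qtl=10)
        H1, f1 = simulate_founders(cfg, np.random.default_rng(7))
        H2, f2 = simulate_founders(cfg, np.random.default_rng(7))
        assert np.array_equal(H1, H2) and np.array_equal(f1, f2)


class TestGeneDrop:
    def test_homozygous_parents_transmit_with_certainty(self):
        cfg = SimulationConfig(n_markers=10, n_qtl=2)
        H = np.ones((2, cfg.n_loci, 2), dtype=np.int8)
        off = drop_genes(H, np.zeros(50, int), np.ones(50, int),
                         np.random.default_rng(0), cfg)
        assert (off.sum(axis=2) == 2).all()

    def test_het_x_het_segregates_1_2_1(self):
        cfg = SimulationConfig(n_markers=1, n_qtl=1)
        H = np.zeros((2, cfg.n_loci, 2), dtype=np.int8)
        H[:, :, 0] = 1  # both parents heterozygous at every locus
        n = 4000
        off = drop_genes(H, np.zeros(n, int), np.ones(n, int),
                         np.random.default_rng(1), cfg).sum(axis=2)
        counts = np.bincount(off[:, 0], minlength=3) / n
        for k, expect in enumerate([0.25, 0.5, 0.25]):
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(counts[k] - expect) < 4 * se

    def test_full_sib_genomic_correlation_near_half(self):
        cfg = SimulationConfig(n_founders=2, n_markers=4000, n_qtl=10)
        H, freqs = simulate_founders(cfg, np.random.default_rng(2))
        n = 60
        off = drop_genes(H, np.zeros(n, int), np.ones(n, int),
                         np.random.default_rng(3), cfg).sum(axis=2).astype(float)
        Zc = off - 2 * freqs
        denom = 2 * freqs * (1 - freqs)
        G = (Zc / np.sqrt(denom)) @ (Zc / np.sqrt(denom)).T / cfg.n_loci
        off_diag = G[np.triu_indices(n, 1)]
        assert abs(off_diag.mean() - 0.5) < 0.05

    def test_ungenotyped_parent_rejected(self):
        cfg = SimulationConfig(n_markers=5, n_qtl=1)
        H = np.ones((2, cfg.n_loci, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            drop_genes(H, np.array([-1]), np.array([0]),
                       np.random.default_rng(0), cfg)


class TestQTLEffects:
    def test_variance_scaling_hits_target(self):
        cfg = SimulationConfig(n_founders=1000, n_markers=500, n_qtl=100,
                               sigma_a2=4.0)
        rng = np.random.default_rng(4)
        H, freqs = simulate_founders(cfg, rng)
        qtl, eff = assign_qtl_effects(cfg, freqs, rng)
        tbv = true_breeding_values(H.sum(axis=2).astype(float), freqs, qtl, eff)
        for t in range(2):
            assert np.var(tbv[:, t]) == pytest.approx(4.0, rel=0.10)

    def test_equal_effects_make_tbv_proportional_to_count_sum(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, (40, 6)).astype(float)
        freqs = np.full(6, 0.5)
        eff = np.ones((6, 1))
        tbv = true_breeding_values(counts, freqs, np.arange(6), eff)
        assert np.allclose(tbv[:, 0], counts.sum(axis=1) - 6.0)

    def test_effect_correlation_matches_age_age_target(self):
        cfg = SimulationConfig(n_qtl=4000, n_markers=4000, qtl_observed=True,
                               age_age_corr=0.7)
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.05, 0.5, cfg.n_loci)
        _, eff = assign_qtl_effects(cfg, freqs, rng)
        r = np.corrcoef(eff[:, 0], eff[:, 1])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)


class TestPhenotypes:
    def test_noise_free_heritability_one_returns_fixed_plus_tbv(self):
        cfg = SimulationConfig(ratio_site_additive=0, ratio_block=0,
                               ratio_site_family=0, ratio_family=0)
        design = pd.DataFrame({
            "id": [f"i{k}" for k in range(10)],
            "site": "S1", "block": 1, "family": "F1",
        })
        tbv = np.linspace(-2, 2, 10)
        out = simulate_phenotypes(
            tbv, design, cfg, np.random.default_rng(0),
            h2_by_site={"S1": 1.0 - 1e-12}, site_means={"S1": 100.0},
            age_by_site={"S1": 10.0},
        )
        assert np.allclose(out["trait"], 100.0 + tbv, atol=1e-4)

    def test_infeasible_heritability_target_rejected(self):
        cfg = SimulationConfig()  # nonzero variance ratios
        design = pd.DataFrame({"id": ["a"], "site": "S1", "block": 1,
                               "family": "F"})
        with pytest.raises(ValueError, match="infeasible"):
            simulate_phenotypes(np.zeros(1), design, cfg,
                                np.random.default_rng(0),
                                h2_by_site={"S1": 0.95},
                                site_means={"S1": 0.0}, age_by_site={"S1": 10.0})

    def test_site_mean_gap_recovered_by_evaluation(self, small_bundle, small_relmat):
        from treegs.ablup import ModelSpec, build_design
        from treegs.reml import MixedModel

        phen = small_bundle.phenotypes_htj
        f1 = phen[phen["site"].str.startswith("F1")]
        y, X, terms = build_design(f1, small_relmat, ModelSpec())
        model = MixedModel(y, X, terms)
        vc = {"additive": 400.0, "site_additive": 120.0, "block": 80.0,
              "site_family": 80.0, "family": 40.0, "residual": 1500.0}
        sol, _ = model.solve(vc)
        # site dummies are columns 1..2 (sites sorted, first dropped)
        gaps_est = sol.beta[1:3]
        means = dict(zip(["F1-S1", "F1-S2", "F1-S3"],
                         small_bundle.config.site_means_htj))
        truth = [means["F1-S2"] - means["F1-S1"], means["F1-S3"] - means["F1-S1"]]
        assert np.allclose(gaps_est, truth, atol=15.0)


class TestBundle:
    def test_end_to_end_structure(self, small_bundle):
        b = small_bundle
        ped_ids = set(b.pedigree.ids)
        assert set(b.phenotypes_htj["id"]).issubset(ped_ids)
        assert set(b.genotypes_f1.index).issubset(ped_ids)
        assert len(b.f2_ids) == b.config.f2_genotyped
        assert b.genotypes_f1.shape[1] == b.config.n_markers
        # hidden causal loci: panel columns never include QTL positions
        assert b.genotypes_f1.shape[1] + b.config.n_qtl == b.config.n_loci

    def test_f2_status_number_is_small(self, small_bundle, small_relmat):
        f2 = small_bundle.truth.loc[small_bundle.truth.generation == "F2", "id"]
        assert status_number(small_relmat, list(f2)) <= 30

    def test_same_seed_bitwise_identical(self):
        cfg = dict(f1_site_sizes=(30, 30), f2_size=20, f2_genotyped=10,
                   n_markers=100, n_qtl=20, n_f1_families=8, n_f2_families=5,
                   n_f2_parents=5, seed=11)
        b1 = build_study_bundle(SimulationConfig(**cfg))
        b2 = build_study_bundle(SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(b1.phenotypes_htj, b2.phenotypes_htj)
        pd.testing.assert_frame_equal(b1.genotypes_f1, b2.genotypes_f1)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)

    def test_default_f1_census_and_families(self):
        cfg = SimulationConfig()
        assert sum(cfg.f1_site_sizes) == 1321
        assert cfg.n_f1_families == 37

    def test_two_cluster_fixture_separates_lineages(self):
        bundle, labels = build_two_cluster_bundle(seed=3)
        assert len(labels) == 120
        truth = bundle.truth.set_index("id")
        f2 = list(labels)
        low = [i for i in f2 if labels[i] == 0]
        high = [i for i in f2 if labels[i] == 1]
        gap = truth.loc[high, "tbv_htj"].mean() - truth.loc[low, "tbv_htj"].mean()
        assert gap > 2 * truth.loc[f2, "tbv_htj"].groupby(
            [labels[i] for i in f2]).std().mean()

    def test_parent_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="at most"):
            build_study_bundle(SimulationConfig(n_founders=4, n_f1_families=10))


class TestBlockLD:
    def test_within_block_ld_exceeds_between(self):
        from treegs.synthetic_data import _block_bounds

        cfg = SimulationConfig(n_founders=60, n_markers=300, n_qtl=30,
                               ld_blocks=15, seed=3)
        H, freqs = simulate_founders(cfg, np.random.default_rng(3))
        haps = np.vstack([H[:, :, 0], H[:, :, 1]]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(haps.T) ** 2
        bounds = _block_bounds(cfg.n_loci, 15)
        within = [R[i, j]
                  for b0, b1 in bounds
                  for i in range(b0, b1 - 1, 3)
                  for j in (i + 1,)]
        between = [R[b1 - 1, b1] for _, b1 in bounds[:-1]]
        between += [R[b0, b1 + 2] for (b0, _), (_, b1) in zip(bounds[:-1], bounds[:-1])]
        assert np.nanmean(within) > 5 * np.nanmean(between)
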