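"""Synthetic family-GWAS generator: marginals, transmission, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snpevals import (
    SimConfig,
    VarianceComponents,
    build_kinship_matrix,
    causal_effect_size,
    compute_metrics,
    simulate_dataset,
    simulate_family_genotypes,
    simulate_parent_alleles,
    simulate_phenotypes,
)
from snpevals.simulate import _simulate_haplotypes, calibrate_latent_correlation


class TestCausalEffectSize:
    def test_zero_heritability_gives_zero_effect(self):
        assert causal_effect_size(0.0, 0.2, VarianceComponents(4, 1, 1)) == 0.0

    def test_scaled_convention_hand_value(self):
        # sqrt(10 / (100 * 6 * 2 * 0.2 * 0.8)) = sqrt(10/192)
        beta = causal_effect_size(
            10.0, 0.2, VarianceComponents(4, 1, 1), convention="scaled"
        )
        assert beta == pytest.approx(np.sqrt(10.0 / 192.0), abs=1e-12)
        assert beta == pytest.approx(0.22822, abs=5e-6)

    def test_variance_fraction_hand_value(self):
        beta = causal_effect_size(10.0, 0.2, VarianceComponents(4, 1, 1))
        assert beta == pytest.approx(np.sqrt(10.0 / 32.0), abs=1e-12)

    def test_monotone_in_h_and_maf(self):
        vc = VarianceComponents(4, 1, 1)
        assert causal_effect_size(10, 0.2, vc) > causal_effect_size(5, 0.2, vc)
        # maf(1-maf) larger at 0.4 => smaller coefficient
        assert causal_effect_size(10, 0.2, vc) > causal_effect_size(10, 0.4, vc)

    def test_rejects_degenerate_maf(self):
        with pytest.raises(ValueError):
            causal_effect_size(10, 0.0, VarianceComponents(4, 1, 1))


class TestHaplotypes:
    def test_independent_limit_uncorrelated(self):
        cfg = SimConfig(within_block_corr=0.0, block_sizes=(6,), block_mafs=(0.5,), n_causal_blocks=1)
        hap = _simulate_haplotypes(cfg, 10_000, np.random.default_rng(0))
        corr = np.corrcoef(hap.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert np.all(np.abs(hap.mean(axis=0) - 0.5) < 0.02)

    def test_marginal_frequency_matches_maf(self):
        cfg = SimConfig()
        hap = _simulate_haplotypes(cfg, 10_000, np.random.default_rng(1))
        freq = hap.mean(axis=0)
        expected = np.repeat(cfg.block_mafs, cfg.block_sizes)
        assert np.all(np.abs(freq - expected) < 0.015)

    def test_binary_calibration_hits_target_correlation(self):
        cfg = SimConfig(corr_scale="binary")
        hap = _simulate_haplotypes(cfg, 10_000, np.random.default_rng(2))
        block = hap[:, :6]  # first block, maf 0.2
        corr = np.corrcoef(block.T)
        off = corr[~np.eye(6, dtype=bool)]
        assert abs(off.mean() - 0.7) < 0.05

    def test_latent_scale_correlation_matches_orthant_value(self):
        # thresholding latent normals at rho=0.7 gives the tetrachoric-implied
        # binary correlation, computable from the orthant probability
        maf = 0.2
        z = stats.norm.ppf(maf)
        p11 = stats.multivariate_normal.cdf(
            [z, z], mean=[0, 0], cov=[[1, 0.7], [0.7, 1]]
        )
        expected = (p11 - maf**2) / (maf * (1 - maf))
        cfg = SimConfig()  # latent scale default
        hap = _simulate_haplotypes(cfg, 10_000, np.random.default_rng(3))
        corr = np.corrcoef(hap[:, :6].T)
        off = corr[~np.eye(6, dtype=bool)]
        assert abs(off.mean() - expected) < 0.05

    def test_calibrated_latent_exceeds_binary_target(self):
        rho = calibrate_latent_correlation(0.2, 0.7)
        assert 0.7 < rho < 1.0

    def test_parent_allele_vector_shape(self):
        cfg = SimConfig()
        vec = simulate_parent_alleles(cfg, np.random.default_rng(4))
        assert vec.shape == (50,)
        assert set(np.unique(vec)) <= {0, 1}


class TestFamilyGenotypes:
    def test_mz_twins_share_genotypes(self):
        cfg = SimConfig()
        G = simulate_family_genotypes(cfg, np.random.default_rng(5), "MZ")
        np.testing.assert_array_equal(G[2], G[3])
        assert set(np.unique(G)) <= {0, 1, 2}

    def test_dz_twin_locus_correlation_near_half(self):
        cfg = SimConfig(block_sizes=(1,), block_mafs=(0.3,), within_block_corr=0.0, n_causal_blocks=1)
        rng = np.random.default_rng(6)
        pairs = np.array(
            [simulate_family_genotypes(cfg, rng, "DZ")[2:, 0] for _ in range(8000)]
        )
        corr = np.corrcoef(pairs.T)[0, 1]
        assert abs(corr - 0.5) < 0.05

    def test_adopted_children_unrelated_to_parents(self):
        cfg = SimConfig(block_sizes=(1,), block_mafs=(0.3,), within_block_corr=0.0, n_causal_blocks=1)
        rng = np.random.default_rng(7)
        fams = np.array(
            [simulate_family_genotypes(cfg, rng, "adopted")[:, 0] for _ in range(8000)]
        )
        corr = np.corrcoef(fams.T)
        assert abs(corr[0, 2]) < 0.05  # father vs adoptee
        assert abs(corr[2, 3]) < 0.05  # adoptee vs adoptee

    def test_hardy_weinberg_homozygote_frequency(self):
        cfg = SimConfig(block_sizes=(1,), block_mafs=(0.25,), within_block_corr=0.0, n_causal_blocks=1)
        rng = np.random.default_rng(8)
        fathers = np.array(
            [simulate_family_genotypes(cfg, rng, "MZ")[0, 0] for _ in range(8000)]
        )
        assert abs(np.mean(fathers == 2) - 0.25**2) < 0.01


class TestPhenotypes:
    def test_near_zero_noise_gives_near_zero_trait(self):
        vc = VarianceComponents(0, 0, 1e-10)
        G = np.zeros((4, 3))
        y = simulate_phenotypes(
            G, np.zeros(3), build_kinship_matrix("MZ"), vc, np.random.default_rng(9)
        )
        assert np.all(np.abs(y) < 1e-4)

    def test_total_variance_bookkeeping(self):
        cfg = SimConfig(h=0.0, m=2500)
        ds, _ = simulate_dataset(cfg, 10)
        y = np.concatenate([f.y for f in ds.families])
        assert abs(np.var(y) - 6.0) < 0.3  # sigma_a2+sigma_c2+sigma_e2 = 6

    @pytest.mark.parametrize(
        "ftype, pair, expected",
        [
            ("MZ", (2, 3), 5.0),  # twins: sigma_a2 + sigma_c2
            ("MZ", (0, 1), 1.0),  # parents: sigma_c2 only
            ("MZ", (0, 2), 3.0),  # parent-child: sigma_a2/2 + sigma_c2
            ("DZ", (2, 3), 3.0),  # DZ twins: sigma_a2/2 + sigma_c2
            ("adopted", (2, 3), 1.0),  # adoptees: sigma_c2 only
        ],
    )
    def test_family_covariance_structure(self, ftype, pair, expected):
        cfg = SimConfig(h=0.0, m=4000, family_type_mix=((ftype, 1.0),))
        ds, _ = simulate_dataset(cfg, 11)
        Y = np.array([f.y for f in ds.families])
        cov = np.cov(Y[:, pair[0]], Y[:, pair[1]])[0, 1]
        assert abs(cov - expected) < 0.35

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            simulate_phenotypes(
                np.zeros((4, 3)),
                np.zeros(2),
                np.eye(4),
                VarianceComponents(1, 1, 1),
                np.random.default_rng(0),
            )


class TestMetrics:
    def test_perfect_selection(self):
        cfg = SimConfig()
        m = compute_metrics(cfg.causal_indices, cfg)
        assert (m.tp, m.tn, m.rtp, m.rtn) == (1.0, 1.0, 1.0, 1.0)

    def test_empty_selection(self):
        m = compute_metrics(set(), SimConfig())
        assert (m.tp, m.tn, m.rtp, m.rtn) == (0.0, 1.0, 0.0, 1.0)

    def test_block_neighbour_counts_for_relaxed_tp_only(self):
        # second SNP of block 1 is not causal but sits in a causal block
        m = compute_metrics({1}, SimConfig())
        assert m.tp == 0.0 and m.rtp == 0.25 and m.rtn == 1.0

    def test_null_design_reports_tn_only(self):
        m = compute_metrics({3, 20}, SimConfig(h=0.0))
        assert np.isnan(m.tp) and np.isnan(m.rtp)
        assert m.tn == pytest.approx(48 / 50)

    @given(sel=st.sets(st.integers(0, 49), max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_metric_identities_for_arbitrary_sets(self, sel):
        cfg = SimConfig()
        m = compute_metrics(sel, cfg)
        causal = set(cfg.causal_indices)
        block5 = set(range(20, 50))
        assert m.tp == len(sel & causal) / 4
        assert m.tn == pytest.approx(1 - len(sel - causal) / 46)
        assert m.rtn == pytest.approx(1 - len(sel & block5) / 30)
        blocks_hit = {cfg.block_of(j) for j in sel if cfg.block_of(j) < 4}
        assert m.rtp == pytest.approx(len(blocks_hit) / 4)
        for v in (m.tp, m.tn, m.rtp, m.rtn):
            assert 0.0 <= v <= 1.0


class TestBenchmarkHarness:
    def test_identical_reports_across_invocations(self):
        from snpevals import MethodSpec, benchmark
        from tests.conftest import SMALL_BLOCKS

        cfg = SimConfig(m=60, h=10.0, **SMALL_BLOCKS)
        spec = MethodSpec(method="mbic2")
        r1 = benchmark(cfg, spec, reps=2, seed=77)
        r2 = benchmark(cfg, spec, reps=2, seed=77)
        assert r1.as_dict() == r2.as_dict()
        np.testing.assert_array_equal(r1.per_rep, r2.per_rep)
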