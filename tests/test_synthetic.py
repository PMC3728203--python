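import numpy as np
import pytest

from ciseqtl import association, synthetic
from ciseqtl.synthetic import (
    CovariateParams,
    PlantedEqtl,
    SimulationConfig,
    draw_block_pools,
    genotypes_from_pools,
    simulate_covariates,
    simulate_expression,
    simulate_study,
)


def _config(**kw):
    base = dict(
        seed=1,
        cohort_sizes=(100,),
        cohort_names=("c1",),
        n_blocks=2,
        snps_per_block=5,
        haplotypes_per_block=4,
        n_probesets=3,
        n_genes=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_single_haplotype_pool_is_monomorphic(self, rng):
        pools = [np.array([[0, 1, 0]], dtype=np.int8)]
        gm = genotypes_from_pools(pools, 50, rng)
        # every individual is the same haplotype twice: dosage 0 or 2, constant per SNP
        np.testing.assert_array_equal(gm.dosages, np.tile([0.0, 2.0, 0.0], (50, 1)))

    def test_two_complementary_haplotypes_give_r2_one(self, rng):
        pools = [np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.int8)]
        gm = genotypes_from_pools(pools, 200, rng)
        corr = np.corrcoef(gm.dosages, rowvar=False)
        np.testing.assert_allclose(corr**2, 1.0, atol=1e-12)

    def test_block_structure_at_large_n(self):
        # within-block r2 exceeds between-block r2; between-block ~ 0 by construction
        config = _config(
            seed=5, cohort_sizes=(5000,), n_blocks=4, snps_per_block=8, haplotypes_per_block=4
        )
        gm = simulate_study(config).genotypes["c1"]
        d = gm.dosages
        keep = [j for j in range(d.shape[1]) if np.ptp(d[:, j]) > 0]
        corr2 = np.corrcoef(d[:, keep], rowvar=False) ** 2
        blocks = np.array([j // 8 for j in keep])
        same = blocks[:, None] == blocks[None, :]
        off_diag = ~np.eye(len(keep), dtype=bool)
        within = corr2[same & off_diag].mean()
        between = corr2[~same].mean()
        assert within > between
        assert between < 0.05

    def test_positions_evenly_spaced(self):
        config = _config(start_pos=1000, locus_span_bp=1000)
        gm = simulate_study(config).genotypes["c1"]
        pos = np.array([s.pos for s in gm.snps])
        assert pos[0] == 1000
        assert len(set(np.diff(pos))) == 1

    def test_shared_pools_across_cohorts(self):
        config = _config(cohort_sizes=(3000, 3000), cohort_names=("a", "b"), seed=9)
        st = simulate_study(config)
        # allele frequencies agree across cohorts because pools are shared
        fa = np.nanmean(st.genotypes["a"].dosages, axis=0) / 2
        fb = np.nanmean(st.genotypes["b"].dosages, axis=0) / 2
        np.testing.assert_allclose(fa, fb, atol=0.05)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="haplotypes_per_block"):
            genotypes_from_pools([np.empty((0, 3), dtype=np.int8)], 10, rng)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="haplotypes_per_block"):
            _config(haplotypes_per_block=0)
        with pytest.raises(ValueError, match="maf_range"):
            _config(maf_range=(0.0, 0.6))
        with pytest.raises(ValueError, match="h2"):
            PlantedEqtl(0, 0, h2=1.0)


class TestCovariates:
    def test_mean_age_matches_target(self):
        # default parameterization: mean age 63.3, checked within Monte-Carlo error
        rng = np.random.default_rng(7)
        cov = simulate_covariates(10_000, CovariateParams(), rng)
        assert abs(cov.age.mean() - 63.3) < 0.5

    def test_age_bounds_respected(self, rng):
        cov = simulate_covariates(5000, CovariateParams(), rng)
        assert cov.age.min() > 18 and cov.age.max() < 95

    def test_male_fraction_one(self, rng):
        cov = simulate_covariates(100, CovariateParams(male_fraction=1.0), rng)
        assert all(s == "male" for s in cov.sex)

    def test_seed_reproducibility(self):
        a = simulate_covariates(50, CovariateParams(), np.random.default_rng(3))
        b = simulate_covariates(50, CovariateParams(), np.random.default_rng(3))
        np.testing.assert_array_equal(a.age, b.age)
        assert a.sex == b.sex and a.smoking == b.smoking


class TestExpression:
    def test_null_h2_pvalues_uniform(self):
        # no planted effects: scan p-values behave as U(0,1)
        config = _config(seed=11, cohort_sizes=(300,), n_probesets=20, snps_per_block=10)
        st = simulate_study(config)
        gm, em = st.genotypes["c1"], st.expression["c1"]
        ps = []
        for j in range(gm.n_snps):
            for k in range(em.n_probesets):
                r = association.fit_single(gm.dosages[:, j], em.values[:, k])
                if r.testable:
                    ps.append(r.p)
        ps = np.array(ps)
        assert 0.01 < np.mean(ps < 0.05) < 0.12
        assert abs(np.mean(ps) - 0.5) < 0.05

    def test_h2_half_recovered_at_large_n(self):
        config = _config(
            seed=13,
            cohort_sizes=(10_000,),
            planted_eqtls=(PlantedEqtl(2, 0, h2=0.5),),
            beta_age=0.0,
            beta_sex=0.0,
            beta_smoking=0.0,
        )
        st = simulate_study(config)
        g = st.genotypes["c1"].dosages[:, 2]
        y = st.expression["c1"].values[:, 0]
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.02

    def test_noise_free_limit_collinear(self):
        config = _config(
            seed=17,
            planted_eqtls=(PlantedEqtl(2, 0, h2=0.999999),),
            beta_age=0.0,
            beta_sex=0.0,
            beta_smoking=0.0,
            outlier_fraction=0.0,
        )
        st = simulate_study(config)
        g = st.genotypes["c1"].dosages[:, 2]
        y = st.expression["c1"].values[:, 0]
        assert np.corrcoef(g, y)[0, 1] ** 2 > 0.9999

    def test_monomorphic_planted_snp_rejected(self, rng):
        pools = [np.zeros((2, 3), dtype=np.int8)]  # SNP 0 monomorphic
        gm = genotypes_from_pools(pools, 50, rng)
        config = _config(n_blocks=1, snps_per_block=3, planted_eqtls=(PlantedEqtl(0, 0, 0.5),))
        cov = simulate_covariates(50, CovariateParams(), rng, sample_ids=list(gm.sample_ids))
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_expression(gm, cov, config, rng)

    def test_outliers_injected(self):
        clean = _config(seed=19, cohort_sizes=(2000,), outlier_fraction=0.0)
        dirty = _config(
            seed=19, cohort_sizes=(2000,), outlier_fraction=0.05, outlier_magnitude_sd=10.0
        )
        sd_clean = simulate_study(clean).expression["c1"].values.std()
        sd_dirty = simulate_study(dirty).expression["c1"].values.std()
        assert sd_dirty > 1.5 * sd_clean


class TestDeterminism:
    def test_study_fully_deterministic(self):
        config = _config(seed=23, planted_eqtls=(PlantedEqtl(1, 1, 0.4),))
        a = simulate_study(config)
        b = simulate_study(config)
        for name in config.cohort_names:
            np.testing.assert_array_equal(a.genotypes[name].dosages, b.genotypes[name].dosages)
            np.testing.assert_array_equal(a.expression[name].values, b.expression[name].values)
            np.testing.assert_array_equal(a.covariates[name].age, b.covariates[name].age)
        assert a.truth.equals(b.truth)

    def test_write_study_byte_identical(self, tmp_path):
        config = _config(seed=29)
        for d in ("one", "two"):
            synthetic.write_study(simulate_study(config), tmp_path / d)
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()


class TestTruthRecovery:
    def test_r2_recovered_within_tolerance(self):
        # h2 = 0.5, n = 400: scan r2 within +/-0.1 of truth in >= 95% of 200 replicates
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            config = _config(
                seed=1000 + i,
                cohort_sizes=(400,),
                planted_eqtls=(PlantedEqtl(2, 0, h2=0.5),),
                beta_age=0.0,
                beta_sex=0.0,
                beta_smoking=0.0,
            )
            st = simulate_study(config)
            r = association.fit_single(
                st.genotypes["c1"].dosages[:, 2], st.expression["c1"].values[:, 0]
            )
            if abs(r.r2 - 0.5) <= 0.1:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_direction_recovered(self):
        # planted sign equals fitted sign in >= 99% of replicates at h2 = 0.2, n = 300
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            config = _config(
                seed=5000 + i,
                cohort_sizes=(300,),
                planted_eqtls=(PlantedEqtl(2, 0, h2=0.2, direction=-1),),
            )
            st = simulate_study(config)
            r = association.fit_single(
                st.genotypes["c1"].dosages[:, 2], st.expression["c1"].values[:, 0]
            )
            if r.direction == -1:
                hits += 1
        assert hits >= 0.99 * n_rep
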