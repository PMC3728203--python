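import numpy as np
import pytest
from scipy import stats

from ciseqtl import multiple_testing, synthetic
from ciseqtl.multiple_testing import (
    effective_tests,
    locus_threshold,
    meff_li_ji,
    probe_correlation,
    snp_correlation,
)
from ciseqtl.datatypes import AdjustedTrait

from conftest import make_genotypes


def _trait(values, pid="ps1"):
    values = np.asarray(values, dtype=float)
    return AdjustedTrait(
        probeset_id=pid,
        residuals=values,
        outlier_mask=np.zeros(values.shape, dtype=bool),
        n_used=int(np.isfinite(values).sum()),
    )


class TestMeffLiJi:
    def test_identity_gives_m(self):
        assert meff_li_ji(np.eye(10)) == pytest.approx(10.0)

    def test_perfect_correlation_gives_one(self):
        # eigenvalues {2, 0}: f(2) = 1, f(0) = 0
        m = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert meff_li_ji(m) == pytest.approx(1.0)

    def test_half_correlation_2x2(self):
        # eigenvalues {1.5, 0.5}: f(1.5) = 1.5, f(0.5) = 0.5 -> 2.0
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert meff_li_ji(m) == pytest.approx(2.0)

    def test_bounds(self, rng):
        for _ in range(20):
            data = rng.normal(size=(50, 8))
            corr = np.corrcoef(data, rowvar=False)
            meff = meff_li_ji(corr)
            assert 1.0 - 1e-9 <= meff <= 8.0 + 1e-9

    def test_equicorrelated_endpoints_and_high_vs_low(self):
        def equi(m, r):
            out = np.full((m, m), r)
            np.fill_diagonal(out, 1.0)
            return out

        assert meff_li_ji(equi(10, 0.0)) == pytest.approx(10.0)
        assert meff_li_ji(equi(10, 1.0)) == pytest.approx(1.0)
        assert meff_li_ji(equi(10, 0.9)) < meff_li_ji(equi(10, 0.2))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="square"):
            meff_li_ji(np.ones((2, 3)))
        with pytest.raises(ValueError, match="symmetric"):
            meff_li_ji(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            meff_li_ji(np.array([[2.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError, match="missing"):
            meff_li_ji(np.array([[1.0, np.nan], [np.nan, 1.0]]))

    def test_negative_eigenvalues_clipped(self):
        # a pairwise-complete pseudo-correlation matrix need not be PSD;
        # construct one with a negative eigenvalue
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert min(np.linalg.eigvalsh(m)) < 0
        meff = meff_li_ji(m)
        assert np.isfinite(meff) and meff >= 1.0


class TestSnpCorrelation:
    def test_identical_columns(self):
        d = np.tile(np.array([0.0, 1, 2, 1, 0])[:, None], (1, 2))
        res = snp_correlation(make_genotypes(d))
        assert res.corr[0, 1] == pytest.approx(1.0)

    def test_between_block_independence(self):
        config = synthetic.SimulationConfig(
            seed=77, cohort_sizes=(5000,), cohort_names=("c1",),
            n_blocks=2, snps_per_block=2, haplotypes_per_block=4, n_probesets=1, n_genes=1,
        )
        gm = synthetic.simulate_study(config).genotypes["c1"]
        res = snp_correlation(gm)
        # SNPs 0,1 in block 1; 2,3 in block 2
        i, j = res.ids.index("snp1"), res.ids.index("snp3")
        assert abs(res.corr[i, j]) < 0.05

    def test_monomorphic_counted_as_one_each(self):
        d = np.column_stack(
            [np.array([0.0, 1, 2, 1, 0]), np.zeros(5), np.full(5, 2.0)]
        )
        res = snp_correlation(make_genotypes(d))
        assert res.n_excluded == 2
        assert effective_tests(res) == pytest.approx(1.0 + 2.0)

    def test_all_monomorphic_falls_back_to_raw_count(self):
        d = np.zeros((5, 3))
        res = snp_correlation(make_genotypes(d))
        with pytest.warns(UserWarning, match="raw count"):
            assert effective_tests(res) == pytest.approx(3.0)


class TestProbeCorrelation:
    def test_duplicate_probeset(self, rng):
        v = rng.normal(0, 1, 40)
        res = probe_correlation([_trait(v, "a"), _trait(v.copy(), "b")])
        assert res.corr[0, 1] == pytest.approx(1.0)

    def test_independent_traits_meff_near_raw(self, rng):
        traits = [_trait(rng.normal(0, 1, 5000), f"p{i}") for i in range(10)]
        meff = effective_tests(probe_correlation(traits))
        assert abs(meff - 10) / 10 < 0.05

    def test_constant_trait_excluded_plus_one(self, rng):
        traits = [
            _trait(rng.normal(0, 1, 30), "a"),
            _trait(rng.normal(0, 1, 30), "b"),
            _trait(np.zeros(30), "c"),
        ]
        res = probe_correlation(traits)
        assert res.excluded_ids == ["c"]
        assert effective_tests(res) == pytest.approx(meff_li_ji(res.corr) + 1.0)


class TestLocusThreshold:
    def test_printed_thresholds_reproduced(self):
        # published effective counts reproduce the printed thresholds
        t1 = locus_threshold(279.64, 35, 0.05)
        t2 = locus_threshold(128.26, 26, 0.05)
        t3 = locus_threshold(246.73, 59, 0.05)
        assert t1.threshold == pytest.approx(5.10e-6, rel=5e-3)
        assert t2.threshold == pytest.approx(1.50e-5, rel=5e-3)
        assert t3.threshold == pytest.approx(3.43e-6, rel=5e-3)

    def test_no_correction_single_test(self):
        assert locus_threshold(1, 1, 0.05).threshold == pytest.approx(0.05)

    def test_display_rounding_only(self):
        th = locus_threshold(279.64, 35, 0.05)
        assert th.display == "5.11e-06"  # display form; full precision retained
        assert th.threshold == pytest.approx(0.05 / (279.64 * 35), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match=">= 1"):
            locus_threshold(0.5, 10, 0.05)
        with pytest.raises(ValueError, match="alpha"):
            locus_threshold(10, 10, 1.5)


class TestCalibration:
    def test_fwer_at_meff_threshold_approximately_conservative(self):
        # family-wise error at alpha/(Meff_snp*Meff_probe) stays below
        # alpha + 2 Monte-Carlo SEs on simulated null data with LD blocks
        config = synthetic.SimulationConfig(
            seed=55, cohort_sizes=(200,), cohort_names=("c1",),
            n_blocks=3, snps_per_block=5, haplotypes_per_block=4,
            n_probesets=3, n_genes=3,
        )
        pools = synthetic.draw_block_pools(config, np.random.default_rng(55))
        rng = np.random.default_rng(56)

        # Meff from a large reference draw of the same pools
        big = synthetic.genotypes_from_pools(pools, 4000, rng)
        meff_snp = effective_tests(snp_correlation(big))
        traits_ref = [_trait(rng.normal(0, 1, 4000), f"p{i}") for i in range(3)]
        meff_probe = effective_tests(probe_correlation(traits_ref))
        thr = 0.05 / (meff_snp * meff_probe)

        n, n_rep, hits = 200, 1000, 0
        for _ in range(n_rep):
            gm = synthetic.genotypes_from_pools(pools, n, rng)
            y = rng.normal(0, 1, (n, 3))
            p_min = _min_p(gm.dosages, y)
            if p_min < thr:
                hits += 1
        fwer = hits / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert fwer <= 0.05 + 2 * mc_se

    def test_permutation_oracle_within_factor_three(self):
        # Meff-implied threshold vs the empirical 5th-percentile min-p from
        # 1,000 label permutations on a 50-SNP x 5-probe locus
        config = synthetic.SimulationConfig(
            seed=60, cohort_sizes=(400,), cohort_names=("c1",),
            n_blocks=5, snps_per_block=10, haplotypes_per_block=4,
            n_probesets=5, n_genes=5,
        )
        st = synthetic.simulate_study(config)
        gm = st.genotypes["c1"]
        rng = np.random.default_rng(61)
        y = rng.normal(0, 1, (400, 5))

        meff_snp = effective_tests(snp_correlation(gm))
        meff_probe = effective_tests(probe_correlation([_trait(y[:, i], f"p{i}") for i in range(5)]))
        thr_meff = 0.05 / (meff_snp * meff_probe)

        mins = np.empty(1000)
        for b in range(1000):
            mins[b] = _min_p(gm.dosages, y[rng.permutation(400)])
        thr_perm = np.quantile(mins, 0.05)
        assert thr_perm / 3 <= thr_meff <= thr_perm * 3


def _min_p(dosages, y):
    """Vectorized min two-sided regression p over all SNP x trait pairs
    (independent of the association module's scalar path)."""
    keep = np.ptp(dosages, axis=0) > 0
    g = dosages[:, keep]
    n = g.shape[0]
    gz = (g - g.mean(axis=0)) / g.std(axis=0)
    yz = (y - y.mean(axis=0)) / y.std(axis=0)
    r = gz.T @ yz / n
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return p.min()
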