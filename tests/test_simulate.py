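import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epiforest as ef
from epiforest.simulate import heritability, hwe_genotype_freqs


class TestHWE:
    def test_symmetric_maf(self):
        np.testing.assert_allclose(hwe_genotype_freqs(0.5), [0.25, 0.5, 0.25])

    def test_maf_02(self):
        np.testing.assert_allclose(hwe_genotype_freqs(0.2), [0.64, 0.32, 0.04])

    @given(st.floats(0.001, 0.5))
    def test_sums_to_one(self, maf):
        assert hwe_genotype_freqs(maf).sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hwe_genotype_freqs(0.0)
        with pytest.raises(ValueError):
            hwe_genotype_freqs(0.7)


class TestPureEpistasisTables:
    @pytest.mark.parametrize("h2,maf", [(0.2, 0.2), (0.2, 0.4), (0.3, 0.2),
                                        (0.3, 0.4), (0.4, 0.2), (0.4, 0.4)])
    def test_zero_marginals_and_exact_h2(self, h2, maf):
        rng = np.random.default_rng(hash((h2, maf)) % 2**31)
        t = ef.pure_epistasis_penetrance(h2, maf, rng=rng)
        K = t.prevalence
        for locus in (0, 1):
            np.testing.assert_allclose(t.marginal_penetrance(locus), K, atol=1e-10)
        assert abs(heritability(t) - h2) < 1e-8
        assert abs(t.recompute_prevalence() - K) < 1e-10

    def test_infeasible_prevalence_raises(self):
        with pytest.raises(RuntimeError, match="prevalence"):
            ef.pure_epistasis_penetrance(0.4, 0.2, prevalence=0.05,
                                         rng=np.random.default_rng(0), max_tries=200)


class TestMarchiniModels:
    def test_zero_effect_is_flat_at_prevalence(self):
        t = ef.marchini_odds_table("additive", lam=0.0, maf=0.2, prevalence=0.02)
        np.testing.assert_allclose(t.values, 0.02, atol=1e-9)

    @pytest.mark.parametrize("kind", ["additive", "multiplicative", "threshold"])
    def test_marginal_or_calibration(self, kind):
        """Each locus's genotype-1-vs-0 marginal odds ratio equals 1+lambda."""
        lam, maf = 0.5, 0.2
        t = ef.marchini_odds_table(kind, lam=lam, maf=maf)
        g = hwe_genotype_freqs(maf)
        for axis in (0, 1):
            marg = (t.values * (g[None, :] if axis == 0 else g[:, None])).sum(axis=1 - axis)
            odds = marg / (1 - marg)
            assert odds[1] / odds[0] == pytest.approx(1 + lam, abs=1e-6)
        assert t.recompute_prevalence() == pytest.approx(t.prevalence, abs=1e-9)

    def test_threshold_plateau(self):
        """Extra risk alleles beyond one per locus do not increase risk."""
        t = ef.marchini_odds_table("threshold", lam=0.5, maf=0.2)
        plateau = t.values[1:, 1:]
        assert np.ptp(plateau) < 1e-12
        assert plateau[0, 0] > t.values[0, 0]


class TestLDMarker:
    def test_perfect_ld_copies(self):
        causal = np.array([0, 1, 2, 1], dtype=np.int8)
        marker = ef.ld_marker(causal, 0.2, 1.0)
        np.testing.assert_array_equal(marker, causal)
        assert marker is not causal

    def test_empirical_r2_matches_target(self):
        rng = np.random.default_rng(0)
        maf, r2 = 0.2, 0.7
        causal = rng.binomial(2, maf, size=100_000).astype(np.int8)
        marker = ef.ld_marker(causal, maf, r2, rng)
        # allele-level correlation^2 estimated from genotype dosages
        # (valid because alleles were sampled independently per haplotype)
        r2_hat = np.corrcoef(causal, marker)[0, 1] ** 2
        assert 0.68 < r2_hat < 0.72
        maf_hat = marker.mean() / 2
        assert abs(maf_hat - maf) < 0.01

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            ef.ld_marker(np.zeros(3, np.int8), 0.2, 0.0)


@pytest.fixture(scope="module")
def triple_table():
    return ef.three_snp_penetrance(0.2, 0.4, rng=np.random.default_rng(1))


class TestThreeSnpModel:

    def test_all_marginals_flat(self, triple_table):
        K = triple_table.prevalence
        for locus in range(3):
            np.testing.assert_allclose(
                triple_table.marginal_penetrance(locus), K, atol=1e-10)

    def test_collapsing_recovers_base_deviations(self, triple_table):
        """HWE-collapse over the third locus leaves deviations proportional
        (here exactly equal, by the weighted-mean-1 normalization)."""
        g3 = hwe_genotype_freqs(triple_table.mafs[2])
        collapsed = (triple_table.values * g3[None, None, :]).sum(axis=2)
        K = triple_table.prevalence
        dev = triple_table.values - K
        # deviations scale linearly in the third genotype's factor
        c = np.array([dev[i, j, :] / dev[i, j, 1]
                      for i in range(3) for j in range(3)
                      if abs(dev[i, j, 1]) > 1e-12])
        np.testing.assert_allclose(c, np.tile(c[0], (len(c), 1)), atol=1e-8)
        assert np.all(np.diff(c[0]) > 0)  # amplification increases with genotype
        # collapsed deviations are proportional to any third-genotype slice
        cdev = collapsed - K
        slice1 = dev[:, :, 1]
        alpha = (cdev * slice1).sum() / (slice1 * slice1).sum()
        np.testing.assert_allclose(cdev, alpha * slice1, atol=1e-10)

    def test_h2_exceeds_base(self, triple_table):
        assert heritability(triple_table) > 0.2


class TestSampler:
    def test_null_panel(self):
        ds = ef.simulate_null(50, 50, 20, rng_seed=0)
        assert ds.truth is None
        assert ds.n_individuals == 100 and ds.n_snps == 20
        ds.validate()

    def test_case_genotype_frequencies_match_bayes_posterior(self):
        """Empirical case-group causal genotype frequencies match
        P(genotype | case) computed from the penetrance table."""
        rng = np.random.default_rng(2)
        t = ef.pure_epistasis_penetrance(0.4, 0.2, rng=rng)
        spec = ef.SimulationSpec(n_cases=10_000, n_controls=100, n_snps=3,
                                 models=[ef.ModelAssignment(t, (0, 2))], rng_seed=4)
        ds = ef.sample_case_control(spec)
        cases = ds.genotypes[ds.phenotype == 1]
        counts = np.zeros((3, 3))
        for g1, g2 in cases[:, [0, 2]]:
            counts[g1, g2] += 1
        emp = counts / counts.sum()
        w = t.genotype_weights()
        post = w * t.values
        post /= post.sum()
        assert np.abs(emp - post).max() < 0.02

    def test_heterogeneous_composition(self):
        rng = np.random.default_rng(3)
        t1 = ef.pure_epistasis_penetrance(0.4, 0.2, rng=rng)
        t2 = ef.pure_epistasis_penetrance(0.4, 0.2, rng=rng)
        spec = ef.SimulationSpec(
            n_cases=400, n_controls=400, n_snps=50,
            models=[ef.ModelAssignment(t1, (1, 2), subpopulation=0),
                    ef.ModelAssignment(t2, (10, 20), subpopulation=1)],
            composition="heterogeneous", rng_seed=5,
        )
        ds = ef.sample_case_control(spec)
        assert ds.n_individuals == 800
        assert len(ds.truth) == 2
        assert set(ds.truth[0]).isdisjoint(ds.truth[1])

    def test_overlapping_slots_rejected(self):
        rng = np.random.default_rng(6)
        t = ef.pure_epistasis_penetrance(0.2, 0.2, rng=rng)
        with pytest.raises(ValueError):
            ef.SimulationSpec(n_cases=10, n_controls=10, n_snps=10,
                              models=[ef.ModelAssignment(t, (0, 1)),
                                      ef.ModelAssignment(t, (1, 2))])

    def test_seeded_generation_reproducible(self):
        rng = np.random.default_rng(8)
        t = ef.pure_epistasis_penetrance(0.3, 0.4, rng=rng)
        spec = ef.SimulationSpec(n_cases=30, n_controls=30, n_snps=40,
                                 models=[ef.ModelAssignment(t, (5, 6))], rng_seed=9)
        a = ef.sample_case_control(spec)
        b = ef.sample_case_control(spec)
        assert a == b

    def test_generated_datasets_pass_validation(self):
        rng = np.random.default_rng(10)
        t = ef.marchini_odds_table("multiplicative", maf=0.2)
        spec = ef.SimulationSpec(n_cases=50, n_controls=50, n_snps=30,
                                 models=[ef.ModelAssignment(t, (3, 4), r2=0.7)],
                                 rng_seed=11)
        ds = ef.sample_case_control(spec)
        ds.validate()  # raises on any invariant violation
        assert ds.truth == [("snp0003", "snp0004")]
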