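"""Panel statistics: MAF spectrum, heterozygosity, exact/MC HWE,
permutation LD and the Benjamini–Yekutieli procedure, each against an
independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transnp import GenotypeMatrix, by_fdr, heterozygosity, hwe_exact, ld_test, \
    maf_spectrum, neutral_maf, uniform_maf
from transnp.popgen import hwe_enumeration_total

from oracles import by_fdr_bruteforce, hwe_exact_bruteforce


def _matrix(data, pops=None):
    genos = pd.DataFrame(data)
    pops = pd.Series(pops if pops is not None else ["p1"] * len(genos),
                     index=genos.index)
    return GenotypeMatrix(genos, pops)


class TestGenotypeMatrix:
    def test_call_rate_and_low_call_flag(self):
        gm = _matrix({"l1": [0, 1, np.nan, np.nan, np.nan],
                      "l2": [2, 1, 0, np.nan, np.nan]})
        assert gm.call_rate.iloc[0] == 1.0
        assert gm.low_call_samples(0.8) == [2, 3, 4]

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            _matrix({"l1": [0, 3]})


class TestMafSpectrum:
    def test_counting_example(self):
        # AA=9, Aa=2, aa=0 over 11 samples: MAF = 2/22, bin [0.05, 0.10)
        gm = _matrix({"l1": [0] * 9 + [1] * 2})
        spectrum, _ = maf_spectrum(gm)
        assert spectrum.loc[1, "bin"] == "[0.05,0.10)"
        assert spectrum.loc[1, "count"] == 1
        assert spectrum["count"].sum() == 1

    def test_monomorphic_locus_in_lowest_bin(self):
        gm = _matrix({"l1": [0, 0, 0, 0]})
        spectrum, l_shape = maf_spectrum(gm)
        assert spectrum.loc[0, "count"] == 1
        assert l_shape

    def test_uniform_truth_flat_neutral_truth_l_shaped(self, rng):
        from transnp import SimConfig, generate_transcriptome, simulate_genotype_matrix

        def spectrum_of(sampler, seed):
            cfg = SimConfig(n_transcripts=40, transcript_length_range=(1000, 1000),
                            snp_density=10.0, maf_distribution=sampler, seed=seed)
            _, truth = generate_transcriptome(cfg)
            genos, pops = simulate_genotype_matrix(100, truth, cfg, missing_rate=0.0)
            return maf_spectrum(GenotypeMatrix(genos, pops))

        flat_spec, flat_l = spectrum_of(uniform_maf(0.05, 0.5), 5)
        neut_spec, neut_l = spectrum_of(neutral_maf(), 6)
        assert neut_l
        counts = flat_spec["count"].to_numpy()[1:]  # drop the boundary-loss bin
        assert counts.max() < 3 * max(counts.min(), 1)
        neut_counts = neut_spec["count"].to_numpy()
        assert neut_counts[0] == neut_counts.max()


class TestHeterozygosity:
    def test_all_heterozygotes(self):
        gm = _matrix({"l1": [1, 1, 1, 1]})
        out = heterozygosity(gm)
        assert out.H_O.iloc[0] == 1.0
        assert out.H_E.iloc[0] == 0.5

    def test_he_bounded_by_half(self, rng):
        data = {f"l{i}": rng.integers(0, 3, 50).astype(float) for i in range(50)}
        out = heterozygosity(_matrix(data))
        assert (out.H_E <= 0.5 + 1e-12).all()

    def test_unbiased_option_scales(self):
        gm = _matrix({"l1": [0, 1, 1, 2]})
        plain = heterozygosity(gm).H_E.iloc[0]
        unb = heterozygosity(gm, unbiased=True).H_E.iloc[0]
        assert unb == pytest.approx(plain * 4 / 3)

    def test_by_population_rows(self):
        gm = _matrix({"l1": [0, 1, 1, 2]}, pops=["a", "a", "b", "b"])
        out = heterozygosity(gm, by_population=True)
        assert set(out.population) == {"a", "b"}
        assert len(out) == 2


class TestHweExact:
    def test_small_table_enumeration(self):
        # n=4, n_A=4: all heterozygote configurations are no more probable
        # than the observed one, so p = 1
        assert hwe_exact(1, 2, 1)["p"] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            n_aa, n_ab, n_bb = rng.integers(0, 15, 3)
            res = hwe_exact(int(n_aa), int(n_ab), int(n_bb))
            if res.get("skipped"):
                continue
            brute = hwe_exact_bruteforce(int(n_aa), int(n_ab), int(n_bb))
            assert res["p"] == pytest.approx(brute, abs=1e-10)

    def test_hw_proportioned_sample_not_significant(self):
        # 100 samples at p=0.5 in perfect proportions: 25/50/25
        assert hwe_exact(25, 50, 25)["p"] > 0.5

    def test_monomorphic_skipped(self):
        assert hwe_exact(10, 0, 0)["skipped"]

    def test_enumeration_sums_to_one(self):
        for n in (2, 5, 10, 25, 60):
            for n_a in range(0, 2 * n + 1, max(1, n // 3)):
                assert hwe_enumeration_total(n, n_a) == pytest.approx(1.0, abs=1e-12)

    def test_mc_mode_agrees_with_enumeration(self):
        exact = hwe_exact(6, 3, 6)["p"]
        mc = hwe_exact(6, 3, 6, mode="mc", iterations=10_000, batches=20, seed=5)
        assert abs(mc["p"] - exact) <= 3 * max(mc["se"], 1e-3)


class TestLdTest:
    def test_identical_loci_minimal_p(self, rng):
        g = rng.integers(0, 3, 60).astype(float)
        res = ld_test(g, g, mc_iterations=2000, batches=20, seed=1)
        assert res["p"] <= 1 / 2000

    def test_swap_symmetry(self, rng):
        g1 = rng.integers(0, 3, 40).astype(float)
        g2 = rng.integers(0, 3, 40).astype(float)
        r12 = ld_test(g1, g2, mc_iterations=500, batches=10, seed=9)
        r21 = ld_test(g2, g1, mc_iterations=500, batches=10, seed=9)
        assert r12["p"] == r21["p"]
        assert r12["g"] == pytest.approx(r21["g"])

    def test_type_one_error_rate(self, rng):
        # independent loci: rejection rate at alpha=0.05 within 3 binomial SD
        n_pairs, n_samples = 120, 100
        rejections = 0
        for i in range(n_pairs):
            g1 = rng.binomial(2, 0.3, n_samples).astype(float)
            g2 = rng.binomial(2, 0.4, n_samples).astype(float)
            res = ld_test(g1, g2, mc_iterations=400, batches=10, seed=100 + i)
            rejections += res["p"] <= 0.05
        rate = rejections / n_pairs
        sd = np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate - 0.05) < 3 * sd + 1e-9

    def test_missing_dropped_pairwise(self, rng):
        g1 = np.array([0, 1, 2, np.nan, 1, 0, 2, 1] * 5, dtype=float)
        g2 = np.array([1, np.nan, 0, 2, 1, 0, 1, 2] * 5, dtype=float)
        res = ld_test(g1, g2, mc_iterations=200, batches=10, seed=2)
        assert 0 < res["p"] <= 1


class TestByFdr:
    def test_single_pvalue_threshold_is_alpha(self):
        assert by_fdr([0.04], alpha=0.05)[0]
        assert not by_fdr([0.06], alpha=0.05)[0]

    def test_hand_computed_example(self):
        # m=3, c(3)=1.8333: only 0.001 <= 1*0.05/(3*1.8333)=0.00909 passes
        flags = by_fdr([0.001, 0.2, 0.9], alpha=0.05)
        assert flags.tolist() == [True, False, False]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=60),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_bruteforce_on_random_vectors(self, ps, alpha):
        assert np.array_equal(by_fdr(ps, alpha), by_fdr_bruteforce(ps, alpha))

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200) ** 2
        ours = by_fdr(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_by")[0]
        assert np.array_equal(ours, ref)

    def test_monotone_lowering_p_never_removes_rejections(self, rng):
        p = rng.uniform(0, 1, 40)
        base = by_fdr(p, alpha=0.05)
        p2 = p.copy()
        p2[np.argmax(p)] = 0.0
        after = by_fdr(p2, alpha=0.05)
        unchanged = p2 == p
        assert np.all(after[unchanged] >= base[unchanged])
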