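import math

import numpy as np
import pytest

from helpers import ewens_k_pmf, ewens_partition_prob, fisher_two_sided, partitions

from domainsel.alignments import CodonAlignment
from domainsel.diversity import SiteFrequencySpectrum, harmonic
from domainsel.neutrality import (
    MKTable,
    coalescent_pvalue,
    ewens_conditional_exact,
    ewens_k_distribution,
    ewens_watterson,
    fay_wu_h,
    fu_li_d_f,
    fus_fs,
    homozygosity,
    mk_table_from_alignment,
    mk_test,
    normalized_h,
    sample_ewens_partition,
    significance_stars,
    tajimas_d,
)


class TestTajima:
    def test_worked_example(self):
        # n=4, S=2, k_hat=7/6
        res = tajimas_d(4, 2, 7 / 6)
        assert res.value == pytest.approx(0.5916, abs=2e-4)

    def test_monomorphic_undefined(self):
        res = tajimas_d(10, 0, 0.0)
        assert res.value is None
        assert not res.defined

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(3, 2, 1.0)

    def test_sign_behavior(self):
        # excess rare variants -> negative; intermediate frequencies -> positive
        n, S = 10, 8
        low = tajimas_d(n, S, 8 * (1 * 9) / 45).value  # all singletons
        high = tajimas_d(n, S, 8 * (5 * 5) / 45).value  # all at frequency 5
        assert low < 0 < high

    def test_zero_when_pi_matches_watterson(self):
        n, S = 12, 7
        assert tajimas_d(n, S, S / harmonic(n)).value == pytest.approx(0.0)


class TestFuLi:
    def test_undefined_without_mutations(self):
        d, f = fu_li_d_f(6, 0, 0, 0.0)
        assert d.value is None and f.value is None

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fu_li_d_f(3, 2, 1, 1.0)

    def test_singleton_excess_negative(self):
        # all 10 mutations on external branches
        d, f = fu_li_d_f(10, 10, 10, 10 * (1 * 9) / 45)
        assert d.value < 0
        assert f.value < 0

    def test_no_singletons_positive_d(self):
        d, _ = fu_li_d_f(10, 10, 0, 10 * (5 * 5) / 45)
        assert d.value > 0

    def test_d_zero_at_expectation(self):
        # eta = a1 * eta_e makes the D numerator vanish (up to integer rounding)
        n = 8
        eta_e = 3
        eta = int(round(harmonic(n) * eta_e))
        d, _ = fu_li_d_f(n, eta, eta_e, 1.0)
        assert abs(d.value) < 0.25


class TestFusFs:
    def test_k_distribution_matches_enumeration(self):
        for n, theta in ((5, 0.7), (7, 2.3), (8, 5.0)):
            ours = ewens_k_distribution(n, theta)
            oracle = ewens_k_pmf(n, theta)
            for k in range(1, n + 1):
                assert ours[k] == pytest.approx(oracle.get(k, 0.0), abs=1e-12)
            assert ours.sum() == pytest.approx(1.0)

    def test_expected_k_identity(self):
        n, theta = 20, 3.7
        pk = ewens_k_distribution(n, theta)
        e_k = float(np.sum(np.arange(n + 1) * pk))
        assert e_k == pytest.approx(sum(theta / (theta + i) for i in range(n)))

    def test_fs_against_enumeration(self):
        n, k_hat, k_haps = 8, 2.5, 6
        res = fus_fs(n, k_hat, k_haps)
        pmf = ewens_k_pmf(n, k_hat)
        s_prime = sum(p for k, p in pmf.items() if k >= k_haps)
        assert res.value == pytest.approx(math.log(s_prime / (1 - s_prime)), rel=1e-9)

    def test_many_haplotypes_negative(self):
        assert fus_fs(20, 2.0, 15).value < 0

    def test_few_haplotypes_positive(self):
        assert fus_fs(20, 5.0, 2).value > 0

    def test_undefined_without_diversity(self):
        assert fus_fs(10, 0.0, 1).value is None


class TestFayWuZeng:
    def test_worked_example(self):
        spec = SiteFrequencySpectrum(n=4, counts=(1, 1, 0))
        res = fay_wu_h(spec, spec.theta_pi())
        assert res.value == pytest.approx(1 / 3)

    def test_high_frequency_derived_negative(self):
        n = 10
        counts = [0] * (n - 1)
        counts[n - 2] = 6  # six mutations at derived frequency n-1
        spec = SiteFrequencySpectrum(n=n, counts=tuple(counts))
        assert fay_wu_h(spec, spec.theta_pi()).value < 0
        assert normalized_h(spec, spec.total).value < 0

    def test_singletons_positive(self):
        n = 10
        counts = [0] * (n - 1)
        counts[0] = 6
        spec = SiteFrequencySpectrum(n=n, counts=tuple(counts))
        assert fay_wu_h(spec, spec.theta_pi()).value > 0
        assert normalized_h(spec, spec.total).value > 0

    def test_monomorphic(self):
        spec = SiteFrequencySpectrum(n=6, counts=(0,) * 5)
        assert fay_wu_h(spec, 0.0).value == 0.0
        assert normalized_h(spec, 0).value is None

    def test_normalized_h_is_standardized(self):
        # across many neutral samples the normalized statistic should have
        # roughly zero mean and unit-scale spread
        from domainsel.coalsim import ScenarioConfig, replicate_summaries

        rng = np.random.default_rng(7)
        config = ScenarioConfig(scenario="neutral", n=20, theta=None, fixed_S=12, L=100)
        sims = replicate_summaries(config, 1500, rng)
        values = [
            normalized_h(r.sfs, r.S).value for r in sims if r.S > 0
        ]
        values = np.array([v for v in values if v is not None])
        assert abs(values.mean()) < 0.15
        assert 0.5 < values.std() < 1.5


class TestEwensWatterson:
    def test_homozygosity_example(self):
        assert homozygosity((2, 1, 1)) == pytest.approx(0.375)

    def test_exact_distribution_is_theta_free_and_valid(self):
        dist = ewens_conditional_exact(6, 3)
        assert sum(p for _, p in dist) == pytest.approx(1.0)
        # oracle: same conditional from the full Ewens formula at any theta
        for theta in (0.5, 3.0):
            pmf = {
                part: ewens_partition_prob(part, theta)
                for part in partitions(6)
                if len(part) == 3
            }
            total = sum(pmf.values())
            for part, p in dist:
                assert p == pytest.approx(pmf[part] / total, rel=1e-9)

    def test_exact_pvalues(self):
        res = ewens_watterson([2, 1, 1])
        assert res.value == pytest.approx(0.375)
        assert res.p_source == "ewens_exact"
        # partitions of 4 into 3 parts: only (2,1,1); both tails are 1
        assert res.extras["p_lower"] == pytest.approx(1.0)
        assert res.extras["p_upper"] == pytest.approx(1.0)

    def test_exact_two_configurations(self):
        # n=5, k=2: partitions (4,1) F=0.68 and (3,2) F=0.52
        dist = dict(
            (part, p) for part, p in ewens_conditional_exact(5, 2)
        )
        res = ewens_watterson([3, 2])
        assert res.p_value == pytest.approx(dist[(3, 2)])  # lower tail
        assert res.extras["p_upper"] == pytest.approx(1.0)

    def test_sampler_matches_exact(self):
        counts = [4, 2, 1, 1]
        exact = ewens_watterson(counts)
        sampled = ewens_watterson(counts, reps=4000, seed=11, exact_limit=2)
        assert sampled.p_source == "ewens_null"
        assert sampled.value == exact.value
        assert sampled.extras["p_lower"] == pytest.approx(
            exact.extras["p_lower"], abs=0.04
        )
        assert sampled.extras["p_upper"] == pytest.approx(
            exact.extras["p_upper"], abs=0.04
        )

    def test_sampler_deterministic(self):
        a = ewens_watterson([5, 3, 2, 1, 1], reps=500, seed=3, exact_limit=2)
        b = ewens_watterson([5, 3, 2, 1, 1], reps=500, seed=3, exact_limit=2)
        assert a.p_value == b.p_value

    def test_degenerate_single_class(self):
        res = ewens_watterson([7])
        assert res.value == pytest.approx(1.0)
        assert res.extras["degenerate"]

    def test_crp_partition_properties(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            part = sample_ewens_partition(9, 1.5, rng)
            assert sum(part) == 9
            assert list(part) == sorted(part, reverse=True)


class TestMK:
    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            table = MKTable(Dn=a, Ds=b, Pn=c, Ps=d)
            res = mk_test(table)
            if res.p_value is None:
                assert (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0
                continue
            assert res.p_value == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-9)

    def test_neutrality_index(self):
        res = mk_test(MKTable(Dn=2, Ds=10, Pn=6, Ps=6))
        assert res.value == pytest.approx((6 / 6) / (2 / 10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MKTable(Dn=-1, Ds=0, Pn=0, Ps=0)

    def test_table_from_alignment(self):
        # codon 1 AAA fixed vs outgroup GAA (nonsyn substitution)
        # codon 2 polymorphic TTT/TTC (synonymous polymorphism)
        # codon 3 CCC fixed vs outgroup CCG (synonymous substitution)
        aln = CodonAlignment(
            (
                ("a", "AAATTTCCC"),
                ("b", "AAATTCCCC"),
                ("out", "GAATTTCCG"),
            ),
            outgroup_id="out",
        )
        table = mk_table_from_alignment(aln)
        assert table == MKTable(Dn=1, Ds=1, Pn=0, Ps=1)

    def test_table_needs_outgroup(self, toy_alignment):
        with pytest.raises(ValueError):
            mk_table_from_alignment(toy_alignment)


class TestCoalescentPvalue:
    def test_deterministic(self):
        a = coalescent_pvalue("TajimaD", -1.5, 20, 10, reps=300, seed=9)
        b = coalescent_pvalue("TajimaD", -1.5, 20, 10, reps=300, seed=9)
        assert a == b

    def test_bounds_and_floor(self):
        # an impossible observation hits the 2/(reps+1) floor
        p_extreme = coalescent_pvalue("TajimaD", -50.0, 20, 10, reps=300, seed=1)
        assert p_extreme == pytest.approx(2 / 301, abs=1e-9)
        p_central = coalescent_pvalue("TajimaD", 0.0, 20, 10, reps=300, seed=1)
        assert p_central > 0.2
        assert p_central <= 1.0

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            coalescent_pvalue("TajimaD", 0.0, 20, 10, reps=50)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            coalescent_pvalue("NotAStat", 0.0, 20, 10, reps=100, seed=0)

    def test_all_statistics_supported(self):
        for stat in ("TajimaD", "FuLiD", "FuLiF", "FuFs", "FayWuH", "nH"):
            p = coalescent_pvalue(stat, 0.0, 12, 8, reps=120, seed=4)
            assert 0 < p <= 1


def test_significance_stars():
    assert significance_stars(None) == ""
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
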