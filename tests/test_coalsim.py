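import math

import numpy as np
import pytest

from domainsel._codon_tables import AA, STOPS
from domainsel.coalsim import (
    GenealogySample,
    ScenarioConfig,
    make_haplotype_fixture,
    neutral_config_matching,
    neutral_syn_fraction,
    place_mutations,
    replicate_summaries,
    sample_genealogy,
    simulate,
    simulate_with_truth,
)
from domainsel.diversity import harmonic, haplotype_counts, sfs, summarize


class TestConfig:
    def test_theta_xor_fixed_s(self):
        with pytest.raises(ValueError):
            ScenarioConfig(theta=None, fixed_S=None)
        with pytest.raises(ValueError):
            ScenarioConfig(theta=5.0, fixed_S=10)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="bottleneck")

    def test_bounds(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n=1)
        with pytest.raises(ValueError):
            ScenarioConfig(syn_fraction=1.5)


class TestGenealogy:
    def test_branch_accounting(self, rng):
        for scenario in ("neutral", "expansion", "balanced_split", "star_sweep"):
            gen = sample_genealogy(ScenarioConfig(scenario=scenario, n=12), rng)
            # a binary coalescent history records 2(n-1) finished branches
            assert len(gen.masks) == 2 * (12 - 1)
            assert all(length >= 0 for length in gen.lengths)
            assert gen.tmrca > 0
            # every branch subtends a proper non-empty subset of leaves
            full = (1 << 12) - 1
            for m in gen.masks:
                assert 0 < m < full
            # the two root children partition the leaf set
            assert gen.masks[-1] | gen.masks[-2] == full
            assert gen.masks[-1] & gen.masks[-2] == 0

    def test_derived_and_haplotype_counts(self):
        # hand-built genealogy on 3 leaves: branches {0}, {1}, {0,1}, {2}
        gen = GenealogySample(
            n=3,
            masks=[0b001, 0b010, 0b011, 0b100],
            lengths=[1.0, 1.0, 0.5, 1.5],
            tmrca=1.5,
            mutation_branches=[0, 2, 2],
        )
        assert gen.derived_counts() == [1, 2, 2]
        # leaf 2 separated from {0,1}; leaf 0 further split by its singleton
        assert gen.haplotype_counts() == [1, 1, 1]
        gen.mutation_branches = [2]
        assert gen.haplotype_counts() == [2, 1]

    def test_fixed_s_places_exact_count(self, rng):
        config = ScenarioConfig(n=10, theta=None, fixed_S=17)
        gen = place_mutations(sample_genealogy(config, rng), config, rng)
        assert len(gen.mutation_branches) == 17

    def test_star_sweep_escape(self, rng):
        config = ScenarioConfig(scenario="star_sweep", n=20, sweep_age=0.05)
        gen = sample_genealogy(config, rng)
        # one branch subtends the whole swept class of n-1 leaves
        sizes = [bin(m).count("1") for m in gen.masks]
        assert max(sizes) == 19


class TestSimulate:
    def test_deterministic(self):
        config = ScenarioConfig(n=8, theta=5.0, L=60, seed=123)
        a, ta = simulate_with_truth(config)
        b, tb = simulate_with_truth(config)
        assert a.records == b.records
        assert ta == tb

    def test_shape_and_outgroup(self):
        config = ScenarioConfig(n=8, theta=5.0, L=60, seed=1)
        aln = simulate(config)
        assert aln.n == 9
        assert aln.outgroup_id == "outgroup"
        assert aln.length == 60
        assert len(aln.ingroup()) == 8

    def test_truth_matches_alignment(self):
        config = ScenarioConfig(n=10, theta=8.0, L=90, seed=7, outgroup_divergence=0.0)
        aln, truth = simulate_with_truth(config)
        ingroup = [s for _, s in aln.ingroup()]
        backbone = aln.sequence("outgroup")  # zero divergence: outgroup = ancestor
        assert truth["outgroup_sites"] == []
        for site, alt, count, label in zip(
            truth["sites"], truth["derived_bases"], truth["derived_counts"],
            truth["site_classes"],
        ):
            carriers = sum(1 for s in ingroup if s[site] == alt)
            assert carriers == count
            assert alt != backbone[site]
            # verify the synonymous/non-synonymous label against the backbone
            codon_idx, pos = divmod(site, 3)
            if codon_idx < config.L // 3:
                ref = backbone[3 * codon_idx : 3 * codon_idx + 3]
                mut = ref[:pos] + alt + ref[pos + 1 :]
                assert mut not in STOPS
                expected = "syn" if AA[mut] == AA[ref] else "nonsyn"
                assert label == expected

    def test_infinite_sites(self):
        config = ScenarioConfig(n=20, theta=None, fixed_S=40, L=300, seed=3)
        _, truth = simulate_with_truth(config)
        assert len(set(truth["sites"])) == len(truth["sites"]) == 40

    def test_fixed_s_exceeding_sites_rejected(self):
        config = ScenarioConfig(n=4, theta=None, fixed_S=100, L=30, seed=0)
        with pytest.raises(ValueError, match="mutable sites"):
            simulate_with_truth(config)

    def test_polarization_recovers_truth(self):
        # perfect outgroup: the polarized SFS equals the generator's counts
        config = ScenarioConfig(n=12, theta=6.0, L=240, seed=11,
                                outgroup_divergence=0.0)
        aln, truth = simulate_with_truth(config)
        spec = sfs(aln)
        observed = [0] * (config.n - 1)
        for d in truth["derived_counts"]:
            observed[d - 1] += 1
        assert list(spec.counts) == observed

    def test_syn_fraction_extremes(self):
        for sf, expected in ((1.0, "syn"), (0.0, "nonsyn")):
            config = ScenarioConfig(n=6, theta=4.0, L=300, seed=5, syn_fraction=sf)
            _, truth = simulate_with_truth(config)
            if truth["S"]:
                assert set(truth["site_classes"]) <= {expected}

    def test_no_stops_in_ingroup(self):
        config = ScenarioConfig(n=10, theta=10.0, L=120, seed=9)
        aln, _ = simulate_with_truth(config)
        for rid, seq in aln.ingroup():
            for j in range(0, 120, 3):
                assert seq[j : j + 3] not in STOPS


class TestMoments:
    def test_expected_s_and_k(self, rng):
        # E[S] = theta * a1(n), E[k_hat] = theta
        n, theta, reps = 10, 5.0, 800
        sims = replicate_summaries(ScenarioConfig(n=n, theta=theta), reps, rng)
        S = np.array([r.S for r in sims], dtype=float)
        k = np.array([r.k_hat for r in sims])
        se_S = S.std(ddof=1) / math.sqrt(reps)
        se_k = k.std(ddof=1) / math.sqrt(reps)
        assert abs(S.mean() - theta * harmonic(n)) < 4 * se_S
        assert abs(k.mean() - theta) < 4 * se_k

    def test_summary_internal_consistency(self, rng):
        sims = replicate_summaries(
            ScenarioConfig(n=8, theta=4.0), 50, rng, haplotypes=True
        )
        for r in sims:
            assert r.S == sum(r.sfs_counts)
            assert r.eta_e == r.sfs_counts[0]
            k_from_sfs = sum(
                c * i * (8 - i) for i, c in enumerate(r.sfs_counts, start=1)
            ) / (8 * 7 / 2)
            assert r.k_hat == pytest.approx(k_from_sfs)
            assert 1 <= r.k_haps <= 8

    def test_sequences_match_genealogy_summaries(self):
        # the emitted alignment reproduces the genealogy-level statistics
        config = ScenarioConfig(n=10, theta=6.0, L=600, seed=21,
                                outgroup_divergence=0.0)
        aln, truth = simulate_with_truth(config)
        d = summarize(aln)
        assert d.S == truth["S"]  # infinite sites: every mutation is a site
        n = config.n
        k_from_truth = sum(c * (n - c) for c in truth["derived_counts"]) / (
            n * (n - 1) / 2
        )
        assert d.k_hat == pytest.approx(k_from_truth)
        assert len(haplotype_counts(aln)) == d.k_haps

    def test_msprime_cross_check(self):
        # independent simulator: same n and theta give compatible mean S and pi
        import msprime

        n, theta, reps = 10, 5.0, 600
        rng = np.random.default_rng(17)
        ours = replicate_summaries(ScenarioConfig(n=n, theta=theta), reps, rng)
        our_S = np.array([r.S for r in ours], dtype=float)
        our_k = np.array([r.k_hat for r in ours])

        ms_S, ms_k = [], []
        # with ploidy=1 and population_size=1 msprime's pairwise coalescence
        # rate is 1, matching our timescale, so the mutation rate is theta/2
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n, ploidy=1, sequence_length=1, population_size=1,
                num_replicates=reps, random_seed=17,
            )
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2.0, random_seed=i + 1, discrete_genome=False,
            )
            ms_S.append(mts.num_sites)
            ms_k.append(mts.diversity(span_normalise=False))
        ms_S = np.array(ms_S)
        ms_k = np.array(ms_k)
        se = math.sqrt(our_S.var() / reps + ms_S.var() / reps)
        assert abs(our_S.mean() - ms_S.mean()) < 4 * se
        se_k = math.sqrt(our_k.var() / reps + ms_k.var() / reps)
        assert abs(our_k.mean() - ms_k.mean()) < 4 * se_k


class TestScenarioShapes:
    def test_expansion_shallower_than_neutral(self, rng):
        neutral = [
            sample_genealogy(ScenarioConfig(n=20), rng).tmrca for _ in range(300)
        ]
        expanded = [
            sample_genealogy(ScenarioConfig(scenario="expansion", n=20), rng).tmrca
            for _ in range(300)
        ]
        assert np.mean(expanded) < 0.5 * np.mean(neutral)

    def test_balanced_split_deeper_than_neutral(self, rng):
        config = ScenarioConfig(scenario="balanced_split", n=20)
        tmrcas = [sample_genealogy(config, rng).tmrca for _ in range(300)]
        # the two demes cannot merge before the split time
        assert min(tmrcas) >= config.split_time

    def test_star_sweep_tmrca_floor(self, rng):
        config = ScenarioConfig(scenario="star_sweep", n=20)
        gen = sample_genealogy(config, rng)
        assert gen.tmrca >= config.sweep_age


class TestHelpers:
    def test_neutral_config_matching(self):
        config = neutral_config_matching(10, 14.145)
        assert config.theta == pytest.approx(14.145 / harmonic(10))

    def test_neutral_syn_fraction_range(self):
        sf = neutral_syn_fraction()
        assert 0.2 < sf < 0.3

    def test_make_haplotype_fixture(self):
        records, truth = make_haplotype_fixture(
            [("A", ["F", "L"], 2), ("B", ["L", "V/I"], 1)],
            positions=[3, 5],
            backbone_length=8,
        )
        assert len(records) == 3
        seqs = dict(records)
        assert seqs["A_1"] == "AAFALAAA"
        assert seqs["B_1"] == "AALAVAAA"  # ambiguity keeps the first residue
        assert truth == {"A": ["A_1", "A_2"], "B": ["B_1"]}

    def test_fixture_validation(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_haplotype_fixture(
                [("A", ["F"], 1), ("A", ["L"], 1)], positions=[1]
            )
        with pytest.raises(ValueError, match="mismatch"):
            make_haplotype_fixture([("A", ["F", "L"], 1)], positions=[1])
        with pytest.raises(ValueError, match="count"):
            make_haplotype_fixture([("A", ["F"], 0)], positions=[1])
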