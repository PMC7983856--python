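import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matingkit.mating import (
    EstimationError,
    MixedMatingModel,
    PollenPool,
    build_pollen_pool,
    estimate_population,
    infer_maternal_genotype,
    outcross_offspring_prob,
    self_offspring_prob,
)
from matingkit.simulate import SimulationConfig, simulate_population, simulate_progeny_arrays

from .conftest import make_array, make_pollen


class TestSelfKernel:
    @pytest.mark.parametrize(
        "mother,offspring,expected",
        [
            ((1, 1), (1, 1), 1.0),
            ((1, 2), (1, 1), 0.25),
            ((1, 2), (2, 2), 0.25),
            ((1, 2), (1, 2), 0.5),
            ((1, 2), (1, 3), 0.0),
            ((1, 1), (1, 2), 0.0),
        ],
    )
    def test_enumerated_values(self, mother, offspring, expected):
        assert self_offspring_prob(offspring, mother) == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.tuples(st.integers(1, 6), st.integers(1, 6)))
    def test_distribution_normalised(self, mother):
        alleles = sorted(set(mother))
        total = sum(
            self_offspring_prob((a, b), mother)
            for i, a in enumerate(alleles)
            for b in alleles[i:]
        )
        assert total == pytest.approx(1.0)


class TestOutcrossKernel:
    @pytest.mark.parametrize(
        "mother,pollen,offspring,expected",
        [
            ((1, 1), {1: 0.7, 2: 0.3}, (1, 2), 0.3),
            ((1, 2), {1: 0.5, 2: 0.5}, (1, 1), 0.25),
            ((1, 1), {1: 0.5, 2: 0.5}, (2, 2), 0.0),
            ((1, 2), {1: 0.2, 2: 0.3, 3: 0.5}, (2, 3), 0.25),
        ],
    )
    def test_enumerated_values(self, mother, pollen, offspring, expected):
        assert outcross_offspring_prob(offspring, mother, pollen) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.tuples(st.integers(1, 5), st.integers(1, 5)), st.integers(0, 10_000))
    def test_distribution_normalised(self, mother, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(5))
        pollen = {a + 1: float(v) for a, v in enumerate(p)}
        alleles = range(1, 6)
        total = sum(
            outcross_offspring_prob((a, b), mother, pollen)
            for a in alleles
            for b in alleles
            if a <= b
        )
        assert total == pytest.approx(1.0)


class TestPollenPool:
    def test_smoothing_covers_offspring_alleles(self):
        arr = make_array([[(1, 2)], [(2, 2)]])
        pool = build_pollen_pool([arr], [np.array([[1, 1]])])
        assert pool.freqs[0][2] > 0

    def test_equal_mothers(self):
        arr = make_array([[(1, 1)], [(2, 2)]])
        pool = build_pollen_pool([arr], [np.array([[1, 1]]), np.array([[2, 2]])], smoothing=0.0)
        assert pool.freqs[0] == {1: 0.5, 2: 0.5}

    def test_frequencies_sum_to_one(self, rng):
        sim = simulate_population(SimulationConfig(seed=8, n_families=5, n_progeny=10))
        pool = build_pollen_pool(sim.arrays, list(sim.maternal_genotypes))
        for f in pool.freqs:
            assert sum(f.values()) == pytest.approx(1.0)


class TestMaternalInference:
    def test_all_homozygous_offspring(self):
        arr = make_array([[(1, 1)]] * 20)
        pool = make_pollen([{1: 0.5, 2: 0.5}])
        geno, w = infer_maternal_genotype(arr, pool)
        assert geno[0].tolist() == [1, 1]

    def test_heterozygote_beats_homozygotes(self):
        # both homozygote classes present among offspring: only a 1/2
        # mother explains them under selfing
        off = [[(1, 1)]] * 5 + [[(2, 2)]] * 5 + [[(1, 2)]] * 10
        arr = make_array(off)
        pool = make_pollen([{1: 0.5, 2: 0.5}])
        geno, _ = infer_maternal_genotype(arr, pool)
        assert geno[0].tolist() == [1, 2]

    def test_provided_genotype_bypasses_inference(self):
        arr = make_array([[(1, 2)]], maternal=[[2, 3]])
        pool = make_pollen([{1: 0.4, 2: 0.3, 3: 0.3}])
        geno, w = infer_maternal_genotype(arr, pool)
        assert geno[0].tolist() == [2, 3]
        assert w[0] == 1.0

    def test_all_missing_locus_stays_missing(self):
        arr = make_array([[(0, 0), (1, 1)], [(0, 0), (1, 2)]])
        pool = make_pollen([{1: 1.0}, {1: 0.5, 2: 0.5}])
        geno, w = infer_maternal_genotype(arr, pool)
        assert geno[0].tolist() == [0, 0]
        assert np.isnan(w[0])

    def test_recovers_true_mothers_mostly(self):
        sim = simulate_population(
            SimulationConfig(seed=21, n_families=10, n_progeny=20, n_loci=6, selfing_intercept=0.0)
        )
        pool = PollenPool(
            [f"L{j + 1}" for j in range(6)],
            [{a + 1: float(p) for a, p in enumerate(f)} for f in sim.truth.allele_freqs],
        )
        correct = total = 0
        for i, arr in enumerate(sim.arrays):
            geno, _ = infer_maternal_genotype(arr, pool)
            correct += (geno == sim.maternal_genotypes[i]).all(axis=1).sum()
            total += geno.shape[0]
        assert correct / total > 0.85


class TestEM:
    def test_forced_outcross(self):
        # every offspring carries a non-maternal allele at locus 1
        arr = make_array([[(1, 3)]] * 10, maternal=[[1, 2]])
        pool = make_pollen([{1: 0.3, 2: 0.3, 3: 0.4}])
        res = MixedMatingModel(arr, pool).fit()
        assert res.s == 0.0 and res.tm == 1.0

    def test_flat_likelihood_not_identifiable(self):
        # mother {A,B} with pollen 1/2-1/2: selfing and outcross kernels
        # coincide for every offspring genotype, so the likelihood is flat
        off = [[(1, 1)]] * 5 + [[(1, 2)]] * 10 + [[(2, 2)]] * 5
        arr = make_array(off, maternal=[[1, 2]])
        pool = make_pollen([{1: 0.5, 2: 0.5}])
        res = MixedMatingModel(arr, pool).fit(s_init=0.37)
        assert not res.identifiable
        assert res.s == pytest.approx(0.37, abs=1e-6)  # stays at s_init

    def test_monotone_loglik(self, rng):
        sim = simulate_population(SimulationConfig(seed=13, n_families=8, n_progeny=20))
        _, pool, results = estimate_population(sim.arrays)
        for res in results:
            assert np.all(np.diff(res._ll_path) >= -1e-9)

    def test_grid_oracle_single_family(self):
        sim = simulate_population(
            SimulationConfig(seed=2, n_families=1, n_progeny=20, n_loci=6, alleles_per_locus=5,
                             selfing_intercept=0.85, selfing_slope=0.0)
        )
        pool = PollenPool(
            [f"L{j + 1}" for j in range(6)],
            [{a + 1: float(p) for a, p in enumerate(f)} for f in sim.truth.allele_freqs],
        )
        m = MixedMatingModel(sim.arrays[0], pool, maternal=sim.maternal_genotypes[0])
        res = m.fit()
        grid = np.arange(0, 1.0001, 0.001)
        ll = [m.loglike(s) for s in grid]
        assert res.s == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)
        assert res.log_likelihood >= max(ll) - 1e-9

    def test_mismatch_locus_demoted_and_counted(self):
        # offspring 2 has no maternal allele at locus 1 -> locus ignored
        arr = make_array([[(1, 2), (1, 1)], [(3, 3), (1, 1)]], maternal=[[1, 2], [1, 1]])
        pool = make_pollen([{1: 0.3, 2: 0.3, 3: 0.4}, {1: 1.0}])
        model = MixedMatingModel(arr, pool)
        assert model.n_mismatch_loci == 1
        assert model.fit().n_offspring_used == 2

    def test_no_informative_offspring_raises(self):
        arr = make_array([[(3, 3)]], maternal=[[1, 2]])
        pool = make_pollen([{1: 0.3, 2: 0.3, 3: 0.4}])
        with pytest.raises(EstimationError):
            MixedMatingModel(arr, pool).fit()

    def test_boundary_estimates_reachable(self):
        # several families so the pollen pool is informative; the fully
        # selfed and fully outcrossed families must hit exact 1 and 0
        sim = simulate_population(SimulationConfig(seed=6, n_families=6, n_progeny=20, n_loci=6))
        s_true = np.array([1.0, 0.0, 0.5, 0.3, 0.7, 0.2])
        arrays = simulate_progeny_arrays(
            sim.config, sim.maternal_genotypes, s_true, sim.truth.allele_freqs,
            np.random.default_rng(3),
        )
        df, _, _ = estimate_population(arrays)
        assert df.loc[0, "s"] == 1.0
        assert df.loc[1, "s"] == 0.0


class TestBootstrap:
    def test_single_replicate_se_absent(self):
        arr = make_array([[(1, 2)]] * 5, maternal=[[1, 2]])
        pool = make_pollen([{1: 0.7, 2: 0.3}])
        res = MixedMatingModel(arr, pool).fit().bootstrap(B=1, seed=0)
        assert res.bootstrap_se is None

    def test_degenerate_family_zero_se(self):
        arr = make_array([[(1, 3)]] * 12, maternal=[[1, 2]])
        pool = make_pollen([{1: 0.3, 2: 0.3, 3: 0.4}])
        res = MixedMatingModel(arr, pool).fit().bootstrap(B=50, seed=0)
        assert res.bootstrap_se == 0.0
        assert res.ci_low == res.ci_high == 1.0

    def test_bootstrap_reproducible(self):
        sim = simulate_population(SimulationConfig(seed=30, n_families=1, n_progeny=20))
        pool = PollenPool(
            [f"L{j + 1}" for j in range(sim.config.n_loci)],
            [{a + 1: float(p) for a, p in enumerate(f)} for f in sim.truth.allele_freqs],
        )
        m = MixedMatingModel(sim.arrays[0], pool, maternal=sim.maternal_genotypes[0])
        r1 = m.fit().bootstrap(B=60, seed=5)
        r2 = m.fit().bootstrap(B=60, seed=5)
        assert r1.bootstrap_se == r2.bootstrap_se
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestPopulationDriver:
    def test_locus_subset_accepted(self):
        """A population that lost one locus (all-missing column) estimates fine."""
        sim = simulate_population(SimulationConfig(seed=31, n_families=4, n_progeny=15, n_loci=6))
        for arr in sim.arrays:
            arr.offspring[:, 5, :] = 0  # locus G8-like failure
        df, _, _ = estimate_population(sim.arrays)
        assert len(df) == 4
        assert df["s"].between(0, 1).all()

    def test_summary_mentions_family(self):
        sim = simulate_population(SimulationConfig(seed=32, n_families=1, n_progeny=10))
        _, _, results = estimate_population(sim.arrays, bootstrap=30, seed=0)
        text = results[0].summary()
        assert "F01" in text and "bootstrap SE" in text
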