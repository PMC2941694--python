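"""Chromosome codec, genetic operators, penalty and the evolution loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrinet._seeds import derive_seed
from nutrinet.encoding import encode
from nutrinet.evaluation import make_3cv
from nutrinet.ga import (
    Codec,
    FitnessCache,
    GAConfig,
    apply_penalty,
    decode,
    election,
    encode_chromosome,
    evaluate_chromosome,
    evolve,
    mutate,
    roulette_select,
    two_point_crossover,
)
from nutrinet.synthetic import SimSpec, simulate


class TestCodec:
    def test_study_layout_is_76_bits(self):
        codec = Codec()  # 63 factors
        assert codec.length == 76 == 63 + 4 + 3 + 4 + 2

    def test_all_ones_mask_selects_everything(self):
        codec = Codec()
        factors, _ = decode(np.ones(76, dtype=np.uint8), codec)
        assert factors.size == 63

    def test_hidden_code_zero_is_one_neuron(self):
        codec = Codec()
        bits = np.zeros(76, dtype=np.uint8)
        bits[0] = 1
        _, hyper = decode(bits, codec)
        assert hyper["n_hidden"] == 1

    def test_hidden_codes_cover_1_to_16(self):
        codec = Codec()
        seen = set()
        for code in range(16):
            bits = np.zeros(76, dtype=np.uint8)
            bits[63:67] = [int(b) for b in format(code, "04b")]
            seen.add(decode(bits, codec)[1]["n_hidden"])
        assert seen == set(range(1, 17))

    def test_encode_decode_round_trip_over_all_tables(self):
        codec = Codec(n_factors=10)
        factors = [0, 3, 7]
        for h, w, m, l in itertools.product(
            range(1, 17), codec.weight_table, codec.momentum_table, codec.lr_table
        ):
            bits = encode_chromosome(factors, h, w, m, l, codec)
            got_f, got_h = decode(bits, codec)
            assert got_f.tolist() == factors
            assert got_h["n_hidden"] == h
            assert got_h["init_weight_range"] == w
            assert got_h["mc"] == m
            assert got_h["lr0"] == l

    def test_study_hyperparameters_reachable(self):
        # the backward-elimination settings lr=0.01, mc=0.9 are codec entries
        codec = Codec()
        assert 0.01 in codec.lr_table
        assert any(abs(m - 0.9) < 0.04 for m in codec.momentum_table)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            decode(np.zeros(75, dtype=np.uint8), Codec())


class TestOperators:
    @given(st.integers(0, 2**31 - 1))
    def test_crossover_conserves_length_and_multiset(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 30).astype(np.uint8)
        b = rng.integers(0, 2, 30).astype(np.uint8)
        c, d = two_point_crossover(a, b, pc=1.0, rng=rng)
        assert len(c) == len(d) == 30
        # positionwise, offspring bits come from one parent or the other
        assert np.all((c == a) | (c == b))
        assert np.all(c + d == a + b)

    def test_crossover_disabled_copies_parents(self, rng):
        a = np.ones(20, dtype=np.uint8)
        b = np.zeros(20, dtype=np.uint8)
        c, d = two_point_crossover(a, b, pc=0.0, rng=rng)
        assert np.array_equal(c, a) and np.array_equal(d, b)

    def test_crossover_hand_spliced(self):
        class CutRng:
            def random(self):
                return 0.0  # always cross

            def choice(self, n, size, replace):
                return np.array([10, 20])

        a = np.array([0] * 30, dtype=np.uint8)
        b = np.array([1] * 30, dtype=np.uint8)
        c, d = two_point_crossover(a, b, pc=1.0, rng=CutRng())
        assert c.tolist() == [0] * 10 + [1] * 10 + [0] * 10
        assert d.tolist() == [1] * 10 + [0] * 10 + [1] * 10

    def test_mutation_full_rate_complements(self, rng):
        bits = rng.integers(0, 2, 40).astype(np.uint8)
        assert np.array_equal(mutate(bits, 1.0, rng), 1 - bits)

    def test_mutation_zero_rate_identity(self, rng):
        bits = rng.integers(0, 2, 40).astype(np.uint8)
        assert np.array_equal(mutate(bits, 0.0, rng), bits)

    def test_roulette_prefers_fitter(self, rng):
        picks = roulette_select(np.array([1.0, 99.0]), rng, 2000)
        assert (picks == 1).mean() > 0.9

    def test_roulette_uniform_on_zero_fitness(self, rng):
        picks = roulette_select(np.zeros(4), rng, 4000)
        counts = np.bincount(picks, minlength=4)
        assert counts.min() > 800


class TestElection:
    def _family(self):
        return [np.full(4, i, dtype=np.uint8) for i in range(4)]

    def test_both_offspring_fitter_survive(self):
        p1, p2, o1, o2 = self._family()
        s = election((p1, p2), (o1, o2), [50, 55, 70, 65])
        assert {x[0] for x in s} == {2, 3}

    def test_both_offspring_worse_parents_survive(self):
        p1, p2, o1, o2 = self._family()
        s = election((p1, p2), (o1, o2), [70, 65, 50, 55])
        assert {x[0] for x in s} == {0, 1}

    def test_mixed_top_two_of_four(self):
        p1, p2, o1, o2 = self._family()
        s = election((p1, p2), (o1, o2), [70, 60, 65, 50])
        assert {x[0] for x in s} == {0, 2}

    def test_offspring_parent_mode(self):
        p1, p2, o1, o2 = self._family()
        s = election((p1, p2), (o1, o2), [70, 60, 65, 62], mode="offspring_parent")
        assert {x[0] for x in s} == {0, 3}


class TestPenalty:
    def test_unbounded_threshold_is_identity(self):
        f = np.array([60.0, 80.0])
        out = apply_penalty(f, np.array([10, 20]), T=None)
        assert np.array_equal(out, f)

    def test_oversized_gets_half_mean_of_feasible(self):
        f = np.array([60.0, 80.0, 90.0])
        out = apply_penalty(f, np.array([3, 4, 11]), T=10)
        assert out.tolist() == [60.0, 80.0, 35.0]

    def test_empty_mask_penalized_regardless_of_threshold(self):
        f = np.array([60.0, 80.0, 90.0])
        out = apply_penalty(f, np.array([3, 4, 0]), T=None)
        assert out.tolist() == [60.0, 80.0, 35.0]

    def test_all_penalized_falls_back_to_overall_mean(self):
        f = np.array([60.0, 80.0])
        with pytest.warns(UserWarning, match="every chromosome"):
            out = apply_penalty(f, np.array([11, 12]), T=10)
        assert out.tolist() == [35.0, 35.0]


@pytest.fixture(scope="module")
def toy_setup():
    # deterministic planted rule: C2 iff the encoded SNP01 genotype >= 0
    spec = SimSpec(
        n_subjects=200,
        n_genotype=4,
        n_nutrition=1,
        seed=17,
        main_effects={"SNP01": 30.0},
        interactions={},
        beta0=15.0,
    )
    mat = encode(simulate(spec).cohort)
    plan = make_3cv(200, derive_seed(17, "cv"), mat.y)
    return mat, plan


class TestEvaluate:
    def test_cache_prevents_retraining(self, toy_setup):
        mat, plan = toy_setup
        cfg = GAConfig(
            population_size=4, codec=Codec(n_factors=mat.X.shape[1]),
            max_epochs=30, seed=0,
        )
        cache = FitnessCache()
        bits = encode_chromosome([0, 1], 2, 0.5, 0.9, 0.01, cfg.codec)
        f1, _ = evaluate_chromosome(bits, mat.X, mat.y, plan, cfg, cache)
        before = cache.n_trainings
        f2, _ = evaluate_chromosome(bits.copy(), mat.X, mat.y, plan, cfg, cache)
        assert f1 == f2
        assert cache.n_trainings == before  # cache hit, no retraining

    def test_planted_mask_scores_high(self, toy_setup):
        mat, plan = toy_setup
        cfg = GAConfig(
            population_size=4, codec=Codec(n_factors=mat.X.shape[1]),
            max_epochs=150, seed=0,
        )
        cache = FitnessCache()
        j = mat.factor_names.index("SNP01")
        bits = encode_chromosome([j], 4, 0.5, 0.9, 0.01, cfg.codec)
        f, size = evaluate_chromosome(bits, mat.X, mat.y, plan, cfg, cache)
        assert size == 1
        assert f > 85.0  # near-deterministic planted rule

    def test_empty_mask_flagged_infeasible(self, toy_setup):
        mat, plan = toy_setup
        cfg = GAConfig(
            population_size=4, codec=Codec(n_factors=mat.X.shape[1]), seed=0
        )
        f, size = evaluate_chromosome(
            np.zeros(cfg.codec.length, dtype=np.uint8), mat.X, mat.y, plan, cfg,
            FitnessCache(),
        )
        assert size == 0 and f == 0.0


@pytest.fixture(scope="module")
def toy_trace(toy_setup):
    mat, plan = toy_setup
    cfg = GAConfig(
        population_size=10, n_generations=10, T=3, seed=4, max_epochs=40,
        codec=Codec(n_factors=mat.X.shape[1]),
    )
    return mat, evolve(mat, cfg, plan)


class TestEvolve:
    def test_single_generation_returns_best(self, toy_setup):
        mat, plan = toy_setup
        cfg = GAConfig(population_size=4, n_generations=1, seed=1, max_epochs=20)
        trace = evolve(mat, cfg, plan)
        assert len(trace.generations) == 1
        assert trace.best_chromosome is not None

    def test_best_fitness_monotone_nondecreasing(self, toy_trace):
        _, trace = toy_trace
        best = [g.best_fitness for g in trace.generations]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_reported_optimum_is_feasible(self, toy_trace):
        _, trace = toy_trace
        assert 0 < trace.best_factors.size <= 3  # within T, non-empty

    def test_cache_bounds_trainings(self, toy_trace):
        _, trace = toy_trace
        assert trace.n_trainings <= 3 * trace.n_unique_evaluated

    def test_chromosome_length_conserved(self, toy_trace):
        mat, trace = toy_trace
        expected = Codec(n_factors=mat.X.shape[1]).length
        assert trace.best_chromosome.size == expected

    def test_rerun_identical(self, toy_setup):
        mat, plan = toy_setup
        cfg = GAConfig(
            population_size=6, n_generations=4, seed=8, max_epochs=20,
            codec=Codec(n_factors=mat.X.shape[1]),
        )
        a = evolve(mat, cfg, plan)
        b = evolve(mat, cfg, plan)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert [g.mean_fitness for g in a.generations] == [
            g.mean_fitness for g in b.generations
        ]

    def test_no_variation_operators_no_novel_patterns(self, toy_setup):
        # with Pc=Pm=0 the gene pool can only shrink, never gain patterns
        mat, plan = toy_setup
        cfg = GAConfig(
            population_size=6, n_generations=5, pc=0.0, pm=0.0, seed=2,
            max_epochs=20, codec=Codec(n_factors=mat.X.shape[1]),
        )
        trace = evolve(mat, cfg, plan)
        # every unique chromosome evaluated must be one of the 6 founders
        assert trace.n_unique_evaluated <= 6
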