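import numpy as np
import pytest

import semgkit as sk
from semgkit.errors import ConfigError, DegenerateDataError
from semgkit.iga_svm import (
    Population,
    crossover,
    mutate,
    refill_population,
    sort_and_tier,
    tiered_select,
)

from .conftest import gaussian_blobs, separable_blobs


def _pop_with_fitness(n, seed=0):
    rng = np.random.default_rng(seed)
    members = [
        sk.Individual(c=float(2.0 ** rng.uniform(-5, 15)),
                      g=float(2.0 ** rng.uniform(-15, 3)),
                      fitness=float(rng.random()))
        for _ in range(n)
    ]
    return Population(members)


SMALL_GA = dict(pop_size=12, max_generations=2, cv_folds=2)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(pop_size=0),
            dict(P=0.0),
            dict(P=0.5, sigma=0.2),  # P + 3*sigma > 1
            dict(pc=1.5),
            dict(c_range=(3.0, 3.0)),
            dict(selection="roulette"),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            sk.GAConfig(**kw)

    def test_defaults_follow_reference_operating_point(self):
        cfg = sk.GAConfig()
        assert (cfg.pop_size, cfg.pc, cfg.pm, cfg.P, cfg.sigma) == (2000, 0.7, 0.1, 0.4, 0.2)
        assert (cfg.max_generations, cfg.cv_folds) == (50, 5)


class TestInitPopulation:
    def test_size_and_bounds(self):
        cfg = sk.GAConfig(pop_size=200)
        pop = sk.init_population(cfg)
        assert len(pop) == 200
        lc = np.log2([m.c for m in pop.members])
        lg = np.log2([m.g for m in pop.members])
        assert lc.min() >= -5 and lc.max() <= 15
        assert lg.min() >= -15 and lg.max() <= 3

    def test_seed_determinism(self):
        a = sk.init_population(sk.GAConfig(pop_size=50, seed=3))
        b = sk.init_population(sk.GAConfig(pop_size=50, seed=3))
        assert [(m.c, m.g) for m in a.members] == [(m.c, m.g) for m in b.members]


class TestFitness:
    def test_separable_classes_score_high(self):
        X, y = separable_blobs(1)
        fit = sk.evaluate_fitness(sk.Individual(c=10.0, g=0.1), X, y, cv_folds=5, seed=0)
        assert fit >= 0.95

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 6))
        y = np.array(["a", "b"] * 40)
        fit = sk.evaluate_fitness(sk.Individual(c=1.0, g=0.1), X, y, cv_folds=5, seed=0)
        assert abs(fit - 0.5) <= 0.1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            sk.evaluate_fitness(
                sk.Individual(c=1.0, g=1.0), np.zeros((10, 2)), np.repeat("a", 10)
            )


class TestTiering:
    @pytest.mark.parametrize("C,expected", [(2000, (500, 500, 500, 500)), (10, (2, 2, 2, 4))])
    def test_quartering_with_remainder_to_good(self, C, expected):
        tiered = sort_and_tier(_pop_with_fitness(C))
        assert tiered.tier_counts == expected

    def test_sorted_ascending_and_bad_is_lowest(self):
        tiered = sort_and_tier(_pop_with_fitness(40))
        fits = [m.fitness for m in tiered.members]
        assert fits == sorted(fits)
        assert max(m.fitness for m in tiered.tier("bad")) <= min(
            m.fitness for m in tiered.tier("good")
        )

    def test_equal_fitness_order_is_deterministic(self):
        members = [sk.Individual(c=float(i + 1), g=1.0, fitness=0.5) for i in range(8)]
        a = sort_and_tier(Population(list(members)))
        b = sort_and_tier(Population(list(members)))
        assert [m.c for m in a.members] == [m.c for m in b.members]

    def test_unset_fitness_rejected(self):
        pop = Population([sk.Individual(c=1.0, g=1.0)] * 8)
        with pytest.raises(ConfigError):
            sort_and_tier(pop)


class TestSelectionAndRefill:
    def test_selected_count_formula(self):
        # equal 500-tiers at P=0.4, sigma=0.2: 200+300+400+500 = 1400
        tiered = sort_and_tier(_pop_with_fitness(2000))
        sel = tiered_select(tiered, 0.4, 0.2, np.random.default_rng(0))
        assert len(sel) == 1400

    def test_top_tier_fully_selected_at_unit_probability(self):
        tiered = sort_and_tier(_pop_with_fitness(40))
        sel = tiered_select(tiered, 0.4, 0.2, np.random.default_rng(0))
        good_ids = {id(m) for m in tiered.tier("good")}
        assert sum(1 for m in sel if id(m) in good_ids) == len(good_ids)

    def test_refill_reinserts_good_then_well(self):
        tiered = sort_and_tier(_pop_with_fitness(2000))
        sel = tiered_select(tiered, 0.4, 0.2, np.random.default_rng(1))
        members = refill_population(sel, tiered, np.random.default_rng(1))
        assert len(members) == 2000
        refill = members[len(sel):]          # 600 vacancies
        good_ids = {id(m) for m in tiered.tier("good")}
        well_ids = {id(m) for m in tiered.tier("well")}
        assert sum(1 for m in refill if id(m) in good_ids) == 500  # whole good tier
        assert sum(1 for m in refill if id(m) in well_ids) == 100

    def test_no_refill_when_selection_is_full(self):
        tiered = sort_and_tier(_pop_with_fitness(16))
        members = refill_population(list(tiered.members), tiered, np.random.default_rng(0))
        assert len(members) == 16


class TestVariationOperators:
    CFG = sk.GAConfig(pop_size=8)

    def test_no_crossover_copies_parents(self):
        a, b = sk.Individual(c=2.0, g=0.5), sk.Individual(c=8.0, g=0.25)
        ca, cb = crossover(a, b, pc=0.0, rng=np.random.default_rng(0), config=self.CFG)
        assert (ca.c, ca.g, cb.c, cb.g) == (2.0, 0.5, 8.0, 0.25)

    def test_blend_of_identical_parents_is_identity(self):
        a = sk.Individual(c=4.0, g=0.125)
        ca, cb = crossover(a, a, pc=1.0, rng=np.random.default_rng(0), config=self.CFG)
        assert ca.c == pytest.approx(4.0) and cb.g == pytest.approx(0.125)

    def test_children_inside_parental_interval(self, rng):
        for _ in range(50):
            a = sk.Individual(c=float(2.0 ** rng.uniform(-5, 15)), g=float(2.0 ** rng.uniform(-15, 3)))
            b = sk.Individual(c=float(2.0 ** rng.uniform(-5, 15)), g=float(2.0 ** rng.uniform(-15, 3)))
            ca, cb = crossover(a, b, pc=1.0, rng=np.random.default_rng(1), config=self.CFG)
            for child in (ca, cb):
                assert min(a.c, b.c) - 1e-12 <= child.c <= max(a.c, b.c) + 1e-12
                assert min(a.g, b.g) - 1e-12 <= child.g <= max(a.g, b.g) + 1e-12

    def test_no_mutation_is_identity(self):
        ind = sk.Individual(c=3.0, g=0.3, fitness=0.7)
        out = mutate(ind, pm=0.0, rng=np.random.default_rng(0), config=self.CFG)
        assert (out.c, out.g, out.fitness) == (3.0, 0.3, 0.7)

    def test_mutation_respects_bounds(self):
        ind = sk.Individual(c=2.0**15, g=2.0**3)  # at the upper corners
        rng = np.random.default_rng(2)
        for _ in range(200):
            out = mutate(ind, pm=1.0, rng=rng, config=self.CFG)
            assert 2.0**-5 - 1e-12 <= out.c <= 2.0**15 + 1e-9
            assert 2.0**-15 - 1e-15 <= out.g <= 2.0**3 + 1e-12

    def test_mutation_noise_is_centred(self):
        ind = sk.Individual(c=2.0**5, g=2.0**-6)
        rng = np.random.default_rng(3)
        shifts = []
        for _ in range(10000):
            out = mutate(ind, pm=1.0, rng=rng, config=self.CFG)
            shifts.append(np.log2(out.c) - 5.0)
        # sd of the mean of 10k draws at scale 2.0 is ~0.02
        assert abs(np.mean(shifts)) <= 0.1


class TestEvolve:
    def test_finds_good_parameters_on_separable_data(self):
        X, y = separable_blobs(2, n_per=6)
        res = sk.evolve(X, y, sk.GAConfig(pop_size=16, max_generations=3, cv_folds=2, seed=0))
        assert res.best_fitness >= 0.9

    def test_zero_generations_returns_best_of_initial_population(self):
        X, y = gaussian_blobs(3, n_per=5)
        res = sk.evolve(X, y, sk.GAConfig(pop_size=10, max_generations=0, cv_folds=2, seed=1))
        assert len(res.history) == 1

    def test_seed_reproducibility(self):
        X, y = gaussian_blobs(4, n_per=5)
        cfg = sk.GAConfig(pop_size=10, max_generations=2, cv_folds=2, seed=42)
        r1, r2 = sk.evolve(X, y, cfg), sk.evolve(X, y, cfg)
        assert (r1.best_c, r1.best_g) == (r2.best_c, r2.best_g)
        assert r1.history == r2.history

    @pytest.mark.parametrize("selection", ["tiered", "tournament"])
    def test_best_so_far_is_monotone(self, selection):
        X, y = gaussian_blobs(5, n_per=8, spread=2.0)
        cfg = sk.GAConfig(pop_size=12, max_generations=4, cv_folds=2, seed=7,
                          selection=selection)
        res = sk.evolve(X, y, cfg)
        best = [h["best_so_far"] for h in res.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_target_fitness_stops_early(self):
        X, y = separable_blobs(6, n_per=6)
        cfg = sk.GAConfig(pop_size=12, max_generations=30, cv_folds=2, seed=0,
                          target_fitness=0.9)
        res = sk.evolve(X, y, cfg)
        assert len(res.history) < 31


class TestTrainEvaluate:
    def test_training_accuracy_on_separable_data(self):
        X, y = separable_blobs(8)
        model = sk.train(X, y, best_c=10.0, best_g=0.1)
        acc, _, _ = sk.evaluate(model, X, y)
        assert acc >= 0.95

    def test_memorization_with_large_penalty(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array(["a", "b"] * 6)
        model = sk.train(X, y, best_c=1e5, best_g=1.0)
        assert np.all(model.predict(X) == y)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            sk.train(np.zeros((5, 2)), np.repeat("a", 5), 1.0, 1.0)

    def test_confusion_matrix_marginals(self):
        X, y = gaussian_blobs(9, n_per=10, spread=1.5, n_classes=3)
        model = sk.train(X, y, best_c=5.0, best_g=0.2)
        acc, per_class, cm = sk.evaluate(model, X, y)
        assert cm.sum() == len(y)
        np.testing.assert_array_equal(cm.sum(axis=1), [10] * 3)  # rows = actual counts
        assert acc == pytest.approx(np.trace(cm) / cm.sum())

    def test_unknown_test_label_rejected(self):
        X, y = separable_blobs(10, n_per=4)
        model = sk.train(X, y, 1.0, 0.1)
        with pytest.raises(DegenerateDataError):
            sk.evaluate(model, X[:2], np.array(["zz", "zz"]))


def test_model_json_round_trip(tmp_path):
    X, y = separable_blobs(11, n_per=5)
    model = sk.train(X, y, best_c=7.0, best_g=0.05)
    path = tmp_path / "model.json"
    sk.save_model(model, X, y, path)
    back = sk.load_model(path)
    assert back.best_c == model.best_c
    np.testing.assert_array_equal(back.predict(X), model.predict(X))
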