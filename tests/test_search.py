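"""Genetic-algorithm operators, determinism, and the exhaustive oracle."""

import math

import numpy as np
import pytest

from btrlearn import (SearchConfig, count_models, crossover, evolve,
                      exhaustive_search, initialize_population, mutate,
                      penalized_select)
from btrlearn.data_io import ValidationError
from btrlearn.search import _FitContext, _ctx_build


def _cfg(**kw):
    base = dict(language="bin", k_min=1, k_max=3, population_size=20,
                generations=5, seed=7)
    base.update(kw)
    return SearchConfig(**base)


class TestInitializePopulation:
    def test_single_feature_models(self, small_dataset):
        m, y = small_dataset
        pop = initialize_population(m, y, _cfg(k_min=1, k_max=1))
        assert all(mdl.k == 1 for mdl in pop.models)

    def test_same_seed_identical(self, small_dataset):
        m, y = small_dataset
        a = initialize_population(m, y, _cfg(language="ter"))
        b = initialize_population(m, y, _cfg(language="ter"))
        assert [(x.structure_key(), x.threshold, x.fitness) for x in a.models] \
            == [(x.structure_key(), x.threshold, x.fitness) for x in b.models]

    def test_strong_feature_is_seeded(self, separable_dataset):
        m, y = separable_dataset
        pop = initialize_population(m, y, _cfg(k_max=2))
        seeded = {f for mdl in pop.models for f in mdl.feature_names}
        assert "feat_0" in seeded  # the perfectly separating feature

    def test_k_max_beyond_p_rejected(self, small_dataset):
        m, y = small_dataset
        with pytest.raises(ValidationError):
            initialize_population(m, y, _cfg(k_max=m.n_features + 1))

    def test_thresholds_all_fitted(self, small_dataset):
        m, y = small_dataset
        pop = initialize_population(m, y, _cfg(language="ratio"))
        assert all(mdl.threshold is not None and mdl.fitness is not None
                   for mdl in pop.models)


class TestMutate:
    def test_rate_zero_identity(self, small_dataset):
        m, y = small_dataset
        ctx = _FitContext(m, y, "ter", "accuracy")
        mdl = _ctx_build(ctx, (0, 3, 5), (1, -1, 1))
        out = mutate(mdl, m, y, 0.0, np.random.default_rng(0))
        assert out is mdl  # threshold included, bit-identical

    def test_rate_one_bin_replaces_all(self, small_dataset):
        m, y = small_dataset
        ctx = _FitContext(m, y, "bin", "accuracy")
        mdl = _ctx_build(ctx, (0, 1, 2), (1, 1, 1))
        out = mutate(mdl, m, y, 1.0, np.random.default_rng(1))
        assert out.k == mdl.k
        assert set(out.feature_indices).isdisjoint(mdl.feature_indices)

    def test_mean_altered_positions_binomial(self):
        """At rate 0.2 on k=5, the number of hit positions is Binomial(5, .2):
        the mean over many mutations must sit near 1.0.

        The alteration count between two canonical models is measured up to
        a global sign flip (the canonical representative may renormalise)."""
        from btrlearn import AbundanceMatrix, SampleTarget

        gen = np.random.default_rng(12)
        p, n = 200, 30
        m = AbundanceMatrix(gen.random((p, n)) + 0.01,
                            [f"f{i}" for i in range(p)],
                            [f"s{j}" for j in range(n)], "raw")
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        y = SampleTarget(list(m.sample_ids), "binary_class", labels)
        ctx = _FitContext(m, y, "ter", "accuracy")
        mdl = _ctx_build(ctx, (0, 1, 2, 3, 4), (1, 1, -1, 1, -1))
        rng = np.random.default_rng(77)
        base = set(zip(mdl.feature_indices, mdl.coefficients))
        flipped = {(f, -c) for f, c in base}
        total = 0
        n_mut = 10_000
        for _ in range(n_mut):
            out = mutate(mdl, m, y, 0.2, rng, _ctx=ctx)
            pairs = set(zip(out.feature_indices, out.coefficients))
            total += min(5 - len(pairs & base), 5 - len(pairs & flipped))
        assert total / n_mut == pytest.approx(1.0, abs=0.05)


class TestCrossover:
    def test_identical_parents_identical_children(self, small_dataset):
        m, y = small_dataset
        ctx = _FitContext(m, y, "ter", "accuracy")
        mdl = _ctx_build(ctx, (1, 4, 6), (1, -1, 1))
        c1, c2 = crossover(mdl, mdl, m, y, np.random.default_rng(5))
        for c in (c1, c2):
            assert c.structure_key() == mdl.structure_key()
            assert c.threshold == mdl.threshold

    def test_children_within_union(self, small_dataset):
        m, y = small_dataset
        ctx = _FitContext(m, y, "bin", "accuracy")
        a = _ctx_build(ctx, (0, 1), (1, 1))
        b = _ctx_build(ctx, (5, 6), (1, 1))
        rng = np.random.default_rng(2)
        for _ in range(20):
            c1, c2 = crossover(a, b, m, y, rng)
            for c in (c1, c2):
                assert set(c.feature_indices) <= {0, 1, 5, 6}
                assert np.isfinite(c.fitness)

    def test_incompatible_languages_rejected(self, small_dataset):
        m, y = small_dataset
        ctx_b = _FitContext(m, y, "bin", "accuracy")
        ctx_t = _FitContext(m, y, "ter", "accuracy")
        a = _ctx_build(ctx_b, (0,), (1,))
        b = _ctx_build(ctx_t, (1,), (1,))
        from btrlearn.models import ModelError

        with pytest.raises(ModelError):
            crossover(a, b, m, y, np.random.default_rng(0))


class TestEvolve:
    def test_zero_generations_is_initial_population(self, small_dataset):
        m, y = small_dataset
        pop = evolve(m, y, _cfg(generations=0))
        assert pop.generation == 0
        assert all(len(h) == 1 for h in pop.fitness_history.values())

    def test_best_fitness_monotone(self, small_dataset):
        m, y = small_dataset
        pop = evolve(m, y, _cfg(language="ter", generations=15))
        for hist in pop.fitness_history.values():
            assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_same_seed_bit_identical(self, small_dataset):
        m, y = small_dataset
        a = evolve(m, y, _cfg(language="ratio"))
        b = evolve(m, y, _cfg(language="ratio"))
        assert [(x.structure_key(), x.threshold, x.fitness) for x in a.models] \
            == [(x.structure_key(), x.threshold, x.fitness) for x in b.models]

    def test_sparsity_bound(self, small_dataset):
        m, y = small_dataset
        pop = evolve(m, y, _cfg(language="ter", k_max=2, generations=10))
        assert max(mdl.k for mdl in pop.models) <= 2

    def test_matches_exhaustive_on_small_instance(self, small_dataset):
        m, y = small_dataset
        pop = evolve(m, y, _cfg(language="ter", population_size=100,
                                generations=30, seed=3))
        oracle = exhaustive_search(m, y, "ter", 3)
        ga = penalized_select(pop)
        ex = penalized_select(oracle)
        assert ga.fitness - 0.01 * ga.k == pytest.approx(
            ex.fitness - 0.01 * ex.k, abs=1e-12)


class TestExhaustive:
    def test_bin_singleton_count(self, small_dataset):
        m, y = small_dataset
        pop = exhaustive_search(m.subset_features([0, 1, 2]), y, "bin", 1)
        assert pop.n_evaluated == 3
        assert len(pop.models) == 3

    @pytest.mark.parametrize("language,p,k_max", [
        ("bin", 5, 3), ("ter", 4, 2), ("ratio", 4, 3), ("ter", 6, 3),
    ])
    def test_count_matches_independent_formula(self, small_dataset,
                                               language, p, k_max):
        m, y = small_dataset
        sub = m.subset_features(list(range(p)))
        pop = exhaustive_search(sub, y, language, k_max)
        # independent closed form: C(p,k) subsets x 2^(k-1) canonical signings
        expected = sum(
            math.comb(p, k) * (1 if language == "bin" else 2 ** (k - 1))
            for k in range(1, k_max + 1))
        assert pop.n_evaluated == expected
        assert len({mdl.structure_key() for mdl in pop.models}) == expected

    def test_ter_p4_k2_counts(self, small_dataset):
        m, y = small_dataset
        pop = exhaustive_search(m.subset_features([0, 1, 2, 3]), y, "ter", 2)
        assert pop.n_evaluated == 4 + 12

    def test_separable_pair_reaches_perfect_accuracy(self, separable_dataset):
        m, y = separable_dataset
        pop = exhaustive_search(m, y, "bin", 2)
        assert pop.best().fitness == 1.0

    def test_guard_bound_refusal(self, small_dataset):
        m, y = small_dataset
        with pytest.raises(ValidationError, match="guard"):
            exhaustive_search(m, y, "ter", 3, guard=10)


class TestCountModels:
    def test_closed_form(self):
        assert count_models(3, 1, "bin") == 3
        assert count_models(4, 2, "ter") == 4 + 12
        assert count_models(4, 2, "ratio") == 4 + 12
        assert count_models(12, 3, "ter") == 12 + 132 + 880
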