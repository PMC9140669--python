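import numpy as np
import pytest

from sfmoabc import GenotypeDataset, SearchConfig, run, run_single_objective
from sfmoabc.core import (
    Evaluator,
    decode_position,
    greedy_step,
    initialize_population,
    opposition,
    selection_probabilities,
    update_elite,
    update_normal,
    _make_source,
    _update_at,
)
from sfmoabc.scalefree import ScaleFreeNetwork


def small_cfg(**kw):
    defaults = dict(n_sources=12, max_iter=5, limit=4, m0=3, n_links=2, seed=0)
    defaults.update(kw)
    return SearchConfig(**defaults)


class TestDecodePosition:
    def test_rounding(self, rng):
        pos = np.array([3.2, 77.8])
        assert decode_position(pos, 100, rng) == (3, 78)
        assert list(pos) == [3.0, 78.0]  # overwritten with decoded integers

    def test_clamping(self, rng):
        assert decode_position(np.array([-4.0, 2.0]), 100, rng) == (1, 2)
        high = decode_position(np.array([150.0, 42.0]), 100, rng)
        assert high == (100, 42)

    def test_collision_redraw(self, rng):
        combo = decode_position(np.array([5.4, 4.6]), 100, rng)
        assert combo[0] == 5 and combo[1] != 5
        assert 1 <= combo[1] <= 100

    def test_always_distinct_in_range(self, rng):
        for _ in range(200):
            pos = rng.uniform(-10, 40, size=2)
            combo = decode_position(pos, 25, rng)
            assert len(set(combo)) == 2
            assert all(1 <= c <= 25 for c in combo)


class TestOpposition:
    def test_direct_substitution(self):
        assert list(opposition(np.array([300.0, 512.0]), 1, 1000)) == [701.0, 489.0]

    def test_involution(self, rng):
        v = rng.uniform(1, 50, size=2)
        assert np.allclose(opposition(opposition(v, 1, 50), 1, 50), v)

    def test_midpoint_fixed_point(self):
        mid = (1 + 99) / 2
        assert np.allclose(opposition(np.array([mid, mid]), 1, 99), [mid, mid])


def make_src(ev, rng, pos):
    return _make_source(np.asarray(pos, float), ev, rng)


@pytest.fixture
def toy_eval(perfect_ds):
    return Evaluator(perfect_ds)


class TestUpdates:
    def test_normal_fixed_point(self, toy_eval, rng):
        src = make_src(toy_eval, rng, [3.0, 8.0])
        v = update_normal(src, src, toy_eval, rng)
        assert np.array_equal(v.position, src.position)

    def test_normal_convexity(self, toy_eval, rng):
        src = make_src(toy_eval, rng, [2.0, 10.0])
        nbr = make_src(toy_eval, rng, [8.0, 4.0])
        r = np.random.default_rng(0)
        raw = src.position + r.random(2) * (nbr.position - src.position)
        lo = np.minimum(src.position, nbr.position)
        hi = np.maximum(src.position, nbr.position)
        assert ((lo <= raw) & (raw <= hi)).all()

    def test_elite_reproducible(self, toy_eval):
        src_pos, nbr_pos = [2.0, 10.0], [8.0, 4.0]
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            src = make_src(toy_eval, rng, src_pos)
            nbr = make_src(toy_eval, rng, nbr_pos)
            outs.append(update_elite(src, nbr, toy_eval, rng, 1, 12).combo)
        assert outs[0] == outs[1]

    def test_elite_candidate_always_valid(self, toy_eval, rng):
        for _ in range(50):
            src = make_src(toy_eval, rng, rng.uniform(1, 12, 2))
            nbr = make_src(toy_eval, rng, rng.uniform(1, 12, 2))
            v = update_elite(src, nbr, toy_eval, rng, 1, 12)
            assert len(set(v.combo)) == 2
            assert all(0 <= c < 12 for c in v.combo)


class TestGreedyStep:
    def mk(self, value, trail=0):
        from sfmoabc.core import FoodSource

        return FoodSource(
            position=np.array([1.0, 2.0]), combo=(0, 1),
            mi=0.0, k2log=1.0, fit=value, value=value, trail=trail,
        )

    def test_candidate_wins(self):
        src = self.mk(0.1, trail=3)
        out = greedy_step(src, self.mk(0.5), self.mk(0.2))
        assert out.value == 0.5 and out.trail == 0

    def test_opposed_wins(self):
        out = greedy_step(self.mk(0.1), self.mk(0.2), self.mk(0.4))
        assert out.value == 0.4

    def test_all_tied_keeps_incumbent_and_increments(self):
        src = self.mk(0.3, trail=1)
        out = greedy_step(src, self.mk(0.3), self.mk(0.3))
        assert out is src and out.trail == 2


class TestSelectionProbabilities:
    def test_normalization(self):
        assert np.allclose(selection_probabilities([1.0, 3.0]), [0.25, 0.75])

    def test_symmetry(self):
        assert np.allclose(selection_probabilities([2.0] * 4), [0.25] * 4)

    def test_all_zero_fallback(self):
        assert np.allclose(selection_probabilities([0.0, 0.0]), [0.5, 0.5])


class TestInitialization:
    def test_population_sorted_onto_hubs(self, model4_ds):
        cfg = small_cfg(n_sources=20)
        pop, net = initialize_population(model4_ds, cfg)
        assert len(pop) == 20 and net.n_nodes == 20
        values = [s.value for s in pop]
        assert values == sorted(values, reverse=True)
        assert all(len(set(s.combo)) == 2 for s in pop)

    def test_seeded_determinism(self, model4_ds):
        cfg = small_cfg(n_sources=15, seed=5)
        pop1, _ = initialize_population(model4_ds, cfg)
        pop2, _ = initialize_population(model4_ds, cfg)
        assert [s.combo for s in pop1] == [s.combo for s in pop2]

    def test_infeasible_order(self):
        ds = GenotypeDataset(
            genotypes=np.zeros((4, 3), dtype=int), phenotype=np.array([0, 1, 0, 1])
        )
        with pytest.raises(ValueError):
            initialize_population(ds, small_cfg())


class TestRun:
    def test_best_trace_non_decreasing(self, model4_ds):
        res = run(model4_ds, small_cfg(max_iter=10))
        assert all(a <= b for a, b in zip(res.best_trace, res.best_trace[1:]))

    def test_bitwise_determinism(self, model4_ds):
        cfg = small_cfg(seed=31)
        assert run(model4_ds, cfg) == run(model4_ds, cfg)

    def test_ranked_unique_and_sorted(self, model4_ds):
        res = run(model4_ds, small_cfg())
        combos = [r.combo for r in res.ranked]
        assert len(combos) == len(set(combos))
        fits = [r.fit for r in res.ranked]
        assert fits == sorted(fits, reverse=True)

    def test_every_combo_valid(self, model4_ds):
        res = run(model4_ds, small_cfg(seed=8))
        for rec in res.ranked:
            assert len(set(rec.combo)) == 2
            assert all(0 <= c < model4_ds.n_snps for c in rec.combo)

    def test_evaluation_budget_formula(self, model4_ds):
        cfg = small_cfg(max_iter=6, n_sources=10)
        res = run(model4_ds, cfg)
        for evals, scout in zip(
            res.iteration_candidate_evals, res.iteration_scout_fired
        ):
            assert evals == 4 * cfg.n_sources + int(scout)


class TestSingleObjective:
    def test_mi_only_finds_deterministic_pair(self, perfect_ds):
        cfg = small_cfg(n_sources=15, max_iter=15, seed=3, objective="mi_only")
        res = run_single_objective(perfect_ds, cfg)
        assert frozenset(res.ranked[0].combo) == frozenset(perfect_ds.truth[0])

    def test_seeded_determinism(self, model4_ds):
        cfg = small_cfg(objective="k2_only", seed=12)
        assert run_single_objective(model4_ds, cfg) == run_single_objective(
            model4_ds, cfg
        )

    def test_budget_formula(self, model4_ds):
        cfg = small_cfg(objective="mi_only", max_iter=6, n_sources=10)
        res = run_single_objective(model4_ds, cfg)
        for evals, scout in zip(
            res.iteration_candidate_evals, res.iteration_scout_fired
        ):
            assert evals == 2 * cfg.n_sources + int(scout)

    def test_rejects_multi(self, model4_ds):
        with pytest.raises(ValueError):
            run_single_objective(model4_ds, small_cfg(objective="multi"))

    def test_run_dispatches_on_objective(self, model4_ds):
        cfg = small_cfg(objective="mi_only", seed=4)
        assert run(model4_ds, cfg) == run_single_objective(model4_ds, cfg)


def test_edgeless_stub_degrades_gracefully(model4_ds):
    """With an edgeless network the neighbor term vanishes and the elite
    update degrades to the classic peer-difference move (smoke only)."""
    cfg = small_cfg(n_sources=8)
    rng = np.random.default_rng(0)
    ev = Evaluator(model4_ds)
    pop, _ = initialize_population(model4_ds, cfg, rng, ev)
    stub = ScaleFreeNetwork(
        n_nodes=8, m0=3, n_links=2,
        adjacency={i: frozenset() for i in range(1, 9)},
    )
    before = max(s.value for s in pop)
    for idx in range(len(pop)):
        _update_at(pop, idx, stub, ev, cfg, rng)
    assert max(s.value for s in pop) >= before
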