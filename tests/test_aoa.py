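"""Archimedes optimizer: operator identities, update rules, full-loop behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p2c.aoa import (AOAConfig, AOAObject, density_factor,
                     initialize_population, normalize_acceleration, optimize,
                     random_search, transfer_operator, update_acceleration,
                     update_density_volume, update_position)


def box(dim=2, lo=-10.0, hi=10.0, **kw):
    return AOAConfig(lower=np.full(dim, lo), upper=np.full(dim, hi), **kw)


def sphere(x):
    return float(np.sum(x ** 2))


class FakeRng:
    """Deterministic stand-in feeding a scripted sequence of draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size=None):
        v = self.draws.pop(0)
        return np.asarray(v, dtype=float) if size is not None else float(v)

    def integers(self, n):
        return int(self.draws.pop(0))


class TestOperators:
    def test_transfer_operator_endpoints(self):
        assert transfer_operator(100, 100) == pytest.approx(1.0)
        assert transfer_operator(0, 100) == pytest.approx(np.exp(-1), abs=1e-9)

    def test_transfer_operator_strictly_increasing(self):
        vals = [transfer_operator(t, 50) for t in range(51)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_density_factor_endpoints(self):
        assert density_factor(100, 100) == pytest.approx(0.0, abs=1e-12)
        assert density_factor(0, 100) == pytest.approx(np.e, abs=1e-9)

    def test_density_factor_strictly_decreasing(self):
        vals = [density_factor(t, 50) for t in range(51)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("fn", [transfer_operator, density_factor])
    def test_out_of_range_iteration_rejected(self, fn):
        with pytest.raises(ValueError, match="outside"):
            fn(11, 10)


class TestInitialization:
    def test_positions_within_bounds(self):
        cfg = box(dim=4)
        pop = initialize_population(cfg, np.random.default_rng(0))
        for obj in pop:
            assert np.all(obj.x >= cfg.lower) and np.all(obj.x <= cfg.upper)
            assert 0.0 <= obj.den <= 1.0 and 0.0 <= obj.vol <= 1.0

    def test_degenerate_bounds_collapse_positions(self):
        cfg = AOAConfig(lower=np.array([2.0, 3.0]), upper=np.array([2.0, 3.0]))
        pop = initialize_population(cfg, np.random.default_rng(1))
        for obj in pop:
            assert np.array_equal(obj.x, [2.0, 3.0])

    def test_seeded_repeatability(self):
        cfg = box()
        a = initialize_population(cfg, np.random.default_rng(7))
        b = initialize_population(cfg, np.random.default_rng(7))
        assert all(np.array_equal(x.x, y.x) and x.den == y.den for x, y in zip(a, b))

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError, match="population"):
            box(n_objects=1)


class TestStateUpdates:
    def test_density_fixed_point_at_best(self):
        obj = AOAObject(x=np.zeros(2), den=0.4, vol=0.6, acc=0.1)
        best = AOAObject(x=np.zeros(2), den=0.4, vol=0.6, acc=0.9)
        update_density_volume(obj, best, np.random.default_rng(0))
        assert obj.den == pytest.approx(0.4) and obj.vol == pytest.approx(0.6)

    def test_forced_full_step_lands_on_best(self):
        obj = AOAObject(x=np.zeros(1), den=0.1, vol=0.2, acc=0.0)
        best = AOAObject(x=np.zeros(1), den=0.8, vol=0.9, acc=0.0)
        update_density_volume(obj, best, FakeRng([1.0, 1.0]))
        assert obj.den == pytest.approx(0.8) and obj.vol == pytest.approx(0.9)

    def test_contraction_toward_best_in_expectation(self):
        rng = np.random.default_rng(3)
        best = AOAObject(x=np.zeros(1), den=0.7, vol=0.3, acc=0.0)
        objs = [AOAObject(x=np.zeros(1), den=rng.random(), vol=rng.random(), acc=0.0)
                for _ in range(1000)]
        gaps = []
        for _ in range(6):
            gaps.append(np.mean([abs(o.den - best.den) for o in objs]))
            for o in objs:
                update_density_volume(o, best, rng)
        assert all(b < a for a, b in zip(gaps, gaps[1:]))

    def test_acceleration_hand_substitution(self):
        cfg = box()
        obj = AOAObject(x=np.zeros(2), den=0.5, vol=0.4, acc=0.0)
        ref = AOAObject(x=np.zeros(2), den=0.3, vol=0.2, acc=1.5)
        # (den_ref + vol_ref*acc_ref)/(den*vol) = (0.3 + 0.2*1.5)/0.2 = 3.0
        assert update_acceleration(obj, ref, 0.4, cfg) == pytest.approx(3.0)

    def test_acceleration_exploitation_self_best_unit_density(self):
        cfg = box()
        best = AOAObject(x=np.zeros(2), den=1.0, vol=1.0, acc=0.25)
        assert update_acceleration(best, best, 0.9, cfg) == pytest.approx(
            best.den + best.vol * best.acc)

    def test_zero_denominator_stabilized(self):
        cfg = box()
        obj = AOAObject(x=np.zeros(2), den=0.0, vol=0.5, acc=0.0)
        ref = AOAObject(x=np.zeros(2), den=0.5, vol=0.5, acc=1.0)
        assert np.isfinite(update_acceleration(obj, ref, 0.4, cfg))


class TestNormalization:
    def test_affine_endpoints_and_midpoint(self):
        cfg = box()
        assert np.allclose(normalize_acceleration([2.0, 4.0, 6.0], cfg),
                           [0.1, 0.5, 0.9])

    def test_single_and_equal_values_map_to_midpoint(self):
        cfg = box()
        assert np.allclose(normalize_acceleration([3.7], cfg), [0.5])
        assert np.allclose(normalize_acceleration([1.0, 1.0, 1.0], cfg), 0.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
    def test_output_always_within_range(self, accs):
        out = normalize_acceleration(accs, box())
        assert np.all(out >= 0.1 - 1e-12) and np.all(out <= 0.9 + 1e-12)


class TestPositionUpdates:
    def test_zero_density_factor_is_no_move(self):
        cfg = box()
        obj = AOAObject(x=np.array([1.0, -2.0]), den=0.5, vol=0.5, acc=0.5)
        best = AOAObject(x=np.array([5.0, 5.0]), den=0.5, vol=0.5, acc=0.5)
        x = update_position(obj, best, 0.5, 0.0, 0.3, cfg, np.random.default_rng(0))
        assert np.array_equal(x, obj.x)

    def test_exploration_fixed_point_at_partner(self):
        cfg = box()
        obj = AOAObject(x=np.array([1.0, 1.0]), den=0.5, vol=0.5, acc=0.5)
        x = update_position(obj, obj, 0.5, 1.0, 0.3, cfg, np.random.default_rng(0))
        assert np.array_equal(x, obj.x)

    def test_exploration_hand_substitution(self):
        cfg = box()
        obj = AOAObject(x=np.zeros(2), den=0.5, vol=0.5, acc=0.5)
        partner = AOAObject(x=np.array([2.0, -2.0]), den=0.5, vol=0.5, acc=0.5)
        # x + C1*r*acc_norm*d*(x_rand - x) = 2*0.5*0.4*1.5*(2,-2) = (1.2,-1.2)
        x = update_position(obj, partner, 0.4, 1.5, 0.3, cfg, FakeRng([[0.5, 0.5]]))
        assert np.allclose(x, [1.2, -1.2])

    def test_exploitation_hand_substitution(self):
        cfg = box()
        obj = AOAObject(x=np.array([1.0, 2.0]), den=0.5, vol=0.5, acc=0.5)
        best = AOAObject(x=np.array([3.0, 4.0]), den=0.5, vol=0.5, acc=0.5)
        # P = 2*0.2-0.5 = -0.1 <= 0.5 -> F=+1; T = min(2*0.8, 1) = 1
        # x + F*C2*r*acc*d*(T*best-x) with C2=6, acc=0.5, d=0.8:
        # [1,2] + 6*[0.5,0.25]*0.5*0.8*[2,2] = [3.4, 3.2]
        x = update_position(obj, best, 0.5, 0.8, 0.8, cfg,
                            FakeRng([0.2, [0.5, 0.25]]))
        assert np.allclose(x, [3.4, 3.2])

    def test_overshoot_is_clamped_to_bounds(self):
        cfg = box(lo=-1.0, hi=1.0)
        obj = AOAObject(x=np.array([0.9, -0.9]), den=0.5, vol=0.5, acc=0.5)
        partner = AOAObject(x=np.array([50.0, -50.0]), den=0.5, vol=0.5, acc=0.5)
        x = update_position(obj, partner, 0.9, 2.0, 0.3, cfg, FakeRng([[1.0, 1.0]]))
        assert np.all(x >= cfg.lower) and np.all(x <= cfg.upper)


class TestOptimize:
    def test_history_monotone_and_bounds_respected(self):
        cfg = box(dim=3, n_objects=10, tmax=40, seed=5)
        seen = []

        def fn(x):
            seen.append(x.copy())
            return sphere(x)

        res = optimize(fn, cfg)
        assert all(b <= a for a, b in zip(res.history, res.history[1:]))
        for x in seen:
            assert np.all(x >= cfg.lower - 1e-12) and np.all(x <= cfg.upper + 1e-12)
        assert res.n_evaluations == cfg.n_objects * (cfg.tmax + 1)

    def test_deterministic_under_fixed_seed(self):
        cfg = box(dim=2, n_objects=8, tmax=20, seed=9)
        a = optimize(sphere, cfg)
        b = optimize(sphere, cfg)
        assert np.array_equal(a.best_x, b.best_x)
        assert a.history == b.history

    def test_single_iteration_returns_best_of_one_cycle(self):
        cfg = box(dim=2, n_objects=6, tmax=1, seed=2)
        res = optimize(sphere, cfg)
        assert len(res.history) == 2
        assert res.best_fitness == min(res.history)

    def test_constant_fitness_flat_history(self):
        cfg = box(dim=2, n_objects=5, tmax=10, seed=1)
        res = optimize(lambda x: 3.25, cfg)
        assert res.best_fitness == 3.25
        assert set(res.history) == {3.25}

    def test_nan_fitness_treated_as_infinite(self, caplog):
        cfg = box(dim=1, n_objects=4, tmax=2, seed=0)
        with caplog.at_level("WARNING", logger="p2c.aoa"):
            res = optimize(lambda x: float("nan"), cfg)
        assert res.best_fitness == np.inf
        assert any("NaN" in r.message for r in caplog.records)

    def test_beats_random_search_on_quadratics(self):
        shift = np.array([1.0, -2.0, 0.5])
        for fn in (sphere, lambda x: float(np.sum((x - shift) ** 2))):
            aoa_best, rs_best = [], []
            for seed in range(3):
                cfg = box(dim=3, n_objects=15, tmax=60, seed=seed)
                aoa_best.append(optimize(fn, cfg).best_fitness)
                rs_best.append(random_search(fn, cfg).best_fitness)
            assert np.median(aoa_best) < np.median(rs_best)
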