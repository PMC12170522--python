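import math

import numpy as np
import pytest

from eiaofs.eiao import (
    IterationFactors,
    OptimizerConfig,
    binarize,
    chaotic_init,
    draw_iteration_factors,
    elite_opposition,
    laplace_crossover,
    laplace_sample,
    levy_step,
    logistic_sequence,
    optimize,
    quality_factor,
    reliability_factor,
    signed_power,
    stage1_collect,
    stage2_filter,
    stage3_organize,
    subjective_influence,
    transfer_sigmoid,
)
from eiaofs.fitness import FitnessConfig, SubsetEvaluator
from eiaofs.synthetic import exhaustive_oracle, generate_fs_benchmark


def _factors(**kw):
    base = dict(theta=0.5, xi=1.0, phi=0.6, gamma=1.0, delta=0.3, lam=-2.0, r5=1.0)
    base.update(kw)
    return IterationFactors(**base)


class TestLogisticSequence:
    def test_first_iterate(self):
        seq = logistic_sequence(0.3, 4.0, 1)
        assert seq[0] == pytest.approx(0.84, abs=1e-12)  # 4 * 0.3 * 0.7

    def test_degenerate_start_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            logistic_sequence(0.5, 4.0, 3)

    def test_long_run_stays_in_unit_interval(self):
        seq = logistic_sequence(0.123, 4.0, 1000)
        assert np.all((seq >= 0.0) & (seq <= 1.0))

    def test_bad_mu_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            logistic_sequence(0.3, 4.5, 3)


class TestChaoticInit:
    def test_unit_box_positions_follow_the_map(self):
        cfg = OptimizerConfig(n_dims=10, n_agents=5, lb=0.0, ub=1.0)
        pos = chaotic_init(cfg, np.random.default_rng(3))
        # with lb=0, ub=1 positions are the raw iterates: each consecutive
        # pair satisfies the logistic recurrence
        for row in pos:
            np.testing.assert_allclose(row[1:], 4.0 * row[:-1] * (1.0 - row[:-1]),
                                       atol=1e-12)

    def test_midpoint_scaling(self):
        assert (4.0 - (-4.0)) * 0.5 + (-4.0) == 0.0

    def test_all_coordinates_within_bounds(self):
        cfg = OptimizerConfig(n_dims=10, n_agents=20, lb=-4.0, ub=4.0)
        pos = chaotic_init(cfg, np.random.default_rng(0))
        assert pos.shape == (20, 10)
        assert np.all(pos >= -4.0) and np.all(pos <= 4.0)


class TestEliteOpposition:
    def test_greedy_never_worsens_elites(self, rng):
        positions = rng.uniform(-4, 4, size=(20, 6))
        fitness = lambda pos: (None, float(np.sum(pos**2)))
        fits = np.array([fitness(p)[1] for p in positions])
        before = np.sort(fits)[:2].copy()
        _, after_fits, _ = elite_opposition(
            positions.copy(), fits.copy(), fitness, 0.1, -4.0, 4.0, rng
        )
        after = np.sort(after_fits)[:2]
        assert np.all(after <= before + 1e-12)

    def test_elite_count_is_ceiling(self, rng):
        calls = []

        def fitness(pos):
            calls.append(1)
            return None, float(pos.sum())

        positions = rng.uniform(-1, 1, size=(20, 4))
        fits = positions.sum(axis=1)
        elite_opposition(positions, fits, fitness, 0.1, -1.0, 1.0, rng)
        assert len(calls) == 2  # ceil(0.1 * 20)

    def test_opposite_point_algebra(self):
        # single elite with degenerate envelope da = db = x: the opposite is
        # r*(2x) - x = (2r - 1)*x
        x = np.array([1.0, -2.0, 0.5])
        r = 0.5
        opposite = r * (x + x) - x
        np.testing.assert_allclose(opposite, (2 * r - 1) * x, atol=1e-15)


class TestTransferAndBinarize:
    def test_sigmoid_at_zero(self):
        assert transfer_sigmoid(0.0) == 0.5

    def test_sigmoid_symmetry(self, rng):
        x = rng.normal(size=100) * 5
        np.testing.assert_allclose(
            transfer_sigmoid(x) + transfer_sigmoid(-x), 1.0, atol=1e-12
        )

    def test_sigmoid_at_four(self):
        # oracle: 1/(1 + e^-4) evaluated directly
        assert transfer_sigmoid(4.0) == pytest.approx(1.0 / (1.0 + math.exp(-4.0)))
        assert transfer_sigmoid(4.0) == pytest.approx(0.9820137900379085, abs=1e-12)

    def test_fixed_half_thresholds_at_sign(self, rng):
        bits = binarize(np.array([3.0, -3.0]), "fixed_half", rng)
        assert list(bits) == [True, False]

    def test_empty_mask_repaired_to_one_bit(self, rng):
        bits = binarize(np.full(30, -10.0), "fixed_half", rng)
        assert bits.sum() == 1

    def test_uniform_random_rate_at_origin(self):
        rng = np.random.default_rng(0)
        bits = binarize(np.zeros(100_000), "uniform_random", rng)
        assert bits.mean() == pytest.approx(0.5, abs=0.01)


class TestIterationFactors:
    def test_influence_zero_when_nu_zero(self, rng):
        assert subjective_influence(rng, nu=0.0) == 0.0

    def test_influence_zero_when_beta_one(self, rng):
        assert subjective_influence(rng, beta_r=1.0) == 0.0

    def test_influence_range(self):
        rng = np.random.default_rng(1)
        vals = np.array([subjective_influence(rng) for _ in range(100_000)])
        assert np.all((vals >= 0.0) & (vals < 2.0))

    def test_quality_zero_at_final_iteration(self, rng):
        for _ in range(20):
            assert quality_factor(50, 50, rng) == 0.0

    def test_quality_envelope(self, rng):
        for it in (1, 10, 25, 49):
            phi = quality_factor(it, 50, rng)
            assert abs(phi) <= 1.0 - it / 50 + 1e-12

    def test_quality_zero_at_cos_root(self, rng):
        delta = (math.pi / 2.0 - 1.0) / 2.0  # makes 2*delta + 1 = pi/2
        assert quality_factor(10, 50, rng, delta_r=delta) == pytest.approx(0.0, abs=1e-15)

    def test_reliability_at_final_iteration(self):
        assert reliability_factor(50, 50, 0.0) == pytest.approx(math.sin(math.pi / 4))

    def test_reliability_at_tenth(self):
        # oracle: sin(pi/40) - 1/8 by direct arithmetic
        expected = math.sin(math.pi / 40.0) - 0.125
        assert reliability_factor(5, 50, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_reliability_rejects_iteration_zero(self):
        with pytest.raises(ValueError):
            reliability_factor(0, 50, 0.0)

    def test_signed_power_negative_base(self):
        assert signed_power(-0.25, 0.5) == pytest.approx(-0.5)
        assert signed_power(0.0, 1.7) == 0.0

    def test_draw_bundles_consistent_derived_values(self):
        rng = np.random.default_rng(4)
        f = draw_iteration_factors(10, 50, rng)
        assert f.lam == pytest.approx(2.0 * (abs(f.gamma) - 2.0))
        expected_delta = signed_power(math.cos(math.pi / 2 * abs(f.gamma)), f.xi)
        assert f.delta == pytest.approx(expected_delta)
        assert 0.0 <= f.r5 < 2.0 * math.pi


class TestStage1:
    def test_zero_theta_is_identity(self, rng):
        pos = rng.uniform(-4, 4, size=(6, 5))
        cand = stage1_collect(pos, 0, 0.0, True, rng, -4.0, 4.0)
        np.testing.assert_allclose(cand, pos[0], atol=1e-15)

    def test_identical_population_is_identity(self, rng):
        pos = np.tile(rng.uniform(-4, 4, size=5), (6, 1))
        cand = stage1_collect(pos, 2, 0.7, True, rng, -4.0, 4.0)
        np.testing.assert_allclose(cand, pos[2], atol=1e-15)

    def test_dual_adds_exactly_second_difference(self, rng):
        from eiaofs.eiao import _difference_update

        x, r1, r2, r3, r4 = rng.normal(size=(5, 7))
        single = _difference_update(x, r1, r2, 0.3)
        dual = _difference_update(x, r1, r2, 0.3, r3, r4)
        np.testing.assert_allclose(dual - single, 0.3 * (r3 - r4), atol=1e-12)

    def test_too_small_population_rejected(self, rng):
        pos = rng.uniform(-1, 1, size=(4, 3))
        with pytest.raises(ValueError, match="donors"):
            stage1_collect(pos, 0, 0.5, True, rng, -1.0, 1.0)

    def test_candidate_clipped(self, rng):
        pos = np.array([[3.9, 3.9], [-3.9, 3.9], [3.9, -3.9]])
        for _ in range(20):
            cand = stage1_collect(pos, 0, 1.0, False, rng, -4.0, 4.0)
            assert np.all(cand >= -4.0) and np.all(cand <= 4.0)


class TestStage2:
    def test_reference_equal_to_self_is_identity(self, rng):
        x = rng.normal(size=6)
        for flag in (True, False):
            cand = stage2_filter(x, x, _factors(), flag, rng, -4.0, 4.0)
            np.testing.assert_allclose(cand, x, atol=1e-15)

    def test_zero_phase_sine_branch_is_identity(self, rng):
        x = rng.normal(size=6)
        other = rng.normal(size=6)
        cand = stage2_filter(
            x, other, _factors(r5=0.0), True, rng, -4.0, 4.0, branch=0.2
        )
        np.testing.assert_allclose(cand, x, atol=1e-15)

    def test_zero_delta_is_identity(self, rng):
        # xi = 1, |gamma| = 1 gives delta = cos(pi/2) = 0 up to roundoff
        delta = signed_power(math.cos(math.pi / 2.0), 1.0)
        x = rng.normal(size=6)
        other = rng.normal(size=6)
        cand = stage2_filter(
            x, other, _factors(delta=delta), False, rng, -4.0, 4.0
        )
        np.testing.assert_allclose(cand, x, atol=1e-12)


class TestLevyStep:
    def test_zero_scale(self, rng):
        np.testing.assert_array_equal(levy_step(8, 1.5, rng, scale=0.0), np.zeros(8))

    def test_length(self, rng):
        assert levy_step(13, 1.5, rng).shape == (13,)

    def test_heavy_tails(self):
        rng = np.random.default_rng(0)
        steps = levy_step(100_000, 1.5, rng)
        from scipy.stats import kurtosis

        assert kurtosis(steps, fisher=False) > 100.0  # Gaussian would be 3
        mags = np.abs(steps)
        assert mags.max() / np.median(mags) > 100.0

    def test_bad_exponent_rejected(self, rng):
        with pytest.raises(ValueError):
            levy_step(5, 2.5, rng)


class TestStage3:
    def test_constant_best_high_phi_no_levy(self, rng):
        c = 1.3
        x_best = np.full(6, c)
        f = _factors(phi=0.8, lam=-2.0)
        cand = stage3_organize(x_best, f, False, rng, -4.0, 4.0)
        cbrt = math.copysign(abs(f.lam) ** (1 / 3), f.lam)
        expected = c * math.cos(math.pi / 2.0 * cbrt)
        np.testing.assert_allclose(cand, expected, atol=1e-12)

    def test_gamma_two_gives_unit_contraction(self, rng):
        # |gamma| = 2 -> lam = 0 -> cos(0) = 1: first factor is x_best itself
        x_best = np.full(4, 0.7)
        f = _factors(phi=0.9, lam=0.0)
        cand = stage3_organize(x_best, f, False, rng, -4.0, 4.0)
        np.testing.assert_allclose(cand, x_best, atol=1e-12)

    def test_levy_adds_exactly_the_vector(self, rng):
        x_best = rng.normal(size=5)
        f = _factors(phi=0.2)
        vec = np.array([0.1, -0.2, 0.0, 0.3, -0.1])
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        off = stage3_organize(x_best, f, False, r1, -40.0, 40.0)
        on = stage3_organize(x_best, f, True, r2, -40.0, 40.0, levy_vec=vec)
        np.testing.assert_allclose(on - off, vec, atol=1e-12)


class TestLaplace:
    def test_as_printed_half_point(self, rng):
        val = laplace_sample(1.0, 2.0, rng, variant="as_printed", u=0.5)
        assert val == pytest.approx(1.0 + 2.0 * math.log(2.0))

    def test_two_uniform_moments(self):
        rng = np.random.default_rng(0)
        p, q = 0.7, 0.4
        samples = np.array(
            [laplace_sample(p, q, rng, variant="two_uniform") for _ in range(100_000)]
        )
        assert samples.mean() == pytest.approx(p, abs=0.05 * q)
        assert samples.var() == pytest.approx(2.0 * q**2, rel=0.05)

    def test_as_printed_support_gap(self):
        rng = np.random.default_rng(1)
        p, q = 0.0, 1.0
        samples = np.array(
            [laplace_sample(p, q, rng, variant="as_printed") for _ in range(20_000)]
        )
        gap = (samples > p) & (samples < p + q * math.log(2.0))
        assert not gap.any()

    def test_bad_q_rejected(self, rng):
        with pytest.raises(ValueError):
            laplace_sample(0.0, -1.0, rng)

    def test_crossover_identical_parents(self, rng):
        x = rng.normal(size=6)
        y1, y2 = laplace_crossover(x, x, 0.0, 0.5, rng)
        np.testing.assert_allclose(y1, x, atol=1e-12)
        np.testing.assert_allclose(y2, x, atol=1e-12)

    def test_crossover_preserves_parent_gap(self, rng):
        x1, x2 = rng.normal(size=(2, 8))
        y1, y2 = laplace_crossover(x1, x2, 0.0, 0.5, rng)
        np.testing.assert_allclose(y1 - y2, x1 - x2, atol=1e-12)

    def test_zero_deviate_returns_parents(self, rng):
        # l = 0 exactly when u = 1 in either branch with p = 0
        assert laplace_sample(0.0, 1.0, rng, variant="as_printed", u=1.0) == 0.0

    def test_crossover_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            laplace_crossover(np.zeros(3), np.zeros(4), 0.0, 0.5, rng)


class TestOptimize:
    def test_constant_fitness_flat_trace(self):
        cfg = OptimizerConfig.eiao(6, n_agents=8, max_iter=10, seed=0)
        res = optimize(lambda m: 0.42, cfg)
        assert res.best_fitness == 0.42
        assert all(f == 0.42 for f in res.trace)
        assert len(res.trace) == 10

    def test_seed_determinism(self, tiny_benchmark):
        X, y, _ = tiny_benchmark
        ev = SubsetEvaluator(X, y, FitnessConfig(seed=3))
        cfg = OptimizerConfig.eiao(X.shape[1], n_agents=10, max_iter=15, seed=3)
        a = optimize(ev, cfg)
        b = optimize(ev, cfg)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.trace == b.trace

    def test_trace_monotone_non_increasing(self, tiny_benchmark):
        X, y, _ = tiny_benchmark
        ev = SubsetEvaluator(X, y, FitnessConfig(seed=1))
        for seed in range(3):
            res = optimize(
                ev, OptimizerConfig.eiao(X.shape[1], n_agents=10, max_iter=20, seed=seed)
            )
            assert all(a >= b - 1e-15 for a, b in zip(res.trace, res.trace[1:]))

    def test_ablation_matches_iao_preset(self, tiny_benchmark):
        X, y, _ = tiny_benchmark
        ev = SubsetEvaluator(X, y, FitnessConfig(seed=5))
        flags_off = OptimizerConfig(
            n_dims=X.shape[1],
            n_agents=10,
            max_iter=15,
            seed=5,
            dual_difference=False,
            sine_cosine_stage2=False,
            levy_stage3=False,
            laplace_crossover=False,
            elite_opposition=False,
        )
        iao = OptimizerConfig.iao(X.shape[1], n_agents=10, max_iter=15, seed=5)
        a = optimize(ev, flags_off)
        b = optimize(ev, iao)
        assert a.trace == b.trace
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.best_fitness == b.best_fitness

    def test_never_beats_exhaustive_oracle(self):
        X, y, _ = generate_fs_benchmark(80, 8, 2, class_sep=1.0, seed=2)
        fcfg = FitnessConfig(seed=2)
        _, best_fit, _ = exhaustive_oracle(X, y, fcfg)
        ev = SubsetEvaluator(X, y, fcfg)
        for seed in range(3):
            res = optimize(ev, OptimizerConfig.eiao(8, n_agents=10, max_iter=15, seed=seed))
            assert res.best_fitness >= best_fit - 1e-12

    def test_fitness_error_is_contextualised(self):
        def bad(mask):
            raise ZeroDivisionError("boom")

        cfg = OptimizerConfig.eiao(5, n_agents=6, max_iter=3, seed=0)
        with pytest.raises(RuntimeError, match="init agent 0"):
            optimize(bad, cfg)

    def test_result_serialization(self, tmp_path):
        cfg = OptimizerConfig.eiao(6, n_agents=8, max_iter=5, seed=0)
        res = optimize(lambda m: float(m.sum()), cfg)
        res.save_json(tmp_path / "sel.json")
        res.save_trace_csv(tmp_path / "trace.csv")
        import json

        data = json.loads((tmp_path / "sel.json").read_text())
        assert data["n_selected"] == len(data["selected_indices"])
        assert len(data["mask_bits"]) == 6
        lines = (tmp_path / "trace.csv").read_text().strip().splitlines()
        assert len(lines) == 6  # header + 5 iterations

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(n_dims=5, lb=1.0, ub=-1.0)
        with pytest.raises(ValueError):
            OptimizerConfig(n_dims=5, elite_fraction=1.5)
        with pytest.raises(ValueError):
            OptimizerConfig(n_dims=5, n_agents=4)  # dual difference needs 5
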