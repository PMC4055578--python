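import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glossim import (DEFAULT_H, DispersalParams, FlyField, VegetationGrid,
                     classical_mean_displacement, diffuse_step,
                     displacement_after, make_band, make_block,
                     make_checkerboard, match_h, stabilize)
from glossim.kinematics import ConvergenceError, DiffusionOperator


class TestMatching:
    def test_classical_displacement_anchor(self):
        # 196 steps of 10 m: the conventional 124.1 m calibration point
        assert classical_mean_displacement(10, 196) == pytest.approx(124.1, abs=0.1)

    def test_zero_steps(self):
        assert classical_mean_displacement(10, 0) == 0.0

    def test_daily_displacement_of_matched_walk(self):
        # the matched walk (h = 0.7858) over the 1000-step daily
        # allocation displaces ~248 m, the riverine-compatible figure
        daily = classical_mean_displacement(10, 1000) * np.sqrt(DEFAULT_H)
        assert daily == pytest.approx(248.5, abs=0.5)

    def test_match_h_anchor(self):
        assert match_h(10, 196) == pytest.approx(0.7858, abs=0.0005)

    def test_match_h_equals_pi_over_4(self):
        assert match_h(10, 196) == pytest.approx(np.pi / 4, abs=0.001)

    @pytest.mark.parametrize("x,n", [(1.0, 7), (10.0, 196), (3.3, 1000)])
    def test_match_h_independent_of_step_size_and_count(self, x, n):
        assert match_h(x, n) == pytest.approx(np.pi / 4, rel=1e-12)

    def test_match_h_with_rounded_anchor(self):
        # using the printed 124.1 m instead of the closed form
        assert match_h(10, 196, reference_displacement=124.1) == pytest.approx(
            0.7858, abs=0.0005)


class TestDiffuseStep:
    def test_uniform_field_is_fixed_point(self, homogeneous_small):
        field = FlyField(np.ones(homogeneous_small.shape))
        out = diffuse_step(field, homogeneous_small)
        np.testing.assert_allclose(out.density, field.density, atol=1e-14)

    def test_point_mass_kernel_h1(self, homogeneous_small):
        density = np.zeros(homogeneous_small.shape)
        density[15, 15] = 1.0
        out = diffuse_step(FlyField(density), homogeneous_small,
                           DispersalParams(h=1.0))
        assert out.density[15, 15] == 0.0
        for r, c in [(14, 15), (16, 15), (15, 14), (15, 16)]:
            assert out.density[r, c] == pytest.approx(0.25)

    def test_crossing_rule_good_to_poor(self):
        # flow into a poor neighbor is scaled by 0.1; the failed 90% returns
        entry = np.ones((1, 3))
        entry[0, 2] = 0.1
        grid = VegetationGrid(entry)
        density = np.zeros((1, 3))
        density[0, 1] = 1.0
        out = diffuse_step(FlyField(density), grid).density
        q = DEFAULT_H / 4
        assert out[0, 2] == pytest.approx(0.1 * q)
        assert out[0, 0] == pytest.approx(q)
        assert out[0, 1] == pytest.approx(1 - q - 0.1 * q)

    def test_no_flow_into_nogo(self):
        entry = np.array([[1.0, 0.0]])
        grid = VegetationGrid(entry)
        out = diffuse_step(FlyField(np.array([[1.0, 0.0]])), grid).density
        assert out[0, 1] == 0.0
        assert out[0, 0] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, homogeneous_small):
        with pytest.raises(ValueError):
            diffuse_step(FlyField(np.ones((3, 3))), homogeneous_small)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_on_random_landscapes(self, seed):
        # exact conservation of flies on arbitrary legal vegetation
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 12), rng.integers(1, 12))
        entry = rng.choice([1.0, 0.1, 0.0], size=shape)
        entry[rng.integers(shape[0]), rng.integers(shape[1])] = 1.0
        grid = VegetationGrid(entry)
        density = rng.random(shape) * grid.habitable_mask
        op = DiffusionOperator(grid)
        total = density.sum()
        for _ in range(50):
            density = op.step(density)
        assert abs(density.sum() - total) <= 1e-12 * max(1.0, total) * 50
        assert density.min() >= 0


class TestDisplacement:
    def test_zero_steps_zero_displacement(self, homogeneous_small):
        stats = displacement_after(homogeneous_small, 0)
        assert stats.mean_displacement == 0.0

    def test_monotone_in_h(self, homogeneous_small):
        d = [displacement_after(homogeneous_small, 100,
                                DispersalParams(h=h)).mean_displacement
             for h in (0.2, 0.5, 0.7858, 1.0)]
        assert all(a < b for a, b in zip(d, d[1:]))

    def test_sqrt_n_growth_in_homogeneous_limit(self):
        grid = make_block(200)
        d = {n: displacement_after(grid, n).mean_displacement
             for n in (100, 400, 1600)}
        assert d[400] / d[100] == pytest.approx(2.0, rel=0.02)
        assert d[1600] / d[400] == pytest.approx(2.0, rel=0.02)

    def test_matches_classical_law_at_196_steps(self):
        # deterministic lattice walk vs the matched classical closed form
        grid = make_block(200)
        expected = classical_mean_displacement(10, 196) * np.sqrt(DEFAULT_H)
        got = displacement_after(grid, 196).mean_displacement
        assert got == pytest.approx(expected, rel=0.03)

    def test_band_beats_checkerboard_block_at_equal_width(self):
        # habitat-shape ordering of movement: band > block of the same width
        band = make_band(1, flank="nogo")
        board = make_checkerboard(1)
        d_band = displacement_after(band, 1000).mean_displacement
        d_board = displacement_after(board, 1000).mean_displacement
        assert d_band > d_board

    def test_displacement_increases_with_habitat_width(self):
        widths = (1, 5, 45)
        d = [displacement_after(make_band(w, flank="nogo"), 1000).mean_displacement
             for w in widths]
        assert all(a < b for a, b in zip(d, d[1:]))

    def test_seed_in_nogo_rejected(self, single_cell_habitat):
        with pytest.raises(ValueError):
            displacement_after(single_cell_habitat, 10, seed_cell=(0, 0))


def _walker_oracle(grid, n_steps, n_walkers, seed, h=DEFAULT_H):
    """Stochastic single-walker simulation of the same movement rules.

    Independent of the deterministic operator: walkers hold integer
    positions; each step picks one of four directions with probability
    h/4 each, bounces at map edges and applies the vegetation crossing
    rule as a Bernoulli draw.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid.shape
    r0, c0 = n_rows // 2, n_cols // 2
    rows = np.full(n_walkers, r0)
    cols = np.full(n_walkers, c0)
    p = grid.entry
    moves = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
    for _ in range(n_steps):
        u = rng.random(n_walkers)
        attempt = u < h
        direction = rng.integers(0, 4, n_walkers)
        dr = moves[direction, 0]
        dc = moves[direction, 1]
        nr = np.clip(rows + dr, 0, n_rows - 1)
        nc = np.clip(cols + dc, 0, n_cols - 1)
        off_map = (rows + dr != nr) | (cols + dc != nc)
        ps = p[rows, cols]
        pd = p[nr, nc]
        ratio = np.where(pd >= ps, 1.0, np.divide(pd, ps, out=np.zeros_like(pd),
                                                  where=ps > 0))
        cross = attempt & ~off_map & (rng.random(n_walkers) < ratio)
        rows = np.where(cross, nr, rows)
        cols = np.where(cross, nc, cols)
    dist = 10.0 * np.hypot(rows - r0, cols - c0)
    return dist.mean(), dist.std(ddof=1) / np.sqrt(n_walkers)


class TestMonteCarloOracle:
    @pytest.mark.parametrize("landscape", ["homogeneous", "poor_stripe"])
    def test_deterministic_matches_walkers(self, landscape):
        if landscape == "homogeneous":
            grid = make_block(25, shape=(25, 25))
        else:
            entry = np.ones((25, 25))
            entry[:, 12:15] = 0.1
            grid = VegetationGrid(entry)
        det = displacement_after(grid, 200).mean_displacement
        mc_mean, mc_se = _walker_oracle(grid, 200, 120_000, seed=7)
        assert abs(det - mc_mean) <= 3 * mc_se


class TestStabilize:
    def test_homogeneous_gives_uniform(self, homogeneous_small):
        field = stabilize(homogeneous_small, tol=1e-12)
        np.testing.assert_allclose(field.density,
                                   field.total / field.density.size, rtol=1e-6)

    def test_good_poor_density_ratio_ten_to_one(self):
        # detailed balance of the crossing rule: density ~ entry probability
        grid = make_checkerboard(5, shape=(20, 20))
        field = stabilize(grid, tol=1e-13)
        good = field.density[grid.entry == 1.0].mean()
        poor = field.density[grid.entry == 0.1].mean()
        assert good / poor == pytest.approx(10.0, rel=1e-3)

    def test_band_keeps_all_mass_inside(self):
        grid = make_band(3, flank="nogo", shape=(21, 40))
        field = stabilize(grid, tol=1e-12)
        assert field.density[~grid.habitable_mask].max() == 0.0
        assert field.total == pytest.approx(1.0)

    def test_nonconvergence_raises(self):
        grid = make_block(31, shape=(31, 31))
        with pytest.raises(ConvergenceError):
            stabilize(grid, tol=1e-300, max_iter=5,
                      initial=np.random.default_rng(0).random(grid.shape))
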