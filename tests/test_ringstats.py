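import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonemap import ringstats, synthetic
from clonemap.core_model import StudyTable
from clonemap.ringstats import (DensityProfile, RingGrid, SimulationBand,
                                annulus_coverage, average_profiles,
                                bootstrap_relabel, clonality_call,
                                coverage_fraction, monte_carlo_band,
                                ring_volume, same_color_ring_density,
                                stack_density_profiles)

from conftest import make_stack

GRID = RingGrid()


def brute_force_densities(stack, grid, metric="xy", edge_correction=True):
    """Independent O(n²) per-cell enumeration of the ring-density statistic."""
    pos = stack.positions(metric)
    colors = stack.colors()
    n = len(stack.cells)
    inv = ringstats._stack_inverse_volumes(stack, grid, metric, edge_correction)
    out = np.zeros((n, len(grid.radii)))
    for i in range(n):
        delta = pos - pos[i]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        d[i] = -1.0
        for j, (lo, hi) in enumerate(grid.edges):
            count = int(np.sum((d > lo) & (d <= hi) & (colors == colors[i])))
            out[i, j] = count * inv[i, j]
    return out


class TestRingVolume:
    def test_direct_evaluation(self):
        assert ring_volume(50, 20, 20) == pytest.approx(125663.70614359171)

    @given(st.floats(1, 50), st.floats(26, 500), st.floats(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, w, r, s):
        expected = s * np.pi * ((r + w / 2) ** 2 - (r - w / 2) ** 2)
        assert ring_volume(r, w, s) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_height(self):
        assert ring_volume(100, 20, 60) == pytest.approx(2 * ring_volume(100, 20, 30))

    def test_radius_too_small_rejected(self):
        with pytest.raises(ValueError):
            ring_volume(10, 20, 30)


class TestCoverage:
    def test_fully_inside_is_one(self):
        assert coverage_fraction((200, 200), 50, 20, (400, 400)) == 1.0

    def test_bisected_annulus_half(self):
        # center on the x = 0 edge of a huge footprint: exactly half covered
        assert coverage_fraction((0, 5e5), 100, 20, (1e6, 1e6)) == \
               pytest.approx(0.5, abs=1e-3)

    def test_outside_footprint_can_be_zero(self):
        assert coverage_fraction((-500, -500), 50, 20, (100, 100)) == 0.0

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cx, cy = rng.uniform(-50, 450, size=2)
            r = rng.uniform(30, 200)
            w = 20.0
            got = coverage_fraction((cx, cy), r, w, (400, 400))
            # Monte Carlo area estimate: uniform points in the annulus
            m = 10 ** 6
            theta = rng.uniform(0, 2 * np.pi, m)
            rho = np.sqrt(rng.uniform((r - w / 2) ** 2, (r + w / 2) ** 2, m))
            px, py = cx + rho * np.cos(theta), cy + rho * np.sin(theta)
            inside = ((px >= 0) & (px <= 400) & (py >= 0) & (py <= 400)).mean()
            se = np.sqrt(inside * (1 - inside) / m) + 1e-9
            assert abs(got - inside) < 3 * se + 1e-3


class TestSameColorDensity:
    def test_isolated_cell_zero_everywhere(self):
        stack = make_stack([(200, 200, 10)], ["YFP"])
        for j in range(len(GRID.radii)):
            assert same_color_ring_density(stack, stack.cells[0], j, GRID) == 0.0

    def test_boundary_interval_semantics(self):
        # two same-color cells exactly 50 µm apart: the distance is in the
        # half-open intervals (30, 50] of ring 40 and (40, 60] of ring 50
        stack = make_stack([(150, 200, 10), (200, 200, 10)], ["RFP", "RFP"])
        dens = stack_density_profiles(stack, GRID, edge_correction=False)
        radii = np.array(GRID.radii)
        v40 = ring_volume(40, 20, 30)
        v50 = ring_volume(50, 20, 30)
        for j, r in enumerate(radii):
            if r == 40:
                assert dens[0, j] == pytest.approx(1 / v40)
            elif r == 50:
                assert dens[0, j] == pytest.approx(1 / v50)
            else:
                assert dens[0, j] == 0.0

    def test_different_colors_do_not_count(self):
        stack = make_stack([(150, 200, 10), (200, 200, 10)], ["RFP", "YFP"])
        dens = stack_density_profiles(stack, GRID)
        assert np.all(dens == 0.0)

    def test_cell_not_in_stack_rejected(self):
        stack = make_stack([(150, 200, 10)], ["RFP"])
        other = make_stack([(10, 10, 10)], ["RFP"], image_id="other")
        with pytest.raises(ValueError):
            same_color_ring_density(stack, other.cells[0], 0, GRID)

    @pytest.mark.parametrize("metric", ["xy", "3d"])
    def test_brute_force_oracle(self, metric):
        for seed in range(3):
            stack = synthetic.simulate_random_pattern(
                40000, (400, 400, 30), seed=seed)
            fast = stack_density_profiles(stack, GRID, metric=metric)
            slow = brute_force_densities(stack, GRID, metric=metric)
            assert np.array_equal(fast, slow)

    def test_scale_covariance(self):
        """Scaling coordinates, radii, width and height by α scales densities
        by α⁻³ (cells per µm³)."""
        alpha = 2.0
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 1, (60, 3)) * np.array([400, 400, 30.0])
        colors = rng.choice(["YFP", "RFP"], size=60)
        base = make_stack(pos, colors)
        scaled = make_stack(pos * alpha, colors,
                            bounds=(400 * alpha, 400 * alpha, 30 * alpha))
        grid2 = RingGrid(radii=tuple(r * alpha for r in GRID.radii),
                         width=GRID.width * alpha)
        d1 = stack_density_profiles(base, GRID)
        d2 = stack_density_profiles(scaled, grid2)
        assert np.allclose(d2, d1 / alpha ** 3, rtol=1e-9, atol=1e-30)

    def test_color_symmetry(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 1, (80, 3)) * np.array([400, 400, 30.0])
        colors = rng.choice(["mCFP", "nGFP", "YFP", "RFP"], size=80)
        perm = {"mCFP": "RFP", "RFP": "YFP", "YFP": "nGFP", "nGFP": "mCFP"}
        a = stack_density_profiles(make_stack(pos, colors), GRID)
        b = stack_density_profiles(
            make_stack(pos, [perm[c] for c in colors]), GRID)
        assert np.array_equal(a, b)


class TestAveraging:
    def test_single_cell_identity(self):
        dens = np.arange(29.0).reshape(1, 29)
        out = average_profiles([dens], ["i0"], ["m0"], GRID)
        assert np.array_equal(out["group"].values, dens[0])

    def test_unweighted_mouse_mean(self):
        # mouse A: two cells in one image averaging 2; mouse B: one cell at 4
        a = np.full((2, 29), 2.0)
        a[0] += 1
        a[1] -= 1
        b = np.full((1, 29), 4.0)
        out = average_profiles([a, b], ["iA", "iB"], ["mA", "mB"], GRID)
        assert np.allclose(out["group"].values, 3.0)

    def test_image_permutation_invariance(self):
        rng = np.random.default_rng(2)
        dens = [rng.random((3, 29)) for _ in range(4)]
        imgs = ["i0", "i1", "i2", "i3"]
        mice = ["m0", "m0", "m1", "m1"]
        fwd = average_profiles(dens, imgs, mice, GRID)["group"].values
        rev = average_profiles(dens[::-1], imgs[::-1], mice[::-1], GRID)["group"].values
        assert np.allclose(fwd, rev)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([np.empty((0, 29))], ["i0"], ["m0"], GRID)


class TestBootstrap:
    def test_single_color_vector(self, random_stack):
        out = bootstrap_relabel(random_stack, ["YFP"], seed=0)
        assert all(c.color == "YFP" for c in out.cells)

    def test_positions_fixed(self, random_stack):
        out = bootstrap_relabel(random_stack, ["YFP", "RFP"], seed=1)
        assert np.array_equal(out.positions(), random_stack.positions())

    def test_empty_vector_rejected(self, random_stack):
        with pytest.raises(ValueError):
            bootstrap_relabel(random_stack, [], seed=0)

    def test_draw_frequencies(self):
        stack = make_stack(np.zeros((10000, 3)) + 5, ["YFP"] * 10000)
        vec = ["YFP"] * 3 + ["RFP"]
        out = bootstrap_relabel(stack, vec, seed=3)
        frac = np.mean([c.color == "RFP" for c in out.cells])
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 10000)


class TestMonteCarloBand:
    def test_degenerate_percentiles(self, random_stack):
        rec, band = monte_carlo_band(StudyTable(stacks=[random_stack]), GRID,
                                     n_sims=1, percentiles=(0, 100), seed=5)
        assert np.array_equal(band.lower, band.upper)

    def test_empty_group_rejected(self):
        empty = make_stack([], [])
        with pytest.raises(ValueError):
            monte_carlo_band(StudyTable(stacks=[empty]), GRID, n_sims=2, seed=0)

    def test_reproducible(self, random_stack):
        a = monte_carlo_band(StudyTable(stacks=[random_stack]), GRID,
                             n_sims=20, seed=9)
        b = monte_carlo_band(StudyTable(stacks=[random_stack]), GRID,
                             n_sims=20, seed=9)
        assert np.array_equal(a[1].upper, b[1].upper)

    def test_clonal_group_flagged_at_short_range(self):
        """A tight Thomas-process group must exceed the band at small radii."""
        def make(mouse_id, image_id, rng):
            cfg = synthetic.ClonalSimConfig(
                parent_intensity=600, offspring_mean=5, dispersion_sigma=15,
                background_intensity=400, bounds=(580.0, 580.0, 30.0))
            stack, _ = synthetic.simulate_clonal_pattern(
                cfg, image_id=image_id, mouse_id=mouse_id, seed=rng)
            return stack
        study = synthetic.simulate_study(3, 3, make, seed=77)
        analysis = ringstats.analyze_group(study, GRID, n_sims=100, seed=78)
        radii = np.array(GRID.radii)
        assert analysis.flags[radii <= 60].all()


class TestClonalityCall:
    def _profile(self, values):
        return DensityProfile("group", GRID, np.asarray(values, float),
                              np.ones(len(GRID.radii)))

    def test_equal_to_upper_not_flagged(self):
        v = np.linspace(1, 2, len(GRID.radii))
        band = SimulationBand(GRID, lower=v * 0.5, upper=v)
        assert not clonality_call(self._profile(v), band).flags.any()

    def test_single_exceedance_flagged(self):
        upper = np.ones(len(GRID.radii))
        rec = np.ones(len(GRID.radii))
        rec[0] = 2.0
        band = SimulationBand(GRID, lower=np.zeros_like(upper), upper=upper)
        call = clonality_call(self._profile(rec), band)
        assert call.flags.sum() == 1 and call.flags[0]
        assert call.max_excess_ratio == pytest.approx(2.0)
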