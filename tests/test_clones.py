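from fractions import Fraction

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from clonemap import synthetic
from clonemap.clones import (SINGLET, CloneParams, clone_density,
                             clone_size_summary, detect_clones,
                             proliferation_index, singlet_fraction)
from clonemap.core_model import StudyTable

from conftest import make_stack


def single_linkage_oracle(stack, epsilon, metric="3d"):
    """Connected components of the per-color ε-threshold graph — the
    reference partition DBSCAN must equal at minPts = 2."""
    clones, singlets = [], []
    colors = stack.colors()
    pos = stack.positions(metric)
    for color in np.unique(colors):
        idx = np.flatnonzero(colors == color)
        if len(idx) == 1:
            singlets.append(stack.cells[idx[0]].cell_id)
            continue
        d = squareform(pdist(pos[idx]))
        adj = csr_matrix((d <= epsilon) & (d > 0))
        n_comp, labels = connected_components(adj, directed=False)
        for k in range(n_comp):
            members = [stack.cells[idx[m]].cell_id
                       for m in np.flatnonzero(labels == k)]
            if len(members) == 1:
                singlets.append(members[0])
            else:
                clones.append(frozenset(members))
    return set(clones), set(singlets)


def cloneset_as_sets(cs):
    return ({frozenset(c.cell_id for c in m) for m in cs.clones.values()},
            {cid for cid, v in cs.assignment.items() if v == SINGLET})


class TestDetectClones:
    def test_pair_within_epsilon_is_clone(self):
        stack = make_stack([(0, 0, 0), (49, 0, 0)], ["YFP", "YFP"])
        cs = detect_clones(stack)
        assert cs.n_clones == 1 and cs.clone_sizes() == [2]

    def test_pair_beyond_epsilon_are_singlets(self):
        stack = make_stack([(0, 0, 0), (51, 0, 0)], ["YFP", "YFP"])
        cs = detect_clones(stack)
        assert cs.n_clones == 0 and cs.n_singlets == 2

    def test_chain_is_density_connected(self):
        stack = make_stack([(0, 0, 0), (40, 0, 0), (80, 0, 0)], ["RFP"] * 3)
        cs = detect_clones(stack)
        assert cs.clone_sizes() == [3]

    def test_colors_cluster_independently(self):
        stack = make_stack([(0, 0, 0), (10, 0, 0)], ["YFP", "RFP"])
        cs = detect_clones(stack)
        assert cs.n_clones == 0 and cs.n_singlets == 2

    def test_partition_and_color_purity(self):
        stack = synthetic.simulate_random_pattern(30000, (400, 400, 30), seed=2)
        cs = detect_clones(stack)
        assert set(cs.assignment) == {c.cell_id for c in stack.cells}
        for members in cs.clones.values():
            assert len(members) >= 2
            assert len({c.color for c in members}) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_single_linkage_oracle(self, seed):
        stack = synthetic.simulate_random_pattern(20000, (400, 400, 30),
                                                  seed=seed)
        got = cloneset_as_sets(detect_clones(stack))
        assert got == single_linkage_oracle(stack, 50.0)

    def test_epsilon_monotonicity(self):
        stack = synthetic.simulate_random_pattern(20000, (400, 400, 30), seed=7)
        counts = [detect_clones(stack, CloneParams(epsilon=e)).n_clones +
                  detect_clones(stack, CloneParams(epsilon=e)).n_singlets
                  for e in (10, 25, 50, 100, 200)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ground_truth_recovery_with_separated_parents(self):
        stack, truth = well_separated_clonal(seed=3)
        cs = detect_clones(stack)
        expected_sizes = sorted(v for v in truth.clone_sizes.values() if v >= 2)
        assert cs.clone_sizes() == expected_sizes
        assert cs.n_clones == len(expected_sizes)


def well_separated_clonal(seed, n_clones=6, sigma=10.0, mean_size=5.0):
    """Clonal pattern with parents on a grid spaced ≥ 3ε so detection is
    unambiguous."""
    return synthetic.simulate_separated_clonal_pattern(
        n_clones=n_clones, spacing=220.0, sigma=sigma,
        offspring_mean=mean_size, seed=seed)


class TestCloneStatistics:
    def test_clone_density_arithmetic(self):
        stack = make_stack([(0, 0, 0), (10, 0, 0), (100, 100, 0), (110, 100, 0),
                            (200, 200, 0), (210, 200, 0)], ["YFP"] * 6,
                           bounds=(200.0, 300.0, 100.0))  # 0.006 mm³
        cs = detect_clones(stack)
        assert cs.n_clones == 3
        assert clone_density(cs) == pytest.approx(500.0)

    def test_zero_clones_zero_density(self):
        stack = make_stack([(0, 0, 0)], ["YFP"], bounds=(100, 100, 100))
        assert clone_density(detect_clones(stack)) == 0.0

    def test_halving_volume_doubles_density(self):
        for h in (100.0, 50.0):
            stack = make_stack([(0, 0, 0), (10, 0, 0)], ["YFP", "YFP"],
                               bounds=(100, 100, h))
            d = clone_density(detect_clones(stack))
            if h == 100.0:
                base = d
        assert d == pytest.approx(2 * base)

    def test_size_summary_mean(self):
        stack = make_stack(
            [(0, 0, 0), (10, 0, 0),
             (100, 100, 0), (110, 100, 0),
             (200, 200, 0), (210, 200, 0), (220, 200, 0), (230, 200, 0), (240, 200, 0)],
            ["YFP"] * 9)
        summary = clone_size_summary([detect_clones(stack)])
        assert summary.sizes == [2, 2, 5]
        assert summary.mean_size == pytest.approx(3.0)

    def test_empty_summary_not_an_error(self):
        stack = make_stack([(0, 0, 0)], ["YFP"])
        summary = clone_size_summary([detect_clones(stack)])
        assert summary.mean_size is None and summary.n_clones == 0

    def test_generator_mean_size_recovery(self):
        sizes = []
        for seed in range(20):
            stack, _ = well_separated_clonal(seed=seed, mean_size=5.0)
            sizes.extend(len(m) for m in detect_clones(stack).clones.values())
        # detection drops singleton clones, which biases the mean upward; the
        # truncated-Poisson mean restricted to sizes ≥ 2 is the fair target
        k = np.arange(2, 60)
        from scipy.stats import poisson
        pmf = poisson.pmf(k - 1, 4.0)
        target = float((k * pmf).sum() / pmf.sum())
        assert abs(np.mean(sizes) - target) / target < 0.1

    def test_singlet_fraction_extremes(self):
        allsing = make_stack([(0, 0, 0), (200, 200, 0)], ["YFP", "YFP"])
        assert singlet_fraction(detect_clones(allsing)) == 1.0
        none = make_stack([(0, 0, 0), (10, 0, 0)], ["YFP", "YFP"])
        assert singlet_fraction(detect_clones(none)) == 0.0

    def test_singlet_fraction_rises_at_low_intensity(self):
        fracs = []
        for intensity in (40000, 10000, 2500):
            vals = []
            for seed in range(5):
                stack = synthetic.simulate_random_pattern(
                    intensity, (400, 400, 30), seed=seed)
                vals.append(singlet_fraction(detect_clones(stack)))
            fracs.append(np.mean(vals))
        assert fracs[0] < fracs[1] < fracs[2]


class TestProliferationIndex:
    def test_exact_fraction(self):
        stack = make_stack([(i * 10, 0, 0) for i in range(6)], ["YFP"] * 6,
                           ki67=[True, True, False, False, False, False])
        cs = detect_clones(stack)
        members = next(iter(cs.clones.values()))
        assert proliferation_index(members) == Fraction(1, 3)

    def test_none_positive_is_zero(self):
        stack = make_stack([(0, 0, 0), (10, 0, 0)], ["YFP"] * 2,
                           ki67=[False, False])
        members = next(iter(detect_clones(stack).clones.values()))
        assert proliferation_index(members) == 0

    def test_missing_flag_names_cell(self):
        stack = make_stack([(0, 0, 0), (10, 0, 0)], ["YFP"] * 2)
        members = next(iter(detect_clones(stack).clones.values()))
        with pytest.raises(ValueError, match=members[0].cell_id):
            proliferation_index(members)

    def test_decreasing_probability_gives_negative_correlation(self):
        from scipy.stats import spearmanr
        negatives = 0
        for seed in range(6):
            sizes, idx = [], []
            root = np.random.SeedSequence(seed)
            for k, stream in enumerate(root.spawn(9)):  # 3 mice × 3 stacks
                cfg = synthetic.ClonalSimConfig(
                    parent_intensity=1500, offspring_mean=5,
                    dispersion_sigma=10, bounds=(580.0, 580.0, 30.0))
                rng = np.random.default_rng(stream)
                stack, truth = synthetic.simulate_clonal_pattern(
                    cfg, image_id=f"i{k}", seed=rng)
                stack = synthetic.assign_ki67(stack, truth,
                                              lambda s: 0.9 / s, seed=rng)
                cs = detect_clones(stack)
                sizes.extend(len(m) for m in cs.clones.values())
                idx.extend(float(proliferation_index(m))
                           for m in cs.clones.values())
            rho = spearmanr(sizes, idx).statistic
            negatives += rho < 0
        assert negatives == 6
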