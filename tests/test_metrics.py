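import itertools
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import antnet as an

# ---------------------------------------------------------------------------
# NODF


def nodf_bruteforce(binary):
    """Naive pairwise-overlap oracle, straight from the metric's definition."""
    b = np.asarray(binary)
    total, pairs = 0.0, 0
    for mat in (b, b.T):
        n = mat.shape[0]
        fills = mat.sum(axis=1)
        for i, j in itertools.combinations(range(n), 2):
            pairs += 1
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] > fills[lo] > 0:
                shared = int((mat[hi] & mat[lo]).sum())
                total += 100.0 * shared / fills[lo]
    return total / pairs


class TestNodf:
    def test_perfectly_nested_matrix_reaches_upper_bound(self, triangle5):
        assert an.nodf(triangle5) == pytest.approx(100.0)

    def test_equal_fills_give_zero(self):
        assert an.nodf(np.eye(2, dtype=int)) == 0.0

    def test_hand_enumerated_example(self):
        # row pairs contribute 0, 100, 100; column pairs 100, 100, 0
        m = [[1, 1, 0], [1, 0, 1], [1, 0, 0]]
        assert an.nodf(m) == pytest.approx(400.0 / 6.0)

    def test_too_small_matrix_is_undefined(self):
        with pytest.raises(an.UndefinedMetricError):
            an.nodf(np.ones((1, 5)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((4, 4)) < 0.5).astype(int)
        assert an.nodf(m) == pytest.approx(nodf_bruteforce(m), abs=1e-12)

    def test_breaking_overlap_strictly_decreases_nodf(self):
        # rows 3 and 0 are nested (row 3 a subset of row 0); moving one of
        # row 3's shared 1s to a column row 0 does not occupy breaks the
        # overlap and lowers the metric
        before = np.array([[0, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 1], [0, 1, 0, 1]])
        after = np.array([[0, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 1], [1, 0, 0, 1]])
        assert an.nodf(before) == pytest.approx(50.0)
        assert an.nodf(after) == pytest.approx(45.8333, abs=1e-4)
        assert an.nodf(after) < an.nodf(before)
        assert an.nodf(after) == pytest.approx(nodf_bruteforce(after), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_simultaneous_permutation(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((5, 6)) < 0.5).astype(int)
        perm = m[rng.permutation(5)][:, rng.permutation(6)]
        assert an.nodf(m) == pytest.approx(an.nodf(perm), abs=1e-9)

    def test_agrees_with_vegan_reference(self, tmp_path):
        """Independent oracle: the R vegan implementation of the same metric."""
        rng = np.random.default_rng(5)
        m = (rng.random((8, 10)) < 0.4).astype(int)
        m[m.sum(axis=1) == 0, 0] = 1
        for j in np.flatnonzero(m.sum(axis=0) == 0):
            m[0, j] = 1
        mat_path = tmp_path / "m.txt"
        np.savetxt(mat_path, m, fmt="%d")
        script = tmp_path / "nodf.R"
        script.write_text(
            f"m <- as.matrix(read.table('{mat_path}'))\n"
            "suppressMessages(library(vegan))\n"
            "r <- nestednodf(m, order=TRUE, weighted=FALSE)\n"
            "cat(sprintf('%.10f', r$statistic['NODF']))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        assert an.nodf(m) == pytest.approx(float(out.stdout), abs=1e-8)


# ---------------------------------------------------------------------------
# H2'


def h2min_exhaustive(row_totals, col_totals):
    """Minimum entropy over all 2x2 integer matrices with the given margins."""
    r1, r2 = row_totals
    c1, c2 = col_totals
    m = r1 + r2
    best = math.inf
    for a in range(min(r1, c1) + 1):
        b, c = r1 - a, c1 - a
        d = r2 - c
        if b < 0 or c < 0 or d < 0 or b > c2:
            continue
        p = np.array([a, b, c, d], dtype=float) / m
        p = p[p > 0]
        best = min(best, float(-(p * np.log(p)).sum()))
    return best


class TestH2Prime:
    def test_one_to_one_matrix_is_maximally_specialized(self):
        assert an.h2prime(np.diag([5, 5, 5])).h2_prime == pytest.approx(1.0)

    def test_uniform_matrix_is_maximally_generalized(self):
        assert an.h2prime(np.ones((2, 2))).h2_prime == pytest.approx(0.0)

    def test_mixed_matrix_frozen_values(self):
        res = an.h2prime([[3, 1], [1, 3]])
        assert res.h2 == pytest.approx(1.2555, abs=1e-4)
        assert res.h2_max == pytest.approx(math.log(4), abs=1e-12)
        assert res.h2_min == pytest.approx(math.log(2), abs=1e-12)
        assert res.h2_prime == pytest.approx(0.1887, abs=1e-4)

    def test_greedy_h2min_matches_exhaustive_on_2x2_margins(self):
        for rows, cols in [((4, 4), (4, 4)), ((5, 3), (6, 2)), ((7, 1), (4, 4))]:
            alloc = an.metrics._h2min_allocation(np.array(rows), np.array(cols))
            p = alloc.ravel() / sum(rows)
            p = p[p > 0]
            greedy = float(-(p * np.log(p)).sum())
            assert greedy == pytest.approx(h2min_exhaustive(rows, cols), abs=1e-12)

    def test_all_zero_matrix_is_undefined(self):
        with pytest.raises(an.UndefinedMetricError):
            an.h2prime(np.zeros((2, 2)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_h2prime_in_unit_interval_and_entropy_ordered(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 6, size=(rng.integers(2, 5), rng.integers(2, 5)))
        if m.sum() == 0:
            m[0, 0] = 1
        res = an.h2prime(m)
        assert 0.0 <= res.h2_prime <= 1.0
        assert res.h2 <= res.h2_max + 1e-9

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 5, size=(4, 5))
        m[0, 0] += 1
        perm = m[rng.permutation(4)][:, rng.permutation(5)]
        assert an.h2prime(m).h2_prime == pytest.approx(an.h2prime(perm).h2_prime, abs=1e-9)


# ---------------------------------------------------------------------------
# Jaccard and core turnover


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, 1.0),
            ({"a", "b"}, {"c", "d"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        ],
    )
    def test_values(self, a, b, expected):
        assert an.jaccard(a, b) == pytest.approx(expected)
        assert an.jaccard(b, a) == pytest.approx(expected)  # symmetric

    def test_two_empty_sets_undefined(self):
        with pytest.raises(an.UndefinedMetricError):
            an.jaccard(set(), set())


class TestGcScores:
    def test_standardized_degrees_and_core(self, degree_network):
        cp = an.gc_scores(degree_network)
        assert cp.k_mean == pytest.approx(2.0)
        assert cp.sigma_k == pytest.approx(1.6733, abs=1e-4)
        assert cp.gc == pytest.approx([1.7928, 0.5976] + [-0.5976] * 4, abs=1e-4)
        assert cp.core == {"a1"}

    def test_gc_scores_standardized_to_mean_zero_sd_one(self, degree_network):
        cp = an.gc_scores(degree_network)
        assert abs(cp.gc.mean()) < 1e-9
        assert cp.gc.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_equal_degrees_degenerate(self):
        records = [
            an.InteractionRecord(f"p{j}", f"a{i}", "diurnal", 1)
            for i in range(2)
            for j in range(3)
        ]
        net = an.build_network(records, "diurnal")
        with pytest.raises(an.DegenerateDegreeError):
            an.gc_scores(net)

    def test_two_species_never_exceed_threshold(self):
        records = [an.InteractionRecord(f"p{j}", "a1", "diurnal", 1) for j in range(10)]
        records.append(an.InteractionRecord("p0", "a2", "diurnal", 1))
        cp = an.gc_scores(an.build_network(records, "diurnal"))
        assert cp.gc == pytest.approx([0.7071, -0.7071], abs=1e-4)
        assert cp.core == set()

    def test_population_sd_preserves_classification(self, degree_network):
        sample = an.gc_scores(degree_network, sd="sample")
        population = an.gc_scores(degree_network, sd="population")
        assert sample.core == population.core

    def test_classification_invariant_to_relabeling(self, degree_network):
        renamed = an.BipartiteNetwork(
            tuple(f"z_{a}" for a in degree_network.ant_labels),
            degree_network.plant_labels,
            degree_network.weights,
            degree_network.period_tag,
        )
        assert an.gc_scores(renamed).core == {f"z_{a}" for a in an.gc_scores(degree_network).core}


class TestCoreTurnover:
    def _cp(self, core, periphery):
        ants = tuple(core + periphery)
        k = np.array([5.0] * len(core) + [1.0] * len(periphery))
        gc = np.array([2.0] * len(core) + [-0.5] * len(periphery))
        labels = tuple(
            [an.metrics.GENERALIST_CORE] * len(core) + [an.metrics.PERIPHERAL] * len(periphery)
        )
        return an.CorePeriphery(ants, k, gc, labels, 2.0, 1.5)

    @pytest.mark.parametrize(
        "day_core, night_core, expected",
        [
            (["A", "B"], ["C"], 1.0),
            (["A", "B"], ["A", "B"], 0.0),
            (["A", "B"], ["B", "C"], 1 - 1 / 3),
        ],
    )
    def test_turnover_values(self, day_core, night_core, expected):
        day = self._cp(day_core, ["x"])
        night = self._cp(night_core, ["y"])
        *_, turnover = an.core_turnover(day, night)
        assert turnover == pytest.approx(expected)
        *_, reverse = an.core_turnover(night, day)
        assert reverse == pytest.approx(expected)  # symmetric

    def test_both_cores_empty_undefined(self):
        empty = self._cp([], ["x", "y"])
        with pytest.raises(an.UndefinedMetricError):
            an.core_turnover(empty, empty)


# ---------------------------------------------------------------------------
# Descriptor battery


class TestDescriptors:
    def test_full_network_mean_richness(self):
        records = [
            an.InteractionRecord(f"p{j}", f"a{i}", "diurnal", 1)
            for i in range(2)
            for j in range(3)
        ]
        net = an.build_network(records, "diurnal")
        desc = an.descriptors(net)
        assert desc.mean_richness_per_plant == pytest.approx(2.0)
        assert desc.richness_sd == pytest.approx(0.0)
        assert desc.core_size == 0  # degenerate degrees, logged not raised

    def test_core_size_from_degree_distribution(self, degree_network):
        assert an.descriptors(degree_network).core_size == 1

    def test_one_to_one_network_fully_specialized(self):
        records = [an.InteractionRecord(f"p{i}", f"a{i}", "diurnal", 5) for i in range(3)]
        net = an.build_network(records, "diurnal")
        assert an.descriptors(net).h2prime == pytest.approx(1.0)
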