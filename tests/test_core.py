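import numpy as np
import pytest

from salicurves import (
    DegenerateInputError,
    SimilarityMatrix,
    ValidationError,
    edge_set,
    normalize,
    orientation_score,
    sali_curve,
    sali_histogram,
    sali_matrix,
    sci,
)
from conftest import random_similarity


# ---------------------------------------------------------------- oracles
def brute_force_s(observed, predicted, sim_values, x):
    """Independent S(X): explicit double loop over all pairs."""
    n = len(observed)
    pairs = [
        (i, j, abs(observed[i] - observed[j]) / (1 - sim_values[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if sim_values[i, j] < 1.0 and observed[i] != observed[j]
    ]
    smax = max(p[2] for p in pairs)
    score = count = 0
    for i, j, s in pairs:
        if s / smax >= x:
            lo, hi = (i, j) if observed[i] < observed[j] else (j, i)
            count += 1
            score += np.sign(predicted[hi] - predicted[lo])
    return score / count if count else 0.0


def brute_force_sci(observed, predicted, sim_values, step=1e-4):
    """Dense-grid trapezoidal SCI, fully independent of the exact path."""
    xs = np.arange(0.0, 1.0 + step / 2, step)
    ys = [brute_force_s(observed, predicted, sim_values, x) for x in xs]
    return np.trapezoid(ys, xs)


def _random_instance(rng, n):
    sim = random_similarity(n, rng)
    observed = rng.normal(size=n)
    predicted = rng.normal(size=n)
    return observed, predicted, sim


# ---------------------------------------------------------------- sali_matrix
class TestSaliMatrix:
    def test_direct_formula(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        m = sali_matrix([1.0, 2.0], sim)
        assert m.sali[0, 1] == pytest.approx(2.0)

    def test_zero_numerator(self):
        sim = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]]))
        m = sali_matrix([1.0, 1.0, 2.0], sim)
        assert m.sali[0, 1] == 0.0
        assert m.eligible[0, 1]

    def test_sim_one_pair_ineligible_not_error(self, caplog):
        sim = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]]))
        with caplog.at_level("WARNING"):
            m = sali_matrix([1.0, 2.0, 3.0], sim)
        assert not m.eligible[0, 1]
        assert "excluded" in caplog.text
        assert m.sali_max == pytest.approx(2.0 / 0.8)

    def test_all_identical_structures_error(self):
        sim = SimilarityMatrix(["a", "b"], np.ones((2, 2)))
        with pytest.raises(DegenerateInputError, match="identical"):
            sali_matrix([1.0, 2.0], sim)

    def test_constant_activity_error(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        with pytest.raises(DegenerateInputError, match="differing"):
            sali_matrix([2.0, 2.0], sim)


# ---------------------------------------------------------------- normalize
class TestNormalize:
    def _matrix(self):
        # pair SALI values 10, 4, 10/3 (the worked-example geometry)
        sim = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]]))
        return sali_matrix([0.0, 1.0, 3.0], sim)

    def test_internal_max(self):
        norm = normalize(self._matrix())
        assert norm[0, 1] == pytest.approx(1.0)
        assert norm[1, 2] == pytest.approx(0.4)
        assert norm[0, 2] == pytest.approx(1.0 / 3.0)

    def test_reference_max(self):
        norm = normalize(self._matrix(), reference_max=20.0)
        assert norm[0, 1] == pytest.approx(0.5)
        assert norm[1, 2] == pytest.approx(0.2)

    def test_reference_below_max_allows_over_one(self, caplog):
        with caplog.at_level("WARNING"):
            norm = normalize(self._matrix(), reference_max=5.0)
        assert norm[0, 1] == pytest.approx(2.0)
        assert "exceed" in caplog.text

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            normalize(self._matrix(), reference_max=0.0)


# ---------------------------------------------------------------- edges & S
class TestEdges:
    def _setup(self, worked_example):
        ids, observed, predicted, sim = worked_example
        m = sali_matrix(observed, sim)
        return observed, predicted, normalize(m), m.eligible, ids

    def test_threshold_zero_keeps_all_unequal_pairs(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 0.0, elig, ids)
        assert g.n_edges == 3

    def test_threshold_one_keeps_maximal_pair(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 1.0, elig, ids)
        assert g.edge_ids() == [("a", "b")]

    def test_intermediate_threshold_enumeration(self, worked_example):
        # norms are (1.0, 0.4, 1/3); at X=0.35 exactly two pairs survive
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 0.35, elig, ids)
        assert sorted(g.edge_ids()) == [("a", "b"), ("b", "c")]

    def test_edges_oriented_low_to_high(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 0.0, elig, ids)
        assert np.all(observed[g.tail] < observed[g.head])

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        observed, predicted, sim = _random_instance(rng, 15)
        m = sali_matrix(observed, sim)
        norm = normalize(m)
        counts = [
            edge_set(norm, observed, x, m.eligible).n_edges
            for x in np.linspace(0, 1, 40)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] >= 1  # closed threshold keeps the maximal pair

    def test_orientation_score_worked_example(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 0.0, elig, ids)
        assert orientation_score(g, predicted) == pytest.approx(1.0 / 3.0)

    def test_orientation_limits(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 0.0, elig, ids)
        assert orientation_score(g, observed) == 1.0
        assert orientation_score(g, -observed) == -1.0

    def test_empty_edge_set_error(self, worked_example):
        observed, predicted, norm, elig, ids = self._setup(worked_example)
        g = edge_set(norm, observed, 1.0, elig, ids)
        g.tail = g.head = np.array([], dtype=int)
        with pytest.raises(DegenerateInputError):
            orientation_score(g, predicted)


# ---------------------------------------------------------------- curve
class TestSaliCurve:
    def test_worked_example_step_structure(self, worked_example):
        ids, observed, predicted, sim = worked_example
        c = sali_curve(observed, predicted, sim)
        np.testing.assert_allclose(c.breakpoints, [1 / 3, 0.4, 1.0])
        np.testing.assert_allclose(c.s_values, [1 / 3, 0.0, 1.0])
        assert c.sci == pytest.approx((1 / 3) * (1 / 3) + 1.0 * 0.6, abs=1e-12)
        assert c.s0 == pytest.approx(1 / 3)
        assert c.s1 == 1.0

    def test_worked_example_against_dense_grid_oracle(self, worked_example):
        ids, observed, predicted, sim = worked_example
        c = sali_curve(observed, predicted, sim)
        oracle = brute_force_sci(observed, predicted, sim.values, step=1e-4)
        assert c.sci == pytest.approx(oracle, abs=5e-4)
        assert c.sci == pytest.approx(0.7111, abs=1e-4)

    def test_perfect_and_reversed_predictor(self, worked_example):
        ids, observed, predicted, sim = worked_example
        perfect = sali_curve(observed, observed, sim)
        assert perfect.sci == 1.0 and np.all(perfect.s_values == 1.0)
        reversed_ = sali_curve(observed, -observed, sim)
        assert reversed_.sci == -1.0 and sci(reversed_) == -1.0

    def test_grid_method_close_to_exact(self, worked_example):
        ids, observed, predicted, sim = worked_example
        exact = sali_curve(observed, predicted, sim, method="exact")
        grid = sali_curve(observed, predicted, sim, method="grid", step=1e-3)
        assert grid.sci == pytest.approx(exact.sci, abs=2e-3)
        assert grid.s0 == exact.s0 and grid.s1 == exact.s1

    def test_evaluate_matches_brute_force_everywhere(self):
        rng = np.random.default_rng(3)
        observed, predicted, sim = _random_instance(rng, 12)
        c = sali_curve(observed, predicted, sim)
        for x in np.linspace(0, 1, 101):
            assert c.evaluate(float(x)) == pytest.approx(
                brute_force_s(observed, predicted, sim.values, float(x))
            )

    def test_antisymmetry_under_prediction_negation(self):
        rng = np.random.default_rng(4)
        observed, predicted, sim = _random_instance(rng, 14)
        c = sali_curve(observed, predicted, sim)
        cn = sali_curve(observed, -predicted, sim)
        np.testing.assert_allclose(cn.s_values, -c.s_values, atol=1e-12)
        assert cn.sci == pytest.approx(-c.sci)
        assert cn.s0 == pytest.approx(-c.s0)
        assert cn.s1 == pytest.approx(-c.s1)

    def test_invariance_monotone_transform_of_predictions(self):
        rng = np.random.default_rng(5)
        observed, predicted, sim = _random_instance(rng, 14)
        c = sali_curve(observed, predicted, sim)
        c2 = sali_curve(observed, np.exp(2.0 * predicted) + 7.0, sim)
        assert c2.sci == pytest.approx(c.sci, abs=1e-12)
        np.testing.assert_allclose(c2.s_values, c.s_values, atol=1e-12)

    def test_invariance_affine_transform_of_observed(self):
        rng = np.random.default_rng(6)
        observed, predicted, sim = _random_instance(rng, 14)
        c = sali_curve(observed, predicted, sim)
        c2 = sali_curve(3.5 * observed + 11.0, predicted, sim)
        np.testing.assert_allclose(c2.breakpoints, c.breakpoints, atol=1e-9)
        assert c2.sci == pytest.approx(c.sci, abs=1e-9)

    def test_reference_max_keeps_domain(self, worked_example):
        ids, observed, predicted, sim = worked_example
        c = sali_curve(observed, predicted, sim, reference_max=5.0)
        # pair norms become 2, 0.8, 2/3: the maximal pair is in every edge set
        assert c.s1 == pytest.approx(1.0)
        assert c.breakpoints[-1] == 1.0

    def test_sci_bounds_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            observed, predicted, sim = _random_instance(rng, int(rng.integers(3, 16)))
            c = sali_curve(observed, predicted, sim)
            assert -1.0 <= c.sci <= 1.0
            assert np.all((c.s_values >= -1.0) & (c.s_values <= 1.0))


# ---------------------------------------------------------------- histogram
class TestHistogram:
    def _matrix(self):
        sim = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]]))
        return sali_matrix([0.0, 1.0, 3.0], sim)

    def test_counts_conserve_pairs(self):
        h = sali_histogram(self._matrix(), n_bins=7)
        assert h.counts.sum() == 3

    def test_single_bin(self):
        h = sali_histogram(self._matrix(), n_bins=1)
        assert list(h.counts) == [3]

    def test_direct_binning(self):
        # sim=0.5 everywhere and integer activities make the SALI values
        # exactly (10, 4, 6); the last bin's right edge is closed
        sim = SimilarityMatrix(["a", "b", "c"], np.array(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]))
        m = sali_matrix([0.0, 5.0, 2.0], sim)
        h = sali_histogram(m, bin_edges=[0.0, 5.0, 10.0])
        assert list(h.counts) == [1, 2]

    def test_bad_bin_count(self):
        with pytest.raises(ValidationError):
            sali_histogram(self._matrix(), n_bins=0)
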