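import numpy as np
import pytest

from cvigrade.image import ValidationError
from cvigrade.selection import (FuzzyAnchors, SelectionState, _SearchCache,
                                conditional_mutual_information, crisp_memberships,
                                entropy, forward_select, fuzzify,
                                joint_memberships, luca_termini_entropy,
                                mutual_information, score_candidate)


def discrete_entropy(*vars_):
    """Plug-in Shannon entropy oracle over the joint contingency table."""
    joint = np.stack([np.asarray(v).ravel() for v in vars_], axis=1)
    _, counts = np.unique(joint, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discrete_mi(x, y):
    return discrete_entropy(x) + discrete_entropy(y) - discrete_entropy(x, y)


class TestFuzzify:
    def test_anchor_vertices(self):
        anchors = FuzzyAnchors(0.0, 5.0, 10.0)
        np.testing.assert_allclose(fuzzify([0.0], anchors), [[1, 0, 0]])
        np.testing.assert_allclose(fuzzify([5.0], anchors), [[0, 1, 0]])
        np.testing.assert_allclose(fuzzify([10.0], anchors), [[0, 0, 1]])

    def test_partition_of_unity(self, rng):
        values = rng.normal(size=200)
        m = fuzzify(values)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()

    def test_constant_feature_degenerate(self):
        m = fuzzify(np.full(10, 3.3))
        np.testing.assert_array_equal(m[:, 1], 1.0)
        assert FuzzyAnchors.from_values(np.full(10, 3.3)).degenerate


class TestLucaTermini:
    def test_crisp_zero(self):
        assert luca_termini_entropy(np.array([0.0, 1.0, 1.0, 0.0])) == 0.0

    def test_single_half_membership_one_bit(self):
        assert luca_termini_entropy(np.array([0.5]), n=1) == pytest.approx(1.0)

    def test_symmetry_and_maximum(self, rng):
        mu = rng.random(50)
        assert luca_termini_entropy(mu) == pytest.approx(
            luca_termini_entropy(1.0 - mu))
        assert luca_termini_entropy(mu) <= luca_termini_entropy(np.full(50, 0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            luca_termini_entropy(np.array([1.2]))


class TestInformationMeasures:
    def test_self_information_crisp(self, rng):
        x = crisp_memberships(rng.integers(0, 3, size=60))
        assert mutual_information(x, x) == pytest.approx(entropy(x), abs=1e-12)

    def test_independent_crisp_exhaustive(self):
        # exhaustive 2-level product sample: exactly independent
        a = np.repeat([0, 0, 1, 1], 5)
        b = np.tile([0, 1, 0, 1], 5)
        mi = mutual_information(crisp_memberships(a), crisp_memberships(b))
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_crisp_mi_matches_discrete_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, 3, size=50)
            y = rng.integers(0, 3, size=50)
            mi = mutual_information(crisp_memberships(x), crisp_memberships(y))
            assert mi == pytest.approx(discrete_mi(x, y), abs=1e-9)
            assert mi >= -1e-9

    def test_joint_entropy_dominates_marginals_crisp(self, rng):
        x = crisp_memberships(rng.integers(0, 4, size=40))
        y = crisp_memberships(rng.integers(0, 2, size=40))
        h_xy = entropy(x, y)
        assert h_xy >= entropy(x) - 1e-12
        assert h_xy >= entropy(y) - 1e-12

    def test_conditional_mi_matches_discrete_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 3, size=50)
            y = rng.integers(0, 3, size=50)
            z = rng.integers(0, 2, size=50)
            cmi = conditional_mutual_information(
                crisp_memberships(x), crisp_memberships(y), crisp_memberships(z))
            oracle = (discrete_entropy(x, z) + discrete_entropy(y, z)
                      - discrete_entropy(x, y, z) - discrete_entropy(z))
            assert cmi == pytest.approx(oracle, abs=1e-9)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            mutual_information(np.ones((5, 3)), np.ones((6, 3)))

    def test_fuzzy_rows_sum_one_after_min_tnorm_join(self, rng):
        x = fuzzify(rng.normal(size=30))
        y = fuzzify(rng.normal(size=30))
        j = joint_memberships(x, y)
        assert j.shape == (30, 9)
        assert (j <= 1).all() and (j >= 0).all()


class TestScoring:
    def test_empty_selection_is_relevance(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        fz = [fuzzify(x[:, i]) for i in range(3)]
        c = crisp_memberships(y)
        assert score_candidate(1, [], fz, c) == pytest.approx(
            mutual_information(fz[1], c))

    def test_duplicate_feature_penalized(self, rng):
        # candidate identical to a selected feature, independent of the class
        f = rng.integers(0, 3, size=60)
        y = rng.integers(0, 2, size=60)
        fz = [crisp_memberships(f), crisp_memberships(f)]
        c = crisp_memberships(y)
        j = score_candidate(1, [0], fz, c)
        rel = mutual_information(fz[1], c)
        # redundancy I(f;f)=H(f) bites harder than I(f;f|C)<=H(f)
        assert j < rel

    def test_class_copy_scores_highest(self, rng):
        y = rng.integers(0, 3, size=80)
        cols = [y.astype(float)] + [rng.normal(size=80) for _ in range(5)]
        fz = [fuzzify(np.asarray(c)) for c in cols]
        c = crisp_memberships(y)
        scores = [score_candidate(i, [], fz, c) for i in range(6)]
        assert int(np.argmax(scores)) == 0

    def test_vectorized_search_matches_reference_scoring(self, rng):
        """The cached/vectorized forward-search scores equal score_candidate."""
        X = rng.normal(size=(40, 6))
        X[:, 0] += rng.integers(0, 3, size=40) * 2.0
        y = rng.integers(0, 3, size=40)
        fz = [fuzzify(X[:, i]) for i in range(6)]
        c = crisp_memberships(y)
        cache = _SearchCache(np.stack(fz), c, beta=0.5)
        for step, s in enumerate([2, 0, 4]):
            ref = np.array([
                score_candidate(f, cache.selected, fz, c)
                if f not in cache.selected else -np.inf
                for f in range(6)
            ])
            got = cache.scores()
            np.testing.assert_allclose(got[ref > -np.inf], ref[ref > -np.inf],
                                       atol=1e-10)
            cache.add(s)


class TestForwardSelect:
    def test_kmax_zero_empty(self, rng):
        state = forward_select(rng.normal(size=(20, 4)),
                               rng.integers(0, 2, size=20), k_max=0)
        assert state.selected == [] and state.scores == []

    def test_class_copy_selected_first(self, rng):
        y = rng.integers(0, 3, size=100)
        X = rng.normal(size=(100, 8))
        X[:, 3] = y
        state = forward_select(X, y, k_max=4)
        assert state.selected[0] == 3

    def test_selection_bounded_by_kmax(self, rng):
        X = rng.normal(size=(50, 10))
        X[:, 0] = X[:, 1] = rng.integers(0, 2, size=50)
        y = X[:, 0].astype(int)
        state = forward_select(X, y, k_max=3)
        assert len(state.selected) <= 3
        assert len(state.scores) == len(state.selected)
        assert len(set(state.selected)) == len(state.selected)

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 3, size=60)
        a = forward_select(X, y, k_max=5)
        b = forward_select(X, y, k_max=5)
        assert a.selected == b.selected and a.scores == b.scores

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 6))
        X[:, 2] += 3.0 * rng.integers(0, 2, size=60)
        y = (X[:, 2] > X[:, 2].mean()).astype(int)
        base = forward_select(X, y, k_max=3).selected
        perm = np.array([3, 0, 5, 1, 4, 2])  # column i -> position perm[i]
        Xp = np.empty_like(X)
        Xp[:, perm] = X
        permuted = forward_select(Xp, y, k_max=3).selected
        assert [perm[i] for i in base] == permuted

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            forward_select(np.empty((0, 0)), np.array([]))

    def test_report_serializable(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, size=30)
        d = forward_select(X, y, k_max=2).to_dict()
        assert set(d) == {"selected", "scores", "anchors"}
        assert len(d["anchors"]) == 4
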