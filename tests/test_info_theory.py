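"""Entropy, mutual information, symmetrical uncertainty and the eta maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antcad.info_theory import (
    DiscretizationScheme,
    conditional_entropy,
    discretize,
    discretize_feature,
    entropy,
    heuristic_fc,
    heuristic_ff,
    information_factor,
    joint_entropy,
    relevance_profile,
    symmetrical_uncertainty,
)
from antcad.table import CategoricalSeries, FeatureTable


def cat(codes, n=None):
    codes = np.asarray(codes)
    return CategoricalSeries(codes, n or int(codes.max()) + 1)


def su_bruteforce(x, y):
    """Independent SU oracle: direct summation over empirical joint counts."""
    n = len(x)
    from collections import Counter

    def H(counts):
        return -sum((c / n) * math.log2(c / n) for c in counts.values() if c)

    hx, hy = H(Counter(x)), H(Counter(y))
    hxy = H(Counter(zip(x, y)))
    i = hx + hy - hxy
    return 0.0 if hx + hy == 0 else 2 * i / (hx + hy)


class TestDiscretize:
    def test_equal_width_midpoint_split(self):
        s = discretize_feature(np.array([0.0, 5.0, 10.0]), DiscretizationScheme(n_bins=2))
        assert s.codes.tolist() == [0, 1, 1]

    @pytest.mark.parametrize("strategy", ["equal_width", "equal_frequency"])
    def test_constant_feature_single_bin(self, strategy):
        s = discretize_feature(np.full(20, 3.7), DiscretizationScheme(strategy=strategy))
        assert s.codes.tolist() == [0] * 20
        assert s.n_categories == 1

    def test_equal_frequency_balanced_occupancy(self, rng):
        x = rng.uniform(size=100)
        s = discretize_feature(x, DiscretizationScheme(strategy="equal_frequency", n_bins=4))
        # sorting oracle: quartiles of 100 distinct values hold 25 each
        assert np.bincount(s.codes).tolist() == [25, 25, 25, 25]

    def test_equal_width_is_monotone(self, rng):
        x = rng.normal(size=200)
        s = discretize_feature(x, DiscretizationScheme(n_bins=8))
        order = np.argsort(x)
        assert np.all(np.diff(s.codes[order]) >= 0)

    def test_deterministic_rerun(self, rng):
        x = rng.normal(size=(50, 4))
        t = FeatureTable(X=x)
        a = discretize(t, DiscretizationScheme(n_bins=5))
        b = discretize(t, DiscretizationScheme(n_bins=5))
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.codes, s2.codes)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discretize_feature(np.array([]), DiscretizationScheme())


class TestEntropy:
    @pytest.mark.parametrize(
        "codes, expected",
        [([0, 1, 0, 1], 1.0), ([2, 2, 2], 0.0), ([0, 0, 1, 2], 1.5)],
    )
    def test_known_values(self, codes, expected):
        assert entropy(cat(codes)) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_log_cardinality(self, rng):
        s = cat(rng.integers(0, 5, size=100), 5)
        assert 0.0 <= entropy(s) <= math.log2(5) + 1e-12


class TestJointAndConditional:
    def test_duplicated_variable(self):
        a = cat([0, 1, 0, 1])
        assert joint_entropy(a, a) == pytest.approx(1.0, abs=1e-12)
        assert conditional_entropy(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_independent_fair_bits(self):
        a = cat([0, 0, 1, 1])
        b = cat([0, 1, 0, 1])
        assert joint_entropy(a, b) == pytest.approx(2.0, abs=1e-12)
        assert conditional_entropy(a, b) == pytest.approx(entropy(a), abs=1e-12)
        assert information_factor(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_empirical_pair_counts(self):
        # pairs {(0,0):2, (0,1):1, (1,1):1} -> p = (1/2, 1/4, 1/4) -> 1.5 bits
        a = cat([0, 0, 0, 1], 2)
        b = cat([0, 0, 1, 1], 2)
        assert joint_entropy(a, b) == pytest.approx(1.5, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy(cat([0, 1]), cat([0, 1, 0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_chain_rule_identity(self, seed):
        r = np.random.default_rng(seed)
        a = cat(r.integers(0, 3, size=60), 3)
        b = cat(r.integers(0, 4, size=60), 4)
        assert conditional_entropy(a, b) == pytest.approx(
            joint_entropy(a, b) - entropy(b), abs=1e-12
        )
        assert conditional_entropy(a, b) >= -1e-12


class TestInformationFactor:
    def test_self_information_is_entropy(self):
        a = cat([0, 1, 0, 1])
        assert information_factor(a, a) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_alternative_identity_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = cat(r.integers(0, 3, size=40), 3)
        b = cat(r.integers(0, 3, size=40), 3)
        expected = entropy(a) + entropy(b) - joint_entropy(a, b)
        assert information_factor(a, b) == pytest.approx(expected, abs=1e-12)
        assert information_factor(a, b) == pytest.approx(information_factor(b, a), abs=1e-12)


class TestSymmetricalUncertainty:
    def test_identical_nonconstant_is_one(self):
        a = cat([0, 1, 2, 0, 1, 2])
        assert symmetrical_uncertainty(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_independent_is_zero(self):
        a = cat([0, 0, 1, 1])
        b = cat([0, 1, 0, 1])
        assert symmetrical_uncertainty(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_both_constant_defined_as_zero(self):
        a = cat([0, 0, 0], 1)
        assert symmetrical_uncertainty(a, a) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, rng.integers(2, 6), size=80)
            y = rng.integers(0, rng.integers(2, 6), size=80)
            ours = symmetrical_uncertainty(cat(x, 6), cat(y, 6))
            assert ours == pytest.approx(su_bruteforce(x.tolist(), y.tolist()), abs=1e-12)
            assert -1e-12 <= ours <= 1 + 1e-12


class TestRelevanceProfile:
    def test_label_copy_feature_scores_one(self):
        labels = np.array([0, 1, 2] * 20)
        X = np.column_stack([labels.astype(float), np.zeros(60)])
        t = FeatureTable(X=X, y=CategoricalSeries(labels, 3))
        prof = relevance_profile(t)
        assert prof.su_fc[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_feature_pair(self, rng):
        x = rng.normal(size=50)
        t = FeatureTable(
            X=np.column_stack([x, x, rng.normal(size=50)]),
            y=CategoricalSeries(rng.integers(0, 2, size=50), 2),
        )
        prof = relevance_profile(t)
        assert prof.su_ff[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(prof.su_ff, prof.su_ff.T)

    def test_planted_informative_rank_above_noise(self, planted):
        table, gt = planted
        prof = relevance_profile(table, include_ff=False)
        assert prof.su_fc[gt.informative].mean() > prof.su_fc[gt.noise].mean()

    def test_unlabeled_table_rejected(self, rng):
        t = FeatureTable(X=rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            relevance_profile(t)


class TestHeuristics:
    @pytest.mark.parametrize("su, expected", [(0.0, 1.0), (0.5, 2.0), (1.0, 1e6)])
    def test_fc_map(self, su, expected):
        assert heuristic_fc(np.array([su]))[0] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("su, expected", [(1.0, 1.0), (0.25, 4.0), (0.0, 1e6)])
    def test_ff_map(self, su, expected):
        assert heuristic_ff(np.array([su]))[0] == pytest.approx(expected, rel=1e-9)

    def test_fc_strictly_increasing(self):
        su = np.linspace(0, 1, 50)
        assert np.all(np.diff(heuristic_fc(su)) > 0)

    def test_ff_strictly_decreasing(self):
        su = np.linspace(0, 0.999, 50)
        assert np.all(np.diff(heuristic_ff(su)) < 0)

    @pytest.mark.parametrize("bad", [-0.2, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            heuristic_fc(np.array([bad]))
        with pytest.raises(ValueError):
            heuristic_ff(np.array([bad]))
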