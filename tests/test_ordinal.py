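"""Ordinal symbolization, PE and JPE_inv against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpe.ordinal import (
    OrdinalConfig,
    connectivity_matrix,
    joint_distribution,
    jpe_inv,
    mirror_symbol,
    pattern_distribution,
    permutation_entropy,
    shannon_entropy,
    symbolize,
)

from _oracles import brute_jpe_inv, brute_mirror, brute_pe, brute_symbols


class TestSymbolize:
    @pytest.mark.parametrize(
        "x, n, tau, expected",
        [
            ([1, 2, 3, 4, 5], 3, 1, [5, 5, 5]),  # monotone ramp: single pattern
            ([3, 1, 2], 3, 1, [1]),  # ranks (1,3,2)
            ([2, 2, 1], 3, 1, [0]),  # temporal tie-break: earlier sample wins
            ([1, 5, 2, 6, 3, 7], 2, 2, [1, 1, 1, 1]),  # tau=2 windows all increasing
        ],
    )
    def test_known_patterns(self, x, n, tau, expected):
        seq = symbolize(x, OrdinalConfig(n, tau))
        assert seq.symbols.tolist() == expected

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=80),
        st.integers(2, 4),
        st.integers(1, 3),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_and_length(self, x, n, tau):
        if len(x) < (n - 1) * tau + 1:
            with pytest.raises(ValueError):
                symbolize(x, OrdinalConfig(n, tau))
            return
        seq = symbolize(x, OrdinalConfig(n, tau))
        assert len(seq) == len(x) - (n - 1) * tau
        assert seq.symbols.tolist() == brute_symbols(x, n, tau)
        assert seq.symbols.max() < math.factorial(n)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            symbolize([1.0, np.nan, 2.0, 3.0], OrdinalConfig(3, 1))

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            OrdinalConfig(1, 1)
        with pytest.raises(ValueError):
            OrdinalConfig(3, 0)


class TestDistributionsAndEntropy:
    def test_point_mass_and_counting(self, rng):
        seq = symbolize([1, 2, 3, 4, 5], OrdinalConfig(3, 1))
        assert pattern_distribution(seq).tolist() == [0, 0, 0, 0, 0, 1]

        x = rng.standard_normal(203)
        seq = symbolize(x, OrdinalConfig(3, 1))
        counts = np.zeros(6)
        for s in brute_symbols(x, 3, 1):
            counts[s] += 1
        np.testing.assert_allclose(pattern_distribution(seq), counts / 201, atol=1e-15)

    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(6, 1 / 6), math.log(6)),
            ([1, 0, 0, 0, 0, 0], 0.0),
            ([0.5, 0.5, 0, 0, 0, 0], math.log(2)),
        ],
    )
    def test_shannon_closed_forms(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_negative(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])


class TestPermutationEntropy:
    def test_monotone_is_zero(self):
        for n in (2, 3, 4):
            assert permutation_entropy(np.arange(50.0), OrdinalConfig(n, 1)) == 0.0

    def test_iid_noise_near_one(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        assert permutation_entropy(x, OrdinalConfig(4, 1)) == pytest.approx(1.0, abs=0.01)

    def test_matches_bruteforce_on_fixed_sequence(self, rng):
        x = rng.standard_normal(30)
        got = permutation_entropy(x, OrdinalConfig(3, 1))
        assert got == pytest.approx(brute_pe(x, 3, 1), abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=20, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_monotone_transform(self, x):
        x = np.asarray(x)
        cfg = OrdinalConfig(3, 1)
        before = permutation_entropy(x, cfg)
        # 0.25 * x is exactly representable, hence exactly order-preserving
        after = permutation_entropy(0.25 * x, cfg)
        assert after == pytest.approx(before, abs=1e-12)


class TestMirror:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_involution_and_bruteforce(self, n):
        for s in range(math.factorial(n)):
            m = mirror_symbol(s, n)
            assert mirror_symbol(m, n) == s
            assert m == brute_mirror(s, n)
            assert m != s  # no self-mirrored pattern for n >= 2

    def test_rank_complement_examples(self):
        assert mirror_symbol(0, 3) == 5  # (1,2,3) <-> (3,2,1)
        assert mirror_symbol(0, 4) == 23  # (1,2,3,4) <-> (4,3,2,1)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mirror_symbol(6, 3)


class TestJointDistribution:
    def test_identical_channels_masked(self):
        seq = symbolize([1, 2, 3, 4, 5], OrdinalConfig(3, 1))
        joint = joint_distribution(seq, seq)
        assert joint.probs[5, 5] == 1.0
        assert joint.retained_mass == 0.0
        # mask covers exactly the identical + mirrored cells
        assert joint.mask.sum() == 2 * 6

    def test_marginals_and_counting_oracle(self, rng):
        cfg = OrdinalConfig(3, 1)
        x, y = rng.standard_normal((2, 52))
        sx, sy = symbolize(x, cfg), symbolize(y, cfg)
        joint = joint_distribution(sx, sy)
        np.testing.assert_allclose(joint.probs.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(joint.probs.sum(axis=1), pattern_distribution(sx), atol=1e-15)
        np.testing.assert_allclose(joint.probs.sum(axis=0), pattern_distribution(sy), atol=1e-15)
        expected = np.zeros((6, 6))
        for a, b in zip(brute_symbols(x, 3, 1), brute_symbols(y, 3, 1)):
            expected[a, b] += 1
        np.testing.assert_allclose(joint.probs, expected / 50, atol=1e-15)

    def test_length_mismatch(self):
        cfg = OrdinalConfig(3, 1)
        with pytest.raises(ValueError, match="length"):
            joint_distribution(
                symbolize(np.arange(10.0), cfg), symbolize(np.arange(9.0), cfg)
            )


class TestJpeInv:
    def test_identical_and_inverted_are_zero(self, rng):
        cfg = OrdinalConfig(4, 1)
        x = rng.standard_normal(2000)
        assert jpe_inv(x, x, cfg) == 0.0
        assert jpe_inv(x, -x, cfg) == 0.0

    def test_independent_noise_near_zero(self):
        r = np.random.default_rng(11)
        x, y = r.standard_normal((2, 100_000))
        assert jpe_inv(x, y, OrdinalConfig(4, 1)) == pytest.approx(0.0, abs=0.01)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 3), st.integers(1, 2))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_bruteforce(self, seed, n, tau):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal((2, 60))
        cfg = OrdinalConfig(n, tau)
        v = jpe_inv(x, y, cfg)
        assert v == jpe_inv(y, x, cfg)  # bit-exact symmetry
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(brute_jpe_inv(x, y, n, tau), abs=1e-12)

    def test_no_renormalization_variant_differs(self, rng):
        cfg = OrdinalConfig(3, 1)
        x, y = rng.standard_normal((2, 500))
        a = jpe_inv(x, y, cfg, renormalize=True)
        b = jpe_inv(x, y, cfg, renormalize=False)
        assert b >= a  # dropped mass lowers the entropy sum

    def test_uncorrected_scores_leakage_higher(self, rng):
        # zero-lag mixtures of independent noise: the exclusion absorbs
        # the mixing, the uncorrected variant does not
        cfg = OrdinalConfig(4, 1)
        for _ in range(20):
            x, w = rng.standard_normal((2, 4000))
            y = 0.75 * x + 0.25 * w
            assert jpe_inv(x, y, cfg, corrected=False) > jpe_inv(x, y, cfg)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            jpe_inv(np.arange(10.0), np.arange(12.0), OrdinalConfig(3, 1))


class TestConnectivityMatrix:
    def test_identical_channels(self):
        data = np.tile(np.random.default_rng(0).standard_normal(300), (3, 1))
        res = connectivity_matrix(data, OrdinalConfig(3, 1))
        assert np.all(res.matrix == 0)
        assert np.all(res.roi_profile == 0)

    def test_consistent_with_pairwise_calls(self, rng):
        data = rng.standard_normal((4, 400))
        cfg = OrdinalConfig(3, 1)
        res = connectivity_matrix(data, cfg)
        assert np.array_equal(res.matrix, res.matrix.T)
        assert np.all(np.diag(res.matrix) == 0)
        for i in range(4):
            for j in range(i + 1, 4):
                assert res.matrix[i, j] == jpe_inv(data[i], data[j], cfg)

    def test_reproducible_for_fixed_seed(self):
        data = np.random.default_rng(42).standard_normal((10, 500))
        cfg = OrdinalConfig(3, 1)
        m1 = connectivity_matrix(data, cfg).matrix
        m2 = connectivity_matrix(data, cfg).matrix
        assert np.array_equal(m1, m2)

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            connectivity_matrix(np.zeros((1, 100)), OrdinalConfig(3, 1))
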