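import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgdtw.dtw import (
    DtwConfig,
    DtwInfeasibleError,
    derivative_series,
    dtw_align,
    local_cost,
)
from oracle_dtw import assert_path_constraints, oracle_min_sum, path_sum

RAW = DtwConfig(alpha=0, beta=1, gamma=0, eta=0, normalize_inputs=False, window_fraction=None)


def random_config(rng) -> DtwConfig:
    """Mixed non-negative weights with at least one positive."""
    while True:
        w = rng.uniform(0.0, 2.0, size=4) * (rng.random(size=4) < 0.7)
        if w.sum() > 0:
            break
    return DtwConfig(
        alpha=w[0], beta=w[1], gamma=w[2], eta=w[3],
        window_fraction=None, normalize_inputs=False,
    )


class TestLocalCost:
    def test_identical_points_cost_zero(self):
        x = [0.1, 0.7, 0.3]
        cfg = DtwConfig(alpha=1, beta=1, gamma=1, eta=1, normalize_inputs=False)
        assert local_cost(x, x, 2, 2, cfg) == 0.0

    def test_pure_index_shift(self):
        x = np.zeros(8)
        cfg = DtwConfig(alpha=1, beta=0, gamma=0, eta=0, normalize_inputs=False)
        assert local_cost(x, x, 3, 7, cfg) == pytest.approx(4.0)

    def test_pure_value_difference(self):
        cfg = RAW
        assert local_cost([0.5, 0.5], [0.2, 0.2], 0, 1, cfg) == pytest.approx(0.3)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            local_cost([0.0, 1.0], [0.0, 1.0], 5, 0, RAW)


class TestDerivatives:
    def test_linear_ramp(self):
        fs = 10.0
        t = np.arange(20) / fs
        d1, d2 = derivative_series(2.0 * t, fs)
        assert np.allclose(d1, 2.0)
        assert np.allclose(d2[1:-1], 0.0)

    def test_constant(self):
        d1, d2 = derivative_series(np.full(10, 3.3), 5.0)
        assert np.allclose(d1, 0.0) and np.allclose(d2, 0.0)

    def test_parabola_second_derivative_exact(self):
        fs = 4.0
        t = np.arange(12) / fs
        _, d2 = derivative_series(t**2, fs)
        assert np.allclose(d2[1:-1], 2.0)  # central differences exact on quadratics

    def test_too_short(self):
        with pytest.raises(ValueError):
            derivative_series([1.0, 2.0], 1.0)


class TestAlign:
    def test_self_alignment_is_diagonal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        path = dtw_align(x, x, RAW)
        assert path.total_cost == 0.0
        assert path.K == 30
        assert np.array_equal(path.pairs[:, 0], path.pairs[:, 1])

    def test_small_example_matches_oracle(self):
        X, Y = [0.0, 1.0, 0.0], [0.0, 1.0, 1.0, 0.0]
        path = dtw_align(X, Y, RAW)
        assert path_sum(X, Y, path.pairs, RAW) == oracle_min_sum(X, Y, RAW)

    def test_window_too_narrow_raises(self):
        cfg = RAW.with_(window_fraction=0.05)
        with pytest.raises(DtwInfeasibleError):
            dtw_align(np.zeros(40), np.zeros(10), cfg)

    def test_dp_equals_oracle_on_200_random_pairs(self):
        """Exhaustive-enumeration equivalence: the primary correctness gate."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            M, N = rng.integers(3, 7), rng.integers(3, 7)
            X, Y = rng.normal(size=M), rng.normal(size=N)
            cfg = random_config(rng)
            path = dtw_align(X, Y, cfg)
            assert path_sum(X, Y, path.pairs, cfg) == oracle_min_sum(X, Y, cfg), f"trial {trial}"

    def test_beta_only_pairs_with_length_two(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            M, N = rng.integers(2, 7), rng.integers(2, 7)
            X, Y = rng.normal(size=M), rng.normal(size=N)
            path = dtw_align(X, Y, RAW)
            assert path_sum(X, Y, path.pairs, RAW) == oracle_min_sum(X, Y, RAW)


class TestPathProperties:
    def test_constraints_on_500_seeded_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(500):
            M, N = rng.integers(2, 40), rng.integers(2, 40)
            X, Y = rng.normal(size=M), rng.normal(size=N)
            if min(M, N) < 3:
                cfg = RAW
            elif trial % 3 == 0:
                # windowed variant; half-width must bridge |M-N|
                frac = min(1.0, (abs(M - N) + rng.integers(1, 10)) / max(M, N))
                cfg = DtwConfig(normalize_inputs=False, window_fraction=frac)
            else:
                cfg = random_config(rng)
            pairs = dtw_align(X, Y, cfg).pairs
            assert_path_constraints(pairs, M, N)

    def test_beta_cost_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=rng.integers(4, 12))
            Y = rng.normal(size=rng.integers(4, 12))
            f, b = dtw_align(X, Y, RAW), dtw_align(Y, X, RAW)
            assert f.K == b.K
            assert f.total_cost == pytest.approx(b.total_cost, abs=1e-12)

    def test_beta_cost_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(6)
        X, Y = rng.normal(size=9), rng.normal(size=7)
        base = dtw_align(X, Y, RAW).total_cost
        shifted = dtw_align(X + 5.0, Y + 5.0, RAW).total_cost
        scaled = dtw_align(-3.0 * X, -3.0 * Y, RAW).total_cost
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-10, 10), min_size=2, max_size=15),
        y=st.lists(st.floats(-10, 10), min_size=2, max_size=15),
    )
    def test_path_invariants_hold_for_arbitrary_inputs(self, x, y):
        pairs = dtw_align(x, y, RAW).pairs
        assert_path_constraints(pairs, len(x), len(y))

    def test_invalid_config_rejected(self):
        from scgdtw.types import InvariantError

        with pytest.raises(InvariantError):
            DtwConfig(alpha=-1.0)
        with pytest.raises(InvariantError):
            DtwConfig(alpha=0, beta=0, gamma=0, eta=0)
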