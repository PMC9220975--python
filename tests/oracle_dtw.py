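"""Brute-force DTW oracle: exhaustive enumeration of admissible paths.

Independent of the dynamic program under test: per-cell costs come from the
scalar ``local_cost`` and every monotone, continuous, boundary-satisfying
path is enumerated explicitly (no recursion on minima), so the minimum is a
plain min over complete path sums.  Tractable for M, N <= 6 where the path
count is bounded by the Delannoy numbers (1683 at 6x6).
"""

from functools import lru_cache
from itertools import product

from scgdtw.dtw import DtwConfig, local_cost


@lru_cache(maxsize=None)
def all_paths(M: int, N: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Every 0-based monotone continuous path from (0, 0) to (M-1, N-1)."""
    out = []

    def rec(i, j, acc):
        if (i, j) == (M - 1, N - 1):
            out.append(tuple(acc))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < M and nj < N:
                acc.append((ni, nj))
                rec(ni, nj, acc)
                acc.pop()

    rec(0, 0, [(0, 0)])
    return tuple(out)


def oracle_min_sum(X, Y, config: DtwConfig) -> float:
    """Minimum over all admissible paths of the summed local cost."""
    M, N = len(X), len(Y)
    C = {(i, j): local_cost(X, Y, i, j, config) for i, j in product(range(M), range(N))}
    best = None
    for path in all_paths(M, N):
        s = 0.0
        for ij in path:
            s += C[ij]
        if best is None or s < best:
            best = s
    return best


def path_sum(X, Y, pairs, config: DtwConfig) -> float:
    """Left-to-right sum of scalar local costs along a path."""
    s = 0.0
    for i, j in pairs:
        s += local_cost(X, Y, int(i), int(j), config)
    return s


def assert_path_constraints(pairs, M: int, N: int) -> None:
    """Boundary, monotonicity, continuity, and K bounds, checked directly."""
    K = len(pairs)
    assert tuple(pairs[0]) == (0, 0), "path must start at (0, 0)"
    assert tuple(pairs[-1]) == (M - 1, N - 1), "path must end at (M-1, N-1)"
    for (a0, b0), (a1, b1) in zip(pairs[:-1], pairs[1:]):
        da, db = a1 - a0, b1 - b0
        assert da >= 0 and db >= 0, "monotonicity violated"
        assert da <= 1 and db <= 1, "continuity violated"
        assert da + db >= 1, "path repeats a cell"
    assert max(M, N) <= K <= M + N - 1, f"K={K} outside [max(M,N), M+N-1]"
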