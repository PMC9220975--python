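"""Dynamic time warping with a hybrid local cost.

Classic DTW costs each matched pair by the difference of the signal values.
For fiducial-point projection between heartbeat signals, morphological
similarity matters more than amplitude alone, so the local cost here blends
four squared differences under one square root:

* index shift ``(a_i - b_i)^2`` (weight ``alpha``) — penalizes drifting far
  from the synchronous diagonal;
* value ``(x_a - y_b)^2`` (weight ``beta``) — the classic term;
* slope ``(x'_a - y'_b)^2`` (weight ``gamma``) — matches rising to rising
  and falling to falling segments;
* concavity ``(x''_a - y''_b)^2`` (weight ``eta``) — matches peaks to peaks
  and valleys to valleys.

With ``alpha = gamma = eta = 0`` and ``beta = 1`` the cost reduces to the
absolute value difference.  The admissible warping paths obey monotonicity,
continuity (unit steps), the boundary condition, and optionally a
Sakoe-Chiba window; the step pattern itself is the slope constraint applied.
The dynamic program minimizes the path **sum** of local costs (the mean over
a path is not DP-decomposable); the reported ``total_cost`` is the mean
per-step cost of the sum-minimal path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .types import InvariantError

__all__ = [
    "DtwConfig",
    "WarpPath",
    "DtwInfeasibleError",
    "derivative_series",
    "local_cost",
    "local_cost_matrix",
    "dtw_align",
]


class DtwInfeasibleError(ValueError):
    """The warping window admits no path from (0, 0) to (M-1, N-1)."""


@dataclass(frozen=True)
class DtwConfig:
    """Weights and constraints for the hybrid-cost alignment.

    Defaults suit cross-beat fiducial projection: the shift term is off
    (R-peak anchoring already handles gross shift), value and slope terms
    carry most of the cost, and a light concavity term disambiguates peaks
    from shoulders.  ``window_fraction`` is the Sakoe-Chiba half-width as a
    fraction of ``max(M, N)``; ``None`` disables the window.
    """

    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 1.0
    eta: float = 0.25
    window_fraction: float | None = 0.1
    normalize_inputs: bool = True
    sampling_rate: float = 1.0  # Hz; scales the derivative terms

    def __post_init__(self) -> None:
        weights = (self.alpha, self.beta, self.gamma, self.eta)
        if any(w < 0 for w in weights):
            raise InvariantError("DTW weights must be >= 0")
        if not any(w > 0 for w in weights):
            raise InvariantError("at least one DTW weight must be > 0")
        if self.window_fraction is not None and not 0 < self.window_fraction <= 1:
            raise InvariantError("window_fraction must lie in (0, 1]")

    def with_(self, **kwargs) -> "DtwConfig":
        return replace(self, **kwargs)


@dataclass
class WarpPath:
    """A monotone, continuous index alignment of X (length M) to Y (length N).

    ``pairs`` holds 0-based index pairs from (0, 0) to (M-1, N-1); the
    documented 1-based convention (1,1)...(M,N) is the same path shifted by
    one.  ``total_cost`` is the mean per-step local cost.
    """

    pairs: np.ndarray
    total_cost: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2 or len(self.pairs) == 0:
            raise InvariantError("pairs must be a non-empty (K, 2) array")

    @property
    def K(self) -> int:
        return len(self.pairs)

    def validate(self, M: int, N: int) -> None:
        """Assert the five path constraints; raise InvariantError otherwise."""
        a, b = self.pairs[:, 0], self.pairs[:, 1]
        if (a[0], b[0]) != (0, 0) or (a[-1], b[-1]) != (M - 1, N - 1):
            raise InvariantError("boundary constraint violated")
        da, db = np.diff(a), np.diff(b)
        if np.any(da < 0) or np.any(db < 0):
            raise InvariantError("monotonicity constraint violated")
        if np.any(da > 1) or np.any(db > 1):
            raise InvariantError("continuity constraint violated")
        if np.any((da == 0) & (db == 0)):
            raise InvariantError("path repeats a cell")
        if not (max(M, N) <= self.K <= M + N - 1):
            raise InvariantError(f"path length K={self.K} outside [max(M,N), M+N-1]")

    def target_indices(self, a_star: int) -> np.ndarray:
        """All Y indices matched to X index ``a_star`` on the path."""
        return self.pairs[self.pairs[:, 0] == a_star, 1]


def derivative_series(X: Sequence[float], sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """First and second finite-difference derivatives of a sampled series.

    Central differences in the interior, one-sided at the edges; units are
    value per second and value per second squared.  Requires length >= 3.
    """
    x = np.asarray(X, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 samples for derivatives, got {x.size}")
    dt = 1.0 / sampling_rate
    d1 = np.gradient(x, dt)
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d1, d2


def _prepare(X, Y, config: DtwConfig):
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if config.normalize_inputs:
        x = (x - x.mean()) / (x.std() or 1.0)
        y = (y - y.mean()) / (y.std() or 1.0)
    need_deriv = config.gamma > 0 or config.eta > 0
    if need_deriv:
        dx1, dx2 = derivative_series(x, config.sampling_rate)
        dy1, dy2 = derivative_series(y, config.sampling_rate)
    else:
        dx1 = dx2 = dy1 = dy2 = None
    return x, y, dx1, dx2, dy1, dy2


def local_cost(X, Y, i: int, j: int, config: DtwConfig) -> float:
    """Hybrid per-step cost between ``X[i]`` and ``Y[j]``.

    sqrt(alpha (i-j)^2 + beta (x_i-y_j)^2 + gamma (x'_i-y'_j)^2
         + eta (x''_i-y''_j)^2)
    """
    x, y, dx1, dx2, dy1, dy2 = _prepare(X, Y, config)
    if not (0 <= i < len(x)) or not (0 <= j < len(y)):
        raise IndexError(f"indices ({i}, {j}) out of range for lengths ({len(x)}, {len(y)})")
    d_idx = float(i - j)
    d_val = x[i] - y[j]
    s = config.alpha * (d_idx * d_idx) + config.beta * (d_val * d_val)
    if dx1 is not None:
        d1 = dx1[i] - dy1[j]
        d2 = dx2[i] - dy2[j]
        s += config.gamma * (d1 * d1) + config.eta * (d2 * d2)
    return math.sqrt(s)


def local_cost_matrix(X, Y, config: DtwConfig) -> np.ndarray:
    """Full M x N matrix of hybrid local costs."""
    x, y, dx1, dx2, dy1, dy2 = _prepare(X, Y, config)
    i = np.arange(len(x), dtype=float)[:, None]
    j = np.arange(len(y), dtype=float)[None, :]
    d_idx = i - j
    d_val = x[:, None] - y[None, :]
    s = config.alpha * (d_idx * d_idx) + config.beta * (d_val * d_val)
    if dx1 is not None:
        d1 = dx1[:, None] - dy1[None, :]
        d2 = dx2[:, None] - dy2[None, :]
        s = s + config.gamma * (d1 * d1) + config.eta * (d2 * d2)
    return np.sqrt(s)


def _band_half_width(M: int, N: int, config: DtwConfig) -> int | None:
    if config.window_fraction is None:
        return None
    return max(1, int(math.ceil(config.window_fraction * max(M, N))))


def dtw_align(X, Y, config: DtwConfig | None = None) -> WarpPath:
    """Optimal warping path between sequences ``X`` and ``Y``.

    Dynamic program over the (banded) cost matrix with unit steps
    (1,0), (0,1), (1,1); ties in backtracking prefer the diagonal step,
    then the X-advance, making the returned path deterministic.

    Raises
    ------
    DtwInfeasibleError
        If the Sakoe-Chiba half-width is narrower than ``|M - N|``.
    ValueError
        If either sequence is shorter than 2 samples.
    """
    config = config or DtwConfig()
    M, N = len(X), len(Y)
    if M < 2 or N < 2:
        raise ValueError("both sequences must have length >= 2")
    w = _band_half_width(M, N, config)
    if w is not None and w < abs(M - N):
        raise DtwInfeasibleError(
            f"window half-width {w} cannot bridge length difference |{M}-{N}|"
        )
    C = local_cost_matrix(X, Y, config)
    if w is not None:
        i = np.arange(M)[:, None]
        j = np.arange(N)[None, :]
        C = np.where(np.abs(i - j) <= w, C, np.inf)

    D = np.full((M, N), np.inf)
    D[0, 0] = C[0, 0]
    for i in range(M):
        jlo = 0 if w is None else max(0, i - w)
        jhi = N if w is None else min(N, i + w + 1)
        Di = D[i]
        Dprev = D[i - 1] if i > 0 else None
        Ci = C[i]
        for j in range(jlo, jhi):
            if i == 0 and j == 0:
                continue
            best = Di[j - 1] if j > 0 else np.inf
            if Dprev is not None:
                if Dprev[j] < best:
                    best = Dprev[j]
                if j > 0 and Dprev[j - 1] < best:
                    best = Dprev[j - 1]
            Di[j] = Ci[j] + best

    if not np.isfinite(D[M - 1, N - 1]):
        raise DtwInfeasibleError("no admissible path reaches (M-1, N-1)")

    # backtrack; tie preference: diagonal, then X-advance, then Y-advance
    path = [(M - 1, N - 1)]
    i, j = M - 1, N - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((D[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((D[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates, key=lambda c: (c[0], c[1]))
        path.append((i, j))
    path.reverse()
    pairs = np.asarray(path, dtype=int)
    total = float(D[M - 1, N - 1] / len(pairs))
    wp = WarpPath(pairs=pairs, total_cost=total)
    wp.validate(M, N)
    return wp
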