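"""Distance kernels and template matching.

Implements the full ladder of matching criteria between a trial walk
and a bank of probabilistic stride templates:

* fixed-length matching with Euclidean or maximum-likelihood
  (Mahalanobis) frame costs;
* uniform temporal scaling: the best scale m is selected by minimizing
  the per-scale ML distance normalized by m (making every scaling
  equally likely);
* non-uniform scaling: dynamic time warping with template-indexed
  Mahalanobis costs (DTW_L);
* SWM: exhaustive joint search over subsequence span and scale
  (the brute-force oracle, cubic in the walk length);
* subsequence DTW (SDTW_L): one O(n m) accumulated-cost recursion with
  a free start, whose row minima locate candidate stride endings;
* SSWM: SDTW_L per scale with 1/m normalization — the efficient
  equivalent of SWM, O(n m |M|).

All indices are 0-based; spans (t_s, t_e) are inclusive.  Every dynamic
program counts its cell updates (``cells``) so that complexity claims
can be checked empirically.

Tie-breaking is fixed for determinism: smallest scale m first, then
smallest t_s, then smallest t_e; the traceback prefers the diagonal
step, then the step consuming the template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .templates import StrideTemplate

INF = float("inf")


class NoMatchError(ValueError):
    """No admissible match exists (walk too short or empty inputs)."""


@dataclass(frozen=True)
class WarpingPath:
    """Monotone alignment between a walk subsequence and a template.

    ``pairs`` holds (walk_index, template_index) tuples, 0-based, from
    (t_s, 0) to (t_e, m-1), with steps in {(1,0), (0,1), (1,1)}.
    """

    pairs: tuple[tuple[int, int], ...]

    @property
    def w(self) -> int:
        return len(self.pairs)

    @property
    def t_s(self) -> int:
        return self.pairs[0][0]

    @property
    def t_e(self) -> int:
        return self.pairs[-1][0]

    def validate(self, m: int) -> None:
        """Raise if the path violates boundary/monotonicity/step rules."""
        p = self.pairs
        if not p:
            raise ValueError("empty warping path")
        if p[0][1] != 0 or p[-1][1] != m - 1:
            raise ValueError("path must span template indices 0..m-1")
        v = p[-1][0] - p[0][0] + 1
        for (a, b), (c, d) in zip(p, p[1:]):
            if (c - a, d - b) not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"invalid step {(a, b)} -> {(c, d)}")
        if not max(m, v) <= self.w <= m + v - 1:
            raise ValueError("path length outside [max(m,v), m+v-1]")

    def frames_for_template_index(self, i: int) -> list[int]:
        """Walk frames aligned to template index i (a contiguous run)."""
        return [t for t, j in self.pairs if j == i]


@dataclass
class MatchResult:
    """Best-matching subsequence of a walk against a template bank."""

    t_s: int
    t_e: int
    m_star: int
    distance: float                      # normalized by m_star
    path: WarpingPath | None = None
    d_s: np.ndarray | None = field(default=None, repr=False)  # (n, m*) D_S
    cells: int = 0                       # DP cell updates spent


def mahalanobis_sq(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Squared Mahalanobis distance (x-mu)^T cov^-1 (x-mu)."""
    diff = np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)
    try:
        sol = np.linalg.solve(np.asarray(cov, dtype=float), diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular covariance: {exc}") from exc
    return float(diff @ sol)


def cost_matrix(X: np.ndarray, template: StrideTemplate) -> np.ndarray:
    """(n, m) matrix of Mahalanobis^2 frame costs d_{M_i}(x_t).

    Uses the template's cached Cholesky factors; exact to 1e-9 against
    a direct solve.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = template.m
    chol = template.cholesky()
    C = np.empty((n, m))
    for i in range(m):
        diff = X - template.means[i]
        z = solve_triangular(chol[i], diff.T, lower=True)
        C[:, i] = np.einsum("ij,ij->j", z, z)
    return C


def euclidean_cost_matrix(X: np.ndarray, template: StrideTemplate) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    diff = X[:, None, :] - template.means[None, :, :]
    return np.einsum("tmd,tmd->tm", diff, diff)


def _check_window(n: int, t_s: int, m: int) -> None:
    if not 0 <= t_s <= n - m:
        raise ValueError(
            f"window [{t_s}, {t_s + m}) overruns walk of length {n}"
        )


def match_fixed_euclidean(X: np.ndarray, t_s: int, template: StrideTemplate) -> float:
    """Fixed-length squared-Euclidean distance D_E at start t_s."""
    X = np.asarray(X, dtype=float)
    _check_window(X.shape[0], t_s, template.m)
    diff = X[t_s:t_s + template.m] - template.means
    return float(np.sum(diff * diff))


def match_fixed_ml(X: np.ndarray, t_s: int, template: StrideTemplate) -> float:
    """Fixed-length ML distance D_L (sum of Mahalanobis^2) at start t_s."""
    X = np.asarray(X, dtype=float)
    _check_window(X.shape[0], t_s, template.m)
    C = cost_matrix(X[t_s:t_s + template.m], template)
    return float(np.trace(C))


def uniform_scaling_match(
    X: np.ndarray, t_s: int, templates: list[StrideTemplate]
) -> tuple[int, float]:
    """Uniform-scaling ML matching US_L at a fixed start.

    Minimizes D_L(x_{t_s:}, T_m)/m over the scales that fit within the
    walk from t_s; ties go to the smallest m.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best: tuple[int, float] | None = None
    for tpl in sorted(templates, key=lambda t: t.m):
        if t_s + tpl.m > n:
            continue
        val = match_fixed_ml(X, t_s, tpl) / tpl.m
        if best is None or val < best[1]:
            best = (tpl.m, val)
    if best is None:
        raise NoMatchError(
            f"no template scale fits the walk from t_s={t_s} (n={n})"
        )
    return best


# ---------------------------------------------------------------------------
# DTW with template-indexed ML costs
# ---------------------------------------------------------------------------

def _traceback(D: np.ndarray, t_end: int, free_start: bool) -> WarpingPath:
    """Trace the optimal path back from (t_end, m-1).

    Preference order on ties: diagonal, then the step consuming the
    template (left), then the step consuming the walk (up).
    """
    t, i = t_end, D.shape[1] - 1
    pairs = [(t, i)]
    while i > 0 or (not free_start and t > 0):
        if i == 0:
            # only the walk-consuming step remains (anchored start)
            t -= 1
        else:
            diag = D[t - 1, i - 1] if t > 0 else INF
            left = D[t, i - 1]
            up = D[t - 1, i] if (t > 0 and not (free_start and i == 0)) else INF
            if t == 0:
                t, i = t, i - 1
            elif diag <= left and diag <= up:
                t, i = t - 1, i - 1
            elif left <= up:
                t, i = t, i - 1
            else:
                t, i = t - 1, i
        pairs.append((t, i))
        if free_start and i == 0:
            # free start: stop at the first column-0 cell on the path
            break
    pairs.reverse()
    return WarpingPath(tuple(pairs))


@dataclass
class DtwResult:
    distance: float
    path: WarpingPath
    table: np.ndarray
    cells: int


def dtw_ml(X_sub: np.ndarray, template: StrideTemplate,
           C: np.ndarray | None = None) -> DtwResult:
    """DTW_L between a full subsequence and a full template.

    Both sequences must be consumed entirely (anchored at both ends).
    ``C`` may supply a precomputed (v, m) cost matrix.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    v, m = X_sub.shape[0], template.m
    if v < 1 or m < 1:
        raise NoMatchError("empty inputs to dtw_ml")
    if C is None:
        C = cost_matrix(X_sub, template)
    D = np.empty((v, m))
    cells = 0
    for t in range(v):
        for i in range(m):
            if t == 0 and i == 0:
                best = 0.0
            elif t == 0:
                best = D[0, i - 1]
            elif i == 0:
                best = D[t - 1, 0]
            else:
                best = min(D[t - 1, i - 1], D[t, i - 1], D[t - 1, i])
            D[t, i] = C[t, i] + best
            cells += 1
    path = _traceback(D, v - 1, free_start=False)
    return DtwResult(float(D[v - 1, m - 1]), path, D, cells)


@dataclass
class SdtwResult:
    distance: float          # unnormalized SDTW_L = min_t D_S[t, m-1]
    t_s: int
    t_e: int
    path: WarpingPath
    d_s: np.ndarray          # full (n, m) accumulated-cost matrix
    cells: int


def sdtw_ml(X: np.ndarray, template: StrideTemplate,
            C: np.ndarray | None = None) -> SdtwResult:
    """Subsequence DTW with ML costs (free start, best ending).

    Fills the accumulated-cost matrix D_S with the free-start boundary
    (any walk prefix may be skipped at no cost), takes the minimum over
    endings of the last template row, and recovers the start by tracing
    the path back from the ending.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape[0], template.m
    if n < 1 or m < 1:
        raise NoMatchError("empty inputs to sdtw_ml")
    if C is None:
        C = cost_matrix(X, template)
    D = np.empty((n, m))
    cells = 0
    for t in range(n):
        for i in range(m):
            if i == 0:
                best = 0.0          # free start: D_S(x_{.:t}, empty) = 0
            elif t == 0:
                best = D[0, i - 1]
            else:
                best = min(D[t - 1, i - 1], D[t, i - 1], D[t - 1, i])
            D[t, i] = C[t, i] + best
            cells += 1
    t_e = int(np.argmin(D[:, m - 1]))      # first minimum -> smallest t_e
    path = _traceback(D, t_e, free_start=True)
    return SdtwResult(float(D[t_e, m - 1]), path.t_s, t_e, path, D, cells)


def swm_oracle(X: np.ndarray, templates: list[StrideTemplate]) -> MatchResult:
    """Brute-force scaling and time warping matching (SWM_L).

    Exhaustively minimizes DTW_L(x_{t_s:t_e}, T_m)/m over every span
    (t_s, t_e) and every scale m — a fresh DTW table per span, cubic in
    the walk length.  Ties: smallest m, then smallest t_s, then t_e.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not templates:
        raise NoMatchError("empty template bank")
    if n < min(t.m for t in templates):
        raise NoMatchError(f"walk of length {n} shorter than every scale")
    best: MatchResult | None = None
    cells = 0
    for tpl in sorted(templates, key=lambda t: t.m):
        m = tpl.m
        C = cost_matrix(X, tpl).tolist()   # python floats: fast inner loop
        for t_s in range(n):
            for t_e in range(t_s, n):
                v = t_e - t_s + 1
                prev: list[float] = []
                for t in range(v):
                    row = C[t_s + t]
                    cur = [0.0] * m
                    for i in range(m):
                        if t == 0 and i == 0:
                            b = 0.0
                        elif t == 0:
                            b = cur[i - 1]
                        elif i == 0:
                            b = prev[0]
                        else:
                            b = min(prev[i - 1], cur[i - 1], prev[i])
                        cur[i] = row[i] + b
                    prev = cur
                cells += v * m
                val = prev[m - 1] / m
                if best is None or val < best.distance:
                    best = MatchResult(t_s, t_e, m, float(val))
    assert best is not None
    tpl = next(t for t in templates if t.m == best.m_star)
    sub = X[best.t_s:best.t_e + 1]
    res = dtw_ml(sub, tpl)
    shifted = tuple((t + best.t_s, i) for t, i in res.path.pairs)
    best.path = WarpingPath(shifted)
    best.cells = cells
    return best


def sswm(X: np.ndarray, templates: list[StrideTemplate]) -> MatchResult:
    """Subsequence scaling and time warping matching (SSWM_L).

    Runs SDTW_L once per scale, normalizes by m, and keeps the best
    scale (ties to the smallest m).  Equivalent to :func:`swm_oracle`
    up to tie-breaking, at O(n m |M|) cost.
    """
    X = np.asarray(X, dtype=float)
    if not templates:
        raise NoMatchError("empty template bank")
    best: MatchResult | None = None
    cells = 0
    for tpl in sorted(templates, key=lambda t: t.m):
        res = sdtw_ml(X, tpl)
        cells += res.cells
        val = res.distance / tpl.m
        if best is None or val < best.distance:
            best = MatchResult(
                res.t_s, res.t_e, tpl.m, float(val), res.path, res.d_s
            )
    assert best is not None
    best.cells = cells
    return best
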