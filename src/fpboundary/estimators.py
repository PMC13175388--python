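"""Boundary estimation from observed crossing pairs.

Given pairs (T_i, X_i(T_i)) anchored on the boundary by the first-passage
mechanism, the boundary Q(t) is reconstructed by penalized B-spline least
squares

    beta_hat(lambda) = argmin_beta  ||X - Phi beta||^2 + lambda beta' S beta
                     = (Phi'Phi + lambda S)^{-1} Phi'X,

with the smoothing parameter chosen by generalized cross-validation,
GCV(lambda) = n RSS(lambda) / (n - edf(lambda))^2 where edf is the trace of
the hat matrix, or by K-fold cross-validation.  A LOESS smoother (local
linear, tricube weights on span-nearest neighbors) serves as a descriptive
alternative estimating the same conditional mean E[X(T) | T = t], and a
classical hinge (continuous piecewise-linear) threshold regression with
grid-searched kink is provided as the fixed-threshold baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import PenaltyMatrix, SplineSpec, evaluate_basis

__all__ = [
    "CrossingPairSet",
    "PenalizedFitResult",
    "LoessFit",
    "HingeFitResult",
    "SingularSystemError",
    "IllPosedError",
    "penalized_fit",
    "gcv_select",
    "kfold_select",
    "loess_fit",
    "loess_span_select",
    "hinge_threshold_fit",
    "evaluate_fit",
    "default_lambda_grid",
]

# relative tie tolerance for smoothing-parameter selection; ties (e.g. data
# exactly in the penalty null space, where all scores are at rounding level)
# resolve toward the smoothest candidate
_TIE_RTOL = 1e-9


class SingularSystemError(np.linalg.LinAlgError):
    """Unpenalized normal equations are rank-deficient; use lambda > 0 or smaller K."""


class IllPosedError(ValueError):
    """Selection criterion undefined for every candidate (n <= edf throughout)."""


def default_lambda_grid(lo: float = 1e-6, hi: float = 1e6, num: int = 41) -> np.ndarray:
    """Log-equispaced smoothing-parameter grid; the default spans [1e-6, 1e6]."""
    return np.logspace(np.log10(lo), np.log10(hi), num)


@dataclass(frozen=True)
class CrossingPairSet:
    """The regression sample {(T_i, X_i(T_i))} of observed crossing pairs."""

    times: np.ndarray
    levels: np.ndarray
    unit_ids: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "levels", levels)
        if times.ndim != 1 or times.shape != levels.shape:
            raise ValueError("times and levels must be 1-D of equal length")
        if times.size < 1:
            raise ValueError("need at least one crossing pair")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(levels))):
            raise ValueError("crossing pairs must be finite")
        if self.unit_ids is not None:
            ids = np.asarray(self.unit_ids)
            if ids.shape != times.shape:
                raise ValueError("unit_ids length mismatch")
            object.__setattr__(self, "unit_ids", ids)

    @property
    def n(self) -> int:
        return self.times.size

    @classmethod
    def from_records(cls, records) -> "CrossingPairSet":
        """Extract the pairs of all crossed units from CrossingRecords."""
        crossed = [r for r in records if r.status == "crossed"]
        if not crossed:
            raise ValueError("no crossed units: cannot form a crossing-pair set")
        return cls(
            times=np.array([r.crossing_time for r in crossed]),
            levels=np.array([r.crossing_level for r in crossed]),
            unit_ids=np.array([r.unit_id for r in crossed], dtype=object),
        )

    @classmethod
    def read(cls, path_or_buf, sep: str = ",") -> "CrossingPairSet":
        df = pd.read_csv(path_or_buf, sep=sep)
        required = {"unit_id", "crossing_time", "crossing_level"}
        if not required.issubset(df.columns):
            raise ValueError(f"crossing-pair table needs columns {sorted(required)}")
        return cls(
            times=df["crossing_time"].to_numpy(float),
            levels=df["crossing_level"].to_numpy(float),
            unit_ids=df["unit_id"].to_numpy(object),
        )

    def write(self, path, sep: str = ",") -> None:
        ids = self.unit_ids if self.unit_ids is not None else np.arange(self.n)
        pd.DataFrame(
            {"unit_id": ids, "crossing_time": self.times, "crossing_level": self.levels}
        ).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class PenalizedFitResult:
    """Penalized spline solution with its smoothing diagnostics."""

    spec: SplineSpec
    coefficients: np.ndarray
    lam: float
    edf: float
    rss: float
    gcv: float
    n: int

    def predict(self, times) -> np.ndarray:
        """Evaluate the fitted boundary on a grid inside the spec domain."""
        return evaluate_basis(self.spec, times) @ self.coefficients

    def as_dict(self) -> dict:
        return {
            "spec": self.spec.as_dict(),
            "coefficients": self.coefficients.tolist(),
            "lambda": self.lam,
            "edf": self.edf,
            "rss": self.rss,
            "gcv": self.gcv,
            "n": self.n,
        }


def _solve_or_lstsq(A, b):
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def penalized_fit(
    pairs: CrossingPairSet,
    spec: SplineSpec,
    penalty: PenaltyMatrix,
    lam: float,
) -> PenalizedFitResult:
    """Solve the penalized least-squares problem at a fixed smoothing parameter.

    Returns the coefficients of (Phi'Phi + lambda S)beta = Phi'X together
    with the effective degrees of freedom edf = tr[Phi (Phi'Phi+lambda S)^{-1} Phi'],
    the residual sum of squares on the pairs, and the GCV score.
    """
    if lam < 0:
        raise ValueError("smoothing parameter must be nonnegative")
    if penalty.K != spec.n_basis_K:
        raise ValueError("penalty matrix size does not match the spline spec")
    Phi = evaluate_basis(spec, pairs.times)
    if lam == 0:
        PtP = Phi.T @ Phi
        rank = np.linalg.matrix_rank(PtP, tol=1e-10 * max(1.0, np.abs(PtP).max()))
        if rank < spec.n_basis_K:
            raise SingularSystemError(
                f"Phi'Phi is rank deficient (rank {rank} < K={spec.n_basis_K}) at lambda=0; "
                "use lambda > 0 or a smaller basis"
            )
    # Solve in the eigenbasis of S, where the penalty is diagonal: adding
    # lam*S to Phi'Phi in the original basis destroys the data term in
    # rounding once lam*S dominates, while here the scale mixing stays on
    # the diagonal and the limiting fit (OLS on the penalty null space) is
    # recovered exactly.
    w, V = np.linalg.eigh(penalty.matrix_S)
    # null-space eigenvalues carry O(||S||*eps) noise; zero them exactly so
    # huge lam cannot resurrect them
    w[w < 100 * np.finfo(float).eps * max(w.max(), 1.0)] = 0.0
    Pv = Phi @ V
    G = Pv.T @ Pv
    A = G + lam * np.diag(w)
    gamma = _solve_or_lstsq(A, Pv.T @ pairs.levels)
    beta = V @ gamma
    # edf = tr(Phi (Phi'Phi + lam S)^{-1} Phi'), similarity-invariant
    edf = float(np.trace(_solve_or_lstsq(A, G)))
    resid = pairs.levels - Phi @ beta
    rss = float(resid @ resid)
    n = pairs.n
    denom = (n - edf) ** 2
    gcv = float(n * rss / denom) if denom > 0 else np.inf
    return PenalizedFitResult(
        spec=spec, coefficients=beta, lam=float(lam), edf=edf, rss=rss, gcv=gcv, n=n
    )


def _select_smoothest(scores: np.ndarray, grid: np.ndarray, scale: float) -> int:
    """Index of the minimizing candidate; ties resolve to the largest grid value."""
    finite = np.isfinite(scores)
    if not finite.any():
        raise IllPosedError("selection score undefined for every candidate")
    m = scores[finite].min()
    tol = _TIE_RTOL * max(abs(m), scale)
    tied = np.flatnonzero(finite & (scores <= m + tol))
    return int(tied[np.argmax(grid[tied])])


def gcv_select(
    pairs: CrossingPairSet,
    spec: SplineSpec,
    penalty: PenaltyMatrix,
    lambda_grid=None,
) -> tuple[float, PenalizedFitResult]:
    """Pick the smoothing parameter minimizing GCV over a grid.

    GCV(lambda) = n RSS(lambda) / (n - edf(lambda))^2.  Candidates whose fit
    leaves fewer than 2 residual degrees of freedom (n - edf < 2) are
    excluded: near-interpolating fits drive both RSS and the GCV denominator
    to zero and the score degenerates.  Ties (within rounding of the
    minimum) break toward the largest lambda, i.e. the smoothest fit.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda grid must be nonempty and strictly positive")
    fits = [penalized_fit(pairs, spec, penalty, lam) for lam in grid]
    scores = np.array([f.gcv if f.n - f.edf >= 2 - 1e-9 else np.inf for f in fits])
    if not np.isfinite(scores).any():
        raise IllPosedError("n <= edf for every lambda on the grid; enlarge lambda or n")
    scale = float(np.mean(pairs.levels**2))
    idx = _select_smoothest(scores, grid, scale)
    return float(grid[idx]), fits[idx]


def _fold_indices(n: int, k: int, seed) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[j::k] for j in range(k)]


def kfold_select(
    pairs: CrossingPairSet,
    spec: SplineSpec,
    penalty: PenaltyMatrix,
    lambda_grid=None,
    k: int = 5,
    seed: int | None = 0,
) -> tuple[float, PenalizedFitResult]:
    """K-fold cross-validation alternative to GCV; deterministic given the seed."""
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    n = pairs.n
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    folds = _fold_indices(n, k, seed)
    cv = np.zeros(grid.size)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train = CrossingPairSet(pairs.times[mask], pairs.levels[mask])
        Phi_out = evaluate_basis(spec, pairs.times[fold])
        for a, lam in enumerate(grid):
            fit = penalized_fit(train, spec, penalty, lam)
            err = pairs.levels[fold] - Phi_out @ fit.coefficients
            cv[a] += float(err @ err)
    cv /= n
    scale = float(np.mean(pairs.levels**2))
    idx = _select_smoothest(cv, grid, scale)
    lam_star = float(grid[idx])
    return lam_star, penalized_fit(pairs, spec, penalty, lam_star)


# ---------------------------------------------------------------------------
# LOESS: local linear regression with tricube weights on span-nearest neighbors


@dataclass(frozen=True)
class LoessFit:
    """Local-linear smoother Q_hat(t) = sum_i w_i(t) X_i(T_i).

    ``weights`` holds the equivalent-kernel row w_.(t) for each evaluation
    point; rows sum to one and reproduce linear data exactly.
    """

    span: float
    eval_times: np.ndarray
    fitted: np.ndarray
    weights: np.ndarray = field(repr=False)
    train_times: np.ndarray = field(repr=False)
    train_levels: np.ndarray = field(repr=False)

    def predict(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, float))
        lo, hi = self.train_times.min(), self.train_times.max()
        if times.min() < lo - 1e-12 or times.max() > hi + 1e-12:
            raise ValueError("LOESS evaluation outside the data range; no extrapolation")
        _, fitted, _ = _loess_core(self.train_times, self.train_levels, self.span, times)
        return fitted

    @property
    def rss(self) -> float:
        _, fitted, _ = _loess_core(self.train_times, self.train_levels, self.span,
                                   self.train_times)
        r = self.train_levels - fitted
        return float(r @ r)


def _loess_core(x, y, span, eval_times):
    n = x.size
    r = max(2, int(np.ceil(span * n)))
    r = min(r, n)
    W = np.zeros((eval_times.size, n))
    fitted = np.empty(eval_times.size)
    for j, t in enumerate(eval_times):
        d = np.abs(x - t)
        order = np.argsort(d, kind="stable")
        idx = order[:r]
        h = d[idx].max()
        if h == 0:
            w = np.zeros(n)
            w[idx] = 1.0
        else:
            w = np.zeros(n)
            u = np.clip(d[idx] / h, 0, 1)
            w[idx] = (1 - u**3) ** 3
            if w[idx].sum() <= 0:  # all neighbors at distance exactly h
                w[idx] = 1.0
        # weighted local line centered at t: value = a of y ~ a + b (x - t)
        xc = x - t
        sw, swx, swxx = w.sum(), w @ xc, w @ (xc * xc)
        det = sw * swxx - swx**2
        if det <= 1e-14 * max(sw * swxx, 1e-300):
            lrow = w / sw  # degenerate spread: local constant
        else:
            lrow = (swxx * w - swx * (w * xc)) / det
        W[j] = lrow
        fitted[j] = lrow @ y
    return W, fitted, r


def loess_fit(pairs: CrossingPairSet, span: float, eval_times) -> LoessFit:
    """LOESS estimate of the conditional crossing-level curve on a grid.

    Local linear fits with tricube weights over the ceil(span*n) nearest
    neighbors; exact on globally linear data, including at the range endpoints.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    x, y = pairs.times, pairs.levels
    if np.unique(x).size < 2:
        raise ValueError("LOESS needs at least 2 distinct crossing times")
    if np.ceil(span * pairs.n) < 2:
        raise ValueError(f"span {span} gives fewer than 2 neighbors at n={pairs.n}")
    eval_times = np.atleast_1d(np.asarray(eval_times, float))
    if eval_times.min() < x.min() - 1e-12 or eval_times.max() > x.max() + 1e-12:
        raise ValueError("evaluation grid outside the crossing-time range")
    W, fitted, _ = _loess_core(x, y, span, eval_times)
    return LoessFit(span=float(span), eval_times=eval_times, fitted=fitted, weights=W,
                    train_times=x.copy(), train_levels=y.copy())


def loess_span_select(
    pairs: CrossingPairSet,
    span_grid,
    k: int = 5,
    seed: int | None = 0,
) -> float:
    """Pick the LOESS span by seeded K-fold cross-validation (ties -> largest span)."""
    grid = np.asarray(span_grid, float)
    n = pairs.n
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    folds = _fold_indices(n, k, seed)
    cv = np.zeros(grid.size)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        xt, yt = pairs.times[mask], pairs.levels[mask]
        t_out = np.clip(pairs.times[fold], xt.min(), xt.max())
        for a, span in enumerate(grid):
            _, pred, _ = _loess_core(xt, yt, span, t_out)
            err = pairs.levels[fold] - pred
            cv[a] += float(err @ err)
    cv /= n
    idx = _select_smoothest(cv, grid, float(np.mean(pairs.levels**2)))
    return float(grid[idx])


# ---------------------------------------------------------------------------
# hinge (continuous piecewise-linear) threshold regression baseline


@dataclass(frozen=True)
class HingeFitResult:
    """Fixed-threshold baseline Y = b0 + b1 Z + b2 (Z - tau)_+ with grid-searched tau."""

    beta0: float
    beta1: float
    beta2: float
    tau_hat: float
    rss_by_tau: dict

    def predict(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        return self.beta0 + self.beta1 * z + self.beta2 * np.maximum(z - self.tau_hat, 0.0)


def hinge_threshold_fit(z, y, tau_grid) -> HingeFitResult:
    """Grid-search OLS fit of the hinge model; tau_hat minimizes RSS (ties -> smallest tau)."""
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    if z.ndim != 1 or z.shape != y.shape or z.size < 4:
        raise ValueError("need >= 4 paired (z, y) observations")
    tau_grid = np.asarray(tau_grid, float)
    if tau_grid.size == 0 or tau_grid.min() < z.min() or tau_grid.max() > z.max():
        raise ValueError("tau grid must be nonempty and lie within the covariate range")
    best = None
    rss_by_tau: dict = {}
    tol = _TIE_RTOL * float(np.mean(y**2) + 1.0)
    for tau in np.sort(tau_grid):
        X = np.column_stack([np.ones_like(z), z, np.maximum(z - tau, 0.0)])
        if np.linalg.matrix_rank(X) < 3:
            warnings.warn(f"collinear hinge design at tau={tau}; candidate skipped")
            continue
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss = float(r @ r)
        rss_by_tau[float(tau)] = rss
        # improvement must beat the rounding band, so the smallest tau wins ties
        if best is None or rss < best[0] - tol:
            best = (rss, float(tau), coef)
    if best is None:
        raise ValueError("every tau candidate produced a collinear design")
    _, tau_hat, coef = best
    return HingeFitResult(
        beta0=float(coef[0]), beta1=float(coef[1]), beta2=float(coef[2]),
        tau_hat=tau_hat, rss_by_tau=rss_by_tau,
    )


def evaluate_fit(fit, times) -> np.ndarray:
    """Evaluate a fitted boundary (penalized spline or LOESS) on a grid."""
    return fit.predict(times)
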