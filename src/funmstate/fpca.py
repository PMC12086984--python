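"""Univariate functional principal component analysis for sparse designs.

This is the shared engine underneath the multivariate and multilevel
decompositions.  Longitudinal markers observed at a handful of irregular
visit times per subject are treated as noisy evaluations of a smooth latent
process

    Y_i(t) = mu(t) + sum_k xi_ik phi_k(t) + eps,   eps ~ N(0, sigma^2),

with mean ``mu``, orthonormal eigenfunctions ``phi_k`` and uncorrelated
scores ``xi_ik`` of variance ``lambda_k``.  Estimation follows the standard
pooled route for sparse data: a penalized-spline fit of the pooled
observations gives the mean; raw cross-products of centered residuals at
distinct time pairs, smoothed in two dimensions with the diagonal left out,
give the covariance surface; a weighted eigendecomposition gives the
eigensystem; and subject scores are best linear unbiased predictors given
each subject's own observations (the conditional-expectation, or PACE,
estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "FunctionGrid",
    "EigenSystem",
    "ScoreMatrix",
    "FunctionalSample",
    "estimate_mean",
    "estimate_covariance",
    "eigendecompose_covariance",
    "pace_scores",
    "reconstruct",
    "fit_fpca",
    "fit_fpca_dense",
]

_LAMBDA_GRID = np.logspace(-4, 6, 21)


@dataclass(frozen=True)
class FunctionGrid:
    """Discrete representation of a continuous (or ordered) domain.

    ``weights`` are quadrature weights.  For a genuinely continuous domain
    (time in years) these are trapezoid weights summing to the domain
    length; for an ordered index domain (the 116 brain regions) they are
    unit weights, so inner products are plain Euclidean ones.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)
        if pts.ndim != 1 or np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if w.shape != pts.shape or np.any(w <= 0):
            raise ValueError("quadrature weights must be positive, one per point")

    @classmethod
    def regular(cls, start: float, stop: float, num: int) -> "FunctionGrid":
        """Equispaced grid with trapezoid weights (sum = domain length)."""
        pts = np.linspace(start, stop, num)
        h = (stop - start) / (num - 1)
        w = np.full(num, h)
        w[0] = w[-1] = h / 2
        return cls(pts, w)

    @classmethod
    def indexed(cls, n: int) -> "FunctionGrid":
        """Integer index grid 1..n with unit weights (Euclidean geometry)."""
        return cls(np.arange(1, n + 1, dtype=float), np.ones(n))

    @property
    def size(self) -> int:
        return self.points.size

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        return float(np.sum(self.weights * f * g))


@dataclass
class EigenSystem:
    """Mean + truncated eigensystem of a functional process on a grid.

    ``pve`` is per-component proportion of variance explained, with the
    denominator taken over the full nonnegative spectrum (``total_variance``),
    not just the retained components.  Eigenfunctions follow the sign
    convention that their quadrature integral is nonnegative, so score
    directions are reproducible downstream.
    """

    grid: FunctionGrid
    mean: np.ndarray
    eigenfunctions: np.ndarray  # (K, G)
    eigenvalues: np.ndarray  # (K,)
    noise_variance: float = 0.0
    pve: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_variance: float = 0.0

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def _check_times(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        lo, hi = self.grid.points[0], self.grid.points[-1]
        if np.any(times < lo - 1e-8) or np.any(times > hi + 1e-8):
            raise ValueError(
                f"times outside grid range [{lo}, {hi}]; extrapolation not supported"
            )
        return np.clip(times, lo, hi)

    def mean_at(self, times: np.ndarray) -> np.ndarray:
        times = self._check_times(times)
        return np.interp(times, self.grid.points, self.mean)

    def phi_at(self, times: np.ndarray) -> np.ndarray:
        """Eigenfunctions linearly interpolated to ``times``; shape (m, K)."""
        times = self._check_times(times)
        return np.column_stack(
            [np.interp(times, self.grid.points, f) for f in self.eigenfunctions]
        ) if self.n_components else np.empty((times.size, 0))

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.points.tolist(),
            "weights": self.grid.weights.tolist(),
            "mean": self.mean.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "noise_variance": float(self.noise_variance),
            "pve": self.pve.tolist(),
            "total_variance": float(self.total_variance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EigenSystem":
        return cls(
            FunctionGrid(np.asarray(d["grid"]), np.asarray(d["weights"])),
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["eigenfunctions"], dtype=float),
            np.asarray(d["eigenvalues"], dtype=float),
            float(d["noise_variance"]),
            np.asarray(d["pve"], dtype=float),
            float(d["total_variance"]),
        )


@dataclass
class ScoreMatrix:
    """Per-subject component scores and their conditional variances."""

    ids: list
    scores: np.ndarray  # (n, K)
    variances: np.ndarray  # (n, K)

    def to_frame(self, prefix: str = "score") -> pd.DataFrame:
        cols = [f"{prefix}{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=pd.Index(self.ids, name="subject_id"),
                            columns=cols)


@dataclass
class FunctionalSample:
    """Sparse longitudinal observations: one (times, values) pair per subject."""

    ids: list
    times: list  # list of 1-d arrays
    values: list  # list of 1-d arrays, matching lengths

    def __post_init__(self):
        if not (len(self.ids) == len(self.times) == len(self.values)):
            raise ValueError("ids, times, values must align")
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for t, v in zip(self.times, self.values):
            if t.shape != v.shape:
                raise ValueError("times and values must match per subject")

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_observations(self) -> int:
        return int(sum(t.size for t in self.times))

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.times:
            return np.empty(0), np.empty(0)
        return np.concatenate(self.times), np.concatenate(self.values)


# ---------------------------------------------------------------------------
# penalized B-spline smoothers


def _bspline_basis(x: np.ndarray, lo: float, hi: float, n_basis: int, degree: int = 3):
    """Cubic B-spline design matrix with open-uniform knots on [lo, hi]."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for cubic splines")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray(), knots


def _diff_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _pspline_fit(x, y, lo, hi, n_basis=15, lam=None):
    """Penalized-spline regression; roughness penalty chosen by GCV unless fixed.

    Returns (coefficients, knots).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    B, knots = _bspline_basis(x, lo, hi, n_basis)
    P = _diff_penalty(n_basis)
    BtB = B.T @ B
    Bty = B.T @ y
    n = y.size
    # small ridge keeps the system well posed when few distinct times exist
    ridge = 1e-9 * (np.trace(BtB) / n_basis + 1.0) * np.eye(n_basis)
    if lam is not None:
        coef = np.linalg.solve(BtB + lam * P + ridge, Bty)
        return coef, knots
    best = (np.inf, None)
    for lam_c in _LAMBDA_GRID:
        A = BtB + lam_c * P + ridge
        try:
            coef = np.linalg.solve(A, Bty)
        except np.linalg.LinAlgError:
            continue
        edf = np.trace(np.linalg.solve(A, BtB))
        rss = float(np.sum((y - B @ coef) ** 2))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best[0]:
            best = (gcv, coef)
    if best[1] is None:
        raise np.linalg.LinAlgError("penalized spline fit failed for all penalties")
    return best[1], knots


def _pspline_eval(coef, knots, x, degree=3):
    x = np.clip(np.asarray(x, dtype=float), knots[degree], knots[-degree - 1])
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return B @ coef


def estimate_mean(sample: FunctionalSample, grid: FunctionGrid,
                  n_basis: int = 15, penalty: float | None = None) -> np.ndarray:
    """Pooled penalized-spline estimate of the mean function on ``grid``.

    All subjects' observations are pooled and smoothed jointly; the
    roughness penalty is chosen by generalized cross-validation unless a
    fixed ``penalty`` is given.
    """
    t, y = sample.pooled()
    if np.unique(t).size < 2:
        raise ValueError("need observations at >= 2 distinct times to estimate a mean")
    lo, hi = grid.points[0], grid.points[-1]
    coef, knots = _pspline_fit(t, y, lo, hi, n_basis=n_basis, lam=penalty)
    return _pspline_eval(coef, knots, grid.points)


def _raw_covariance_pairs(sample: FunctionalSample, mean: np.ndarray,
                          grid: FunctionGrid):
    """Centered residual cross-products at distinct same-subject time pairs."""
    s_list, t_list, p_list, diag_t, diag_v = [], [], [], [], []
    gp = grid.points
    for t, y in zip(sample.times, sample.values):
        if t.size == 0:
            continue
        r = y - np.interp(t, gp, mean)
        diag_t.append(t)
        diag_v.append(r**2)
        if t.size < 2:
            continue
        j, k = np.meshgrid(np.arange(t.size), np.arange(t.size), indexing="ij")
        off = j != k
        s_list.append(t[j[off]])
        t_list.append(t[k[off]])
        p_list.append(r[j[off]] * r[k[off]])
    if not s_list:
        raise ValueError("insufficient design: no same-subject off-diagonal pairs")
    return (np.concatenate(s_list), np.concatenate(t_list), np.concatenate(p_list),
            np.concatenate(diag_t), np.concatenate(diag_v))


def estimate_covariance(sample: FunctionalSample, mean: np.ndarray,
                        grid: FunctionGrid, n_basis: int = 10,
                        penalty: float | None = None) -> tuple[np.ndarray, float]:
    """Smoothed covariance surface and measurement-noise variance.

    Raw cross-products ``r_ij r_ik`` at distinct time pairs are smoothed with
    a tensor-product penalized spline, leaving the diagonal out so that
    measurement noise does not contaminate the surface.  The noise variance
    is the average gap between a one-dimensional smooth of the squared
    residuals (which includes noise) and the surface's own diagonal, floored
    at zero.
    """
    s, t, p, dt, dv = _raw_covariance_pairs(sample, mean, grid)
    lags = np.unique(np.round(np.abs(s - t), 10))
    if lags.size < 3:
        raise ValueError("insufficient design: fewer than 3 distinct time lags")
    lo, hi = grid.points[0], grid.points[-1]
    Bs, knots = _bspline_basis(s, lo, hi, n_basis)
    Bt, _ = _bspline_basis(t, lo, hi, n_basis)
    # row-wise Khatri-Rao product gives the tensor design
    n_pairs = p.size
    X = (Bs[:, :, None] * Bt[:, None, :]).reshape(n_pairs, n_basis * n_basis)
    P1 = _diff_penalty(n_basis)
    I = np.eye(n_basis)
    Pen = np.kron(P1, I) + np.kron(I, P1)
    XtX = X.T @ X
    Xtp = X.T @ p
    ridge = 1e-9 * (np.trace(XtX) / XtX.shape[0] + 1.0) * np.eye(XtX.shape[0])
    if penalty is not None:
        lam_values = [penalty]
    else:
        lam_values = _LAMBDA_GRID
    best = (np.inf, None)
    for lam_c in lam_values:
        A = XtX + lam_c * Pen + ridge
        try:
            coef = np.linalg.solve(A, Xtp)
        except np.linalg.LinAlgError:
            continue
        if penalty is not None:
            best = (0.0, coef)
            break
        edf = np.trace(np.linalg.solve(A, XtX))
        rss = float(np.sum((p - X @ coef) ** 2))
        gcv = n_pairs * rss / max(n_pairs - edf, 1e-8) ** 2
        if gcv < best[0]:
            best = (gcv, coef)
    if best[1] is None:
        raise np.linalg.LinAlgError("covariance smoothing failed")
    C = best[1].reshape(n_basis, n_basis)
    Bg, _ = _bspline_basis(grid.points, lo, hi, n_basis)
    surface = Bg @ C @ Bg.T
    surface = (surface + surface.T) / 2.0

    # diagonal (includes noise): 1-d smooth of squared residuals
    coef_d, knots_d = _pspline_fit(dt, dv, lo, hi, n_basis=n_basis)
    var_with_noise = _pspline_eval(coef_d, knots_d, grid.points)
    sigma2 = float(np.mean(var_with_noise - np.diag(surface)))
    floor = 1e-8 * max(float(np.max(np.diag(surface))), 0.0)
    sigma2 = max(sigma2, floor, 0.0)
    return surface, sigma2


def eigendecompose_covariance(surface: np.ndarray, grid: FunctionGrid,
                              pve_threshold: float = 0.90,
                              k_max: int | None = None,
                              mean: np.ndarray | None = None,
                              noise_variance: float = 0.0) -> EigenSystem:
    """Weighted eigendecomposition of a covariance surface.

    Solves the quadrature eigenproblem ``W^1/2 C W^1/2 v = lambda v`` and maps
    eigenvectors back to functions orthonormal under the grid inner product.
    Negative eigenvalues (sampling artifacts) are clipped at zero; the
    smallest K with cumulative PVE >= ``pve_threshold`` is retained (capped at
    ``k_max``); each eigenfunction is flipped, if needed, so its quadrature
    integral is nonnegative.
    """
    surface = np.asarray(surface, dtype=float)
    if not np.all(np.isfinite(surface)):
        raise ValueError("covariance surface contains non-finite entries")
    if surface.shape != (grid.size, grid.size):
        raise ValueError("surface shape does not match grid")
    sw = np.sqrt(grid.weights)
    M = (surface * sw[None, :]) * sw[:, None]
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(np.sum(evals))
    if total <= 0:
        mean_v = np.zeros(grid.size) if mean is None else np.asarray(mean, float)
        return EigenSystem(grid, mean_v, np.empty((0, grid.size)), np.empty(0),
                           noise_variance, np.empty(0), 0.0)
    pve_all = evals / total
    cum = np.cumsum(pve_all)
    K = int(np.searchsorted(cum, pve_threshold - 1e-12) + 1)
    K = min(K, evals.size)
    if k_max is not None:
        K = min(K, k_max)
    K = max(K, 1)
    phi = (evecs[:, :K] / sw[:, None]).T  # (K, G)
    for k in range(K):
        integ = float(np.sum(grid.weights * phi[k]))
        if integ < 0 or (abs(integ) < 1e-12 and phi[k][np.argmax(np.abs(phi[k]))] < 0):
            phi[k] = -phi[k]
    mean_v = np.zeros(grid.size) if mean is None else np.asarray(mean, dtype=float)
    return EigenSystem(grid, mean_v, phi, evals[:K], noise_variance,
                       pve_all[:K], total)


def pace_scores(sample: FunctionalSample, eigsys: EigenSystem) -> ScoreMatrix:
    """Conditional-expectation (BLUP) scores for sparse noisy observations.

    For subject i with observation vector y_i at times t_i,
    ``xi_hat = Lambda Phi_i' (Phi_i Lambda Phi_i' + sigma^2 I)^{-1} (y_i - mu_i)``
    with Phi_i the eigenfunctions interpolated to t_i.  Conditional variances
    ``diag(Lambda - Lambda Phi' Sigma^{-1} Phi Lambda)`` are returned alongside.
    """
    K = eigsys.n_components
    n = sample.n_subjects
    scores = np.zeros((n, K))
    variances = np.tile(eigsys.eigenvalues, (n, 1)) if K else np.zeros((n, 0))
    lam = eigsys.eigenvalues
    s2 = eigsys.noise_variance
    warned = False
    for i, (t, y) in enumerate(zip(sample.times, sample.values)):
        if t.size == 0 or K == 0:
            continue
        Phi = eigsys.phi_at(t)
        resid = y - eigsys.mean_at(t)
        Sigma = (Phi * lam) @ Phi.T + s2 * np.eye(t.size)
        if s2 <= 0 and np.linalg.matrix_rank(Sigma) < t.size:
            if not warned:
                warnings.warn("singular subject system; regularizing with 1e-10 jitter")
                warned = True
            Sigma = Sigma + 1e-10 * np.eye(t.size)
        LPhiT = lam[:, None] * Phi.T  # (K, m)
        sol = np.linalg.solve(Sigma, np.column_stack([resid, Phi]))
        scores[i] = LPhiT @ sol[:, 0]
        condcov = np.diag(lam) - LPhiT @ sol[:, 1:] * lam[None, :]
        variances[i] = np.clip(np.diag(condcov), 0.0, None)
    return ScoreMatrix(list(sample.ids), scores, variances)


def reconstruct(eigsys: EigenSystem, scores: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Fitted curve(s) mu(t) + sum_k xi_k phi_k(t) at ``times``.

    ``scores`` may be a single K-vector or an (n, K) matrix; returns a
    matching (m,) or (n, m) array.  Times outside the grid raise.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    mu = eigsys.mean_at(times)
    Phi = eigsys.phi_at(times)  # (m, K)
    out = mu[None, :] + scores @ Phi.T
    return out[0] if out.shape[0] == 1 else out


def fit_fpca(sample: FunctionalSample, grid: FunctionGrid | None = None,
             pve_threshold: float = 0.90, k_max: int | None = None,
             mean_basis: int = 15, cov_basis: int = 8
             ) -> tuple[EigenSystem, ScoreMatrix]:
    """Full sparse-FPCA pipeline: mean, covariance, eigensystem, PACE scores."""
    if grid is None:
        t, _ = sample.pooled()
        grid = FunctionGrid.regular(float(t.min()), float(t.max()), 61)
    mean = estimate_mean(sample, grid, n_basis=mean_basis)
    surface, s2 = estimate_covariance(sample, mean, grid, n_basis=cov_basis)
    eig = eigendecompose_covariance(surface, grid, pve_threshold, k_max,
                                    mean=mean, noise_variance=s2)
    return eig, pace_scores(sample, eig)


def fit_fpca_dense(profiles: np.ndarray, grid: FunctionGrid, ids=None,
                   pve_threshold: float = 0.90, k_max: int | None = None
                   ) -> tuple[EigenSystem, ScoreMatrix]:
    """FPCA of fully observed profiles (one row per subject) on ``grid``.

    The mean is the pointwise average and the covariance the sample
    covariance; scores are quadrature projections of the centered profiles
    (the noiseless dense limit of the PACE estimator).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != grid.size:
        raise ValueError("profiles must be (n_subjects, grid.size)")
    if ids is None:
        ids = list(range(profiles.shape[0]))
    mean = profiles.mean(axis=0)
    R = profiles - mean
    C = (R.T @ R) / max(profiles.shape[0] - 1, 1)
    eig = eigendecompose_covariance(C, grid, pve_threshold, k_max, mean=mean)
    scores = (R * grid.weights) @ eig.eigenfunctions.T
    variances = np.zeros_like(scores)
    return eig, ScoreMatrix(list(ids), scores, variances)
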