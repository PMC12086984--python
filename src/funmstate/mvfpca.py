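"""Multivariate FPCA across correlated longitudinal markers.

The joint decomposition uses the univariate-expansion (two-stage) route:
each marker is first reduced by sparse univariate FPCA to its own scores;
the empirical covariance of the stacked score vectors is then
eigendecomposed, and the multivariate eigenfunctions are linear
combinations of the univariate eigenfunctions with the joint eigenvector
entries as weights.  Markers are standardized to unit total variance
before the joint step by default, since the 11 neuropsychological scales
carry incommensurate units (ADAS points, seconds, composite z-scores);
this choice is recorded on the fitted object because it changes the
interpretation of downstream regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .fpca import (EigenSystem, FunctionGrid, FunctionalSample, ScoreMatrix,
                   fit_fpca, pace_scores)

__all__ = ["MVEigenSystem", "fit_mvfpca", "mv_scores", "pca_baseline_scores"]


@dataclass
class MVEigenSystem:
    """Joint eigensystem over stacked univariate FPC scores.

    ``joint_eigenvectors`` has one row per retained joint component, columns
    ordered marker-by-marker (``block_slices`` maps marker -> column range).
    Multivariate eigenfunction blocks are ``psi_m^(p) = sum_k c_{m,pk}
    phi_k^(p)`` on the (standardized) marker processes; with orthonormal
    univariate eigenfunctions and orthonormal joint eigenvectors these
    blocks satisfy sum_p <psi_k^(p), psi_l^(p)> = delta_kl.
    """

    marker_names: tuple
    univariate: dict  # name -> EigenSystem
    block_slices: dict  # name -> slice into stacked score vector
    joint_eigenvectors: np.ndarray  # (M, total_K)
    joint_eigenvalues: np.ndarray  # (M,)
    pve: np.ndarray
    total_variance: float
    scales: dict  # name -> multiplier applied to that marker's scores
    standardized: bool

    @property
    def n_components(self) -> int:
        return int(self.joint_eigenvalues.size)

    def eigenfunction_block(self, m: int, name: str) -> np.ndarray:
        """psi_m^(p) on the marker's grid (standardized process units)."""
        eig = self.univariate[name]
        c = self.joint_eigenvectors[m, self.block_slices[name]]
        return c @ eig.eigenfunctions


def _stacked_scores(mv_or_parts, samples: dict) -> tuple[list, np.ndarray]:
    """PACE scores per marker aligned on the union of subject ids.

    Subjects missing a marker entirely get conditional-expectation zeros for
    that block (and NaN in the alignment matrix used for covariance).
    """
    univariate, slices, scales = mv_or_parts
    ids = sorted(set().union(*[set(s.ids) for s in samples.values()]))
    total_K = sum(sl.stop - sl.start for sl in slices.values())
    mat = np.full((len(ids), total_K), np.nan)
    pos = {sid: i for i, sid in enumerate(ids)}
    for name, sample in samples.items():
        eig = univariate[name]
        sm = pace_scores(sample, eig)
        sl = slices[name]
        for sid, row in zip(sm.ids, sm.scores):
            mat[pos[sid], sl] = row * scales[name]
    return ids, mat


def fit_mvfpca(samples: dict, grid: FunctionGrid | None = None,
               pve_threshold: float = 0.90, standardize: bool = True,
               uni_pve: float = 0.90, uni_k_max: int | None = None,
               attenuation_correction: bool = True) -> MVEigenSystem:
    """Fit the multivariate decomposition from per-marker sparse samples.

    Stage 1 runs univariate sparse FPCA per marker at its own ``uni_pve``
    threshold; stage 2 eigendecomposes the (pairwise-complete) covariance of
    the stacked, optionally standardized scores, retaining joint components
    to cumulative PVE >= ``pve_threshold``.

    Because PACE scores are shrunken toward zero, their raw covariance
    understates the latent score covariance, and by a different factor per
    component (sparser-observed or lower-variance components shrink more),
    which biases the joint variance shares.  With
    ``attenuation_correction`` (default) each entry of the score covariance
    is rescaled by the estimated component reliabilities
    ``r = 1 - E[conditional variance] / lambda`` — diagonal entries divided
    by r, cross entries by r_i r_j — the classical measurement-error
    disattenuation, with reliabilities floored at 0.2 to keep noise
    amplification bounded.  For dense, low-noise designs r ~ 1 and the
    correction is a no-op.
    """
    if not samples:
        raise ValueError("no marker samples given")
    univariate, slices, scales = {}, {}, {}
    reliab = []
    start = 0
    for name in samples:
        eig, sm = fit_fpca(samples[name], grid=grid, pve_threshold=uni_pve,
                           k_max=uni_k_max)
        if eig.n_components == 0:
            raise ValueError(f"marker {name!r} retained zero components; "
                             "check its design")
        univariate[name] = eig
        slices[name] = slice(start, start + eig.n_components)
        start += eig.n_components
        scales[name] = (1.0 / np.sqrt(eig.total_variance)
                        if standardize and eig.total_variance > 0 else 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = 1.0 - sm.variances.mean(axis=0) / eig.eigenvalues
        reliab.append(np.clip(np.nan_to_num(r, nan=1.0), 0.2, 1.0))
    ids, mat = _stacked_scores((univariate, slices, scales), samples)
    Z = pd.DataFrame(mat).cov(min_periods=2).to_numpy()  # pairwise complete
    if np.any(~np.isfinite(Z)):
        raise ValueError("score covariance not estimable; too much missingness")
    Z = (Z + Z.T) / 2.0
    if attenuation_correction:
        r = np.concatenate(reliab)
        diag = np.diag(Z) / r
        Z = Z / np.outer(r, r)
        np.fill_diagonal(Z, diag)
    evals, evecs = np.linalg.eigh(Z)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(np.sum(evals))
    pve_all = evals / total
    M = int(np.searchsorted(np.cumsum(pve_all), pve_threshold - 1e-12) + 1)
    M = min(M, evals.size)
    C = evecs[:, :M].T  # (M, total_K)
    # sign convention: weighted sum of univariate-eigenfunction integrals >= 0
    integrals = np.empty(start)
    for name, sl in slices.items():
        eig = univariate[name]
        integrals[sl] = eig.eigenfunctions @ eig.grid.weights
    for m in range(M):
        s = float(C[m] @ integrals)
        if s < 0 or (abs(s) < 1e-12 and C[m, np.argmax(np.abs(C[m]))] < 0):
            C[m] = -C[m]
    return MVEigenSystem(tuple(samples), univariate, slices, C, evals[:M],
                         pve_all[:M], total, scales, standardize)


def mv_scores(mv: MVEigenSystem, samples: dict) -> ScoreMatrix:
    """Joint component scores: rho_im = sum_{p,k} c_{m,pk} xi_hat_ik^(p).

    Univariate scores are PACE estimates; a subject with no observations of
    a marker contributes that block's conditional expectation (zero), and
    the affected score entries are flagged via the ``missing_any`` attribute
    on the returned frame-compatible object.
    """
    ids, mat = _stacked_scores((mv.univariate, mv.block_slices, mv.scales),
                               samples)
    missing = np.any(~np.isfinite(mat), axis=1)
    mat = np.nan_to_num(mat, nan=0.0)
    scores = mat @ mv.joint_eigenvectors.T
    out = ScoreMatrix(ids, scores, np.zeros_like(scores))
    out.missing_any = missing
    return out


def pca_baseline_scores(samples: dict, domain=(0.0, 15.0), n_bins: int = 5,
                        n_components: int = 2, standardize: bool = True
                        ) -> ScoreMatrix:
    """Conventional-PCA sensitivity path (the scalar-model covariate source).

    Each subject's observations of each marker are averaged within
    ``n_bins`` equal time windows (the last observation in a window carries
    into its average), empty windows are column mean-imputed, columns are
    optionally standardized, and the matrix is reduced by ordinary PCA.
    This deliberately ignores the functional structure; it is the
    comparison arm, not the recommended estimator.  Carrying values across
    windows is deliberately avoided: with follow-up of unequal length it
    manufactures a dominant "time under observation" component.
    """
    ids = sorted(set().union(*[set(s.ids) for s in samples.values()]))
    pos = {sid: i for i, sid in enumerate(ids)}
    edges = np.linspace(domain[0], domain[1], n_bins + 1)
    cols = []
    for name, sample in samples.items():
        block = np.full((len(ids), n_bins), np.nan)
        for sid, t, y in zip(sample.ids, sample.times, sample.values):
            i = pos[sid]
            for b in range(n_bins):
                in_bin = (t >= edges[b]) & (t <= edges[b + 1] if b == n_bins - 1
                                            else t < edges[b + 1])
                if in_bin.any():
                    block[i, b] = float(np.mean(y[in_bin]))
        cols.append(block)
    X = np.hstack(cols)
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
    n_components = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return ScoreMatrix(ids, scores, np.zeros_like(scores))
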