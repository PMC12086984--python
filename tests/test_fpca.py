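"""Sparse FPCA engine: mean, covariance, eigendecomposition, PACE scores."""

import numpy as np
import pytest

from funmstate.fpca import (EigenSystem, FunctionGrid, FunctionalSample,
                            eigendecompose_covariance, estimate_covariance,
                            estimate_mean, fit_fpca, fit_fpca_dense,
                            pace_scores, reconstruct)
from funmstate.simulate import simulate_sparse_functional

GRID = FunctionGrid.regular(0.0, 15.0, 61)


def _angle_deg(grid, f, g):
    ip = grid.inner(f, g)
    nf = np.sqrt(grid.inner(f, f))
    ng = np.sqrt(grid.inner(g, g))
    return np.degrees(np.arccos(min(abs(ip) / (nf * ng), 1.0)))


# ---------------------------------------------------------------------- mean

def test_mean_constant_observations():
    rng = np.random.default_rng(0)
    times = [np.sort(rng.uniform(0, 15, 5)) for _ in range(40)]
    sample = FunctionalSample(list(range(40)), times,
                              [np.full(5, 3.7) for _ in range(40)])
    mu = estimate_mean(sample, GRID)
    assert np.allclose(mu, 3.7, atol=1e-8)


def test_mean_linear_function_recovered():
    rng = np.random.default_rng(1)
    times = [np.sort(rng.uniform(0, 15, 6)) for _ in range(60)]
    sample = FunctionalSample(list(range(60)), times, [t.copy() for t in times])
    mu = estimate_mean(sample, GRID)
    assert np.abs(mu[3:-3] - GRID.points[3:-3]).max() < 1e-3


def test_mean_sine_recovery_sparse():
    sample, _, truth = simulate_sparse_functional(
        500, (1.0,), 0.3, mean_fn=lambda t: np.sin(t / 2), seed=1)
    mu = estimate_mean(sample, truth["grid"])
    rmse = np.sqrt(np.mean((mu - np.sin(truth["grid"].points / 2)) ** 2))
    assert rmse < 0.05


def test_mean_single_time_rank_error():
    sample = FunctionalSample([0, 1], [np.array([2.0]), np.array([2.0])],
                              [np.array([1.0]), np.array([3.0])])
    with pytest.raises(ValueError, match="distinct"):
        estimate_mean(sample, GRID)


# ---------------------------------------------------------------- covariance

def test_covariance_surface_symmetric_and_rank1():
    """Rank-1 surface recovered to <10% Frobenius error.

    The comparison target uses the realized score variance of the draw, so
    the check isolates smoothing quality from the Monte-Carlo noise of the
    finite score sample (whose variance this seed draws ~2.6 sd low).
    """
    sample, scores, truth = simulate_sparse_functional(500, (4.0,), 0.3, seed=1)
    mu = estimate_mean(sample, truth["grid"])
    C, s2 = estimate_covariance(sample, mu, truth["grid"])
    assert np.abs(C - C.T).max() == 0.0
    phi = truth["eigenfunctions"][0]
    target = scores[:, 0].var(ddof=1) * np.outer(phi, phi)
    rel = np.linalg.norm(C - target) / np.linalg.norm(target)
    assert rel < 0.1
    pop = 4.0 * np.outer(phi, phi)
    assert np.linalg.norm(C - pop) / np.linalg.norm(pop) < 0.25


def test_noise_variance_recovered_pure_noise():
    rng = np.random.default_rng(2)
    n, sd = 500, 0.7
    times = [np.sort(rng.uniform(0, 15, 6)) for _ in range(n)]
    sample = FunctionalSample(list(range(n)), times,
                              [rng.normal(0, sd, 6) for _ in range(n)])
    mu = estimate_mean(sample, GRID)
    C, s2 = estimate_covariance(sample, mu, GRID)
    assert s2 == pytest.approx(sd**2, rel=0.10)
    assert np.abs(C).max() < 0.1 * sd**2 + 0.02


def test_covariance_insufficient_lags():
    sample = FunctionalSample([0], [np.array([0.0, 1.0])],
                              [np.array([0.0, 1.0])])
    with pytest.raises(ValueError, match="lags"):
        estimate_covariance(sample, np.zeros(61), GRID)


# ----------------------------------------------------------- eigen decomposition

def test_rank1_eigendecomposition_exact():
    phi = np.sin(GRID.points / 3) + 1.2
    phi = phi / np.sqrt(GRID.inner(phi, phi))
    C = 2.5 * np.outer(phi, phi)
    eig = eigendecompose_covariance(C, GRID, pve_threshold=0.99)
    assert eig.eigenvalues[0] == pytest.approx(2.5, abs=1e-8)
    assert _angle_deg(GRID, eig.eigenfunctions[0], phi) < 1e-4


def test_pve_boundary_retention():
    """Spectrum (9, .9, .1) at threshold 0.90 keeps exactly one component."""
    g = FunctionGrid.regular(0, 1, 50)
    basis = [np.ones(50), np.sqrt(3) * (2 * g.points - 1),
             np.sqrt(5) * (6 * g.points**2 - 6 * g.points + 1)]
    basis = [b / np.sqrt(g.inner(b, b)) for b in basis]
    C = sum(l * np.outer(b, b) for l, b in zip((9.0, 0.9, 0.1), basis))
    eig = eigendecompose_covariance(C, g, pve_threshold=0.90)
    assert eig.n_components == 1
    assert eig.pve[0] == pytest.approx(0.9, abs=1e-6)


def test_agreement_with_dense_eigh_oracle():
    """Weighted eigendecomposition agrees with a brute-force dense solve."""
    rng = np.random.default_rng(5)
    g = FunctionGrid.regular(0, 1, 50)
    A = rng.standard_normal((50, 8))
    C = A @ A.T / 8
    eig = eigendecompose_covariance(C, g, pve_threshold=0.9999, k_max=8)
    sw = np.sqrt(g.weights)
    evals = np.linalg.eigvalsh((C * sw[None, :]) * sw[:, None])[::-1]
    assert np.allclose(eig.eigenvalues, evals[:eig.n_components], atol=1e-10)


def test_orthonormality_and_sign_convention():
    sample, _, truth = simulate_sparse_functional(300, (4.0, 1.0), 0.5, seed=3)
    eig, _ = fit_fpca(sample, grid=truth["grid"])
    G = eig.eigenfunctions
    for j in range(eig.n_components):
        for k in range(eig.n_components):
            ip = truth["grid"].inner(G[j], G[k])
            assert ip == pytest.approx(1.0 if j == k else 0.0, abs=1e-6)
        assert np.sum(truth["grid"].weights * G[j]) >= -1e-9
    assert np.all(np.diff(eig.eigenvalues) <= 1e-12)
    assert np.all(eig.eigenvalues >= 0)


# ------------------------------------------------------------------- scores

def test_pace_dense_noiseless_equals_projection():
    sample, scores, truth = simulate_sparse_functional(50, (4.0, 1.0), 0.0,
                                                       seed=4)
    grid = truth["grid"]
    dense = FunctionalSample(
        list(range(50)), [grid.points] * 50,
        [truth["mean"] + truth["eigenfunctions"].T @ s for s in scores])
    eig = EigenSystem(grid, truth["mean"], truth["eigenfunctions"],
                      truth["eigenvalues"], 0.0,
                      np.array([0.8, 0.2]), 5.0)
    sm = pace_scores(dense, eig)
    proj = np.array([
        [(grid.weights * (v - truth["mean"]) * f).sum()
         for f in truth["eigenfunctions"]] for v in dense.values])
    assert np.abs(sm.scores - proj).max() < 1e-6


def test_pace_zero_deviation_zero_scores():
    grid = GRID
    mean = np.sin(grid.points / 4)
    phi = np.ones((1, 61)) / np.sqrt(15.0)
    eig = EigenSystem(grid, mean, phi, np.array([2.0]), 0.5,
                      np.array([1.0]), 2.0)
    t = np.array([1.0, 6.0, 11.0])
    sample = FunctionalSample([0], [t], [np.interp(t, grid.points, mean)])
    sm = pace_scores(sample, eig)
    assert np.allclose(sm.scores, 0.0, atol=1e-12)


def test_pace_recovery_correlation():
    sample, scores, truth = simulate_sparse_functional(500, (4.0, 1.0), 0.5,
                                                       seed=1)
    _, sm = fit_fpca(sample, grid=truth["grid"])
    r = np.corrcoef(sm.scores[:, 0], scores[:, 0])[0, 1]
    assert r > 0.9


def test_pace_to_ols_limit():
    """PACE reduces to least-squares projection as noise -> 0 on dense data."""
    sample, scores, truth = simulate_sparse_functional(20, (4.0, 1.0), 0.0,
                                                       seed=6)
    grid = truth["grid"]
    dense = FunctionalSample(
        list(range(20)), [grid.points] * 20,
        [truth["mean"] + truth["eigenfunctions"].T @ s for s in scores])
    for s2 in (1e-6, 1e-9):
        eig = EigenSystem(grid, truth["mean"], truth["eigenfunctions"],
                          truth["eigenvalues"], s2, np.array([0.8, 0.2]), 5.0)
        sm = pace_scores(dense, eig)
        assert np.abs(sm.scores - scores).max() < 1e-3


# -------------------------------------------------------------- reconstruct

def test_reconstruct_zero_scores_is_mean():
    grid = GRID
    eig = EigenSystem(grid, np.cos(grid.points), np.ones((1, 61)) / 15**0.5,
                      np.array([1.0]), 0.0, np.array([1.0]), 1.0)
    t = np.array([0.5, 7.25, 14.0])
    assert np.allclose(reconstruct(eig, np.zeros(1), t),
                       np.interp(t, grid.points, eig.mean))


def test_reconstruct_extrapolation_error():
    eig = EigenSystem(GRID, np.zeros(61), np.ones((1, 61)), np.array([1.0]),
                      0.0, np.array([1.0]), 1.0)
    with pytest.raises(ValueError, match="extrapolation"):
        reconstruct(eig, np.zeros(1), np.array([16.0]))


def test_projection_identity_dense_rank2():
    sample, scores, truth = simulate_sparse_functional(10, (4.0, 1.0), 0.0,
                                                       seed=8)
    grid = truth["grid"]
    curves = truth["mean"] + scores @ truth["eigenfunctions"]
    dense = FunctionalSample(list(range(10)), [grid.points] * 10, list(curves))
    eig = EigenSystem(grid, truth["mean"], truth["eigenfunctions"],
                      truth["eigenvalues"], 0.0, np.array([0.8, 0.2]), 5.0)
    sm = pace_scores(dense, eig)
    rec = reconstruct(eig, sm.scores, grid.points)
    assert np.abs(rec - curves).max() < 1e-5


def test_reconstruction_error_decreases_in_k():
    sample, scores, truth = simulate_sparse_functional(100, (4.0, 1.0, 0.25),
                                                       0.2, seed=9)
    grid = truth["grid"]
    curves = truth["mean"] + scores @ truth["eigenfunctions"]
    errs = []
    for K in (1, 2, 3):
        eig = EigenSystem(grid, truth["mean"], truth["eigenfunctions"][:K],
                          truth["eigenvalues"][:K], 0.2**2,
                          np.ones(K) / K, truth["eigenvalues"].sum())
        sm = pace_scores(sample, eig)
        rec = reconstruct(eig, sm.scores, grid.points)
        errs.append(np.mean((rec - curves) ** 2))
    assert errs[0] > errs[1] > errs[2]


def test_fit_fpca_dense_profiles():
    rng = np.random.default_rng(10)
    g = FunctionGrid.indexed(40)
    phi = np.sin(np.pi * g.points / 40)
    phi /= np.linalg.norm(phi)
    scores = rng.normal(0, 2.0, 300)
    prof = 1.0 + np.outer(scores, phi)
    eig, sm = fit_fpca_dense(prof, g, pve_threshold=0.99)
    assert eig.eigenvalues[0] == pytest.approx(scores.var(ddof=1), rel=1e-6)
    assert np.corrcoef(sm.scores[:, 0], scores)[0, 1] > 0.9999
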