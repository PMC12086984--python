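"""Multivariate FPCA: joint components over stacked univariate scores."""

import numpy as np
import pytest

from funmstate.fpca import FunctionalSample
from funmstate.mvfpca import fit_mvfpca, mv_scores, pca_baseline_scores
from funmstate.pipeline import _marker_sample
from funmstate.simulate import (MARKER_NAMES, MarkerModel, SimConfig,
                                generate_cohort, simulate_markers,
                                simulate_sparse_functional)


@pytest.fixture(scope="module")
def marker_samples(marker_cohort):
    subjects, _ = marker_cohort
    return {m: _marker_sample(subjects, m) for m in MARKER_NAMES}


@pytest.fixture(scope="module")
def fitted_raw(marker_samples):
    """Joint fit on the generator's own (commensurate) scale."""
    mv = fit_mvfpca(marker_samples, standardize=False)
    return mv, mv_scores(mv, marker_samples)


@pytest.fixture(scope="module")
def fitted_std(marker_samples):
    """Default (standardized) joint fit."""
    mv = fit_mvfpca(marker_samples)
    return mv, mv_scores(mv, marker_samples)


def test_identical_markers_symmetric_loadings():
    """Duplicating a marker gives MVFPC1 equal weight on both blocks; the
    joint variance split matches the marker's own retained-component split."""
    sample, _, _ = simulate_sparse_functional(200, (4.0, 1.0), 0.05, seed=2,
                                              n_obs_range=(8, 12))
    twin = FunctionalSample(list(sample.ids),
                            [t.copy() for t in sample.times],
                            [v.copy() for v in sample.values])
    # plain estimator: duplicated data violate the independent-measurement
    # assumption behind the disattenuation, and the identity is algebraic
    mv = fit_mvfpca({"m1": sample, "m2": twin}, standardize=False,
                    attenuation_correction=False)
    sl1, sl2 = mv.block_slices["m1"], mv.block_slices["m2"]
    c1 = mv.joint_eigenvectors[0]
    assert np.allclose(np.abs(c1[sl1]), np.abs(c1[sl2]), atol=1e-6)
    lam = mv.univariate["m1"].eigenvalues
    # the joint split tracks the marker's own split; PACE shrinkage (larger
    # for the low-variance component) nudges it slightly upward
    assert mv.pve[0] == pytest.approx(lam[0] / lam.sum(), abs=0.05)


def test_independent_markers_block_diagonal():
    """Two independent markers with variances ~(4, 1): joint eigenvalues
    track the marker variances and eigenvectors align with the blocks."""
    s1, _, _ = simulate_sparse_functional(400, (4.0,), 0.1, seed=3,
                                          n_obs_range=(8, 12))
    s2, _, _ = simulate_sparse_functional(400, (1.0,), 0.1, seed=4,
                                          n_obs_range=(8, 12))
    mv = fit_mvfpca({"a": s1, "b": s2}, standardize=False, pve_threshold=0.99)
    assert mv.joint_eigenvalues[0] == pytest.approx(4.0, rel=0.25)
    assert mv.joint_eigenvalues[1] == pytest.approx(1.0, rel=0.3)
    c = mv.joint_eigenvectors
    assert abs(c[0, mv.block_slices["a"]][0]) > 0.95
    assert abs(c[1, mv.block_slices["b"]][0]) > 0.95


def test_joint_structure_recovery(fitted_raw):
    """The 11-scale generator's 72.47/18.31 joint variance split is
    recovered within 5 percentage points at n=500."""
    mv, _ = fitted_raw
    assert 100 * mv.pve[0] == pytest.approx(72.47, abs=5.0)
    assert 100 * mv.pve[1] == pytest.approx(18.31, abs=5.0)


def test_mv_scores_recovery(fitted_raw, marker_cohort):
    _, sm = fitted_raw
    _, truth = marker_cohort
    ts = np.array([truth["joint_scores"][sid] for sid in sm.ids])
    assert abs(np.corrcoef(sm.scores[:, 0], ts[:, 0])[0, 1]) > 0.9


def test_single_marker_identity_embedding():
    sample, _, _ = simulate_sparse_functional(300, (4.0, 1.0), 0.2, seed=5,
                                              n_obs_range=(8, 12))
    mv = fit_mvfpca({"only": sample}, standardize=False, pve_threshold=0.99)
    sm = mv_scores(mv, {"only": sample})
    from funmstate.fpca import pace_scores

    uni = pace_scores(sample, mv.univariate["only"])
    # the joint step can only rotate a single block orthogonally, so the
    # score vectors agree up to rotation: norms match
    assert np.allclose(np.linalg.norm(sm.scores, axis=1),
                       np.linalg.norm(uni.scores, axis=1), atol=1e-8)


def test_mean_subject_gets_zero_scores():
    sample, _, _ = simulate_sparse_functional(100, (4.0, 1.0), 0.2, seed=6,
                                              n_obs_range=(8, 12))
    mv = fit_mvfpca({"m": sample}, standardize=False)
    eig = mv.univariate["m"]
    t = eig.grid.points[::8]
    flat = FunctionalSample(["mean-subject"], [t], [eig.mean_at(t)])
    sm = mv_scores(mv, {"m": flat})
    assert np.allclose(sm.scores, 0.0, atol=1e-10)


def test_block_orthonormality(fitted_std):
    """sum_p <psi_k^(p), psi_l^(p)> = delta_kl across eigenfunction blocks."""
    mv, _ = fitted_std
    n_comp = mv.n_components
    gram = np.zeros((n_comp, n_comp))
    for name in mv.marker_names:
        eig = mv.univariate[name]
        for k in range(n_comp):
            for l in range(n_comp):
                gram[k, l] += eig.grid.inner(mv.eigenfunction_block(k, name),
                                             mv.eigenfunction_block(l, name))
    assert np.allclose(gram, np.eye(n_comp), atol=1e-6)


def test_marker_permutation_invariance(marker_samples):
    mv1 = fit_mvfpca(marker_samples)
    rev = {m: marker_samples[m] for m in reversed(MARKER_NAMES)}
    mv2 = fit_mvfpca(rev)
    assert np.allclose(mv1.joint_eigenvalues, mv2.joint_eigenvalues, rtol=1e-8)
    s1 = mv_scores(mv1, marker_samples).scores
    s2 = mv_scores(mv2, rev).scores
    assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-6)


def test_scores_uncorrelated(marker_samples):
    """With the plain (uncorrected) estimator the joint eigenvectors
    diagonalize the empirical score covariance, so sample correlations of
    the joint scores vanish up to missingness effects."""
    mv = fit_mvfpca(marker_samples, attenuation_correction=False)
    sm = mv_scores(mv, marker_samples)
    n = sm.scores.shape[0]
    corr = np.corrcoef(sm.scores[:, :3].T)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    assert np.abs(off).max() < 3 / np.sqrt(n) + 0.05


def test_joint_pve_retention(fitted_std):
    mv, _ = fitted_std
    assert np.sum(mv.pve) <= 1.0 + 1e-9
    assert np.sum(mv.pve) >= 0.90 - 1e-9  # retained to the 90% threshold
    assert np.all(np.diff(np.cumsum(mv.pve)) >= 0)


# --------------------------------------------------------------- PCA baseline

def test_pca_baseline_dense_grid_matches_pca():
    rng = np.random.default_rng(7)
    n, nb = 120, 5
    edges = np.linspace(0, 15, nb + 1)
    mid = (edges[:-1] + edges[1:]) / 2
    fac = rng.standard_normal(n)
    load = np.linspace(1, 2, nb)
    vals = np.outer(fac, load)
    sample = FunctionalSample(list(range(n)), [mid] * n, list(vals))
    sm = pca_baseline_scores({"m": sample}, n_bins=nb, n_components=1,
                             standardize=False)
    r = np.corrcoef(sm.scores[:, 0], fac)[0, 1]
    assert abs(r) > 0.9999


def test_pca_baseline_agrees_with_mvfpc1_dense():
    """On a dense, low-noise design the conventional-PCA first score tracks
    MVFPC1 (sensitivity-analysis consistency)."""
    rng = np.random.default_rng(8)
    model = MarkerModel.default(noise_sd=0.1, missing_rate=0.0)
    t = np.linspace(0.5, 14.5, 10)
    n = 300
    samples = {m: FunctionalSample([], [], []) for m in model.names}
    for i in range(n):
        rho = rng.normal(0, np.sqrt(model.joint_eigenvalues))
        obs = simulate_markers(model, rho, t, rng)
        for m, (mt, mvals) in obs.items():
            samples[m].ids.append(i)
            samples[m].times.append(mt)
            samples[m].values.append(mvals)
    mv = fit_mvfpca(samples)
    mvs = mv_scores(mv, samples)
    ps = pca_baseline_scores(samples, n_components=2)
    assert ps.ids == mvs.ids
    r = np.corrcoef(ps.scores[:, 0], mvs.scores[:, 0])[0, 1]
    assert abs(r) > 0.8
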