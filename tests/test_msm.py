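"""Multistate model: generator, matrix exponential, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import funmstate as fm
from funmstate.cohort import StateCode, SubjectHistory, VisitRecord
from funmstate.msm import (DEFAULT_TRANSITIONS, IntensitySpec,
                           _batch_transition_probs, build_intensity_matrix,
                           compare_models, length_of_stay,
                           panel_log_likelihood, parametric_bootstrap,
                           transition_probability_matrix)
from funmstate.simulate import SimConfig, default_intensity_spec, generate_cohort

R, M, A = StateCode.RNC, StateCode.MCI, StateCode.AD


def _subj(sid, seq):
    return SubjectHistory(sid, {}, [VisitRecord(sid, t, s) for t, s in seq])


# ------------------------------------------------------------- intensity matrix

def test_intensity_matrix_reported_scale():
    """Baseline intensities land exactly on the published per-year scale."""
    Q = build_intensity_matrix(default_intensity_spec())
    assert Q[1, 0] == pytest.approx(0.035)  # MCI -> rNC
    assert Q[1, 2] == pytest.approx(0.120)  # MCI -> AD
    assert Q[0, 1] == pytest.approx(0.117)  # rNC -> MCI
    assert np.allclose(Q.sum(axis=1), 0.0)
    assert np.all(Q[2] == 0.0)  # AD absorbing


def test_intensity_proportionality():
    spec = default_intensity_spec(score_names=("s",), beta=[[0], [np.log(2)], [0]])
    Q1 = build_intensity_matrix(spec, scores={"s": 1.0})
    Q0 = build_intensity_matrix(spec, scores={"s": 0.0})
    assert Q1[1, 2] == pytest.approx(2 * Q0[1, 2])


def test_missing_covariate_named():
    spec = default_intensity_spec(covariate_names=("age",))
    with pytest.raises(KeyError, match="age"):
        build_intensity_matrix(spec, covariates={})


def test_intensity_overflow_names_transition():
    spec = default_intensity_spec(score_names=("s",), beta=[[0], [100.0], [0]])
    with pytest.raises(OverflowError):
        build_intensity_matrix(spec, scores={"s": 1.0})


@given(st.lists(st.floats(-3, 1), min_size=3, max_size=3))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_generator_rows_sum_to_zero(log_q):
    spec = IntensitySpec(DEFAULT_TRANSITIONS, np.array(log_q))
    Q = build_intensity_matrix(spec)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(Q - np.diag(np.diag(Q)) >= 0)


# --------------------------------------------------------- matrix exponential

def test_p_identity_at_zero():
    Q = build_intensity_matrix(default_intensity_spec())
    assert np.allclose(transition_probability_matrix(Q, 0.0), np.eye(3))


def test_two_state_closed_form():
    """P_MCI,AD(5) = 1 - exp(-0.12*5) when MCI->AD is the only transition."""
    spec = IntensitySpec(DEFAULT_TRANSITIONS,
                         np.log([1e-300, 0.12, 1e-300]))
    Q = np.zeros((3, 3))
    Q[1, 2], Q[1, 1] = 0.12, -0.12
    P = transition_probability_matrix(Q, 5.0)
    assert P[1, 2] == pytest.approx(1 - np.exp(-0.6), abs=1e-12)
    assert P[1, 2] == pytest.approx(0.4512, abs=5e-5)


def test_expm_matches_ode_oracle():
    """P(t) from scaling-and-squaring equals Runge-Kutta integration of the
    Kolmogorov forward equation to 1e-8."""
    Q = build_intensity_matrix(default_intensity_spec())
    for t in (1.0, 5.0, 15.0):
        P = transition_probability_matrix(Q, t)
        sol = solve_ivp(lambda _, y: (y.reshape(3, 3) @ Q).ravel(),
                        (0, t), np.eye(3).ravel(), rtol=1e-11, atol=1e-13)
        P_ode = sol.y[:, -1].reshape(3, 3)
        assert np.abs(P - P_ode).max() < 1e-8
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


def test_chapman_kolmogorov():
    Q = build_intensity_matrix(default_intensity_spec())
    for a, b in ((1.0, 2.0), (0.5, 7.5), (4.0, 11.0)):
        Pab = transition_probability_matrix(Q, a + b)
        prod = (transition_probability_matrix(Q, a)
                @ transition_probability_matrix(Q, b))
        assert np.abs(Pab - prod).max() < 1e-8


def test_absorption_probability_monotone():
    Q = build_intensity_matrix(default_intensity_spec())
    p = [transition_probability_matrix(Q, t)[1, 2] for t in np.linspace(0, 15, 40)]
    assert np.all(np.diff(p) >= -1e-12)


def test_invalid_generator_rejected():
    bad = np.array([[0.5, -0.5, 0], [0, 0, 0], [0, 0, 0.0]])
    with pytest.raises(ValueError, match="generator"):
        transition_probability_matrix(bad, 1.0)


@given(st.floats(1e-4, 2.0), st.floats(1e-4, 2.0), st.floats(1e-4, 2.0),
       st.floats(0.0, 20.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_batch_probs_agree_with_expm(a, b, c, dt):
    """The analytic spectral fast path equals scipy's expm for random rates."""
    Q = np.array([[-a, a, 0.0], [b, -(b + c), c], [0, 0, 0.0]])
    P_ref = transition_probability_matrix(Q, dt)
    P_fast = _batch_transition_probs(a, b, c, dt)
    assert np.abs(P_fast - P_ref).max() < 1e-9


# ------------------------------------------------------------------ likelihood

def test_loglik_stay_probability_one():
    spec = IntensitySpec(DEFAULT_TRANSITIONS, np.log([1e-300] * 3))
    cohort = [_subj("a", [(0, M), (1, M)])]
    assert panel_log_likelihood(cohort, spec) == pytest.approx(0.0, abs=1e-10)


def test_loglik_single_pair_closed_form():
    spec = IntensitySpec(DEFAULT_TRANSITIONS, np.log([1e-300, 0.12, 1e-300]))
    cohort = [_subj("a", [(0, M), (5, A)])]
    ll = panel_log_likelihood(cohort, spec)
    assert ll == pytest.approx(np.log(1 - np.exp(-0.6)), abs=1e-9)
    assert ll == pytest.approx(-0.7959, abs=2e-4)


def test_loglik_markov_factorization():
    spec = default_intensity_spec()
    both = [_subj("a", [(0, M), (1, M), (3, R)])]
    split = [_subj("a1", [(0, M), (1, M)]), _subj("a2", [(1, M), (3, R)])]
    assert panel_log_likelihood(both, spec) == pytest.approx(
        panel_log_likelihood(split, spec), abs=1e-12)


def test_loglik_invariant_to_subject_order(small_cohort):
    subjects, _ = small_cohort
    spec = default_intensity_spec()
    ll = panel_log_likelihood(subjects, spec)
    assert panel_log_likelihood(subjects[::-1], spec) == pytest.approx(ll, abs=1e-9)


def test_loglik_disallowed_pair_minus_inf():
    spec = default_intensity_spec()
    cohort = [_subj("a", [(0, M), (1, A), (0, R)][:2])]
    bad = [SubjectHistory("b", {}, [VisitRecord("b", 0.0, A),
                                    VisitRecord("b", 1.0, M)])]
    with pytest.warns(UserWarning, match="zero-probability"):
        assert panel_log_likelihood(bad, spec) == -np.inf


# --------------------------------------------------------------------- fitting

def test_fit_deterministic(small_cohort):
    subjects, _ = small_cohort
    f1 = fm.fit_fmsm(subjects, seed=3)
    f2 = fm.fit_fmsm(subjects, seed=3)
    assert np.abs(f1.spec.pack() - f2.spec.pack()).max() < 1e-10
    assert f1.aic == pytest.approx(2 * f1.n_params - 2 * f1.loglik)


def test_fit_matches_truth_moderate_n(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    for (a, b), q in fit.intensities.items():
        truth = {(M, R): 0.035, (M, A): 0.120, (R, M): 0.117}[(a, b)]
        assert q == pytest.approx(truth, rel=0.5)  # n=300: loose sanity only
    assert fit.convergence["status"] == "converged"
    v = fit.vcov
    assert np.allclose(v, v.T, atol=1e-10)
    assert np.linalg.eigvalsh(v).min() > -1e-10


# ----------------------------------------------------------------- functionals

def test_length_of_stay_zero_generator():
    stays = length_of_stay(np.zeros((3, 3)), horizon=15.0)
    assert stays["percent"]["MCI"] == pytest.approx(100.0)


def test_length_of_stay_two_state_closed_form():
    """E[time in MCI over 15y] = (1 - exp(-1.8)) / 0.12 with a single exit."""
    Q = np.zeros((3, 3))
    Q[1, 2], Q[1, 1] = 0.12, -0.12
    stays = length_of_stay(Q, horizon=15.0)
    assert stays["years"]["MCI"] == pytest.approx((1 - np.exp(-1.8)) / 0.12,
                                                  abs=1e-6)


def test_length_of_stay_conserves_horizon(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    stays = length_of_stay(fit, horizon=15.0)
    assert sum(stays["years"].values()) == pytest.approx(15.0, abs=1e-6)


def test_bootstrap_degenerate_vcov(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    fit0 = fm.msm.FMSMFit(fit.spec, np.zeros_like(fit.vcov), fit.loglik,
                          fit.aic, fit.n_params, fit.convergence)
    cis = parametric_bootstrap(fit0, B=50, seed=0)
    assert np.allclose(cis["intensity"]["lower"], cis["intensity"]["point"])
    assert np.allclose(cis["intensity"]["upper"], cis["intensity"]["point"])


def test_bootstrap_requires_two_draws(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    with pytest.raises(ValueError, match="B >= 2"):
        parametric_bootstrap(fit, B=1)


def test_bootstrap_ci_width_shrinks_with_n():
    widths = []
    for n in (250, 1000):
        subjects, _ = generate_cohort(SimConfig(n_subjects=n), seed=13)
        fit = fm.fit_fmsm(subjects)
        cis = parametric_bootstrap(fit, B=300, seed=1)
        w = cis["intensity"]["upper"] - cis["intensity"]["lower"]
        widths.append(w)
    assert np.all(widths[1] < widths[0])
    # roughly 1/sqrt(n): a factor-4 sample gives about half the width
    assert np.median(widths[1] / widths[0]) < 0.75


# ------------------------------------------------------------ model comparison

def test_compare_identical_models(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    table = compare_models({"m0": fit, "m0b": fit}, [])
    assert table["aic"].iloc[0] == table["aic"].iloc[1]


def test_lrt_nested_pair(small_cohort):
    subjects, _ = small_cohort
    rng = np.random.default_rng(5)
    sc = pd.DataFrame({"junk": rng.standard_normal(len(subjects))},
                      index=[s.subject_id for s in subjects])
    f0 = fm.fit_fmsm(subjects)
    f1 = fm.fit_fmsm(subjects, score_names=("junk",), scores=sc)
    table = compare_models({"f0": f0, "f1": f1}, [("f0", "f1")])
    lrt = table.attrs["lrt"]
    assert lrt.loc[0, "df"] == 3
    assert 0.0 <= lrt.loc[0, "p"] <= 1.0
    assert f1.aic - f0.aic == pytest.approx(
        2 * (f1.n_params - f0.n_params) - 2 * (f1.loglik - f0.loglik))


def test_lrt_refuses_non_nested(small_cohort):
    subjects, _ = small_cohort
    f0 = fm.fit_fmsm(subjects)
    with pytest.raises(ValueError, match="refused"):
        compare_models({"a": f0, "b": f0}, [("a", "b")])


# ----------------------------------------------------- observed vs expected

def test_observed_expected_at_entry(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    ove = fm.observed_vs_expected(fit, subjects, [0.0, 5.0])
    first = ove.iloc[0]
    assert first["observed_MCI"] == pytest.approx(100.0)
    assert first["expected_MCI"] == pytest.approx(100.0)


def test_misspecified_model_has_larger_discrepancy(small_cohort):
    subjects, _ = small_cohort
    fit = fm.fit_fmsm(subjects)
    grid = np.linspace(0, 15, 16)
    good = fm.observed_vs_expected(fit, subjects, grid).attrs["max_discrepancy"]
    spec3 = fit.spec.unpack(fit.spec.pack() + np.r_[np.log(3) * np.ones(3)])
    bad_fit = fm.msm.FMSMFit(spec3, fit.vcov, 0, 0, 3, {})
    bad = fm.observed_vs_expected(bad_fit, subjects, grid).attrs["max_discrepancy"]
    assert bad > good
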