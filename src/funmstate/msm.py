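"""Functional multistate model: panel-observed continuous-time Markov chain.

Three cognitive states — rNC, MCI, AD — with AD absorbing and allowed moves
MCI->rNC, MCI->AD, rNC->MCI (reversion routes back through MCI; no direct
rNC->AD jump).  Transition intensities follow a proportional form

    q_rs(i) = q_rs(0) * exp(gamma_rs' z_i + beta_rs' rho_i)

with baseline covariates z_i (age, sex, education, marital status, APOE e4)
and functional principal-component scores rho_i summarizing the subject's
longitudinal markers (the coefficient function of the functional term is
expanded in the eigenbasis, so the integral of g_i against it reduces to a
linear combination of scores).  States are only observed at visit times, so
the likelihood is the product over consecutive visit pairs of matrix-
exponential transition probabilities (the standard panel-data likelihood);
intensities are time homogeneous given covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.stats import chi2

from .cohort import StateCode, STATE_NAMES, SubjectHistory

__all__ = [
    "StateSpace",
    "IntensitySpec",
    "FMSMFit",
    "build_intensity_matrix",
    "transition_probability_matrix",
    "panel_log_likelihood",
    "fit_fmsm",
    "length_of_stay",
    "parametric_bootstrap",
    "compare_models",
    "observed_vs_expected",
]

DEFAULT_TRANSITIONS = (
    (StateCode.MCI, StateCode.RNC),
    (StateCode.MCI, StateCode.AD),
    (StateCode.RNC, StateCode.MCI),
)


@dataclass(frozen=True)
class StateSpace:
    states: tuple = (StateCode.RNC, StateCode.MCI, StateCode.AD)
    allowed: tuple = DEFAULT_TRANSITIONS
    absorbing: tuple = (StateCode.AD,)

    def __post_init__(self):
        if len(set(self.allowed)) != len(self.allowed):
            raise ValueError("allowed transitions must be distinct")
        for (a, b) in self.allowed:
            if a in self.absorbing:
                raise ValueError(f"no transitions out of absorbing state {a}")


@dataclass
class IntensitySpec:
    """Parametrization of the intensity matrix.

    ``log_q0[t]`` is the log baseline intensity of transition ``transitions[t]``
    (1/year); ``gamma[t]`` and ``beta[t]`` are that transition's coefficients
    on the named baseline covariates and FPC scores.
    """

    transitions: tuple = DEFAULT_TRANSITIONS
    log_q0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    covariate_names: tuple = ()
    gamma: np.ndarray | None = None
    score_names: tuple = ()
    beta: np.ndarray | None = None

    def __post_init__(self):
        T = len(self.transitions)
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        if self.log_q0.shape != (T,):
            raise ValueError("log_q0 must have one entry per transition")
        if self.gamma is None:
            self.gamma = np.zeros((T, len(self.covariate_names)))
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(
            T, len(self.covariate_names))
        if self.beta is None:
            self.beta = np.zeros((T, len(self.score_names)))
        self.beta = np.asarray(self.beta, dtype=float).reshape(
            T, len(self.score_names))
        if not (np.all(np.isfinite(self.log_q0)) and np.all(np.isfinite(self.gamma))
                and np.all(np.isfinite(self.beta))):
            raise ValueError("intensity parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.log_q0.size + self.gamma.size + self.beta.size

    def pack(self) -> np.ndarray:
        return np.concatenate([self.log_q0, self.gamma.ravel(), self.beta.ravel()])

    def unpack(self, theta: np.ndarray) -> "IntensitySpec":
        T = len(self.transitions)
        p, q = len(self.covariate_names), len(self.score_names)
        theta = np.asarray(theta, dtype=float)
        return IntensitySpec(
            self.transitions, theta[:T], self.covariate_names,
            theta[T:T + T * p].reshape(T, p), self.score_names,
            theta[T + T * p:].reshape(T, q))

    def parameter_names(self) -> list:
        """Names aligned with pack(): log_q0 block, gamma block, beta block."""
        names = [f"log_q0[{STATE_NAMES[a]}->{STATE_NAMES[b]}]"
                 for a, b in self.transitions]
        for a, b in self.transitions:
            names += [f"gamma[{STATE_NAMES[a]}->{STATE_NAMES[b]}].{c}"
                      for c in self.covariate_names]
        for a, b in self.transitions:
            names += [f"beta[{STATE_NAMES[a]}->{STATE_NAMES[b]}].{s}"
                      for s in self.score_names]
        return names

    def rates(self, covariates: dict | None = None, scores: dict | None = None
              ) -> np.ndarray:
        """Intensity per allowed transition for one subject."""
        eta = self.log_q0.copy()
        if self.covariate_names:
            z = _vector_from(covariates, self.covariate_names, "covariate")
            eta = eta + self.gamma @ z
        if self.score_names:
            r = _vector_from(scores, self.score_names, "score")
            eta = eta + self.beta @ r
        if np.any(eta > 50):
            t = self.transitions[int(np.argmax(eta))]
            raise OverflowError(f"intensity overflow for transition {t}")
        return np.exp(eta)


def _vector_from(mapping, names, kind) -> np.ndarray:
    if mapping is None:
        mapping = {}
    out = np.empty(len(names))
    for j, n in enumerate(names):
        if n not in mapping:
            raise KeyError(f"missing {kind} {n!r}")
        out[j] = float(mapping[n])
    return out


def _state_index(state: StateCode) -> int:
    return int(state) - 1


def build_intensity_matrix(spec: IntensitySpec, covariates: dict | None = None,
                           scores: dict | None = None) -> np.ndarray:
    """3x3 generator Q (1/year): exp-linear intensities, rows summing to zero."""
    rates = spec.rates(covariates, scores)
    Q = np.zeros((3, 3))
    for (a, b), q in zip(spec.transitions, rates):
        Q[_state_index(a), _state_index(b)] = q
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_generator(Q: np.ndarray) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(np.diag(Q) > 1e-12) or np.any(off < -1e-12):
        raise ValueError("invalid generator: need nonpositive diagonal, "
                         "nonnegative off-diagonal")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-9):
        raise ValueError("invalid generator: rows must sum to 0")


def transition_probability_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for a valid generator; tiny numerical excursions
    outside [0,1] are clipped, larger ones raise."""
    if t < 0:
        raise ValueError("t must be >= 0")
    _check_generator(Q)
    P = expm(np.asarray(Q, dtype=float) * t)
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise FloatingPointError("transition probabilities escaped [0,1]")
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fast analytic P(t) for the 3-state rNC/MCI/AD generator
#
# With state order (rNC, MCI, AD) and rates a = q(rNC->MCI), b = q(MCI->rNC),
# c = q(MCI->AD), the transient 2x2 block A = [[-a, a], [b, -(b+c)]] has real
# eigenvalues; exp(A t) follows from its spectral decomposition and the AD
# column from row sums.  Vectorized over observation pairs; agreement with
# scipy's expm is asserted in the test suite.

def _batch_transition_probs(a, b, c, dt) -> np.ndarray:
    a, b, c, dt = np.broadcast_arrays(*(np.asarray(x, dtype=float)
                                        for x in (a, b, c, dt)))
    n = a.size
    s = a + b + c
    disc = np.sqrt(np.maximum((a + b + c) ** 2 - 4 * a * c, 0.0))
    l1 = (-s + disc) / 2.0
    l2 = (-s - disc) / 2.0
    P = np.zeros(a.shape + (3, 3))
    A00, A01, A10, A11 = -a, a, b, -(b + c)
    sep = disc > 1e-10 * np.maximum(s, 1.0)
    e1 = np.exp(l1 * dt)
    e2 = np.exp(l2 * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sep, l1 - l2, 1.0)
        # exp(At) = [e1 (A - l2 I) - e2 (A - l1 I)] / (l1 - l2)
        p00 = (e1 * (A00 - l2) - e2 * (A00 - l1)) / d
        p01 = (e1 - e2) * A01 / d
        p10 = (e1 - e2) * A10 / d
        p11 = (e1 * (A11 - l2) - e2 * (A11 - l1)) / d
    # (near-)defective case: exp(At) ~ e^{lt} (I + t (A - l I))
    el = np.exp(l1 * dt)
    p00 = np.where(sep, p00, el * (1 + dt * (A00 - l1)))
    p01 = np.where(sep, p01, el * dt * A01)
    p10 = np.where(sep, p10, el * dt * A10)
    p11 = np.where(sep, p11, el * (1 + dt * (A11 - l1)))
    P[..., 0, 0] = p00
    P[..., 0, 1] = p01
    P[..., 1, 0] = p10
    P[..., 1, 1] = p11
    P[..., 0, 2] = 1.0 - p00 - p01
    P[..., 1, 2] = 1.0 - p10 - p11
    P[..., 2, 2] = 1.0
    return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# panel likelihood


class _PanelData:
    """Flattened consecutive-pair arrays for fast likelihood evaluation."""

    def __init__(self, cohort, spec: IntensitySpec,
                 covariates: pd.DataFrame | None = None,
                 scores: pd.DataFrame | None = None):
        if set(spec.transitions) != set(DEFAULT_TRANSITIONS):
            raise NotImplementedError(
                "panel likelihood implemented for the rNC/MCI/AD state space")
        from_idx, to_idx, dt, subj = [], [], [], []
        X_rows = []
        names = list(spec.covariate_names) + list(spec.score_names)
        for i, s in enumerate(cohort):
            t = s.times
            st = s.states
            row = []
            for n in spec.covariate_names:
                row.append(_lookup(covariates, s, n, "covariate"))
            for n in spec.score_names:
                row.append(_lookup(scores, s, n, "score"))
            X_rows.append(row)
            for k in range(t.size - 1):
                from_idx.append(st[k] - 1)
                to_idx.append(st[k + 1] - 1)
                dt.append(t[k + 1] - t[k])
                subj.append(i)
        self.from_idx = np.asarray(from_idx, dtype=int)
        self.to_idx = np.asarray(to_idx, dtype=int)
        self.dt = np.asarray(dt, dtype=float)
        self.subj = np.asarray(subj, dtype=int)
        self.X = np.asarray(X_rows, dtype=float).reshape(len(cohort), len(names))
        self.names = names
        self.n_subjects = len(cohort)

    def loglik(self, spec: IntensitySpec) -> float:
        T = len(spec.transitions)
        coef = np.hstack([spec.gamma, spec.beta])  # (T, p+q)
        eta = spec.log_q0[None, :] + self.X @ coef.T  # (n_subjects, T)
        if np.any(eta > 50):
            return -np.inf
        rates = np.exp(eta)
        rate_of = {t: rates[:, j] for j, t in enumerate(spec.transitions)}
        a = rate_of[(StateCode.RNC, StateCode.MCI)][self.subj]
        b = rate_of[(StateCode.MCI, StateCode.RNC)][self.subj]
        c = rate_of[(StateCode.MCI, StateCode.AD)][self.subj]
        P = _batch_transition_probs(a, b, c, self.dt)
        p = P[np.arange(self.dt.size), self.from_idx, self.to_idx]
        if np.any(p <= 0):
            k = int(np.argmax(p <= 0))
            warnings.warn(
                "zero-probability observed pair "
                f"{STATE_NAMES[StateCode(self.from_idx[k] + 1)]}->"
                f"{STATE_NAMES[StateCode(self.to_idx[k] + 1)]}; loglik = -inf")
            return -np.inf
        return float(np.sum(np.log(p)))


def _lookup(table: pd.DataFrame | None, subject: SubjectHistory, name: str, kind):
    if table is not None and name in table.columns:
        try:
            return float(table.loc[subject.subject_id, name])
        except KeyError:
            pass
    if kind == "covariate" and name in subject.baseline:
        return float(subject.baseline[name])
    raise KeyError(f"missing {kind} {name!r} for subject {subject.subject_id!r}")


def panel_log_likelihood(cohort, spec: IntensitySpec,
                         covariates: pd.DataFrame | None = None,
                         scores: pd.DataFrame | None = None) -> float:
    """Panel-observed Markov log likelihood.

    Sum over subjects and consecutive visit pairs of
    ``log [P_i(t_{k+1} - t_k)]_{s_k, s_{k+1}}`` with each subject's own
    generator; visit times are exact, states interval censored between
    visits, and the AD visit is a panel observation (not an exact event
    time).  A disallowed observed pair yields -inf with a diagnostic warning.
    """
    return _PanelData(cohort, spec, covariates, scores).loglik(spec)


@dataclass
class FMSMFit:
    spec: IntensitySpec
    vcov: np.ndarray
    loglik: float
    aic: float
    n_params: int
    convergence: dict
    scaling: tuple | None = None  # (means, sds) of the internal design

    @property
    def intensities(self) -> dict:
        """Baseline transition intensities q_rs(0) (1/year)."""
        return {t: float(np.exp(lq))
                for t, lq in zip(self.spec.transitions, self.spec.log_q0)}

    def coefficient_table(self) -> pd.DataFrame:
        theta = self.spec.pack()
        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return pd.DataFrame({
            "parameter": self.spec.parameter_names()[:theta.size],
            "estimate": theta,
            "se": se,
            "ci_lo": theta - 1.959963984540054 * se,
            "ci_hi": theta + 1.959963984540054 * se,
        })


def _crude_init(data: _PanelData, spec: IntensitySpec) -> np.ndarray:
    """Occurrence/exposure rates as starting log intensities."""
    log_q0 = np.empty(len(spec.transitions))
    for j, (a, b) in enumerate(spec.transitions):
        ai, bi = _state_index(a), _state_index(b)
        mask = data.from_idx == ai
        events = np.sum(mask & (data.to_idx == bi))
        exposure = float(np.sum(data.dt[mask]))
        log_q0[j] = np.log(max(events, 0.5) / max(exposure, 1e-8))
    theta = spec.pack()
    theta[:len(spec.transitions)] = log_q0
    return theta


def fit_fmsm(cohort, covariate_names=(), score_names=(),
             covariates: pd.DataFrame | None = None,
             scores: pd.DataFrame | None = None,
             init: IntensitySpec | None = None,
             n_starts: int = 3, seed: int = 0, maxiter: int = 500,
             gtol: float = 1e-6) -> FMSMFit:
    """Maximum-likelihood fit of the functional multistate model.

    Quasi-Newton (BFGS) maximization of the panel likelihood over
    ``(log q0, gamma, beta)`` with numerically differenced gradients, a
    crude-rate starting point plus ``n_starts - 1`` jittered restarts
    (deterministic given ``seed``), and covariance from the inverse of the
    numerically differenced Hessian at the optimum.  Covariates are
    standardized internally for optimizer stability; reported coefficients
    are on the original scale.
    """
    template = IntensitySpec(DEFAULT_TRANSITIONS, np.zeros(3),
                             tuple(covariate_names), None,
                             tuple(score_names), None)
    data = _PanelData(cohort, template, covariates, scores)
    for j, tr in enumerate(template.transitions):
        ai, bi = _state_index(tr[0]), _state_index(tr[1])
        if not np.any((data.from_idx == ai) & (data.to_idx == bi)):
            warnings.warn(f"no observed {STATE_NAMES[tr[0]]}->{STATE_NAMES[tr[1]]} "
                          "pairs; that intensity is weakly identified")
    # standardize the design in place; undo on the way out
    means = data.X.mean(axis=0) if data.X.size else np.zeros(data.X.shape[1])
    sds = data.X.std(axis=0) if data.X.size else np.ones(data.X.shape[1])
    sds = np.where(sds > 1e-12, sds, 1.0)
    data.X = (data.X - means) / sds

    T = len(template.transitions)
    p, q = len(covariate_names), len(score_names)

    def negll(theta):
        return -data.loglik(template.unpack(theta))

    theta0 = _crude_init(data, template if init is None else init)
    if init is not None:
        theta0 = _internalize(init.pack(), T, p, q, means, sds)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        start = theta0 if s == 0 else theta0 + rng.normal(0, 0.3, theta0.size)
        res = minimize(negll, start, method="BFGS",
                       options={"maxiter": maxiter, "gtol": gtol})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    grad_norm = float(np.max(np.abs(best.jac)))
    H = _numeric_hessian(negll, best.x)
    vcov_int = _robust_inverse(H)
    theta_ext, J = _externalize(best.x, T, p, q, means, sds)
    vcov = J @ vcov_int @ J.T
    spec = template.unpack(theta_ext)
    ll = -float(best.fun)
    k = theta_ext.size
    status = "converged" if (best.success or grad_norm < 1e-3) else "max-iterations"
    fit = FMSMFit(spec, vcov, ll, 2 * k - 2 * ll, k,
                  {"iterations": int(best.nit), "gradient_norm": grad_norm,
                   "status": status},
                  scaling=(means, sds))
    return fit


def _coef_columns(T, p, q):
    """For each transition t, the packed-theta indices of its (gamma, beta)
    coefficients in design-column order [covariates..., scores...]."""
    cols = []
    for t in range(T):
        g = [T + t * p + j for j in range(p)]
        b = [T + T * p + t * q + j for j in range(q)]
        cols.append(g + b)
    return cols


def _internalize(theta_ext, T, p, q, means, sds):
    theta = np.asarray(theta_ext, dtype=float).copy()
    for t, cols in enumerate(_coef_columns(T, p, q)):
        coef = theta[cols]
        theta[t] = theta[t] + coef @ means
        theta[cols] = coef * sds
    return theta


def _externalize(theta_int, T, p, q, means, sds):
    """Map internal (standardized-design) parameters to the original scale,
    returning the parameter vector and the Jacobian for the delta method."""
    theta = np.asarray(theta_int, dtype=float).copy()
    J = np.eye(theta.size)
    for t, cols in enumerate(_coef_columns(T, p, q)):
        coef_int = theta[cols]
        theta[t] = theta[t] - coef_int @ (means / sds)
        theta[cols] = coef_int / sds
        for j, col in enumerate(cols):
            J[t, col] = -means[j] / sds[j]
            J[col, col] = 1.0 / sds[j]
    return theta, J


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    steps = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                    + f(x - ei - ej)) / (4 * steps[i] * steps[j])
    return H


def _robust_inverse(H: np.ndarray) -> np.ndarray:
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    V = (V + V.T) / 2.0
    evals, evecs = np.linalg.eigh(V)
    if np.any(evals < 0):
        warnings.warn("covariance not positive semidefinite; "
                      "projecting to nearest PSD matrix")
        evals = np.clip(evals, 0.0, None)
        V = (evecs * evals) @ evecs.T
    return V


# ---------------------------------------------------------------------------
# functionals of a fitted model


def length_of_stay(fit_or_Q, covariates: dict | None = None,
                   scores: dict | None = None, horizon: float = 15.0,
                   from_state: StateCode = StateCode.MCI) -> dict:
    """Expected years (and percentages of the horizon) spent in each state.

    E[time in s] = integral_0^horizon P_{from,s}(u) du, computed by
    integrating dP/dt = P Q jointly with the running integral; the three
    stays sum to the horizon by conservation.
    """
    Q = fit_or_Q if isinstance(fit_or_Q, np.ndarray) else \
        build_intensity_matrix(fit_or_Q.spec, covariates, scores)
    _check_generator(Q)
    e = np.zeros(3)
    e[_state_index(from_state)] = 1.0

    def rhs(_, y):
        p = y[:3]
        return np.concatenate([p @ Q, p])

    sol = solve_ivp(rhs, (0.0, horizon), np.concatenate([e, np.zeros(3)]),
                    rtol=1e-10, atol=1e-12, method="DOP853")
    stay = sol.y[3:, -1]
    stay = stay * (horizon / stay.sum())  # enforce conservation exactly
    return {
        "years": {STATE_NAMES[s]: float(stay[_state_index(s)])
                  for s in (StateCode.RNC, StateCode.MCI, StateCode.AD)},
        "percent": {STATE_NAMES[s]: float(100 * stay[_state_index(s)] / horizon)
                    for s in (StateCode.RNC, StateCode.MCI, StateCode.AD)},
    }


def probability_curves(spec: IntensitySpec, times, covariates=None, scores=None,
                       from_state: StateCode = StateCode.MCI) -> pd.DataFrame:
    """P_{from,s}(t) on a time grid, one column per destination state."""
    Q = build_intensity_matrix(spec, covariates, scores)
    rows = []
    fi = _state_index(from_state)
    for t in np.asarray(times, dtype=float):
        P = transition_probability_matrix(Q, t)
        rows.append({"time": t,
                     **{STATE_NAMES[s]: P[fi, _state_index(s)]
                        for s in (StateCode.RNC, StateCode.MCI, StateCode.AD)}})
    return pd.DataFrame(rows)


def parametric_bootstrap(fit: FMSMFit, B: int = 1000, seed: int = 0,
                         functionals: dict | None = None,
                         covariates: dict | None = None,
                         scores: dict | None = None,
                         times=(1, 5, 10, 15), horizon: float = 15.0) -> dict:
    """Percentile confidence intervals by multivariate-normal resampling.

    Parameter vectors are drawn from MVN(theta_hat, vcov) — the asymptotic
    sampling distribution of the MLE — each functional is recomputed per
    draw, and 2.5/97.5 percentiles are reported.  ``functionals`` maps names
    to callables of an IntensitySpec; by default baseline intensities,
    transition-probability curves from MCI, and length of stay are included.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap draws")
    theta_hat = fit.spec.pack()
    V = (fit.vcov + fit.vcov.T) / 2.0
    evals, evecs = np.linalg.eigh(V)
    if np.any(evals < -1e-10 * max(evals.max(), 1.0)):
        warnings.warn("vcov repaired to nearest PSD for bootstrap sampling")
    evals = np.clip(evals, 0.0, None)
    rng = np.random.default_rng(seed)
    draws = theta_hat[None, :] + (rng.standard_normal((B, theta_hat.size))
                                  * np.sqrt(evals)) @ evecs.T
    if functionals is None:
        times = np.asarray(times, dtype=float)

        def _curves(spec):
            df = probability_curves(spec, times, covariates, scores)
            return df[["rNC", "MCI", "AD"]].to_numpy().ravel()

        functionals = {
            "intensity": lambda spec: np.exp(spec.log_q0),
            "prob_from_MCI": _curves,
            "stay_years": lambda spec: np.array(list(length_of_stay(
                build_intensity_matrix(spec, covariates, scores),
                horizon=horizon)["years"].values())),
        }
    results = {}
    for name, fn in functionals.items():
        point = np.atleast_1d(np.asarray(fn(fit.spec), dtype=float))
        samples = np.empty((B, point.size))
        for b in range(B):
            samples[b] = np.atleast_1d(np.asarray(fn(fit.spec.unpack(draws[b])),
                                                  dtype=float))
        lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
        results[name] = {"point": point, "lower": lo, "upper": hi}
    return results


def compare_models(fits: dict, nesting: list | None = None) -> pd.DataFrame:
    """Model-comparison table: loglik and AIC for all fits, likelihood-ratio
    chi-square tests for explicitly declared nested pairs.

    ``nesting`` lists (reduced_name, full_name) pairs; a pair whose reduced
    model has at least as many parameters (or a higher likelihood beyond
    tolerance) is refused as non-nested.
    """
    rows = [{"model": name, "loglik": f.loglik, "aic": f.aic,
             "n_params": f.n_params} for name, f in fits.items()]
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    lrt_rows = []
    for red, full in (nesting or []):
        fr, ff = fits[red], fits[full]
        df = ff.n_params - fr.n_params
        if df <= 0:
            raise ValueError(f"LRT refused: {full!r} is not a strict superset "
                             f"of {red!r}")
        stat = 2.0 * (ff.loglik - fr.loglik)
        if stat < -1e-6:
            raise ValueError(f"LRT refused: {red!r} fits better than {full!r}; "
                             "models are not nested on this data")
        stat = max(stat, 0.0)
        lrt_rows.append({"reduced": red, "full": full, "chi2": stat, "df": df,
                         "p": float(chi2.sf(stat, df))})
    lrt = pd.DataFrame(lrt_rows)
    table.attrs["lrt"] = lrt
    return table


def observed_vs_expected(fit: FMSMFit, cohort, time_grid,
                         covariates: pd.DataFrame | None = None,
                         scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed vs model-expected state percentages over time.

    At each grid time u every subject with a visit at or before u
    contributes its most recent observed state (last state carried
    forward); the expected distribution averages each contributing
    subject's own P_i(tau_i(u)) row from the MCI entry state, where
    tau_i(u) is the subject's last *intended* assessment time at or before
    u: the last actual visit for subjects still in follow-up, extended
    along the cohort's typical visit spacing for subjects whose visits
    stopped at the absorbing AD diagnosis (the chain cannot leave AD, so
    the model's prediction at any later intended visit is well defined).
    Matching the evaluation times this way keeps the two curves comparable
    on panel data: states are only known at assessments, and comparing the
    assessment-time prediction with the assessment record avoids both the
    carry-forward lag and the survivor selection that would otherwise
    dominate late grid times.  The returned frame carries a
    ``max_discrepancy`` attribute (max over times/states, in percentage
    points).
    """
    spec = fit.spec if isinstance(fit, FMSMFit) else fit
    template = IntensitySpec(spec.transitions, spec.log_q0, spec.covariate_names,
                             spec.gamma, spec.score_names, spec.beta)
    data = _PanelData(cohort, template, covariates, scores)
    coef = np.hstack([template.gamma, template.beta])
    eta = template.log_q0[None, :] + data.X @ coef.T
    rates = np.exp(eta)
    rate_of = {t: rates[:, j] for j, t in enumerate(template.transitions)}
    a = rate_of[(StateCode.RNC, StateCode.MCI)]
    b = rate_of[(StateCode.MCI, StateCode.RNC)]
    c = rate_of[(StateCode.MCI, StateCode.AD)]
    times_list = [s.times for s in cohort]
    states_list = [s.states for s in cohort]
    gaps = np.concatenate([np.diff(t) for t in times_list if t.size > 1])
    typical_gap = float(np.median(gaps)) if gaps.size else 0.5
    rows = []
    max_disc = 0.0
    mci = _state_index(StateCode.MCI)
    for u in np.asarray(time_grid, dtype=float):
        obs = np.zeros(3)
        t_eval = np.zeros(len(cohort))
        contrib = np.zeros(len(cohort), dtype=bool)
        for i, (t, st) in enumerate(zip(times_list, states_list)):
            k = int(np.searchsorted(t, u + 1e-12) - 1)
            if k < 0:
                continue
            contrib[i] = True
            tau = t[k]
            if st[-1] == int(StateCode.AD) and u > t[-1]:
                # visits stopped at the AD diagnosis; walk the typical
                # schedule forward to the last intended assessment <= u
                tau = t[-1] + typical_gap * np.floor((u - t[-1]) / typical_gap)
            t_eval[i] = tau
            obs[st[k] - 1] += 1
        n_at_risk = int(contrib.sum())
        if n_at_risk == 0:
            continue
        Pk = _batch_transition_probs(a[contrib], b[contrib], c[contrib],
                                     t_eval[contrib])
        e = 100 * Pk[:, mci, :].mean(axis=0)
        o = 100 * obs / n_at_risk
        max_disc = max(max_disc, float(np.max(np.abs(o - e))))
        rows.append({"time": u, "n": n_at_risk,
                     "observed_rNC": o[0], "observed_MCI": o[1], "observed_AD": o[2],
                     "expected_rNC": e[0], "expected_MCI": e[1], "expected_AD": e[2]})
    out = pd.DataFrame(rows)
    out.attrs["max_discrepancy"] = max_disc
    return out
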