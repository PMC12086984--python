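"""Seedable synthetic-cohort simulator.

Generates cohorts with the statistical structure the functional multistate
model assumes, so every estimator in the package can be exercised and its
parameter recovery measured without access to the restricted source data:

* continuous-time Markov state paths (Gillespie simulation) starting in MCI
  with AD absorbing, intensities on the reported scale
  (q(MCI->rNC)=0.035, q(rNC->MCI)=0.117, q(MCI->AD)=0.120 per year);
* irregular panel observation: first visit at entry, inter-visit gaps drawn
  from a truncated Gamma around 0.75 y, visits until AD or the horizon by
  default; optional independent exponential censoring (``followup_median``)
  reproduces the short, skewed follow-up of observational cohorts (every
  subject keeps at least two visits);
* multivariate longitudinal markers built from a low-rank joint eigenbasis
  shared across the 11 scales, observed sparsely with noise;
* multilevel 116-region gray-matter density profiles with subject-level and
  visit-level eigenfunctions controlling the between/within variance split.

Ground truth (paths, scores, parameters) is returned next to the cohort so
recovery studies can score the estimators.  Randomness uses numpy's
PCG64-backed default_rng throughout; a fixed seed reproduces the cohort
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import StateCode, SubjectHistory, VisitRecord, N_REGIONS
from .fpca import FunctionGrid, FunctionalSample
from .msm import IntensitySpec, build_intensity_matrix, DEFAULT_TRANSITIONS

__all__ = [
    "MarkerModel",
    "RegionModel",
    "SimConfig",
    "default_intensity_spec",
    "simulate_trajectory",
    "panel_observe",
    "simulate_markers",
    "simulate_regions",
    "generate_cohort",
    "simulate_sparse_functional",
]

MARKER_NAMES = (
    "ADAS11", "ADAS13", "ADASQ4", "RAVLT_immediate", "RAVLT_learning",
    "RAVLT_forgetting", "RAVLT_perc_forgetting", "TMTB", "FAQ",
    "mPACCdigit", "mPACCtrailsB",
)


def default_intensity_spec(covariate_names=(), score_names=(), gamma=None,
                           beta=None) -> IntensitySpec:
    """Intensities on the reported scale: MCI->rNC 0.035, MCI->AD 0.120,
    rNC->MCI 0.117 per year."""
    return IntensitySpec(
        DEFAULT_TRANSITIONS,
        np.log([0.035, 0.120, 0.117]),
        tuple(covariate_names), gamma, tuple(score_names), beta)


def _orthonormal_cosines(grid: FunctionGrid, ks) -> np.ndarray:
    """Cosine system orthonormal under the grid's quadrature weights."""
    a, b = grid.points[0], grid.points[-1]
    L = b - a
    fns = []
    for k in ks:
        if k == 0:
            f = np.ones(grid.size)
        else:
            f = np.cos(np.pi * k * (grid.points - a) / L)
        f = f / np.sqrt(grid.inner(f, f))
        fns.append(f)
    return np.asarray(fns)


@dataclass
class MarkerModel:
    """Joint low-rank generator for the 11 neuropsychological scales.

    Marker p for subject i at time t is
        mu_p(t) + sum_m rho_im * sum_k loadings[m,p,k] f_k(t) + noise,
    with shared basis functions f_k orthonormal on the grid, joint scores
    rho_im ~ N(0, joint_eigenvalues[m]) and loading rows orthonormal over
    (p, k), so the joint components are the latent principal directions and
    the joint eigenvalue shares are the target PVEs.
    """

    grid: FunctionGrid
    names: tuple
    means: np.ndarray  # (P, G)
    basis: np.ndarray  # (Kb, G) orthonormal under quadrature
    loadings: np.ndarray  # (M, P, Kb), rows orthonormal when flattened
    joint_eigenvalues: np.ndarray  # (M,)
    noise_sd: float = 0.5
    missing_rate: float = 0.1

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls, horizon: float = 15.0, total_variance: float = 22.0,
                pve=(0.7247, 0.1831, 0.06, 0.0322), noise_sd: float = 0.5,
                missing_rate: float = 0.1, basis_seed: int = 12345
                ) -> "MarkerModel":
        """Four joint components with a 72.47/18.31/6/3.22 variance split
        (the leading shares on the scale reported for the source cohort)."""
        grid = FunctionGrid.regular(0.0, horizon, 61)
        basis = _orthonormal_cosines(grid, (0, 1))
        P, Kb, M = len(MARKER_NAMES), basis.shape[0], len(pve)
        rng = np.random.default_rng(basis_seed)
        A = rng.standard_normal((P * Kb, P * Kb))
        Qmat, _ = np.linalg.qr(A)
        loadings = Qmat[:, :M].T.reshape(M, P, Kb)
        t = grid.points
        means = np.array([10.0 + 0.5 * p + (0.3 + 0.05 * p) * t
                          for p in range(P)])
        lam = total_variance * np.asarray(pve, dtype=float)
        return cls(grid, MARKER_NAMES, means, basis, loadings, lam,
                   noise_sd, missing_rate)

    @classmethod
    def univariate(cls, eigenvalues=(4.0, 1.0), noise_sd: float = 0.5,
                   horizon: float = 15.0, name: str = "marker",
                   mean_fn=None) -> "MarkerModel":
        """Single marker whose own eigenfunctions are the basis functions."""
        grid = FunctionGrid.regular(0.0, horizon, 61)
        K = len(eigenvalues)
        basis = _orthonormal_cosines(grid, range(K))
        loadings = np.zeros((K, 1, K))
        for k in range(K):
            loadings[k, 0, k] = 1.0
        mean = (np.zeros(grid.size) if mean_fn is None
                else np.asarray(mean_fn(grid.points), dtype=float))
        return cls(grid, (name,), mean[None, :], basis, loadings,
                   np.asarray(eigenvalues, dtype=float), noise_sd, 0.0)


@dataclass
class RegionModel:
    """Two-level generator for 116-region gray-matter density profiles.

    Y_ij(s) = mu(s) + sum_k xi_ik phi1_k(s) + sum_l zeta_ijl phi2_l(s) + eps,
    with subject scores xi (level 1) and visit scores zeta (level 2);
    the between-subject variance share is
    rho = sum(level1_values) / (sum(level1_values) + sum(level2_values)).
    """

    grid: FunctionGrid
    mean: np.ndarray
    level1_fns: np.ndarray  # (K1, G), Euclidean-orthonormal
    level1_values: np.ndarray
    level2_fns: np.ndarray  # (K2, G)
    level2_values: np.ndarray
    noise_sd: float = 0.02

    @property
    def rho(self) -> float:
        s1 = float(np.sum(self.level1_values))
        s2 = float(np.sum(self.level2_values))
        return s1 / (s1 + s2) if (s1 + s2) > 0 else np.nan

    @classmethod
    def default(cls, rho: float = 0.6, total_variance: float = 0.5,
                noise_sd: float = 0.02) -> "RegionModel":
        grid = FunctionGrid.indexed(N_REGIONS)
        s = grid.points
        mean = (100.0 / N_REGIONS) * (1.0 + 0.3 * np.sin(2 * np.pi * s / N_REGIONS))
        fns = _orthonormal_cosines(grid, (1, 2, 3, 4))
        lam1 = rho * total_variance * np.array([0.7, 0.3])
        lam2 = (1 - rho) * total_variance * np.array([0.7, 0.3])
        return cls(grid, mean, fns[:2], lam1, fns[2:], lam2, noise_sd)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    n_subjects: int = 300
    horizon: float = 15.0
    visit_gap_mean: float = 0.75
    visit_gap_shape: float = 9.0  # Gamma shape; sd = mean/sqrt(shape) = 0.25 y
    visit_gap_bounds: tuple = (0.25, 2.0)
    followup_median: float | None = None  # exponential censoring; None = none
    intensity: IntensitySpec = field(default_factory=default_intensity_spec)
    markers: MarkerModel | None = None
    regions: RegionModel | None = None
    informative_dropout: float = 0.0  # extra log-hazard of censoring per sd
    # of the first joint marker score; 0 disables (the default)
    seed: int = 0

    def with_markers(self, **kwargs) -> "SimConfig":
        return replace(self, markers=MarkerModel.default(horizon=self.horizon,
                                                         **kwargs))

    def with_regions(self, **kwargs) -> "SimConfig":
        return replace(self, regions=RegionModel.default(**kwargs))


def _draw_covariates(rng) -> dict:
    return {
        "age": float(np.clip(rng.normal(73.0, 7.0), 55.0, 92.0)),
        "sex": float(rng.integers(0, 2)),
        "education": float(np.clip(np.round(rng.normal(16.0, 2.7)), 6, 20)),
        "married": float(rng.random() < 0.75),
        "apoe4": float(rng.random() < 0.45),
    }


def simulate_trajectory(Q: np.ndarray, horizon: float, rng,
                        start: StateCode = StateCode.MCI) -> list:
    """Exact (Gillespie) simulation of the continuous-time chain.

    Returns [(entry_time, state), ...]; holding times are exponential with
    rate -q_rr and the destination is drawn proportionally to q_rs.  Stops
    at AD or at the horizon.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite transition rate in generator")
    path = [(0.0, start)]
    t, state = 0.0, start
    while t < horizon and state != StateCode.AD:
        i = int(state) - 1
        rate = -Q[i, i]
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = np.clip(Q[i], 0.0, None)
        probs[i] = 0.0
        dest = rng.choice(3, p=probs / probs.sum()) + 1
        state = StateCode(dest)
        path.append((t, state))
    return path


def panel_observe(path: list, visit_times) -> list:
    """State of a continuous path at each visit; visits after the first
    AD-observed visit are dropped (the cohort truncation rule)."""
    visit_times = np.asarray(visit_times, dtype=float)
    entry = np.array([p[0] for p in path])
    states = [p[1] for p in path]
    out = []
    for t in visit_times:
        k = int(np.searchsorted(entry, t + 1e-12) - 1)
        s = states[max(k, 0)]
        out.append((float(t), s))
        if s == StateCode.AD:
            break
    return out


def _visit_schedule(config: SimConfig, rng) -> np.ndarray:
    times = [0.0]
    while times[-1] < config.horizon:
        gap = rng.gamma(config.visit_gap_shape,
                        config.visit_gap_mean / config.visit_gap_shape)
        gap = float(np.clip(gap, *config.visit_gap_bounds))
        times.append(times[-1] + gap)
    times = np.asarray(times)
    return times[times <= config.horizon]


def simulate_markers(model: MarkerModel, joint_scores: np.ndarray,
                     visit_times, rng) -> dict:
    """Sparse marker observations at the subject's visit times.

    Returns {name: (times, values)} after missingness thinning; a visit
    time outside the model grid raises.
    """
    visit_times = np.asarray(visit_times, dtype=float)
    lo, hi = model.grid.points[0], model.grid.points[-1]
    if np.any(visit_times < lo - 1e-9) or np.any(visit_times > hi + 1e-9):
        raise ValueError("visit time outside the marker model grid")
    Bt = np.column_stack([np.interp(visit_times, model.grid.points, f)
                          for f in model.basis])  # (m, Kb)
    out = {}
    for p, name in enumerate(model.names):
        mu = np.interp(visit_times, model.grid.points, model.means[p])
        coefs = joint_scores @ model.loadings[:, p, :]  # (Kb,)
        vals = mu + Bt @ coefs
        vals = vals + rng.normal(0.0, model.noise_sd, vals.shape)
        keep = rng.random(vals.shape) >= model.missing_rate
        out[name] = (visit_times[keep], vals[keep])
    return out


def simulate_regions(model: RegionModel, subject_scores: np.ndarray,
                     n_visits: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-visit 116-point profiles; returns (profiles (J, G), visit scores)."""
    zeta = rng.normal(0.0, np.sqrt(model.level2_values),
                      size=(n_visits, model.level2_values.size))
    profiles = (model.mean[None, :]
                + subject_scores @ model.level1_fns
                + zeta @ model.level2_fns
                + rng.normal(0.0, model.noise_sd, (n_visits, model.grid.size)))
    return profiles, zeta


def generate_cohort(config: SimConfig, seed: int | None = None
                    ) -> tuple[list, dict]:
    """Compose the full simulator; returns (subjects, truth).

    ``truth`` records the continuous paths, joint marker scores, subject
    region scores and the generating parameters for recovery studies.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subjects = []
    truth = {
        "config": config,
        "paths": {}, "joint_scores": {}, "region_subject_scores": {},
        "region_visit_scores": {}, "covariates": {},
    }
    M = (config.markers.joint_eigenvalues.size if config.markers is not None
         else len(config.intensity.score_names))
    score_names = tuple(config.intensity.score_names)
    for i in range(config.n_subjects):
        sid = f"S{i:05d}"
        cov = _draw_covariates(rng)
        rho = (rng.normal(0.0, np.sqrt(config.markers.joint_eigenvalues))
               if config.markers is not None else
               rng.standard_normal(max(M, 1)))
        score_map = {name: float(rho[j]) for j, name in enumerate(score_names)}
        Q = build_intensity_matrix(config.intensity, cov, score_map)
        path = simulate_trajectory(Q, config.horizon, rng)
        visits = _visit_schedule(config, rng)
        if config.followup_median is not None:
            rate = np.log(2.0) / config.followup_median
            if config.informative_dropout and config.markers is not None:
                z1 = rho[0] / np.sqrt(config.markers.joint_eigenvalues[0])
                rate = rate * np.exp(config.informative_dropout * z1)
            censor = rng.exponential(1.0 / rate)
            keep = visits <= max(censor, visits[1] if visits.size > 1 else 0.0)
            visits = visits[keep]
        observed = panel_observe(path, visits)
        obs_times = np.array([t for t, _ in observed])
        marker_obs = {}
        if config.markers is not None:
            marker_obs = simulate_markers(config.markers, rho, obs_times, rng)
        region_profiles = None
        if config.regions is not None:
            xi = rng.normal(0.0, np.sqrt(config.regions.level1_values))
            region_profiles, zeta = simulate_regions(
                config.regions, xi, len(observed), rng)
            truth["region_subject_scores"][sid] = xi
            truth["region_visit_scores"][sid] = zeta
        visit_records = []
        for j, (t, state) in enumerate(observed):
            markers = {}
            for name, (mt, mv) in marker_obs.items():
                hit = np.isclose(mt, t)
                if hit.any():
                    markers[name] = float(mv[np.argmax(hit)])
            regions = region_profiles[j] if region_profiles is not None else None
            visit_records.append(VisitRecord(sid, t, state, markers, regions))
        subjects.append(SubjectHistory(sid, cov, visit_records))
        truth["paths"][sid] = path
        truth["joint_scores"][sid] = rho
        truth["covariates"][sid] = cov
    return subjects, truth


def simulate_sparse_functional(n_subjects: int, eigenvalues, noise_sd: float,
                               mean_fn=None, n_obs_range=(5, 12),
                               domain=(0.0, 15.0), seed: int = 0,
                               grid_size: int = 61):
    """Sparse draws from a K-component Karhunen-Loeve process.

    Each subject gets a uniformly drawn number of observation times placed
    uniformly on the domain; the default 5-12 observations per subject
    emulates intermittent attendance of a 6-monthly-to-annual visit schedule
    over a 15-year window.  Returns (FunctionalSample, true scores (n, K), EigenSystem-like
    truth dict with grid/mean/eigenfunctions/eigenvalues).
    """
    rng = np.random.default_rng(seed)
    lo, hi = domain
    grid = FunctionGrid.regular(lo, hi, grid_size)
    K = len(eigenvalues)
    phi = _orthonormal_cosines(grid, range(K))
    mean = (np.zeros(grid.size) if mean_fn is None
            else np.asarray(mean_fn(grid.points), dtype=float))
    ids, times, values = [], [], []
    scores = rng.normal(0.0, np.sqrt(eigenvalues), size=(n_subjects, K))
    for i in range(n_subjects):
        m = int(rng.integers(n_obs_range[0], n_obs_range[1] + 1))
        t = np.sort(rng.uniform(lo, hi, m))
        mu = np.interp(t, grid.points, mean)
        Phi = np.column_stack([np.interp(t, grid.points, f) for f in phi])
        y = mu + Phi @ scores[i] + rng.normal(0.0, noise_sd, m)
        ids.append(i)
        times.append(t)
        values.append(y)
    truth = {"grid": grid, "mean": mean, "eigenfunctions": phi,
             "eigenvalues": np.asarray(eigenvalues, dtype=float),
             "noise_sd": noise_sd}
    return FunctionalSample(ids, times, values), scores, truth
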