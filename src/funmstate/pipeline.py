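"""End-to-end workflow: scores -> model suite -> comparison tables.

Reproduces the analysis pattern the package is built for as one configured
pipeline: extract MVFPC scores from the neuropsychological scales, spatial
FPC and fMLFPC scores from region profiles, fit the preplanned model suite
(FMSM 0-5 with functional scores, MSM 1-3 with conventional-PCA scores),
and emit comparison tables, probability curves, length-of-stay summaries
and observed-vs-expected assessment data.  Score extraction is computed
once and shared across models; every artifact is a DataFrame/dict, with
optional CSV/JSON persistence.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cio
from .cohort import StateCode
from .fpca import FunctionalSample
from .mlfpca import MultilevelSample, fit_fmlfpca, mlfpc_scores, spatial_fpca_baseline
from .msm import (FMSMFit, compare_models, fit_fmsm, length_of_stay,
                  observed_vs_expected, parametric_bootstrap, probability_curves)
from .mvfpca import fit_mvfpca, mv_scores, pca_baseline_scores
from .simulate import MARKER_NAMES, SimConfig, generate_cohort

logger = logging.getLogger(__name__)

BASELINE_COVARIATES = ("age", "sex", "education", "married", "apoe4")

MODEL_SUITE = ("FMSM0", "FMSM1", "FMSM2", "FMSM3", "FMSM4", "FMSM5",
               "MSM1", "MSM2", "MSM3")

# score sources each model adds on top of the baseline covariates
_MODEL_SOURCES = {
    "FMSM0": (),
    "FMSM1": ("mvfpc",),
    "FMSM2": ("spatial",),
    "FMSM3": ("mlfpc",),
    "FMSM4": ("mvfpc", "spatial"),
    "FMSM5": ("mvfpc", "mlfpc"),
    "MSM1": ("pca_markers",),
    "MSM2": ("pca_regions",),
    "MSM3": ("pca_markers", "pca_regions"),
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    simulate: bool = True
    sim: SimConfig | None = None
    cohort_path: str | None = None
    markers: tuple = MARKER_NAMES
    pve_threshold: float = 0.90
    models: tuple = ("FMSM0", "FMSM1")
    horizon: float = 15.0
    bootstrap_B: int = 0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for m in self.models:
            if m not in MODEL_SUITE:
                raise ValueError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _needs(config: PipelineConfig, source: str) -> bool:
    return any(source in _MODEL_SOURCES[m] for m in config.models)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps({k: repr(v) for k, v in vars(config).items()},
                         sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns an artifact bundle: cohort, transition table, score frames,
    fitted models, comparison table, probability curves, length of stay,
    observed-vs-expected data, and (if requested) bootstrap CIs for the
    best model.  Any stage failure aborts with the stage name; completed
    artifacts stay in the bundle.
    """
    bundle: dict = {"config": config, "config_hash": _config_hash(config)}
    stage = "load"
    try:
        if config.simulate:
            sim = config.sim or SimConfig(seed=config.seed)
            needs_regions = (_needs(config, "mlfpc") or _needs(config, "spatial")
                             or _needs(config, "pca_regions"))
            if sim.markers is None and (_needs(config, "mvfpc")
                                        or _needs(config, "pca_markers")):
                sim = sim.with_markers()
            if sim.regions is None and needs_regions:
                sim = sim.with_regions()
            subjects, truth = generate_cohort(sim, seed=config.seed)
            bundle["truth"] = truth
        else:
            if config.cohort_path is None:
                raise ValueError("cohort_path required when simulate=False")
            subjects, report = cio.read_cohort(config.cohort_path)
            bundle["exclusions"] = report
        subjects, report = cio.validate_and_truncate(subjects)
        bundle["cohort"] = subjects
        bundle["exclusions"] = report
        bundle["transitions"] = cio.count_transitions(subjects)
        bundle["followup"] = cio.summarize_followup(subjects)

        stage = "validate-config"
        have_regions = any(v.regions is not None
                           for s in subjects for v in s.visits)
        for src in ("mlfpc", "spatial", "pca_regions"):
            if _needs(config, src) and not have_regions:
                raise ValueError(
                    f"models {config.models} need region profiles but the "
                    "cohort has none")

        stage = "scores"
        score_frames = {}
        marker_samples = None
        if _needs(config, "mvfpc") or _needs(config, "pca_markers"):
            marker_samples = {
                name: _marker_sample(subjects, name) for name in config.markers}
            marker_samples = {k: v for k, v in marker_samples.items()
                              if v.n_observations > 0}
        if _needs(config, "mvfpc"):
            mv = fit_mvfpca(marker_samples, pve_threshold=config.pve_threshold)
            sm = mv_scores(mv, marker_samples)
            score_frames["mvfpc"] = sm.to_frame("MVFPC")
            bundle["mvfpca"] = mv
        if _needs(config, "pca_markers"):
            sm = pca_baseline_scores(marker_samples,
                                     domain=(0.0, config.horizon))
            score_frames["pca_markers"] = sm.to_frame("PCmark")
        if _needs(config, "spatial") or _needs(config, "pca_regions"):
            ids, base_profiles = _baseline_profiles(subjects)
        if _needs(config, "spatial"):
            eig, sm = spatial_fpca_baseline(base_profiles, ids=ids,
                                            pve_threshold=config.pve_threshold)
            score_frames["spatial"] = sm.to_frame("SFPC")
            bundle["spatial_fpca"] = eig
        if _needs(config, "pca_regions"):
            from sklearn.decomposition import PCA

            X = base_profiles - base_profiles.mean(axis=0)
            pca = PCA(n_components=2, svd_solver="full")
            sc = pca.fit_transform(X)
            score_frames["pca_regions"] = pd.DataFrame(
                sc, index=pd.Index(ids, name="subject_id"),
                columns=["PCreg1", "PCreg2"])
        if _needs(config, "mlfpc"):
            ml_sample = MultilevelSample.from_cohort(subjects)
            fit_ml = fit_fmlfpca(ml_sample, pve_threshold=config.pve_threshold)
            subj_sm, _ = mlfpc_scores(fit_ml, ml_sample)
            score_frames["mlfpc"] = subj_sm.to_frame("MLFPC")
            bundle["mlfpca"] = fit_ml
        bundle["score_frames"] = score_frames

        stage = "fit"
        fits: dict = {}
        for m in config.models:
            frames = [score_frames[src] for src in _MODEL_SOURCES[m]]
            scores = pd.concat(frames, axis=1) if frames else None
            score_names = tuple(scores.columns) if scores is not None else ()
            logger.info("fitting %s (%d score covariates)", m, len(score_names))
            fits[m] = fit_fmsm(subjects, covariate_names=BASELINE_COVARIATES,
                               score_names=score_names, scores=scores,
                               seed=config.seed)
            fits[m].score_frame = scores
        bundle["fits"] = fits

        stage = "compare"
        nesting = [("FMSM0", m) for m in config.models
                   if m != "FMSM0" and "FMSM0" in fits and m.startswith("FMSM")]
        bundle["comparison"] = compare_models(fits, nesting)

        stage = "curves"
        times = np.linspace(0, config.horizon, 61)
        best_name = bundle["comparison"]["model"].iloc[0]
        best = fits[best_name]
        bundle["best_model"] = best_name
        cov0, sc0 = _reference_profile(subjects, best)
        curves = {}
        for origin in (StateCode.MCI, StateCode.RNC):
            curves[cio.STATE_NAMES[origin]] = probability_curves(
                best.spec, times, cov0, sc0, from_state=origin)
        bundle["probability_curves"] = curves
        bundle["length_of_stay"] = length_of_stay(
            best, cov0, sc0, horizon=config.horizon)
        bundle["observed_vs_expected"] = observed_vs_expected(
            best, subjects, np.linspace(0, config.horizon, 16),
            scores=getattr(best, "score_frame", None))

        if config.bootstrap_B >= 2:
            stage = "bootstrap"
            bundle["bootstrap"] = parametric_bootstrap(
                best, B=config.bootstrap_B, seed=config.seed,
                covariates=cov0, scores=sc0, horizon=config.horizon)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    if config.out_dir:
        _persist(bundle, Path(config.out_dir))
    return bundle


def _marker_sample(subjects, name: str) -> FunctionalSample:
    ids, times, values = [], [], []
    for s in subjects:
        t, y = s.marker_series(name)
        if t.size:
            ids.append(s.subject_id)
            times.append(t)
            values.append(y)
    return FunctionalSample(ids, times, values)


def _baseline_profiles(subjects):
    ids, profiles = [], []
    for s in subjects:
        for v in s.visits:
            if v.regions is not None:
                ids.append(s.subject_id)
                profiles.append(v.regions)
                break
    return ids, np.asarray(profiles)


def _reference_profile(subjects, fit: FMSMFit):
    """Cohort-average covariates and zero scores for reference curves."""
    cov = {}
    for name in fit.spec.covariate_names:
        vals = [s.baseline.get(name) for s in subjects if name in s.baseline]
        cov[name] = float(np.mean(vals)) if vals else 0.0
    scores = {name: 0.0 for name in fit.spec.score_names}
    return cov, scores


def report_tables(bundle: dict) -> dict:
    """Text-ready summaries: coefficients per model, transition counts,
    PVE tables per FPCA stage, length of stay."""
    tables: dict = {}
    coef_frames = []
    for name, fit in bundle.get("fits", {}).items():
        tab = fit.coefficient_table()
        tab.insert(0, "model", name)
        coef_frames.append(tab)
    tables["coefficients"] = (pd.concat(coef_frames, ignore_index=True)
                              if coef_frames else
                              pd.DataFrame(columns=["model", "parameter",
                                                    "estimate", "se",
                                                    "ci_lo", "ci_hi"]))
    tables["transitions"] = (bundle["transitions"].to_frame()
                             if "transitions" in bundle else pd.DataFrame())
    pve_rows = []
    if "mvfpca" in bundle:
        mv = bundle["mvfpca"]
        for k, p in enumerate(mv.pve):
            pve_rows.append({"stage": "MVFPCA", "component": k + 1,
                             "pve": 100 * p,
                             "cumulative": 100 * float(np.sum(mv.pve[:k + 1]))})
        for name, eig in mv.univariate.items():
            for k, p in enumerate(eig.pve):
                pve_rows.append({"stage": f"FPCA:{name}", "component": k + 1,
                                 "pve": 100 * p,
                                 "cumulative": 100 * float(np.sum(eig.pve[:k + 1]))})
    if "spatial_fpca" in bundle:
        eig = bundle["spatial_fpca"]
        for k, p in enumerate(eig.pve):
            pve_rows.append({"stage": "spatialFPCA", "component": k + 1,
                             "pve": 100 * p,
                             "cumulative": 100 * float(np.sum(eig.pve[:k + 1]))})
    if "mlfpca" in bundle:
        ml = bundle["mlfpca"]
        for label, eig in (("fMLFPCA:level1", ml.level1),
                           ("fMLFPCA:level2", ml.level2)):
            for k, p in enumerate(eig.pve):
                pve_rows.append({"stage": label, "component": k + 1,
                                 "pve": 100 * p,
                                 "cumulative": 100 * float(np.sum(eig.pve[:k + 1]))})
    tables["pve"] = pd.DataFrame(pve_rows,
                                 columns=["stage", "component", "pve",
                                          "cumulative"])
    if "length_of_stay" in bundle:
        los = bundle["length_of_stay"]
        tables["length_of_stay"] = pd.DataFrame({
            "state": list(los["years"]),
            "years": list(los["years"].values()),
            "percent": list(los["percent"].values()),
        })
    if "comparison" in bundle:
        tables["comparison"] = bundle["comparison"]
    return tables


def _persist(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = report_tables(bundle)
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out_dir / f"{name}.csv", index=False)
    if "comparison" in bundle:
        lrt = bundle["comparison"].attrs.get("lrt")
        if lrt is not None and len(lrt):
            lrt.to_csv(out_dir / "lrt.csv", index=False)
    for origin, df in bundle.get("probability_curves", {}).items():
        df.to_csv(out_dir / f"probability_from_{origin}.csv", index=False)
    if "observed_vs_expected" in bundle:
        bundle["observed_vs_expected"].to_csv(
            out_dir / "observed_vs_expected.csv", index=False)
    if "exclusions" in bundle:
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump(bundle["exclusions"].to_dict(), fh, indent=2)
    meta = {"config_hash": bundle["config_hash"],
            "best_model": bundle.get("best_model")}
    with open(out_dir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)
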