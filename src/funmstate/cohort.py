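"""Panel-observed cohort data model, readers, validation, transition counts.

A cohort is a list of subjects enrolled in a transient cognitive state (MCI)
and reassessed at irregular visit times; states are MCI, rNC (reverted to
normal cognition after an MCI diagnosis) and AD, with AD absorbing.  The
inclusion rules are: MCI at study entry, at least two visits, and no
observations after the first AD diagnosis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_REGIONS = 116
REGION_COLUMNS = [f"region_{i:03d}" for i in range(1, N_REGIONS + 1)]
BASELINE_FIELDS = ("age", "sex", "education", "married", "apoe4")


class StateCode(IntEnum):
    """Cognitive states: rNC and MCI transient, AD absorbing."""

    RNC = 1
    MCI = 2
    AD = 3


_STATE_LABELS = {
    "NC": StateCode.RNC, "RNC": StateCode.RNC,
    "MCI": StateCode.MCI,
    "AD": StateCode.AD, "DEMENTIA": StateCode.AD,
    "1": StateCode.RNC, "2": StateCode.MCI, "3": StateCode.AD,
}

STATE_NAMES = {StateCode.RNC: "rNC", StateCode.MCI: "MCI", StateCode.AD: "AD"}


def parse_state(label) -> StateCode:
    key = str(label).strip().upper()
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _STATE_LABELS:
        raise ValueError(f"unrecognized cognitive state label: {label!r}")
    return _STATE_LABELS[key]


@dataclass
class VisitRecord:
    subject_id: object
    time: float  # years since entry
    state: StateCode
    markers: dict = field(default_factory=dict)
    regions: np.ndarray | None = None

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("visit time must be >= 0")
        if self.regions is not None:
            r = np.asarray(self.regions, dtype=float)
            if r.shape != (N_REGIONS,):
                raise ValueError(f"region vector must have {N_REGIONS} entries")
            if np.any(r < 0):
                raise ValueError("region densities must be nonnegative")
            self.regions = r


@dataclass
class SubjectHistory:
    subject_id: object
    baseline: dict
    visits: list

    @property
    def times(self) -> np.ndarray:
        return np.array([v.time for v in self.visits], dtype=float)

    @property
    def states(self) -> np.ndarray:
        return np.array([int(v.state) for v in self.visits], dtype=int)

    @property
    def followup(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if t.size else 0.0

    def marker_series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one marker, missing visits dropped."""
        t, y = [], []
        for v in self.visits:
            val = v.markers.get(name)
            if val is not None and np.isfinite(val):
                t.append(v.time)
                y.append(float(val))
        return np.asarray(t), np.asarray(y)


@dataclass
class ExclusionReport:
    """Counts of visits/subjects removed by each inclusion rule."""

    post_ad_visits: int = 0
    duplicate_time_visits: int = 0
    subjects_too_few_visits: int = 0
    subjects_entry_state: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TransitionTable:
    """Counts and within-origin percentages of consecutive visit-pair moves."""

    counts: dict  # (StateCode, StateCode) -> int; origin==dest means "stay"
    percentages: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), c in sorted(self.counts.items()):
            rows.append({
                "from": STATE_NAMES[a], "to": STATE_NAMES[b],
                "count": c, "percent": self.percentages[(a, b)],
            })
        return pd.DataFrame(rows)


@dataclass
class CohortSchema:
    """Column-name map for long-format cohort CSVs."""

    subject: str = "subject_id"
    time: str = "time"
    state: str = "state"
    markers: tuple = ()
    baseline: dict = field(default_factory=lambda: {f: f for f in BASELINE_FIELDS})
    region_prefix: str = "region_"
    time_in_months: bool = False
    normalize_regions: bool = False


def read_cohort(path, schema: CohortSchema | None = None, validate: bool = True):
    """Read a long-format visit CSV into SubjectHistory records.

    Subjects are returned sorted by id with visits sorted by time.  When
    ``validate`` (default), the inclusion rules are applied and exclusions
    logged; set it to False to get the raw grouping.
    Returns (subjects, ExclusionReport).
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path)
    for col in (schema.subject, schema.time, schema.state):
        if col not in df.columns:
            raise KeyError(f"required column missing from {path}: {col!r}")
    region_cols = [c for c in df.columns if c.startswith(schema.region_prefix)]
    if region_cols:
        region_cols = sorted(region_cols)
        if len(region_cols) != N_REGIONS:
            raise ValueError(
                f"expected {N_REGIONS} region columns, found {len(region_cols)}")
    marker_cols = list(schema.markers)
    subjects = []
    for sid, g in df.groupby(schema.subject, sort=True):
        g = g.sort_values(schema.time, kind="stable")
        baseline = {}
        for field_name, col in schema.baseline.items():
            if col in df.columns:
                baseline[field_name] = float(g[col].iloc[0])
        visits = []
        for idx, row in g.iterrows():
            try:
                state = parse_state(row[schema.state])
            except ValueError as exc:
                raise ValueError(f"row {idx + 2}: {exc}") from exc
            t = float(row[schema.time])
            if schema.time_in_months:
                t /= 12.0
            markers = {}
            for m in marker_cols:
                if m in df.columns and pd.notna(row[m]):
                    markers[m] = float(row[m])
            regions = None
            if region_cols:
                r = row[region_cols].to_numpy(dtype=float)
                if np.all(np.isfinite(r)):
                    if schema.normalize_regions:
                        r = r / r.sum() * 100.0
                    regions = r
            visits.append(VisitRecord(sid, t, state, markers, regions))
        subjects.append(SubjectHistory(sid, baseline, visits))
    if validate:
        return validate_and_truncate(subjects)
    return subjects, ExclusionReport()


def validate_and_truncate(subjects):
    """Apply inclusion rules; problems become report entries, never errors.

    Removes duplicate-time visits (keeping the last record at each time) and
    post-AD visits, then drops subjects with fewer than two remaining visits
    or a non-MCI entry state.  Idempotent.
    """
    report = ExclusionReport()
    kept = []
    for s in subjects:
        visits = sorted(s.visits, key=lambda v: v.time)
        dedup = {}
        for v in visits:
            if v.time in dedup:
                report.duplicate_time_visits += 1
                logger.warning("subject %s: duplicate visit time %.4g, keeping last",
                               s.subject_id, v.time)
            dedup[v.time] = v
        visits = [dedup[t] for t in sorted(dedup)]
        truncated = []
        for v in visits:
            truncated.append(v)
            if v.state == StateCode.AD:
                n_dropped = len(visits) - len(truncated)
                if n_dropped:
                    report.post_ad_visits += n_dropped
                    logger.warning("subject %s: dropped %d visit(s) after AD",
                                   s.subject_id, n_dropped)
                break
        if len(truncated) < 2:
            report.subjects_too_few_visits += 1
            continue
        if truncated[0].state != StateCode.MCI:
            report.subjects_entry_state += 1
            continue
        kept.append(SubjectHistory(s.subject_id, dict(s.baseline), truncated))
    return kept, report


def write_cohort(subjects, path, schema: CohortSchema | None = None) -> None:
    """Write subjects back to a long-format CSV (inverse of read_cohort)."""
    schema = schema or CohortSchema()
    rows = []
    for s in subjects:
        for v in s.visits:
            row = {schema.subject: s.subject_id, schema.time: v.time,
                   schema.state: STATE_NAMES[v.state]}
            for f_name, col in schema.baseline.items():
                if f_name in s.baseline:
                    row[col] = s.baseline[f_name]
            row.update(v.markers)
            if v.regions is not None:
                row.update(dict(zip(REGION_COLUMNS, v.regions)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def count_transitions(subjects) -> TransitionTable:
    """Tabulate consecutive visit-pair transitions with within-origin percentages."""
    counts: dict = {}
    for s in subjects:
        states = s.states
        for a, b in zip(states[:-1], states[1:]):
            key = (StateCode(a), StateCode(b))
            counts[key] = counts.get(key, 0) + 1
    origin_totals: dict = {}
    for (a, _), c in counts.items():
        origin_totals[a] = origin_totals.get(a, 0) + c
    percentages = {k: 100.0 * c / origin_totals[k[0]] for k, c in counts.items()}
    return TransitionTable(counts, percentages)


def transition_table_from_counts(counts: dict) -> TransitionTable:
    """TransitionTable straight from a counts map (e.g. a published table)."""
    counts = {(StateCode(a), StateCode(b)): int(c) for (a, b), c in counts.items()}
    origin_totals: dict = {}
    for (a, _), c in counts.items():
        origin_totals[a] = origin_totals.get(a, 0) + c
    percentages = {k: 100.0 * c / origin_totals[k[0]] for k, c in counts.items()}
    return TransitionTable(counts, percentages)


def summarize_followup(subjects) -> dict:
    """Follow-up summary: median/IQR/min/max of last-minus-first visit time.

    Quantiles use numpy's linear-interpolation convention.
    """
    fu = np.array([s.followup for s in subjects], dtype=float)
    n_obs = int(sum(len(s.visits) for s in subjects))
    if fu.size == 0:
        return {"n_subjects": 0, "n_observations": 0, "median": np.nan,
                "iqr": (np.nan, np.nan), "min": np.nan, "max": np.nan}
    q1, med, q3 = np.percentile(fu, [25, 50, 75])
    return {
        "n_subjects": int(fu.size),
        "n_observations": n_obs,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "min": float(fu.min()),
        "max": float(fu.max()),
    }


def save_report(report: ExclusionReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
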