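"""Synthetic longitudinal biomarker cohorts with known ground-truth dynamics.

Emulates the structure of an observational Parkinson's disease progression
cohort: PD patients enrolled ~2 years after motor onset and followed for up
to 6 years on a fixed visit schedule, a control group followed on the same
schedule, five biofluid markers (CSF amyloid-beta 1-42, alpha-synuclein,
total tau, phosphorylated tau, serum neurofilament light chain) and three
cognitive scores (MoCA, HVLT delayed recall, Letter-Number Sequencing).
Every subject's marker values are generated from a closed-form trajectory
family plus i.i.d. Gaussian measurement noise, so downstream estimates can
be compared against an exact truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

# ---------------------------------------------------------------------------
# column and marker vocabulary
# ---------------------------------------------------------------------------

COL_SUBJECT = "subject_id"
COL_GROUP = "group"
COL_MARKER = "marker"
COL_VISIT = "visit_label"
COL_AGE = "age"
COL_TIME = "duration_years"
COL_VALUE = "value"
COL_HB = "hemoglobin_ng_ml"

REQUIRED_COLUMNS = (
    COL_SUBJECT,
    COL_GROUP,
    COL_MARKER,
    COL_VISIT,
    COL_AGE,
    COL_TIME,
    COL_VALUE,
)

GROUP_PD = "PD"
GROUP_CONTROL = "control"

ABETA = "csf_abeta42"
ASYN = "csf_asyn"
TTAU = "csf_ttau"
PTAU = "csf_ptau"
NFL = "serum_nfl"
MOCA = "moca"
HVLT = "hvlt_dr"
LNS = "lns"

BIOFLUID_MARKERS = (ABETA, ASYN, TTAU, PTAU, NFL)
COGNITIVE_SCORES = (MOCA, HVLT, LNS)
ALL_MARKERS = BIOFLUID_MARKERS + COGNITIVE_SCORES

#: Default visit schedule in years from baseline: BL, 6M, ..., 72M
#: (the 42M visit is absent from the emulated study's schedule).
DEFAULT_VISIT_SCHEDULE = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 4.5, 5.0, 5.5, 6.0)


class ConfigurationError(ValueError):
    """Raised for invalid cohort configuration (counts, SDs, probabilities)."""


# ---------------------------------------------------------------------------
# ground-truth dynamics
# ---------------------------------------------------------------------------

FAMILIES = ("exponential_approach", "logistic", "constant")


@dataclass(frozen=True)
class TruthDynamics:
    """Closed-form trajectory family standing in for a marker's true dynamics.

    Parameters
    ----------
    family : str
        One of ``exponential_approach`` (monotone approach to a plateau,
        the shape seen for CSF amyloid and alpha-synuclein),
        ``logistic`` (sigmoid growth, the shape seen for serum NfL) or
        ``constant``.
    k : float
        Rate constant in 1/year; must be >= 0.
    plateau : float
        Asymptotic level P (exponential_approach), in marker units.
    onset_level : float
        Level X0 at motor onset (t = 0), in marker units.
    capacity : float
        Carrying capacity K for the logistic family, in marker units.
    """

    family: str
    k: float = 0.0
    plateau: float = float("nan")
    onset_level: float = float("nan")
    capacity: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown dynamics family {self.family!r}")
        if self.k < 0:
            raise ValueError("rate constant k must be >= 0")
        if self.family == "logistic" and not self.capacity > 0:
            raise ValueError("logistic family requires capacity K > 0")

    def level(self, t: np.ndarray | float, onset_level: float | None = None):
        """Evaluate the closed-form trajectory at time(s) ``t`` (years from onset)."""
        t = np.asarray(t, dtype=float)
        x0 = self.onset_level if onset_level is None else onset_level
        if self.family == "constant":
            return np.broadcast_to(np.float64(x0), t.shape).copy()
        if self.family == "exponential_approach":
            return self.plateau + (x0 - self.plateau) * np.exp(-self.k * t)
        # logistic: X(t) = K / (1 + ((K - X0)/X0) e^{-kt})
        ratio = (self.capacity - x0) / x0
        return self.capacity / (1.0 + ratio * np.exp(-self.k * t))

    def rate(self, x: np.ndarray | float):
        """True annual change rate f(X) = dX/dt as a function of level."""
        x = np.asarray(x, dtype=float)
        if self.family == "constant":
            return np.zeros_like(x)
        if self.family == "exponential_approach":
            return -self.k * (x - self.plateau)
        return self.k * x * (1.0 - x / self.capacity)


def true_trajectory(dynamics: TruthDynamics, grid, onset_level: float | None = None):
    """Exact trajectory of a :class:`TruthDynamics` on a time grid.

    ``grid`` is in years from motor onset and must lie within [-5, 30].
    Returns a :class:`pdtraj.trajectory.Trajectory` (the oracle for
    recovery tests and worked examples).
    """
    from .trajectory import Trajectory  # local import: avoid cycle

    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < -5.0 - 1e-12 or grid.max() > 30.0 + 1e-12):
        raise ValueError("time grid must lie within [-5, 30] years from onset")
    levels = dynamics.level(grid, onset_level=onset_level)
    x0 = dynamics.onset_level if onset_level is None else onset_level
    return Trajectory(
        marker="truth",
        group="truth",
        times=grid.copy(),
        levels=np.atleast_1d(levels).astype(float),
        anchor_level=float(x0),
        step=float("nan"),
    )


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

def _default_pd_dynamics() -> dict:
    # Shapes and magnitudes echo the emulated cohort: amyloid and
    # alpha-synuclein decline toward a plateau, tau species rise slowly,
    # NfL rises sigmoidally, cognitive scores decline slowly.
    return {
        ABETA: TruthDynamics("exponential_approach", k=0.15, plateau=830.0, onset_level=940.0),
        ASYN: TruthDynamics("exponential_approach", k=0.10, plateau=1170.0, onset_level=1600.0),
        TTAU: TruthDynamics("exponential_approach", k=0.05, plateau=242.0, onset_level=161.0),
        PTAU: TruthDynamics("exponential_approach", k=0.04, plateau=30.0, onset_level=14.0),
        NFL: TruthDynamics("logistic", k=0.12, capacity=35.0, onset_level=12.4),
        MOCA: TruthDynamics("exponential_approach", k=0.03, plateau=18.0, onset_level=27.5),
        HVLT: TruthDynamics("exponential_approach", k=0.04, plateau=30.0, onset_level=45.0),
        LNS: TruthDynamics("exponential_approach", k=0.03, plateau=7.0, onset_level=10.6),
    }


def _default_control_dynamics() -> dict:
    # Controls sit at their group baseline means with no systematic change.
    means = {ABETA: 1022.6, ASYN: 1701.3, TTAU: 192.9, PTAU: 17.6, NFL: 12.4,
             MOCA: 28.2, HVLT: 48.8, LNS: 10.9}
    return {m: TruthDynamics("constant", onset_level=v) for m, v in means.items()}


def _default_noise_sd() -> dict:
    return {ABETA: 100.0, ASYN: 150.0, TTAU: 15.0, PTAU: 1.5, NFL: 2.0,
            MOCA: 1.0, HVLT: 3.0, LNS: 1.0}


def _default_onset_level_sd() -> dict:
    return {ABETA: 380.0, ASYN: 620.0, TTAU: 55.0, PTAU: 5.0, NFL: 5.0,
            MOCA: 1.5, HVLT: 8.0, LNS: 2.4}


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults emulate the study conditions: ~400 PD and ~180 control
    subjects, baseline disease duration ~ N(2.0, 2.0^2) truncated at 0,
    twelve scheduled visits over 6 years with independent per-visit
    dropout, and additive Gaussian measurement noise per marker.
    """

    n_pd: int = 396
    n_control: int = 182
    dynamics: dict = field(default_factory=_default_pd_dynamics)
    control_dynamics: dict = field(default_factory=_default_control_dynamics)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    onset_level_sd: dict = field(default_factory=_default_onset_level_sd)
    baseline_duration_mean: float = 2.0
    baseline_duration_sd: float = 2.0
    visit_schedule: tuple = DEFAULT_VISIT_SCHEDULE
    dropout_prob: float = 0.10
    unscheduled_rate: float = 0.0
    high_hemoglobin_fraction: float = 0.05
    outlier_fraction: float = 0.02
    cognitive_outlier_fraction: float = 0.0
    aao_mean: float = 60.0
    aao_sd: float = 10.0
    control_age_mean: float = 60.6
    control_age_sd: float = 11.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd <= 0 or self.n_control <= 0:
            raise ConfigurationError("subject counts must be positive")
        for name, p in (("dropout_prob", self.dropout_prob),
                        ("high_hemoglobin_fraction", self.high_hemoglobin_fraction),
                        ("outlier_fraction", self.outlier_fraction),
                        ("cognitive_outlier_fraction", self.cognitive_outlier_fraction),
                        ("unscheduled_rate", self.unscheduled_rate)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for d in (self.noise_sd, self.onset_level_sd):
            for m, sd in d.items():
                if sd < 0:
                    raise ConfigurationError(f"negative SD for {m}")
        if self.baseline_duration_sd < 0:
            raise ConfigurationError("baseline_duration_sd must be >= 0")
        self.visit_schedule = tuple(float(v) for v in self.visit_schedule)
        if self.visit_schedule[0] != 0.0:
            raise ConfigurationError("visit schedule must start at baseline (0)")

    @property
    def markers(self) -> tuple:
        return tuple(self.dynamics)


def load_cohort_config(path) -> CohortConfig:
    """Read a :class:`CohortConfig` from a YAML file.

    Dynamics entries are mappings, e.g.::

        dynamics:
          csf_abeta42: {family: exponential_approach, k: 0.15,
                        plateau: 830, onset_level: 940}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return cohort_config_from_dict(raw)


def cohort_config_from_dict(raw: dict) -> CohortConfig:
    kwargs = dict(raw)
    for key in ("dynamics", "control_dynamics"):
        if key in kwargs:
            kwargs[key] = {m: TruthDynamics(**spec) if isinstance(spec, dict) else spec
                           for m, spec in kwargs[key].items()}
    if "visit_schedule" in kwargs:
        kwargs["visit_schedule"] = tuple(kwargs["visit_schedule"])
    return CohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.ppf(rng.random(size), a, b, loc=mean, scale=sd)


def _visit_label(offset: float) -> str:
    return "BL" if offset == 0.0 else f"{int(round(offset * 12))}M"


def generate_cohort(config: CohortConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    visits : pandas.DataFrame
        Long table, one row per subject x visit x marker, with columns
        ``subject_id, group, marker, visit_label, age, duration_years,
        value, hemoglobin_ng_ml`` (hemoglobin only for alpha-synuclein rows).
        For PD subjects ``duration_years`` is disease duration; for
        controls it is time from baseline.
    covariates : pandas.DataFrame
        One row per subject: age at onset (PD), baseline age, baseline
        disease duration, baseline MoCA and baseline CSF amyloid values.
    truth : pandas.DataFrame
        Hidden ground truth: per-subject onset levels and planted
        contaminant labels (``kind`` in {high_hemoglobin, baseline_outlier,
        cognitive_outlier}). Not an input to any downstream stage.

    The same config (including ``seed``) always yields byte-identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    markers = config.markers

    # --- subject-level draws -------------------------------------------------
    aao = _truncated_normal(rng, config.aao_mean, config.aao_sd, 30.0, 90.0, config.n_pd)
    base_dur = _truncated_normal(rng, config.baseline_duration_mean,
                                 config.baseline_duration_sd, 0.0, np.inf, config.n_pd)
    ctrl_age = _truncated_normal(rng, config.control_age_mean, config.control_age_sd,
                                 30.0, 90.0, config.n_control)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    cov_rows: list[dict] = []

    def _emit_subject(sid, group, t0_offsetless, age_at_t0, marker_onsets, dynamics_map):
        """Generate all visits for one subject; returns per-marker baseline values."""
        offsets = np.array(config.visit_schedule)
        keep = np.ones(offsets.size, dtype=bool)
        if config.dropout_prob > 0:
            keep[1:] = rng.random(offsets.size - 1) >= config.dropout_prob
        offsets = offsets[keep]
        labels = [_visit_label(o) for o in config.visit_schedule]
        labels = [lab for lab, k in zip(labels, keep) if k]
        if config.unscheduled_rate > 0:
            n_un = rng.binomial(2, config.unscheduled_rate)
            if n_un:
                extra = np.sort(rng.uniform(0.1, config.visit_schedule[-1], n_un))
                offsets = np.concatenate([offsets, extra])
                labels = labels + ["UN"] * n_un
                order = np.argsort(offsets, kind="stable")
                offsets = offsets[order]
                labels = [labels[i] for i in order]

        baselines = {}
        for marker in markers:
            dyn = dynamics_map[marker]
            t = t0_offsetless + offsets
            vals = dyn.level(t, onset_level=marker_onsets[marker])
            sd = config.noise_sd.get(marker, 0.0)
            if sd > 0:
                vals = vals + rng.normal(0.0, sd, vals.shape)
            for j, (off, lab) in enumerate(zip(offsets, labels)):
                hb = np.nan
                if marker == ASYN:
                    if rng.random() < config.high_hemoglobin_fraction:
                        hb = rng.uniform(200.0, 500.0)
                        truth_rows.append({COL_SUBJECT: sid, COL_MARKER: marker,
                                           COL_VISIT: lab, "kind": "high_hemoglobin"})
                    else:
                        hb = rng.uniform(20.0, 150.0)
                rows.append({COL_SUBJECT: sid, COL_GROUP: group, COL_MARKER: marker,
                             COL_VISIT: lab, COL_AGE: age_at_t0 + off,
                             COL_TIME: t0_offsetless + off, COL_VALUE: vals[j],
                             COL_HB: hb})
            baselines[marker] = vals[0]
        return baselines

    # --- PD subjects ---------------------------------------------------------
    for i in range(config.n_pd):
        sid = f"PD{i + 1:04d}"
        onsets = {}
        for marker in markers:
            dyn = config.dynamics[marker]
            sd = config.onset_level_sd.get(marker, 0.0)
            x0 = dyn.onset_level + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            onsets[marker] = x0
            truth_rows.append({COL_SUBJECT: sid, COL_MARKER: marker, COL_VISIT: "",
                               "kind": "onset_level", COL_VALUE: x0})
        baselines = _emit_subject(sid, GROUP_PD, base_dur[i], aao[i] + base_dur[i],
                                  onsets, config.dynamics)

        # planted extreme-baseline contaminants
        if config.outlier_fraction > 0 and rng.random() < config.outlier_fraction:
            bio = [m for m in markers if m in BIOFLUID_MARKERS]
            if bio:
                marker = bio[rng.integers(len(bio))]
                _plant_baseline_outlier(rows, sid, marker)
                if marker == ASYN:
                    # an outlier planted on a hemoglobin-screened sample must
                    # survive the hemoglobin stage to be attributable
                    truth_rows[:] = [t for t in truth_rows
                                     if not (t[COL_SUBJECT] == sid
                                             and t[COL_MARKER] == ASYN
                                             and t[COL_VISIT] == "BL"
                                             and t["kind"] == "high_hemoglobin")]
                truth_rows.append({COL_SUBJECT: sid, COL_MARKER: marker, COL_VISIT: "BL",
                                   "kind": "baseline_outlier"})
        if config.cognitive_outlier_fraction > 0 and rng.random() < config.cognitive_outlier_fraction:
            cog = [m for m in markers if m in COGNITIVE_SCORES]
            if cog:
                marker = cog[rng.integers(len(cog))]
                lab = _plant_cognitive_outlier(rows, sid, marker)
                if lab is not None:
                    truth_rows.append({COL_SUBJECT: sid, COL_MARKER: marker,
                                       COL_VISIT: lab, "kind": "cognitive_outlier"})

        cov_rows.append({COL_SUBJECT: sid, COL_GROUP: GROUP_PD,
                         "age_at_onset": aao[i], "baseline_age": aao[i] + base_dur[i],
                         "baseline_duration": base_dur[i],
                         "moca_baseline": baselines.get(MOCA, np.nan),
                         "abeta_baseline": baselines.get(ABETA, np.nan)})

    # --- controls ------------------------------------------------------------
    for i in range(config.n_control):
        sid = f"HC{i + 1:04d}"
        onsets = {}
        for marker in markers:
            dyn = config.control_dynamics[marker]
            sd = config.onset_level_sd.get(marker, 0.0)
            onsets[marker] = dyn.onset_level + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        baselines = _emit_subject(sid, GROUP_CONTROL, 0.0, ctrl_age[i],
                                  onsets, config.control_dynamics)
        cov_rows.append({COL_SUBJECT: sid, COL_GROUP: GROUP_CONTROL,
                         "age_at_onset": np.nan, "baseline_age": ctrl_age[i],
                         "baseline_duration": np.nan,
                         "moca_baseline": baselines.get(MOCA, np.nan),
                         "abeta_baseline": baselines.get(ABETA, np.nan)})

    visits = pd.DataFrame(rows)
    covariates = pd.DataFrame(cov_rows)
    truth = pd.DataFrame(truth_rows)
    return visits, covariates, truth


def _plant_baseline_outlier(rows, sid, marker):
    # push the baseline value far past any 3xIQR fence
    for r in rows:
        if r[COL_SUBJECT] == sid and r[COL_MARKER] == marker and r[COL_VISIT] == "BL":
            r[COL_VALUE] = abs(r[COL_VALUE]) * 15.0 + 1000.0
            if marker == ASYN and r[COL_HB] >= 200.0:
                r[COL_HB] = 100.0  # keep the planted sample past the hb screen
            return


def _plant_cognitive_outlier(rows, sid, marker):
    cand = [r for r in rows
            if r[COL_SUBJECT] == sid and r[COL_MARKER] == marker and r[COL_VISIT] != "BL"]
    if not cand:
        return None
    r = cand[-1]
    r[COL_VALUE] = r[COL_VALUE] + 60.0
    return r[COL_VISIT]


def recovery_benchmark_config(seed: int = 0, noise_sd: float = 20.0) -> CohortConfig:
    """A single-marker recovery benchmark: truth dX/dt = -0.08 (X - 600).

    400 PD subjects with mean onset level 1000 and realistic between-subject
    heterogeneity (SD 380, ~38% relative spread, echoing the cross-sectional
    SDs of CSF amyloid in observational PD cohorts — wide enough that
    observed baselines straddle the plateau), measurement noise SD 20,
    baseline disease duration ~ N(2, 2^2) truncated at 0, six annual visits.
    Used by the end-to-end parameter-recovery tests and worked examples.
    """
    dyn = {ABETA: TruthDynamics("exponential_approach", k=0.08, plateau=600.0,
                                onset_level=1000.0)}
    ctrl = {ABETA: TruthDynamics("constant", onset_level=1000.0)}
    return CohortConfig(
        n_pd=400, n_control=100, dynamics=dyn, control_dynamics=ctrl,
        noise_sd={ABETA: noise_sd}, onset_level_sd={ABETA: 380.0},
        baseline_duration_mean=2.0, baseline_duration_sd=2.0,
        visit_schedule=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0), dropout_prob=0.0,
        high_hemoglobin_fraction=0.0, outlier_fraction=0.0, seed=seed)


# ---------------------------------------------------------------------------
# small worked example with planted rule violations
# ---------------------------------------------------------------------------

def planted_violation_table():
    """A deterministic 12-subject toy cohort exercising every filter rule.

    Planted violations: subject T12 has a single visit; T01 and T02 each
    have one high-hemoglobin (>= 200 ng/mL) alpha-synuclein sample; T03's
    baseline amyloid is far beyond Q3 + 3*IQR; T04 has one MoCA score far
    beyond the baseline mean + 4 SD.

    Returns ``(table, expected_exclusions)`` where the expectation is a set
    of ``(subject_id, marker, reason)`` tuples.
    """
    rows = []
    abeta_base = [850, 860, 10000, 880, 890, 900, 910, 920, 930, 940, 950]
    moca_base = [27, 28, 27, 28, 27, 28, 27, 28, 27, 28, 27]
    for i in range(11):
        sid = f"T{i + 1:02d}"
        for j, t in enumerate((0.0, 1.0, 2.0)):
            lab = ("BL", "12M", "24M")[j]
            hb = 100.0
            if (sid == "T01" and lab == "24M") or (sid == "T02" and lab == "24M"):
                hb = 250.0
            rows.append({COL_SUBJECT: sid, COL_GROUP: GROUP_PD, COL_MARKER: ASYN,
                         COL_VISIT: lab, COL_AGE: 62.0 + t, COL_TIME: 2.0 + t,
                         COL_VALUE: 1500.0 - 10 * t, COL_HB: hb})
            rows.append({COL_SUBJECT: sid, COL_GROUP: GROUP_PD, COL_MARKER: ABETA,
                         COL_VISIT: lab, COL_AGE: 62.0 + t, COL_TIME: 2.0 + t,
                         COL_VALUE: float(abeta_base[i]) - 5 * t, COL_HB: np.nan})
            moca = float(moca_base[i])
            if sid == "T04" and lab == "24M":
                moca = 60.0
            rows.append({COL_SUBJECT: sid, COL_GROUP: GROUP_PD, COL_MARKER: MOCA,
                         COL_VISIT: lab, COL_AGE: 62.0 + t, COL_TIME: 2.0 + t,
                         COL_VALUE: moca, COL_HB: np.nan})
    # single-visit subject
    for marker, val in ((ASYN, 1480.0), (ABETA, 905.0), (MOCA, 27.0)):
        rows.append({COL_SUBJECT: "T12", COL_GROUP: GROUP_PD, COL_MARKER: marker,
                     COL_VISIT: "BL", COL_AGE: 61.0, COL_TIME: 1.5, COL_VALUE: val,
                     COL_HB: 90.0 if marker == ASYN else np.nan})
    expected = {
        ("T12", ASYN, "insufficient_visits"),
        ("T12", ABETA, "insufficient_visits"),
        ("T12", MOCA, "insufficient_visits"),
        ("T01", ASYN, "high_hemoglobin"),
        ("T02", ASYN, "high_hemoglobin"),
        ("T03", ABETA, "baseline_outlier"),
        ("T04", MOCA, "cognitive_outlier"),
    }
    return pd.DataFrame(rows), expected


def save_cohort(visits, covariates, truth, outdir) -> None:
    """Write the three cohort tables as CSV into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visits.to_csv(outdir / "cohort.csv", index=False)
    covariates.to_csv(outdir / "covariates.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)


def config_to_dict(config: CohortConfig) -> dict:
    """JSON/YAML-serializable view of a config (for manifests)."""
    d = dataclasses.asdict(config)
    for key in ("dynamics", "control_dynamics"):
        d[key] = {m: dataclasses.asdict(v) if isinstance(v, TruthDynamics) else v
                  for m, v in d[key].items()}
    d["visit_schedule"] = list(d["visit_schedule"])
    return d
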