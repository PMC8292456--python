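"""End-to-end pipeline: generate/load -> filter -> kinetics -> rate models
-> trajectories -> summary report.

Each stage reads its inputs from, and writes its outputs to, a working
directory, so the stages can run as one shot (:func:`run_pipeline`) or
individually from the command line. All tabular outputs are CSV/TSV and
all summaries JSON; with a fixed configuration and seed every data product
is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filters as flt
from . import synthetic as syn
from .kinetics import compute_kinetics, onset_anchor
from .ratespline import (
    DegenerateKnotsError,
    RateModel,
    fit_rate_model,
    rate_curve_table,
    rate_roots,
)
from .synthetic import (
    COL_GROUP,
    COL_MARKER,
    COL_SUBJECT,
    COL_TIME,
    COL_VALUE,
    GROUP_CONTROL,
    GROUP_PD,
    REQUIRED_COLUMNS,
)
from .trajectory import (
    ControlReference,
    Trajectory,
    anchor_control_trajectory,
    convergence_check,
    find_crossing,
    integrate_trajectory,
    percent_change,
    to_zscores,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

PD_STRATA = (flt.STRATUM_PD_ALL, flt.STRATUM_PDCU, flt.STRATUM_PDCI,
             flt.STRATUM_ABETA_HIGH, flt.STRATUM_ABETA_LOW)
EXPORT_GRID_YEARS = 0.25  # trajectory TSV thinning; integration grid is finer


@dataclasses.dataclass
class PipelineConfig:
    """Bundle of the per-stage configurations plus solver settings."""

    cohort: syn.CohortConfig = dataclasses.field(default_factory=syn.CohortConfig)
    filters: flt.FilterConfig = dataclasses.field(default_factory=flt.FilterConfig)
    step_years: float = 0.01
    method: str = "heun"  # or "midpoint"
    anchor_stat: str = "mean"
    baseline_stat: str = "first"  # or "mean": level paired with each rate
    t_min: float = -5.0
    t_max: float = 30.0
    markers: tuple | None = None  # None = all markers in the data
    stratify: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = syn.config_to_dict(self.cohort)
        d["markers"] = list(self.markers) if self.markers else None
        d["filters"]["cognitive_markers"] = list(self.filters.cognitive_markers)
        return d


def load_pipeline_config(path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from YAML (all sections optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "cohort" in raw:
        kwargs["cohort"] = syn.cohort_config_from_dict(raw["cohort"])
    if "filters" in raw:
        fraw = dict(raw["filters"])
        if "cognitive_markers" in fraw:
            fraw["cognitive_markers"] = tuple(fraw["cognitive_markers"])
        kwargs["filters"] = flt.FilterConfig(**fraw)
    for key in ("step_years", "method", "anchor_stat", "baseline_stat",
                "t_min", "t_max", "stratify"):
        if key in raw:
            kwargs[key] = raw[key]
    if raw.get("markers"):
        kwargs["markers"] = tuple(raw["markers"])
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_input(df: pd.DataFrame) -> list[dict]:
    """Report-only checks of a long-format cohort table.

    Flags missing required columns, non-numeric marker values (with row
    index), duplicated subject-visit-marker rows, unknown group labels and
    negative durations for controls. Never mutates the data.
    """
    issues: list[dict] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    for col in missing:
        issues.append({"issue": "missing_column", "column": col})
    if missing:
        return issues
    vals = pd.to_numeric(df[COL_VALUE], errors="coerce")
    for idx in df.index[vals.isna() & df[COL_VALUE].notna()]:
        issues.append({"issue": "non_numeric_value", "row": int(idx)})
    dup = df.duplicated([COL_SUBJECT, COL_MARKER, syn.COL_VISIT, COL_TIME], keep="first")
    for idx in df.index[dup]:
        issues.append({"issue": "duplicate_row", "row": int(idx)})
    bad_groups = set(df[COL_GROUP].unique()) - {GROUP_PD, GROUP_CONTROL}
    for g in sorted(bad_groups):
        issues.append({"issue": "unknown_group", "group": str(g)})
    times = pd.to_numeric(df[COL_TIME], errors="coerce")
    for idx in df.index[times.isna()]:
        issues.append({"issue": "non_numeric_time", "row": int(idx)})
    return issues


def derive_covariates(visits: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the per-subject covariate table from a long table.

    Baseline age and duration come from each subject's earliest visit;
    PD age at onset is age minus disease duration; baseline MoCA and
    baseline CSF amyloid come from those marker series when present.
    """
    rows = []
    for sid, sub in visits.groupby(COL_SUBJECT, sort=True):
        first = sub.loc[sub[COL_TIME].idxmin()]
        group = first[COL_GROUP]
        base_t = float(first[COL_TIME])
        base_age = float(first[syn.COL_AGE])
        aao = base_age - base_t if group == GROUP_PD else np.nan

        def baseline_of(marker):
            s = sub[sub[COL_MARKER] == marker]
            if s.empty:
                return np.nan
            return float(s.loc[s[COL_TIME].idxmin(), COL_VALUE])

        rows.append({COL_SUBJECT: sid, COL_GROUP: group, "age_at_onset": aao,
                     "baseline_age": base_age,
                     "baseline_duration": base_t if group == GROUP_PD else np.nan,
                     "moca_baseline": baseline_of(syn.MOCA),
                     "abeta_baseline": baseline_of(syn.ABETA)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, workdir: Path) -> None:
    workdir.mkdir(parents=True, exist_ok=True)
    visits, covariates, truth = syn.generate_cohort(config.cohort)
    syn.save_cohort(visits, covariates, truth, workdir)
    logger.info("simulate: %d rows, %d subjects", len(visits), len(covariates))


def stage_filter(config: PipelineConfig, workdir: Path,
                 input_csv: Path | None = None) -> None:
    visits = pd.read_csv(input_csv or workdir / "cohort.csv")
    issues = validate_input(visits)
    if any(i["issue"] == "missing_column" and i["column"] != syn.COL_HB for i in issues):
        raise ValueError(f"input schema violation: {issues}")
    if syn.COL_HB not in visits.columns:
        logger.warning("input has no %s column: hemoglobin filter SKIPPED", syn.COL_HB)
        visits[syn.COL_HB] = np.nan
    (workdir / "validation.json").write_text(_dump_json(issues))

    result = flt.apply_filters(visits, config.filters)
    result.data.to_csv(workdir / "filtered.csv", index=False)
    result.report.to_csv(workdir / "filter_report.tsv", sep="\t", index=False)
    (workdir / "filter_summary.json").write_text(_dump_json(result.summary))

    cov_path = workdir / "covariates.csv"
    covariates = (pd.read_csv(cov_path) if cov_path.exists()
                  else derive_covariates(visits))
    strata = flt.stratify(covariates, config.filters)
    covariates.to_csv(cov_path, index=False)
    strata.to_csv(workdir / "strata.tsv", sep="\t", index=False)
    logger.info("filter: %s", result.summary)


def stage_kinetics(config: PipelineConfig, workdir: Path) -> None:
    filtered = pd.read_csv(workdir / "filtered.csv")
    kin, exclusions = compute_kinetics(filtered, baseline_stat=config.baseline_stat)
    kin.to_csv(workdir / "kinetics.tsv", sep="\t", index=False)
    if exclusions:
        pd.DataFrame(exclusions).to_csv(workdir / "kinetics_exclusions.tsv",
                                        sep="\t", index=False)
    logger.info("kinetics: %d series fitted, %d degenerate", len(kin), len(exclusions))


def _strata_for(config: PipelineConfig):
    strata = [flt.STRATUM_PD_ALL, flt.STRATUM_CONTROL]
    if config.stratify:
        strata += [flt.STRATUM_PDCU, flt.STRATUM_PDCI,
                   flt.STRATUM_ABETA_HIGH, flt.STRATUM_ABETA_LOW]
    return strata


def stage_rates(config: PipelineConfig, workdir: Path) -> None:
    kin = pd.read_csv(workdir / "kinetics.tsv", sep="\t")
    covariates = pd.read_csv(workdir / "covariates.csv")
    strata = pd.read_csv(workdir / "strata.tsv", sep="\t")
    filtered = pd.read_csv(workdir / "filtered.csv")

    markers = config.markers or tuple(sorted(kin[COL_MARKER].unique()))
    models, anchors, curves = [], [], []
    for stratum in _strata_for(config):
        ids = flt.stratum_subjects(strata, covariates, stratum)
        sub_all = kin[kin[COL_SUBJECT].isin(ids)]
        for marker in markers:
            sub = sub_all[sub_all[COL_MARKER] == marker]
            if len(sub) < 5:
                logger.warning("rates: %s/%s skipped (n=%d)", stratum, marker, len(sub))
                continue
            try:
                model = fit_rate_model(sub["baseline_level"], sub["rate"],
                                       n_subjects=len(sub), marker=marker,
                                       group=stratum,
                                       quantile_method=config.filters.quantile_method)
            except (ValueError, DegenerateKnotsError) as exc:
                logger.warning("rates: %s/%s skipped (%s)", stratum, marker, exc)
                continue
            models.append(model.to_dict())
            anchors.append({"stratum": stratum, COL_MARKER: marker,
                            "anchor_level": onset_anchor(sub, config.anchor_stat),
                            "n_subjects": len(sub)})
            curves.append(rate_curve_table(model))

    (workdir / "rate_models.json").write_text(_dump_json(models))
    pd.DataFrame(anchors).to_csv(workdir / "anchors.tsv", sep="\t", index=False)
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(
            workdir / "rate_curves.tsv", sep="\t", index=False)

    ref = ControlReference.from_cohort(filtered, covariates)
    (workdir / "control_reference.json").write_text(_dump_json({
        "means": ref.means, "sds": ref.sds,
        "median_baseline_age": ref.median_baseline_age,
        "median_pd_aao": ref.median_pd_aao,
    }))
    logger.info("rates: %d models fitted", len(models))


def _load_ref(workdir: Path) -> ControlReference:
    d = json.loads((workdir / "control_reference.json").read_text())
    return ControlReference(means=d["means"], sds=d["sds"],
                            median_baseline_age=d["median_baseline_age"],
                            median_pd_aao=d["median_pd_aao"])


def stage_trajectories(config: PipelineConfig, workdir: Path) -> None:
    models = [RateModel.from_dict(d)
              for d in json.loads((workdir / "rate_models.json").read_text())]
    anchors = pd.read_csv(workdir / "anchors.tsv", sep="\t")
    ref = _load_ref(workdir)

    frames = []
    for model in models:
        key = (anchors["stratum"] == model.group) & (anchors[COL_MARKER] == model.marker)
        if not key.any():
            continue
        try:
            if model.group == flt.STRATUM_CONTROL:
                traj = anchor_control_trajectory(model, ref, model.marker,
                                                 h=config.step_years,
                                                 method=config.method)
            else:
                anchor = float(anchors.loc[key, "anchor_level"].iloc[0])
                traj = integrate_trajectory(model, anchor, t_min=config.t_min,
                                            t_max=config.t_max, h=config.step_years,
                                            method=config.method)
        except Exception as exc:  # divergence etc.: skip stratum, keep pipeline alive
            logger.warning("trajectories: %s/%s failed (%s)", model.group,
                           model.marker, exc)
            continue
        if model.marker in ref.sds:
            traj = to_zscores(traj, ref, model.marker)
        dh = convergence_check(model, traj.anchor_level, config.step_years,
                               t_min=min(config.t_min, 0.0), t_max=config.t_max,
                               method=config.method)
        logger.info("trajectories: %s/%s h-vs-h/2 max diff %.2e; diagnostics %s",
                    model.group, model.marker, dh, traj.diagnostics)
        frames.append(traj.to_frame(every=EXPORT_GRID_YEARS))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["marker", "stratum", "duration_years",
                                      "level", "z"]))
    out.to_csv(workdir / "trajectories.tsv", sep="\t", index=False)
    logger.info("trajectories: %d curves", len(frames))


def _traj_from_frame(frame: pd.DataFrame) -> Trajectory:
    frame = frame.sort_values("duration_years")
    z = frame["z"].to_numpy(dtype=float)
    return Trajectory(marker=frame["marker"].iloc[0], group=frame["stratum"].iloc[0],
                      times=frame["duration_years"].to_numpy(dtype=float),
                      levels=frame["level"].to_numpy(dtype=float),
                      z_scores=None if np.all(np.isnan(z)) else z,
                      step=EXPORT_GRID_YEARS)


def stage_report(config: PipelineConfig, workdir: Path, seed: int | None = None,
                 input_paths: tuple = ()) -> None:
    models = [RateModel.from_dict(d)
              for d in json.loads((workdir / "rate_models.json").read_text())]
    traj_tab = pd.read_csv(workdir / "trajectories.tsv", sep="\t")

    trajs = {}
    for (marker, stratum), frame in traj_tab.groupby(["marker", "stratum"], sort=True):
        trajs[(marker, stratum)] = _traj_from_frame(frame)

    summary: dict = {"markers": {}}
    for model in models:
        entry = summary["markers"].setdefault(model.marker, {})
        roots = rate_roots(model)
        stratum_entry = {
            "rate_roots": [{"level": r.level, "stable": r.stable} for r in roots],
            "n_subjects": model.n_subjects,
        }
        traj = trajs.get((model.marker, model.group))
        if traj is not None:
            t_hi = min(config.t_max, float(traj.times.max()))
            t_lo = max(0.0, float(traj.times.min()))
            try:
                stratum_entry["percent_change_onset_to_30y"] = percent_change(
                    traj, t_lo, t_hi)
            except ZeroDivisionError:
                stratum_entry["percent_change_onset_to_30y"] = None
            ctrl = trajs.get((model.marker, flt.STRATUM_CONTROL))
            if ctrl is not None and model.group != flt.STRATUM_CONTROL:
                stratum_entry["crossing_vs_control_years"] = find_crossing(traj, ctrl)
            if traj.z_scores is not None:
                stratum_entry["z_zero_crossing_years"] = find_crossing(traj, 0.0, "z")
        entry[model.group] = stratum_entry
    (workdir / "summary.json").write_text(_dump_json(summary))

    manifest = {
        "config_hash": hashlib.sha256(
            _dump_json(config.to_dict()).encode()).hexdigest(),
        "seed": config.cohort.seed if seed is None else seed,
        "input_paths": [str(p) for p in input_paths],
        "row_counts": _count_rows(workdir),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (workdir / "manifest.json").write_text(_dump_json(manifest))


def _count_rows(workdir: Path) -> dict:
    counts = {}
    for name in ("cohort.csv", "filtered.csv", "kinetics.tsv", "anchors.tsv",
                 "trajectories.tsv"):
        p = workdir / name
        if p.exists():
            with open(p) as fh:
                counts[name] = max(sum(1 for _ in fh) - 1, 0)
    return counts


def _dump_json(obj) -> str:
    return json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n"


def run_pipeline(config: PipelineConfig | None = None, source: str = "synthetic",
                 outdir="pdtraj_run", seed: int | None = None) -> Path:
    """Run every stage; ``source`` is ``"synthetic"`` or a cohort CSV path.

    ``seed`` overrides the cohort config's seed. Returns the output
    directory containing the filter report, kinetics TSV, rate-model JSON,
    trajectory TSV, summary JSON and run manifest.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort, seed=int(seed)))
    workdir = Path(outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    input_paths: tuple = ()
    if source == "synthetic":
        stage_simulate(config, workdir)
        stage_filter(config, workdir)
    else:
        input_paths = (source,)
        stage_filter(config, workdir, input_csv=Path(source))
    stage_kinetics(config, workdir)
    stage_rates(config, workdir)
    stage_trajectories(config, workdir)
    stage_report(config, workdir, seed=seed, input_paths=input_paths)
    return workdir
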