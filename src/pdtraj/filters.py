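"""Cohort inclusion/exclusion rules and stratification.

The filter chain mirrors the study's flow: (1) keep only subject-marker
series with at least two valid measurements; (2) drop alpha-synuclein
samples with CSF hemoglobin >= 200 ng/mL (blood contamination inflates
alpha-synuclein); (3) drop subjects whose baseline biomarker level lies
more than 3 interquartile ranges below Q1 or above Q3; (4) drop subjects
with any cognitive score beyond the group's baseline mean +/- 4 SD.
Stratification splits PD subjects by baseline cognition (MoCA > 25 ->
cognitively unimpaired, PDCU; otherwise PDCI) and by baseline CSF
amyloid-beta 1-42 (< 683.45 pg/mL -> low-amyloid group).

Every exclusion is logged with a stage and reason code so a filter report
can be audited against the raw data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import (
    ABETA,
    ASYN,
    COGNITIVE_SCORES,
    COL_GROUP,
    COL_HB,
    COL_MARKER,
    COL_SUBJECT,
    COL_TIME,
    COL_VALUE,
    GROUP_CONTROL,
    GROUP_PD,
)

logger = logging.getLogger(__name__)

STAGE_MIN_VISITS = "min_visits"
STAGE_HEMOGLOBIN = "hemoglobin"
STAGE_BASELINE_OUTLIER = "baseline_outlier"
STAGE_COGNITIVE_OUTLIER = "cognitive_outlier"

REPORT_COLUMNS = (COL_SUBJECT, COL_MARKER, "stage", "reason")


@dataclass
class FilterConfig:
    """Thresholds for the filter chain. All thresholds must be positive."""

    min_measurements: int = 2
    hemoglobin_cutoff: float = 200.0  # ng/mL, strict: hb >= cutoff excluded
    iqr_multiplier: float = 3.0
    cognitive_sd_multiplier: float = 4.0
    moca_cutoff: float = 25.0  # PDCU iff MoCA > cutoff
    abeta_cutoff: float = 683.45  # pg/mL; low iff strictly below
    drop_missing_hemoglobin: bool = False
    quantile_method: str = "linear"
    alpha_syn_marker: str = ASYN
    cognitive_markers: tuple = COGNITIVE_SCORES

    def __post_init__(self) -> None:
        for name in ("min_measurements", "hemoglobin_cutoff", "iqr_multiplier",
                     "cognitive_sd_multiplier", "moca_cutoff", "abeta_cutoff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterResult:
    data: pd.DataFrame
    report: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _log_entries(entries, subjects_markers, stage, reason):
    for sid, marker in subjects_markers:
        entries.append({COL_SUBJECT: sid, COL_MARKER: marker,
                        "stage": stage, "reason": reason})


def _baseline_rows(df: pd.DataFrame) -> pd.DataFrame:
    """First (earliest-time) row of every subject-marker series."""
    df = df.reset_index(drop=True)  # guard against duplicate index labels
    idx = df.groupby([COL_SUBJECT, COL_MARKER], sort=False)[COL_TIME].idxmin()
    return df.loc[idx]


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_min_visits(df: pd.DataFrame, min_measurements: int = 2):
    """Retain subject-marker series with >= ``min_measurements`` valid rows."""
    entries: list[dict] = []
    if df.empty:
        logger.warning("filter_min_visits: empty input")
        return df.copy(), entries
    counts = df.groupby([COL_SUBJECT, COL_MARKER]).size()
    bad = counts[counts < min_measurements].index
    if len(bad):
        _log_entries(entries, bad, STAGE_MIN_VISITS, "insufficient_visits")
        keep = ~pd.MultiIndex.from_frame(df[[COL_SUBJECT, COL_MARKER]]).isin(bad)
        df = df[keep]
    return df.copy(), entries


def filter_hemoglobin(df: pd.DataFrame, cutoff: float = 200.0,
                      alpha_syn_marker: str = ASYN,
                      drop_missing: bool = False,
                      min_measurements: int = 2):
    """Drop alpha-synuclein samples with hemoglobin >= ``cutoff`` ng/mL.

    The rule is sample-level and alpha-synuclein-specific; other markers
    keep their rows regardless of hemoglobin. Samples with missing
    hemoglobin are retained with a warning unless ``drop_missing``. Series
    pushed below ``min_measurements`` by sample removal are dropped too
    (logged under this stage), which keeps the full chain idempotent.
    """
    entries: list[dict] = []
    if df.empty:
        return df.copy(), entries
    is_asyn = df[COL_MARKER] == alpha_syn_marker
    hb = df[COL_HB] if COL_HB in df.columns else pd.Series(np.nan, index=df.index)
    if (hb.dropna() < 0).any():
        raise ValueError("negative hemoglobin value")
    missing = is_asyn & hb.isna()
    if missing.any():
        if drop_missing:
            logger.warning("dropping %d alpha-synuclein samples with missing hemoglobin",
                           int(missing.sum()))
        else:
            logger.warning("retaining %d alpha-synuclein samples with missing hemoglobin",
                           int(missing.sum()))
    high = is_asyn & (hb >= cutoff)
    drop = (high | missing) if drop_missing else high
    if drop.any():
        for sid, marker in (df.loc[high, [COL_SUBJECT, COL_MARKER]]
                            .drop_duplicates().itertuples(index=False)):
            entries.append({COL_SUBJECT: sid, COL_MARKER: marker,
                            "stage": STAGE_HEMOGLOBIN, "reason": "high_hemoglobin"})
        if drop_missing:
            for sid, marker in (df.loc[missing, [COL_SUBJECT, COL_MARKER]]
                                .drop_duplicates().itertuples(index=False)):
                entries.append({COL_SUBJECT: sid, COL_MARKER: marker,
                                "stage": STAGE_HEMOGLOBIN, "reason": "missing_hemoglobin"})
        df = df[~drop]
        # cascade: series reduced below the minimum are no longer usable
        counts = df[df[COL_MARKER] == alpha_syn_marker].groupby(
            [COL_SUBJECT, COL_MARKER]).size()
        bad = counts[counts < min_measurements].index
        if len(bad):
            _log_entries(entries, bad, STAGE_HEMOGLOBIN,
                         "insufficient_visits_after_hemoglobin")
            keep = ~pd.MultiIndex.from_frame(df[[COL_SUBJECT, COL_MARKER]]).isin(bad)
            df = df[keep]
    return df.copy(), entries


def filter_baseline_outliers(df: pd.DataFrame, iqr_multiplier: float = 3.0,
                             quantile_method: str = "linear"):
    """Exclude subject-marker series whose *baseline* value is an extreme outlier.

    A baseline value is an outlier iff it is strictly more than
    ``iqr_multiplier`` interquartile ranges below the first quartile or
    above the third quartile of that marker's baseline distribution.
    Quartiles use linear interpolation between order statistics by
    default. Markers with fewer than 4 baseline values are left
    unfiltered (quartiles undefined), with a warning.
    """
    entries: list[dict] = []
    if df.empty:
        return df.copy(), entries
    base = _baseline_rows(df)
    drop_keys = []
    for marker, sub in base.groupby(COL_MARKER, sort=False):
        vals = sub[COL_VALUE].to_numpy(dtype=float)
        if len(vals) < 4:
            logger.warning("baseline outlier filter skipped for %s: only %d values",
                           marker, len(vals))
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75], method=quantile_method)
        iqr = q3 - q1
        lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        out = (vals < lo) | (vals > hi)  # strict: "more than"
        for sid in sub.loc[out, COL_SUBJECT]:
            drop_keys.append((sid, marker))
    if drop_keys:
        _log_entries(entries, drop_keys, STAGE_BASELINE_OUTLIER, "baseline_outlier")
        keep = ~pd.MultiIndex.from_frame(df[[COL_SUBJECT, COL_MARKER]]).isin(drop_keys)
        df = df[keep]
    return df.copy(), entries


def filter_cognitive_outliers(df: pd.DataFrame, sd_multiplier: float = 4.0,
                              cognitive_markers=COGNITIVE_SCORES):
    """Exclude subjects with a cognitive score beyond the baseline mean +/- k*SD.

    For each cognitive score and group, the reference distribution is the
    group's *baseline* scores (mean, sample SD). Any visit's score strictly
    beyond ``mean +/- sd_multiplier * SD`` excludes that subject's series
    for that score. With SD = 0 only values differing from the mean are
    excluded.
    """
    entries: list[dict] = []
    if df.empty:
        return df.copy(), entries
    base = _baseline_rows(df)
    drop_keys = []
    for (group, marker), sub in df[df[COL_MARKER].isin(cognitive_markers)].groupby(
            [COL_GROUP, COL_MARKER], sort=False):
        ref = base[(base[COL_GROUP] == group) & (base[COL_MARKER] == marker)][COL_VALUE]
        vals = ref.to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1)
        dev = (sub[COL_VALUE] - mean).abs()
        out = dev > sd_multiplier * sd  # strict: "beyond"
        for sid in sub.loc[out, COL_SUBJECT].unique():
            drop_keys.append((sid, marker))
    if drop_keys:
        _log_entries(entries, drop_keys, STAGE_COGNITIVE_OUTLIER, "cognitive_outlier")
        keep = ~pd.MultiIndex.from_frame(df[[COL_SUBJECT, COL_MARKER]]).isin(drop_keys)
        df = df[keep]
    return df.copy(), entries


# ---------------------------------------------------------------------------
# chain and stratification
# ---------------------------------------------------------------------------

def apply_filters(df: pd.DataFrame, config: FilterConfig | None = None) -> FilterResult:
    """Run the full filter chain in its fixed order and build the report.

    Order: min-visits -> hemoglobin -> baseline outlier -> cognitive
    outlier. The report lists one row per excluded subject-marker series
    (or contaminated sample batch) with its stage and reason; the summary
    gives per-stage series counts that add up to input minus output.
    """
    config = config or FilterConfig()
    entries: list[dict] = []

    def n_series(d):
        return 0 if d.empty else d.groupby([COL_SUBJECT, COL_MARKER]).ngroups

    n_in = n_series(df)
    stage_counts = {}

    before = n_series(df)
    df, e = filter_min_visits(df, config.min_measurements)
    entries += e
    stage_counts[STAGE_MIN_VISITS] = before - n_series(df)

    before = n_series(df)
    df, e = filter_hemoglobin(df, config.hemoglobin_cutoff, config.alpha_syn_marker,
                              config.drop_missing_hemoglobin, config.min_measurements)
    entries += e
    stage_counts[STAGE_HEMOGLOBIN] = before - n_series(df)

    before = n_series(df)
    df, e = filter_baseline_outliers(df, config.iqr_multiplier, config.quantile_method)
    entries += e
    stage_counts[STAGE_BASELINE_OUTLIER] = before - n_series(df)

    before = n_series(df)
    df, e = filter_cognitive_outliers(df, config.cognitive_sd_multiplier,
                                      config.cognitive_markers)
    entries += e
    stage_counts[STAGE_COGNITIVE_OUTLIER] = before - n_series(df)

    report = pd.DataFrame(entries, columns=list(REPORT_COLUMNS))
    summary = {
        "series_in": n_in,
        "series_out": n_series(df),
        "series_excluded_by_stage": stage_counts,
    }
    return FilterResult(data=df.reset_index(drop=True), report=report, summary=summary)


STRATUM_PD_ALL = "pd_all"
STRATUM_CONTROL = "control"
STRATUM_PDCU = "pdcu"
STRATUM_PDCI = "pdci"
STRATUM_ABETA_HIGH = "abeta_high"
STRATUM_ABETA_LOW = "abeta_low"


def stratify(covariates: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Assign cognition and amyloid stratum labels per subject.

    PD subjects: cognition is ``pdcu`` iff baseline MoCA > 25 else
    ``pdci``; amyloid is ``abeta_low`` iff baseline CSF amyloid-beta 1-42
    is strictly below 683.45 pg/mL, else ``abeta_high`` (the cut-off value
    itself falls in the high group). Controls get ``control`` in both
    fields. A missing covariate flags the subject ``unclassifiable`` for
    that stratification only.
    """
    config = config or FilterConfig()
    out = []
    for row in covariates.itertuples(index=False):
        sid = getattr(row, COL_SUBJECT)
        group = getattr(row, COL_GROUP)
        if group == GROUP_CONTROL:
            out.append({COL_SUBJECT: sid, "cognition": STRATUM_CONTROL,
                        "abeta": STRATUM_CONTROL})
            continue
        moca = getattr(row, "moca_baseline", np.nan)
        abeta = getattr(row, "abeta_baseline", np.nan)
        if moca is None or (isinstance(moca, float) and np.isnan(moca)):
            cog = "unclassifiable"
        else:
            cog = STRATUM_PDCU if moca > config.moca_cutoff else STRATUM_PDCI
        if abeta is None or (isinstance(abeta, float) and np.isnan(abeta)):
            ab = "unclassifiable"
        else:
            ab = STRATUM_ABETA_LOW if abeta < config.abeta_cutoff else STRATUM_ABETA_HIGH
        out.append({COL_SUBJECT: sid, "cognition": cog, "abeta": ab})
    return pd.DataFrame(out, columns=[COL_SUBJECT, "cognition", "abeta"])


def stratum_subjects(strata: pd.DataFrame, covariates: pd.DataFrame, stratum: str):
    """Subject ids belonging to a named stratum."""
    pd_ids = covariates.loc[covariates[COL_GROUP] == GROUP_PD, COL_SUBJECT]
    if stratum == STRATUM_PD_ALL:
        return set(pd_ids)
    if stratum == STRATUM_CONTROL:
        return set(covariates.loc[covariates[COL_GROUP] == GROUP_CONTROL, COL_SUBJECT])
    if stratum in (STRATUM_PDCU, STRATUM_PDCI):
        return set(strata.loc[strata["cognition"] == stratum, COL_SUBJECT])
    if stratum in (STRATUM_ABETA_HIGH, STRATUM_ABETA_LOW):
        return set(strata.loc[strata["abeta"] == stratum, COL_SUBJECT])
    raise ValueError(f"unknown stratum {stratum!r}")
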