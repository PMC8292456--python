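"""Per-subject linear kinetics: annual change rate and level at motor onset.

Each subject-marker series gets an ordinary least squares fit of marker
value on time. For PD subjects the time axis is disease duration in years,
so the intercept extrapolates the marker level back to motor onset
(duration 0); for controls the time axis is years from baseline and the
intercept is the level at the baseline visit. The slope is the subject's
annual change rate in marker units per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import COL_GROUP, COL_MARKER, COL_SUBJECT, COL_TIME, COL_VALUE

KINETICS_COLUMNS = (COL_SUBJECT, COL_GROUP, COL_MARKER, "rate", "onset_level",
                    "baseline_level", "n_points")


class DegenerateSeriesError(ValueError):
    """All observation times identical; no slope is identifiable."""


@dataclass(frozen=True)
class SubjectKinetics:
    subject_id: str
    marker: str
    rate: float            # marker units / year (OLS slope)
    onset_level: float     # marker units (OLS prediction at time 0)
    baseline_level: float  # first observed value
    n_points: int


def fit_subject_line(times, values) -> tuple[float, float]:
    """Exact OLS slope and intercept of ``values ~ times``.

    Raises :class:`DegenerateSeriesError` when all times coincide and
    ``ValueError`` for fewer than two points.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two measurements")
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0.0:
        raise DegenerateSeriesError("zero_time_variance")
    slope = np.sum((t - tbar) * (v - v.mean())) / sxx
    intercept = v.mean() - slope * tbar
    return float(slope), float(intercept)


def compute_kinetics(df: pd.DataFrame, baseline_stat: str = "first"):
    """Fit every subject-marker series in a long table.

    Returns ``(kinetics, exclusions)``: a DataFrame with one row per
    series (columns ``subject_id, group, marker, rate, onset_level,
    baseline_level, n_points``) and a list of exclusion log entries for
    degenerate series (reason ``zero_time_variance``).

    The regressor is the ``duration_years`` column for both groups; its
    meaning (disease duration for PD, time from baseline for controls) is
    set upstream by the data layout.

    ``baseline_stat`` selects the level each subject's rate is paired with
    in the rate-versus-level regression: ``"first"`` (the first observed
    value, the default) or ``"mean"`` (the mid-interval mean, which pairs
    the span-averaged slope with the span's central level and avoids the
    rate attenuation the first-value pairing incurs on curved
    trajectories).
    """
    if baseline_stat not in ("first", "mean"):
        raise ValueError(f"unknown baseline_stat {baseline_stat!r}")
    rows = []
    exclusions = []
    if df.empty:
        return pd.DataFrame(columns=list(KINETICS_COLUMNS)), exclusions
    for (sid, marker), sub in df.groupby([COL_SUBJECT, COL_MARKER], sort=True):
        sub = sub.sort_values(COL_TIME, kind="stable")
        t = sub[COL_TIME].to_numpy(dtype=float)
        v = sub[COL_VALUE].to_numpy(dtype=float)
        if t.size < 2:
            exclusions.append({COL_SUBJECT: sid, COL_MARKER: marker,
                               "stage": "kinetics", "reason": "insufficient_visits"})
            continue
        try:
            slope, intercept = fit_subject_line(t, v)
        except DegenerateSeriesError:
            exclusions.append({COL_SUBJECT: sid, COL_MARKER: marker,
                               "stage": "kinetics", "reason": "zero_time_variance"})
            continue
        rows.append({COL_SUBJECT: sid, COL_GROUP: sub[COL_GROUP].iloc[0],
                     COL_MARKER: marker, "rate": slope, "onset_level": intercept,
                     "baseline_level": float(v[0] if baseline_stat == "first"
                                              else v.mean()),
                     "n_points": int(t.size)})
    return pd.DataFrame(rows, columns=list(KINETICS_COLUMNS)), exclusions


def onset_anchor(kinetics: pd.DataFrame, stat: str = "mean") -> float:
    """Group anchor level: mean (default) or median of per-subject onset levels."""
    if kinetics.empty:
        raise ValueError("empty group: no kinetics to anchor on")
    levels = kinetics["onset_level"].to_numpy(dtype=float)
    if stat == "mean":
        return float(levels.mean())
    if stat == "median":
        return float(np.median(levels))
    raise ValueError(f"unknown anchor statistic {stat!r}")
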