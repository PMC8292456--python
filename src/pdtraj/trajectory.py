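"""Trajectory integration, control anchoring, z-scoring and summaries.

The fitted rate function f makes each marker's long-term dynamics an
autonomous scalar ODE, dX/dt = f(X). Integrating it with the modified
Euler (Heun predictor-corrector) scheme from the group's mean level at
motor onset gives the estimated trajectory over the window from 5 years
before to 30 years after motor onset: forward from the anchor with step
+h, backward with -h.

Controls have no onset, so their trajectory is integrated on the age axis,
anchored at (median control baseline age, control baseline mean), and then
re-indexed onto the disease-duration axis via
``duration = age - median PD age at motor onset``.

Z-scores standardize any trajectory against the control group's *baseline*
distribution: z(t) = (x(t) - mu_c) / sigma_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ratespline import RateModel, evaluate_rate
from .synthetic import (
    COL_GROUP,
    COL_MARKER,
    COL_SUBJECT,
    COL_TIME,
    COL_VALUE,
    GROUP_CONTROL,
    GROUP_PD,
)

T_MIN_DEFAULT = -5.0
T_MAX_DEFAULT = 30.0
STEP_DEFAULT = 0.01  # years
#: Rate extrapolation corridor: fit_range widened by this fraction of its
#: width on each side; outside it the rate is held at the corridor edge.
CORRIDOR_FRACTION = 0.25


class DivergenceError(RuntimeError):
    """Integration left any plausible range (|x| > 1e6 x anchor scale)."""


@dataclass
class Trajectory:
    """A marker trajectory on a regular grid of years from motor onset."""

    marker: str
    group: str
    times: np.ndarray
    levels: np.ndarray
    z_scores: np.ndarray | None = None
    anchor_time: float = 0.0
    anchor_level: float = float("nan")
    step: float = STEP_DEFAULT
    diagnostics: list = field(default_factory=list)

    def level_at(self, t):
        """Level at arbitrary time(s) by linear interpolation on the grid."""
        return np.interp(t, self.times, self.levels)

    def z_at(self, t):
        if self.z_scores is None:
            raise ValueError("z-scores not computed for this trajectory")
        return np.interp(t, self.times, self.z_scores)

    def to_frame(self, every: float | None = None) -> pd.DataFrame:
        """Tabular view, optionally thinned to one row per ``every`` years."""
        times, levels = self.times, self.levels
        z = self.z_scores
        if every is not None:
            stride = max(int(round(every / self.step)), 1)
            sel = np.arange(0, times.size, stride)
            if sel[-1] != times.size - 1:
                sel = np.append(sel, times.size - 1)
            times, levels = times[sel], levels[sel]
            z = None if z is None else z[sel]
        return pd.DataFrame({
            "marker": self.marker, "stratum": self.group,
            "duration_years": times, "level": levels,
            "z": np.full(times.size, np.nan) if z is None else z,
        })


@dataclass
class ControlReference:
    """Control-group reference moments used for z-scoring and anchoring.

    ``means``/``sds`` hold the per-marker mean and sample SD of control
    *baseline* values; ``median_baseline_age`` is the controls' median age
    at the baseline visit and ``median_pd_aao`` the PD group's median age
    at motor onset (both in years).
    """

    means: dict
    sds: dict
    median_baseline_age: float
    median_pd_aao: float

    def __post_init__(self) -> None:
        for marker, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"control baseline SD must be positive for {marker}")

    @classmethod
    def from_cohort(cls, visits: pd.DataFrame, covariates: pd.DataFrame) -> "ControlReference":
        ctrl = visits[visits[COL_GROUP] == GROUP_CONTROL].reset_index(drop=True)
        idx = ctrl.groupby([COL_SUBJECT, COL_MARKER], sort=False)[COL_TIME].idxmin()
        base = ctrl.loc[idx]
        means = base.groupby(COL_MARKER)[COL_VALUE].mean().to_dict()
        sds = base.groupby(COL_MARKER)[COL_VALUE].std(ddof=1).to_dict()
        degenerate = [m for m, sd in sds.items() if not sd > 0]
        for m in degenerate:  # no spread -> z-scores undefined for this marker
            import logging
            logging.getLogger(__name__).warning(
                "control baseline SD not positive for %s; z-scores disabled", m)
            del sds[m]
        ctrl_cov = covariates[covariates[COL_GROUP] == GROUP_CONTROL]
        pd_cov = covariates[covariates[COL_GROUP] == GROUP_PD]
        return cls(means=means, sds=sds,
                   median_baseline_age=float(ctrl_cov["baseline_age"].median()),
                   median_pd_aao=float(pd_cov["age_at_onset"].median()))


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def heun_step(x: float, h: float, f) -> float:
    """One modified-Euler (Heun) step: x' = x + h/2 [f(x) + f(x + h f(x))].

    Second-order accurate; ``h`` may be negative for backward integration
    into the premotor phase. Non-finite rates abort the step.
    """
    k1 = f(x)
    k2 = f(x + h * k1)
    if not (np.isfinite(k1) and np.isfinite(k2)):
        raise DivergenceError(f"non-finite rate at level {x!r}")
    return x + 0.5 * h * (k1 + k2)


def midpoint_step(x: float, h: float, f) -> float:
    """Explicit midpoint step (the other common 'modified Euler'); also 2nd order."""
    k1 = f(x)
    k2 = f(x + 0.5 * h * k1)
    if not (np.isfinite(k1) and np.isfinite(k2)):
        raise DivergenceError(f"non-finite rate at level {x!r}")
    return x + h * k2

_STEPPERS = {"heun": heun_step, "midpoint": midpoint_step}


def _corridor_rate(f, lo: float, hi: float, events: list):
    """Wrap a rate function so levels outside [lo, hi] use the edge rate."""
    def wrapped(x):
        if x < lo:
            events.append(("clamp_low", float(x)))
            return f(lo)
        if x > hi:
            events.append(("clamp_high", float(x)))
            return f(hi)
        return f(x)
    return wrapped


def integrate_trajectory(model, anchor: float, t_min: float = T_MIN_DEFAULT,
                         t_max: float = T_MAX_DEFAULT, h: float = STEP_DEFAULT,
                         method: str = "heun", marker: str = "", group: str = "",
                         corridor: tuple | None = None) -> Trajectory:
    """Integrate dX/dt = f(X) from the anchor (t=0, X=anchor) over [t_min, t_max].

    ``model`` is a :class:`~pdtraj.ratespline.RateModel` or any callable
    f(x). Forward integration uses step +h, backward -h; the level at t=0
    equals the anchor exactly. For a RateModel the rate is evaluated
    inside an extrapolation corridor (``fit_range`` widened by 25% of its
    width on each side); outside, the rate is held at the corridor edge
    and a diagnostic is recorded — the natural-spline linear tails are not
    trusted far from the data. Integration aborts with
    :class:`DivergenceError` if |X| exceeds 1e6 times the anchor scale.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    if not t_min <= 0.0 <= t_max:
        raise ValueError("anchor time 0 must lie within [t_min, t_max]")
    if not np.isfinite(anchor):
        raise ValueError("anchor level must be finite")
    step_fn = _STEPPERS[method]
    events: list = []
    if isinstance(model, RateModel):
        if corridor is None:
            lo, hi = model.fit_range
            pad = CORRIDOR_FRACTION * (hi - lo)
            corridor = (lo - pad, hi + pad)
        f = _corridor_rate(lambda x: evaluate_rate(model, x), corridor[0],
                           corridor[1], events)
        if not marker:
            marker = model.marker
        if not group:
            group = model.group
    elif corridor is not None:
        f = _corridor_rate(model, corridor[0], corridor[1], events)
    else:
        f = model

    limit = 1e6 * max(abs(anchor), 1.0)
    n_fwd = int(round(t_max / h))
    n_back = int(round(-t_min / h))

    fwd = np.empty(n_fwd + 1)
    fwd[0] = anchor
    for i in range(n_fwd):
        fwd[i + 1] = step_fn(fwd[i], h, f)
        if abs(fwd[i + 1]) > limit:
            raise DivergenceError(
                f"divergence at t={(i + 1) * h:.2f}: level {fwd[i + 1]:.3e}; "
                f"events={events[-5:]}")
    back = np.empty(n_back + 1)
    back[0] = anchor
    for i in range(n_back):
        back[i + 1] = step_fn(back[i], -h, f)
        if abs(back[i + 1]) > limit:
            raise DivergenceError(
                f"divergence at t={-(i + 1) * h:.2f}: level {back[i + 1]:.3e}; "
                f"events={events[-5:]}")

    times = np.concatenate([(-h) * np.arange(n_back, 0, -1), h * np.arange(n_fwd + 1)])
    levels = np.concatenate([back[n_back:0:-1], fwd])
    diagnostics = []
    if events:
        n_lo = sum(1 for kind, _ in events if kind == "clamp_low")
        n_hi = len(events) - n_lo
        diagnostics.append({"event": "rate_clamped", "below": n_lo, "above": n_hi})
    if np.any(levels < 0):
        diagnostics.append({"event": "negative_levels",
                            "min_level": float(levels.min())})
    return Trajectory(marker=marker, group=group, times=times, levels=levels,
                      anchor_time=0.0, anchor_level=float(anchor), step=h,
                      diagnostics=diagnostics)


def anchor_control_trajectory(model_control, ref: ControlReference, marker: str,
                              h: float = STEP_DEFAULT, method: str = "heun") -> Trajectory:
    """Control trajectory integrated in age space and re-indexed by duration.

    The anchor is (median control baseline age, control baseline mean
    level). The age window is chosen so the re-indexed duration axis,
    ``duration = age - median PD age at motor onset``, covers [-5, 30].
    """
    if marker not in ref.means:
        raise ValueError(f"control reference lacks baseline mean for {marker!r}")
    for name in ("median_baseline_age", "median_pd_aao"):
        if not np.isfinite(getattr(ref, name)):
            raise ValueError(f"control reference field {name} missing")
    mu = ref.means[marker]
    offset = ref.median_baseline_age - ref.median_pd_aao  # duration at anchor age
    t_min = T_MIN_DEFAULT - offset
    t_max = T_MAX_DEFAULT - offset
    if not t_min <= 0.0 <= t_max:
        raise ValueError(
            "median control baseline age maps outside the [-5, 30] duration window")
    traj = integrate_trajectory(model_control, mu, t_min=t_min, t_max=t_max, h=h,
                                method=method, marker=marker, group=GROUP_CONTROL)
    return replace(traj, times=traj.times + offset, anchor_time=offset)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def to_zscores(traj: Trajectory, ref: ControlReference,
               marker: str | None = None) -> Trajectory:
    """Standardize a trajectory against the control baseline distribution."""
    marker = marker or traj.marker
    if marker not in ref.sds:
        raise ValueError(f"control reference lacks SD for {marker!r}")
    sigma = ref.sds[marker]
    if not sigma > 0:
        raise ValueError("control baseline SD must be positive")
    z = (traj.levels - ref.means[marker]) / sigma
    return replace(traj, z_scores=z)


def percent_change(traj: Trajectory, t_from: float = 0.0, t_to: float = 30.0) -> float:
    """Percent change of the level between two times: 100 (x(t_to)-x(t_from))/x(t_from)."""
    x0 = float(traj.level_at(t_from))
    x1 = float(traj.level_at(t_to))
    if x0 == 0.0:
        raise ZeroDivisionError("percent change undefined: level at t_from is zero")
    return 100.0 * (x1 - x0) / x0


def find_crossing(traj_a: Trajectory, other, field_name: str = "level"):
    """Earliest time where trajectory A crosses B (trajectory or constant).

    The difference A - B is scanned on A's grid (B interpolated if needed);
    the first sign change is refined by linear interpolation. Returns the
    crossing time in years, or ``None`` when the curves never cross.
    ``field_name`` selects ``level`` or ``z``.
    """
    def values(traj, times):
        if field_name == "level":
            return traj.level_at(times)
        if field_name == "z":
            return traj.z_at(times)
        raise ValueError(f"unknown field {field_name!r}")

    times = traj_a.times
    if isinstance(other, Trajectory):
        lo = max(times.min(), other.times.min())
        hi = min(times.max(), other.times.max())
        times = times[(times >= lo) & (times <= hi)]
        if times.size < 2:
            return None
        diff = values(traj_a, times) - values(other, times)
    else:
        diff = values(traj_a, times) - float(other)

    sign = np.sign(diff)
    if not np.any(sign != 0):
        return None  # identical curves: no crossing
    prev = sign[0]
    for i in range(diff.size - 1):
        s = sign[i + 1]
        if s == 0.0:
            if prev != 0.0:
                return float(times[i + 1])  # touches zero exactly at a grid point
            continue
        if prev == 0.0:
            prev = s  # leading coincident stretch: curves separate here, no sign flip
            continue
        if prev * s < 0:
            t0, t1 = times[i], times[i + 1]
            d0, d1 = diff[i], diff[i + 1]
            return float(t0 + (t1 - t0) * d0 / (d0 - d1))
        prev = s
    return None


def convergence_check(model, anchor: float, h: float, **kwargs) -> float:
    """Max |X_h - X_{h/2}| over the grid — a step-size self-check."""
    a = integrate_trajectory(model, anchor, h=h, **kwargs)
    b = integrate_trajectory(model, anchor, h=h / 2, **kwargs)
    return float(np.max(np.abs(a.levels - b.level_at(a.times))))
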