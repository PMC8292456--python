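"""Population rate-versus-level model via restricted cubic spline regression.

The central modelling step: regress per-subject annual change rates on
per-subject baseline levels with a restricted (natural) cubic spline, giving
a smooth population-level rate function f so that a marker's long-term
dynamics obey the autonomous first-order ODE dX/dt = f(X).

Knots sit at the 5/35/65/95 percentiles of the baseline levels (4 knots)
or, when the fitting sample has fewer than 100 subjects, at the 5/50/95
percentiles (3 knots). The spline basis is the truncated-power natural
spline construction: with knots t_1 < ... < t_K,

    b_1(x) = x
    b_{j+1}(x) = (x-t_j)_+^3
                 - (x-t_{K-1})_+^3 (t_K-t_j)/(t_K-t_{K-1})
                 + (x-t_K)_+^3 (t_{K-1}-t_j)/(t_K-t_{K-1}),   j = 1..K-2,

which is twice continuously differentiable everywhere and exactly linear
outside [t_1, t_K]. Nonlinear columns may be rescaled by (t_K-t_1)^2 for
conditioning; fitted values are invariant to that choice because the
column span is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

KNOT_PERCENTILES_4 = (5.0, 35.0, 65.0, 95.0)
KNOT_PERCENTILES_3 = (5.0, 50.0, 95.0)
SMALL_SAMPLE_THRESHOLD = 100  # below this subject count, use 3 knots


class DegenerateKnotsError(ValueError):
    """Percentile knots coincide even after the 3-knot fallback."""


class RankDeficientError(ValueError):
    """Spline design matrix is rank-deficient."""


def place_knots(levels, n_subjects: int | None = None,
                quantile_method: str = "linear") -> np.ndarray:
    """Percentile-based knot locations for the rate-level spline.

    4 knots at the 5/35/65/95 percentiles when the sample has at least
    100 subjects, otherwise 3 knots at 5/50/95. Percentiles use linear
    interpolation between order statistics. Falls back from 4 to 3 knots
    if percentile ties make knots coincide; raises
    :class:`DegenerateKnotsError` if even 3 knots coincide.
    """
    levels = np.asarray(levels, dtype=float)
    if np.unique(levels).size < 10:
        raise ValueError("need at least 10 distinct baseline levels to place knots")
    n = len(levels) if n_subjects is None else int(n_subjects)
    pcts = KNOT_PERCENTILES_4 if n >= SMALL_SAMPLE_THRESHOLD else KNOT_PERCENTILES_3
    knots = np.quantile(levels, np.asarray(pcts) / 100.0, method=quantile_method)
    if np.any(np.diff(knots) <= 0) and len(pcts) == 4:
        knots = np.quantile(levels, np.asarray(KNOT_PERCENTILES_3) / 100.0,
                            method=quantile_method)
    if np.any(np.diff(knots) <= 0):
        raise DegenerateKnotsError("degenerate_knots: percentile knots coincide")
    return knots


def rcs_basis(x, knots, normalize: bool = True) -> np.ndarray:
    """Restricted cubic spline basis matrix, shape ``(n, K-1)``.

    Column 0 is x itself; columns 1..K-2 are the truncated-power natural
    spline terms. With ``normalize=True`` the nonlinear columns are divided
    by ``(t_K - t_1)**2`` (better conditioning; identical fitted values).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    if knots.size < 3 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be >= 3 strictly increasing values")
    K = knots.size
    t_km1, t_k = knots[-2], knots[-1]
    denom = t_k - t_km1
    cols = [x]
    for j in range(K - 2):
        tj = knots[j]
        term = (np.clip(x - tj, 0.0, None) ** 3
                - np.clip(x - t_km1, 0.0, None) ** 3 * (t_k - tj) / denom
                + np.clip(x - t_k, 0.0, None) ** 3 * (t_km1 - tj) / denom)
        if normalize:
            term = term / (knots[-1] - knots[0]) ** 2
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class RateModel:
    """Fitted rate-versus-level function for one marker and stratum.

    ``intercept`` and ``coefs`` parameterize
    f(x) = intercept + rcs_basis(x, knots) @ coefs. ``fit_range`` is the
    [min, max] of the baseline levels the model was fitted on — the region
    where f is data-supported; beyond it the natural linear tails
    extrapolate (the trajectory solver clamps far extrapolation).
    """

    marker: str
    group: str
    knots: np.ndarray
    intercept: float
    coefs: np.ndarray
    fit_range: tuple
    n_subjects: int
    normalized: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __call__(self, x):
        return evaluate_rate(self, x)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "group": self.group,
            "knots": [float(v) for v in self.knots],
            "intercept": float(self.intercept),
            "coefs": [float(v) for v in self.coefs],
            "fit_range": [float(self.fit_range[0]), float(self.fit_range[1])],
            "n_subjects": int(self.n_subjects),
            "normalized": bool(self.normalized),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        return cls(marker=d["marker"], group=d["group"],
                   knots=np.asarray(d["knots"], dtype=float),
                   intercept=float(d["intercept"]),
                   coefs=np.asarray(d["coefs"], dtype=float),
                   fit_range=(float(d["fit_range"][0]), float(d["fit_range"][1])),
                   n_subjects=int(d["n_subjects"]),
                   normalized=bool(d.get("normalized", True)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def fit_rate_model(baseline_levels, rates, knots=None, n_subjects=None,
                   normalize: bool = True, marker: str = "", group: str = "",
                   quantile_method: str = "linear") -> RateModel:
    """OLS fit of annual change rate on the spline basis of baseline level.

    ``knots`` defaults to :func:`place_knots` on the baseline levels.
    Raises :class:`RankDeficientError` (with the design condition number)
    when the design matrix does not have full column rank.
    """
    x = np.asarray(baseline_levels, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size != y.size:
        raise ValueError("baseline_levels and rates must have equal length")
    if knots is None:
        knots = place_knots(x, n_subjects=n_subjects, quantile_method=quantile_method)
    knots = np.asarray(knots, dtype=float)
    if x.size < knots.size + 1:
        raise ValueError("need at least K+1 subjects to fit a K-knot model")
    basis = rcs_basis(x, knots, normalize=normalize)
    design = np.column_stack([np.ones(x.size), basis])
    cond = np.linalg.cond(design)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise RankDeficientError(
            f"rank-deficient spline design (rank {rank} < {design.shape[1]}, "
            f"condition number {cond:.3e})")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return RateModel(marker=marker, group=group, knots=knots,
                     intercept=float(beta[0]), coefs=beta[1:].copy(),
                     fit_range=(float(x.min()), float(x.max())),
                     n_subjects=int(n_subjects if n_subjects is not None else x.size),
                     normalized=normalize,
                     diagnostics={"condition_number": float(cond)})


def evaluate_rate(model: RateModel, x):
    """Fitted annual change rate f(x); scalar in, scalar out."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    basis = rcs_basis(x, model.knots, normalize=model.normalized)
    out = model.intercept + basis @ model.coefs
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class RateRoot:
    level: float
    stable: bool  # f' < 0 at the root: trajectories plateau here


def rate_roots(model: RateModel, n_grid: int = 2001, tol: float = 1e-9):
    """Zero crossings of the fitted rate curve within ``fit_range``.

    Sign changes on a dense level grid are refined by bisection (brentq)
    until |f| < ``tol``; each root is labelled stable (f' < 0) or unstable.
    Returns a possibly empty list of :class:`RateRoot`.
    """
    lo, hi = model.fit_range
    grid = np.linspace(lo, hi, n_grid)
    f = evaluate_rate(model, grid)
    if np.max(np.abs(f)) <= tol:
        return []  # rate indistinguishable from zero: no isolated roots
    roots: list[RateRoot] = []
    h_deriv = max((hi - lo) / n_grid, 1e-9)
    for i in range(n_grid - 1):
        a, b = f[i], f[i + 1]
        if a == 0.0 and b == 0.0:
            continue  # identically-zero stretch, no isolated root
        if a == 0.0:
            level = grid[i]
        elif a * b < 0:
            level = optimize.brentq(lambda z: evaluate_rate(model, z),
                                    grid[i], grid[i + 1], xtol=1e-12, rtol=1e-15)
        else:
            continue
        if abs(evaluate_rate(model, level)) > tol:
            continue
        deriv = (evaluate_rate(model, level + h_deriv)
                 - evaluate_rate(model, level - h_deriv)) / (2 * h_deriv)
        if roots and abs(level - roots[-1].level) < 10 * h_deriv:
            continue
        roots.append(RateRoot(level=float(level), stable=bool(deriv < 0)))
    if f[-1] == 0.0 and (not roots or abs(grid[-1] - roots[-1].level) > 10 * h_deriv):
        deriv = (evaluate_rate(model, grid[-1]) - evaluate_rate(model, grid[-1] - h_deriv)) / h_deriv
        roots.append(RateRoot(level=float(grid[-1]), stable=bool(deriv < 0)))
    return roots


def rate_curve_table(model: RateModel, n_points: int = 200):
    """(level, fitted rate) grid over ``fit_range`` for export/plotting."""
    import pandas as pd

    lo, hi = model.fit_range
    levels = np.linspace(lo, hi, n_points)
    return pd.DataFrame({"marker": model.marker, "stratum": model.group,
                         "level": levels, "rate": evaluate_rate(model, levels)})
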