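"""Asymptotic season-detectability curve: fitting and design inversion.

Season detectability as a function of season length S is modelled by the
saturating form p*(S) = A (1 - exp(-R S)) with horizontal asymptote
A in [0, 1] and rate R > 0 per day. Fitting is bounded nonlinear least
squares with the analytic Jacobian; 95% confidence intervals are Wald
t-intervals from the Gauss-Newton covariance at the solution (the standard
nls-style intervals). The inverse S(p*) = -ln(1 - p*/A) / R supports design
planning: the minimum season length needed to reach a target season
detectability, infinite when the target exceeds the asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CURVE_FIT_COLUMNS",
    "FitError",
    "CurveFit",
    "detectability_curve",
    "fit_detectability_curve",
    "invert_curve",
    "fit_by_design",
]

CURVE_FIT_COLUMNS = [
    "species_id",
    "array_size",
    "A_hat",
    "A_lo",
    "A_hi",
    "R_hat",
    "R_lo",
    "R_hi",
    "rss",
    "converged",
    "n_points",
]

_R_FLOOR = 1e-9


class FitError(ValueError):
    """Raised when curve fitting is attempted on unusable inputs."""


@dataclass(frozen=True)
class CurveFit:
    """Fitted saturating detectability curve for one species x array size."""

    A: float
    R: float
    ci_A: tuple[float, float]
    ci_R: tuple[float, float]
    rss: float
    converged: bool
    n_points: int
    species_id: str | None = None
    array_size: int | None = None

    def predict(self, season_length: "float | np.ndarray") -> "float | np.ndarray":
        return detectability_curve(season_length, self.A, self.R)


def detectability_curve(season_length, A: float, R: float):
    """Season detectability p* = A (1 - exp(-R S)) at season length S days."""
    return A * (1.0 - np.exp(-R * np.asarray(season_length, dtype=float)))


def _initial_guess(S: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """A0 = max observed p* (clipped); R0 from log-linearizing the smallest-S points."""
    A0 = float(np.clip(y.max(), 1e-6, 1.0))
    order = np.argsort(S, kind="stable")
    R0 = None
    vals = []
    for i in order[:2]:
        frac = y[i] / A0
        if 0.0 < frac < 1.0 and S[i] > 0:
            vals.append(-math.log1p(-frac) / S[i])
    if vals:
        R0 = float(np.mean(vals))
    if R0 is None or not np.isfinite(R0) or R0 <= 0:
        R0 = 1.0 / float(np.mean(S[S > 0])) if (S > 0).any() else 0.01
    return A0, R0


def fit_detectability_curve(
    season_lengths,
    p_star,
    init: tuple[float, float] | None = None,
    species_id: str | None = None,
    array_size: int | None = None,
) -> CurveFit:
    """Bounded least-squares fit of p* = A (1 - exp(-R S)).

    Requires at least 3 distinct season lengths and p* values in [0, 1].
    Degenerate data (all p* = 0, which leaves R unidentified) yields a
    result with ``converged=False`` and NaN intervals rather than silent
    defaults. Confidence intervals are 95% Wald t-intervals with
    sigma^2 = RSS / (n - 2).
    """
    S = np.asarray(season_lengths, dtype=float)
    y = np.asarray(p_star, dtype=float)
    if S.shape != y.shape or S.ndim != 1:
        raise FitError("season_lengths and p_star must be 1-d arrays of equal length")
    if np.unique(S).size < 3:
        raise FitError("need at least 3 distinct season lengths")
    if ((y < 0) | (y > 1)).any() or not np.isfinite(y).all():
        raise FitError("p_star values must lie in [0, 1]")
    if (S < 0).any():
        raise FitError("season lengths must be >= 0")
    n = S.size

    if not (y > 0).any():
        return CurveFit(
            A=0.0, R=float("nan"), ci_A=(float("nan"), float("nan")),
            ci_R=(float("nan"), float("nan")), rss=0.0, converged=False,
            n_points=n, species_id=species_id, array_size=array_size,
        )

    A0, R0 = init if init is not None else _initial_guess(S, y)
    A0 = float(np.clip(A0, 1e-6, 1.0))
    R0 = float(max(R0, _R_FLOOR * 10))

    def resid(theta: np.ndarray) -> np.ndarray:
        A, R = theta
        return A * (1.0 - np.exp(-R * S)) - y

    def jac(theta: np.ndarray) -> np.ndarray:
        A, R = theta
        e = np.exp(-R * S)
        return np.column_stack([1.0 - e, A * S * e])

    sol = optimize.least_squares(
        resid, x0=[A0, R0], jac=jac,
        bounds=([0.0, _R_FLOOR], [1.0, np.inf]),
        ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    A_hat, R_hat = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    converged = bool(sol.success) and np.isfinite(rss)

    ci_A = ci_R = (float("nan"), float("nan"))
    if converged and n > 2:
        J = jac(sol.x)
        JtJ = J.T @ J
        try:
            cov = np.linalg.inv(JtJ) * (rss / (n - 2))
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            tcrit = stats.t.ppf(0.975, df=n - 2)
            ci_A = (A_hat - tcrit * se[0], A_hat + tcrit * se[0])
            ci_R = (R_hat - tcrit * se[1], R_hat + tcrit * se[1])
        except np.linalg.LinAlgError:
            converged = False
    return CurveFit(
        A=A_hat, R=R_hat, ci_A=ci_A, ci_R=ci_R, rss=rss,
        converged=converged, n_points=n,
        species_id=species_id, array_size=array_size,
    )


def invert_curve(fit: CurveFit, target_p_star: float) -> float:
    """Minimum season length (days) at which the fitted curve reaches the target.

    Returns ``math.inf`` when the target is at or above the asymptote
    (unreachable for any season length). Raises on unconverged fits.
    """
    if not fit.converged:
        raise FitError("cannot invert an unconverged fit")
    if not 0.0 < target_p_star < 1.0:
        raise ValueError("target_p_star must lie strictly in (0, 1)")
    if target_p_star >= fit.A:
        return math.inf
    return -math.log1p(-target_p_star / fit.A) / fit.R


def fit_by_design(
    mc_results: pd.DataFrame,
    binning: bool = False,
    bin_width_days: int = 7,
) -> pd.DataFrame:
    """Fit the season-detectability curve per (species, array size).

    Fits to per-iteration (S, p*) points by default; with ``binning`` the
    points are first averaged within season-length bins of
    ``bin_width_days``, which de-weights heavily sampled season lengths.
    Returns a tidy table with columns :data:`CURVE_FIT_COLUMNS`; groups with
    too few distinct season lengths or degenerate data appear with
    ``converged=False``.
    """
    rows = []
    for (species, m), grp in mc_results.groupby(["species_id", "array_size"], sort=True):
        S = grp["season_length"].to_numpy(dtype=float)
        y = grp["p_star"].to_numpy(dtype=float)
        if binning:
            bins = (S - 1) // bin_width_days
            agg = pd.DataFrame({"bin": bins, "S": S, "y": y}).groupby("bin").mean()
            S, y = agg["S"].to_numpy(), agg["y"].to_numpy()
        try:
            fit = fit_detectability_curve(S, y, species_id=species, array_size=int(m))
        except FitError:
            fit = CurveFit(
                A=float("nan"), R=float("nan"),
                ci_A=(float("nan"), float("nan")), ci_R=(float("nan"), float("nan")),
                rss=float("nan"), converged=False, n_points=len(S),
                species_id=species, array_size=int(m),
            )
        rows.append(
            (species, int(m), fit.A, fit.ci_A[0], fit.ci_A[1],
             fit.R, fit.ci_R[0], fit.ci_R[1], fit.rss, fit.converged, fit.n_points)
        )
    return pd.DataFrame(rows, columns=CURVE_FIT_COLUMNS)
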