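"""Thermal-inactivation kinetics.

Irreversible heat inactivation of the enzyme follows second-order kinetics
in residual activity,

    1/A(t) = 1/A0 + kd * t,

with A in percent of the untreated control and kd in %^-1 min^-1.  The fit
is ordinary least squares in the linearized space (t, 1/A) — the same
regression whose slope, intercept and R^2 a plot of 1/RA versus time
reports.  With percent units the half-life (time for A to fall from 100 to
50) is t_1/2 = 1/(100*kd).

The temperature that halves activity within a fixed incubation (T50) is the
inflection point of a sigmoidal Boltzmann fit to residual activity versus
incubation temperature.  Differences in the apparent activation free energy
of inactivation between a variant and WT are computed from retained
activities after the same heat treatment:

    ddG = R*T*ln[ (1-RA_wt)*RA_var / ((1-RA_var)*RA_wt) ],

positive when the variant retains more activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import ActivityDecaySeries, TemperatureActivitySeries, R_J
from .errors import FitError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class SecondOrderFit:
    """OLS fit of 1/A vs t: slope kd (%^-1 min^-1), intercept 1/A0 (%^-1)."""

    kd: float
    inv_a0: float
    r2: float
    se_kd: float

    @property
    def a0(self) -> float:
        return 1.0 / self.inv_a0


@dataclass(frozen=True)
class BoltzmannFit:
    """Sigmoid RA(T) = lower + (upper - lower)/(1 + exp((T - t50)/width))."""

    t50: float
    width: float
    upper: float
    lower: float
    se_t50: float
    r2: float


def fit_second_order(series: ActivityDecaySeries, weighted: bool = False) -> SecondOrderFit:
    """Fit the linearized second-order decay model to one decay series.

    R^2 is reported in the transformed (1/A) space, matching how the
    regression is usually printed alongside 1/RA-vs-time lines.  The
    default is plain OLS; ``weighted=True`` uses weights proportional to
    A^4, the delta-method variance of 1/A under homoscedastic noise on A.
    """
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 decay points")
    if np.any(series.activities <= 0):
        raise ValidationError("all activities must be positive for the 1/A transform")
    t = series.times
    inv_a = 1.0 / series.activities
    if weighted:
        w = series.activities**4
        wsum = w.sum()
        tb, yb = (w * t).sum() / wsum, (w * inv_a).sum() / wsum
        slope = (w * (t - tb) * (inv_a - yb)).sum() / (w * (t - tb) ** 2).sum()
        intercept = yb - slope * tb
        resid = inv_a - (intercept + slope * t)
        dof = len(t) - 2
        s2 = (w * resid**2).sum() / dof if dof > 0 else math.nan
        se = math.sqrt(s2 / (w * (t - tb) ** 2).sum())
        sst = (w * (inv_a - yb) ** 2).sum()
        r2 = 1.0 - (w * resid**2).sum() / sst if sst > 0 else math.nan
        return SecondOrderFit(kd=float(slope), inv_a0=float(intercept), r2=float(r2), se_kd=se)
    res = stats.linregress(t, inv_a)
    r2 = float(res.rvalue**2) if len(t) > 2 else 1.0
    return SecondOrderFit(
        kd=float(res.slope),
        inv_a0=float(res.intercept),
        r2=r2,
        se_kd=float(res.stderr),
    )


def half_life(kd: float) -> float:
    """Half-life in minutes from a second-order rate constant in %^-1 min^-1.

    With activity in percent, A drops from A0=100 to 50 after
    t = (1/50 - 1/100)/kd = 1/(100*kd).
    """
    if kd <= 0:
        raise ValidationError(f"half-life undefined for kd={kd} (no decay)")
    return 1.0 / (100.0 * kd)


def retained_activity(fit: SecondOrderFit, t: float) -> float:
    """Predicted residual activity (%) at time t (min) under the fitted model."""
    if t < 0:
        raise ValidationError("time must be non-negative")
    return 1.0 / (fit.inv_a0 + fit.kd * t)


def _boltzmann(T, upper, lower, t50, width):
    return lower + (upper - lower) / (1.0 + np.exp((T - t50) / width))


def fit_t50(series: TemperatureActivitySeries) -> BoltzmannFit:
    """Fit a Boltzmann sigmoid to residual activity vs incubation temperature.

    T50 is the inflection point; it is bounded to the measured temperature
    range.  Initial guesses: plateaus from the data extremes, T50 at the
    steepest observed descent, width 2 deg C.
    """
    if len(series) < 6:
        raise InsufficientDataError("need at least 6 points spanning both plateaus")
    T, ra = series.temperatures, series.activities
    upper0, lower0 = float(ra.max()), float(ra.min())
    drops = np.diff(ra) / np.diff(T)
    t50_0 = float(T[:-1][np.argmin(drops)] + 0.5 * np.diff(T)[np.argmin(drops)])
    p0 = [upper0, lower0, t50_0, 2.0]
    bounds = (
        [-np.inf, -np.inf, float(T.min()), 1e-6],
        [np.inf, np.inf, float(T.max()), float(T.max() - T.min())],
    )
    try:
        popt, pcov = optimize.curve_fit(_boltzmann, T, ra, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError("Boltzmann fit did not converge", {"p0": p0}) from exc
    resid = ra - _boltzmann(T, *popt)
    ss_tot = float(np.sum((ra - ra.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    se = np.sqrt(np.diag(pcov))
    if popt[1] >= popt[0]:
        raise FitError("fitted lower plateau not below upper plateau", {"popt": popt.tolist()})
    return BoltzmannFit(
        t50=float(popt[2]),
        width=float(popt[3]),
        upper=float(popt[0]),
        lower=float(popt[1]),
        se_t50=float(se[2]),
        r2=r2,
    )


def ddg_inactivation(ra_wt: float, ra_var: float, temp_k: float = 333.15) -> float:
    """Deactivation free-energy change of a variant vs WT, in kJ mol^-1.

    Both retained activities are fractions in (0, 1) after the same heat
    treatment; ``temp_k`` defaults to the 60 deg C incubation.  Positive
    values mean the variant inactivates more slowly than WT.
    """
    for name, ra in (("ra_wt", ra_wt), ("ra_var", ra_var)):
        if not 0.0 < ra < 1.0:
            raise ValidationError(f"{name}={ra} must lie strictly in (0, 1)")
    return (
        R_J
        * temp_k
        * math.log(((1.0 - ra_wt) * ra_var) / ((1.0 - ra_var) * ra_wt))
        / 1000.0
    )
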