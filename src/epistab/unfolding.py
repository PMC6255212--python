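"""Two-state thermal unfolding and aggregation-onset analysis.

A thermal melt monitored by the intrinsic-fluorescence 350/330 nm ratio is
fitted to the two-state (van't Hoff) transition model

    I(T) = [I_N + a*T + (I_D + b*T) * K(T)] / (1 + K(T)),
    K(T) = exp[(dHvh / R) * (1/Tm - 1/T)],

with linear native and denatured baselines, temperatures in Kelvin, dHvh in
kcal mol^-1, and R = 1.987 cal mol^-1 K^-1.  The van't Hoff entropy is
always the derived quantity dSvh = dHvh / Tm, and the unfolded mole
fraction at any temperature is f(T) = K(T) / (1 + K(T)) (0.5 at Tm).

The aggregation-onset temperature Tagg is read from the simultaneous
static-light-scattering channel: the trace is flat until intermolecular
assembly begins, then rises steeply.  Since instrument counts are in
arbitrary units, the detector here is affine-invariant: a rise is declared
at the first run of consecutive points above the pre-transition baseline
plus a multiple of its scatter, and the onset is the back-extrapolated
intersection of the rise line with the baseline level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import MeltSeries, R_CAL, celsius_to_kelvin, kelvin_to_celsius
from .errors import FitError, InsufficientDataError, ValidationError

_R_KCAL = R_CAL / 1000.0  # kcal mol^-1 K^-1


@dataclass(frozen=True)
class TwoStateFit:
    """Parameters of the two-state melt fit; Tm in deg C, dHvh in kcal/mol.

    Baseline intercepts ``i_n``/``i_d`` refer to the Kelvin temperature axis
    used internally; slopes ``a``/``b`` are signal per degree (identical in
    K and C).
    """

    tm: float
    dhvh: float
    i_n: float
    a: float
    i_d: float
    b: float
    se: dict
    r2: float
    in_range: bool = True

    @property
    def dsvh(self) -> float:
        return svh(self.dhvh, celsius_to_kelvin(self.tm))


def equilibrium_constant(dhvh: float, tm_k: float, t_k: np.ndarray | float):
    """Unfolding equilibrium constant K(T) of the two-state model."""
    return np.exp((dhvh / _R_KCAL) * (1.0 / tm_k - 1.0 / np.asarray(t_k, float)))


def two_state_signal(t_k, i_n, a, i_d, b, dhvh, tm_k):
    """Observed melt signal for given baselines and transition parameters."""
    k = equilibrium_constant(dhvh, tm_k, t_k)
    return (i_n + a * t_k + (i_d + b * t_k) * k) / (1.0 + k)


def svh(dhvh: float, tm_k: float) -> float:
    """van't Hoff entropy dSvh = dHvh / Tm, in kcal mol^-1 K^-1 (Tm in K)."""
    if tm_k <= 0:
        raise ValidationError("Tm must be positive Kelvin")
    return dhvh / tm_k


def fraction_unfolded(dhvh: float, tm_k: float, t_k) -> float:
    """Unfolded mole fraction f(T) = K/(1+K); strictly increasing in T."""
    if tm_k <= 0 or np.any(np.asarray(t_k) <= 0):
        raise ValidationError("temperatures must be positive Kelvin")
    k = equilibrium_constant(dhvh, tm_k, t_k)
    return k / (1.0 + k)


def fit_two_state(series: MeltSeries) -> TwoStateFit:
    """Fit the two-state melt model to a fluorescence-ratio melt series.

    Initialization: baselines by OLS over the first and last 15% of points,
    Tm at the steepest point of the smoothed signal derivative, dHvh start
    100 kcal/mol.  Tm is bounded to the measured range; a transition whose
    fitted midpoint sits on the boundary is flagged ``in_range=False``.
    """
    if series.ratio is None:
        raise ValidationError("melt series lacks a fluorescence-ratio channel")
    if len(series) < 10:
        raise InsufficientDataError("need at least 10 melt points")
    t_k = celsius_to_kelvin(series.temperatures)
    y = series.ratio
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(float(y.mean()))):
        raise FitError("no transition amplitude in melt signal", {"span": span})

    n_edge = max(3, int(0.15 * len(y)))
    lo = stats.linregress(t_k[:n_edge], y[:n_edge])
    hi = stats.linregress(t_k[-n_edge:], y[-n_edge:])
    dy = np.gradient(np.convolve(y, np.ones(3) / 3.0, mode="same"), t_k)
    tm0 = float(t_k[np.argmax(np.abs(dy))])
    tm0 = min(max(tm0, float(t_k[1])), float(t_k[-2]))
    p0 = [lo.intercept, lo.slope, hi.intercept, hi.slope, 100.0, tm0]
    bounds = (
        [-np.inf, -np.inf, -np.inf, -np.inf, 1e-3, float(t_k[0])],
        [np.inf, np.inf, np.inf, np.inf, 5000.0, float(t_k[-1])],
    )
    try:
        popt, pcov = optimize.curve_fit(
            two_state_signal, t_k, y, p0=p0, bounds=bounds, maxfev=40000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError("two-state fit did not converge", {"p0": p0}) from exc
    resid = y - two_state_signal(t_k, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    perr = np.sqrt(np.diag(pcov))
    i_n, a, i_d, b, dhvh, tm_k_fit = popt
    in_range = t_k[0] + 1e-6 < tm_k_fit < t_k[-1] - 1e-6
    return TwoStateFit(
        tm=kelvin_to_celsius(float(tm_k_fit)),
        dhvh=float(dhvh),
        i_n=float(i_n),
        a=float(a),
        i_d=float(i_d),
        b=float(b),
        se={"tm": float(perr[5]), "dhvh": float(perr[4])},
        r2=r2,
        in_range=bool(in_range),
    )


def detect_tagg(
    series: MeltSeries,
    trigger_sd: float = 5.0,
    run_length: int = 3,
    baseline_points: int = 5,
) -> float | None:
    """Aggregation-onset temperature from an SLS trace, in deg C.

    The pre-aggregation baseline (mean and SD) is estimated from the first
    ``baseline_points`` points and extended forward while points stay below
    the trigger level ``mean + trigger_sd * SD``.  A rise is the first run of
    ``run_length`` consecutive points above that level; the onset is where
    the OLS line through the rise run crosses the baseline mean.  Returns
    None when no rise occurs in the measured range.  Invariant to affine
    rescaling of the counts.
    """
    if series.sls is None:
        raise ValidationError("melt series lacks an SLS channel")
    t, y = series.temperatures, series.sls
    if len(t) < 10:
        raise InsufficientDataError("need at least 10 SLS points")
    if baseline_points < 2:
        raise ValidationError("baseline needs at least 2 points")

    base = y[:baseline_points]
    mean, sd = float(base.mean()), float(base.std(ddof=1))
    # floor the SD so a noiseless (exactly flat) baseline still triggers
    sd = max(sd, 1e-9 * max(float(y.max() - y.min()), 1.0))
    level = mean + trigger_sd * sd

    above = y > level
    start = None
    for i in range(len(y) - run_length + 1):
        if above[i : i + run_length].all():
            start = i
            break
    if start is None:
        return None
    if start == 0:
        raise ValidationError("SLS signal rises at the first point; no baseline to extrapolate")
    if start < baseline_points:
        base = y[:start]
        mean = float(base.mean())

    end = start
    while end < len(y) and above[end]:
        end += 1
    rise = stats.linregress(t[start:end], y[start:end]) if end - start >= 2 else None
    if rise is None or rise.slope <= 0:
        raise FitError("rise segment is not increasing", {"start": int(start), "end": int(end)})
    base_slope = stats.linregress(t[: max(start, 2)], y[: max(start, 2)]).slope
    if base_slope > 0.5 * rise.slope:
        raise ValidationError("no flat pre-aggregation baseline before the rise")
    onset = float((mean - rise.intercept) / rise.slope)
    # a noisy trigger can back-extrapolate slightly outside the scanned range
    return float(min(max(onset, t[0]), t[-1]))
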