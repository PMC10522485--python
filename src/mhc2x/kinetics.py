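"""Peptide-exchange kinetics from fluorescence-polarization traces.

Dissociation traces are fitted with a floating-baseline single
exponential (rebinding is negligible under large competitor excess);
association traces yield initial velocities from an early linear window.
The DM-susceptibility statistic and the mean-threshold allotype grouping
are computed from the fitted rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .synthetic import KineticTrace

__all__ = [
    "RateEstimate",
    "SusceptibilityRecord",
    "fit_dissociation",
    "fit_initial_velocity",
    "dm_susceptibility",
    "classify_allotypes",
    "summarize_replicates",
]


@dataclass
class RateEstimate:
    """Fitted rate (per minute) or initial velocity (signal units per minute)."""

    rate: float
    stderr: float
    residual_variance: float = 0.0
    converged: bool = True
    warning: str | None = None
    params: dict = field(default_factory=dict)


@dataclass
class SusceptibilityRecord:
    allotype: str
    dm_susceptibility: float  # µM⁻¹ min⁻¹
    group: str | None = None  # "high" | "low"


def _validate_trace(trace: KineticTrace, mode: str) -> None:
    if trace.mode != mode:
        raise InvalidParameterError(f"trace mode must be {mode!r}, got {trace.mode!r}")
    if trace.times.size < 5:
        raise InsufficientDataError("kinetic trace needs at least 5 points")


def fit_dissociation(trace: KineticTrace) -> RateEstimate:
    """Fit baseline + amplitude·exp(−k·t); return k with its standard error."""
    _validate_trace(trace, "dissociation")
    t, y = trace.times, trace.signal
    span = np.ptp(y)
    if span == 0:
        return RateEstimate(rate=0.0, stderr=0.0, residual_variance=0.0,
                            converged=True, warning="flat trace; rate set to 0")

    def model(tt, baseline, amplitude, k):
        return baseline + amplitude * np.exp(-k * tt)

    # crude rate guess from the signal half-life
    y0, yend = y[0], y[-1]
    half = yend + 0.5 * (y0 - yend)
    below = np.nonzero(y <= half)[0] if y0 > yend else np.nonzero(y >= half)[0]
    t_half = t[below[0]] if below.size else t[-1] / 2 or 1.0
    k0 = np.log(2.0) / max(t_half, 1e-9)
    p0 = [yend, y0 - yend, k0]
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError("dissociation fit did not converge",
                              {"p0": p0, "reason": str(exc)}) from exc
    baseline, amplitude, k = popt
    resid = y - model(t, *popt)
    dof = max(t.size - 3, 1)
    rv = float(resid @ resid / dof)
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.inf
    warning = None
    if k < 0:
        warning = "negative rate fitted; treating as 0"
        k = 0.0
    return RateEstimate(rate=float(k), stderr=se, residual_variance=rv,
                        converged=True, warning=warning,
                        params={"baseline": float(baseline), "amplitude": float(amplitude)})


def fit_initial_velocity(trace: KineticTrace, early_fraction: float = 0.2) -> RateEstimate:
    """OLS slope over the early window of an association trace.

    The window holds all points before the signal rises past
    ``early_fraction`` of the final plateau (relative to the start), but
    never fewer than 4 points.
    """
    _validate_trace(trace, "association")
    if not 0 < early_fraction < 1:
        raise InvalidParameterError("early_fraction must be in (0, 1)")
    t, y = trace.times, trace.signal
    y0, yend = y[0], y[-1]
    rising = yend >= y0
    cut = y0 + early_fraction * (yend - y0)
    mask = (y <= cut) if rising else (y >= cut)
    # window is a prefix: stop at the first point beyond the cut
    beyond = np.nonzero(~mask)[0]
    n_early = beyond[0] if beyond.size else t.size
    n_early = max(n_early, 4)
    if t.size < 4:
        raise InsufficientDataError("need at least 4 points for the initial window")
    n_early = min(n_early, t.size)
    tw, yw = t[:n_early], y[:n_early]
    A = np.vstack([tw, np.ones_like(tw)]).T
    coef, res, _, _ = np.linalg.lstsq(A, yw, rcond=None)
    slope, intercept = coef
    dof = max(n_early - 2, 1)
    rv = float(res[0] / dof) if res.size else 0.0
    sxx = np.sum((tw - tw.mean()) ** 2)
    se = float(np.sqrt(rv / sxx)) if sxx > 0 else np.inf
    warning = "negative initial velocity" if slope < 0 else None
    return RateEstimate(rate=float(slope), stderr=se, residual_variance=rv,
                        converged=True, warning=warning,
                        params={"intercept": float(intercept), "n_points": int(n_early)})


def dm_susceptibility(k_off_dm: float, k_off_in: float, dm_conc: float) -> float:
    """(k_off,DM − k_off,in) / [DM], in µM⁻¹ min⁻¹ for [DM] in µM."""
    if dm_conc <= 0:
        raise InvalidParameterError("dm_conc must be positive")
    return (k_off_dm - k_off_in) / dm_conc


def classify_allotypes(records: list[SusceptibilityRecord]) -> tuple[list[SusceptibilityRecord], float]:
    """Split allotypes at the arithmetic-mean susceptibility.

    Strictly above the mean → "high"; at or below → "low". Returns the
    annotated records (new objects) and the threshold used.
    """
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records to classify")
    values = np.array([r.dm_susceptibility for r in records], dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("susceptibilities must be finite")
    threshold = float(values.mean())
    out = [SusceptibilityRecord(r.allotype, r.dm_susceptibility,
                                "high" if r.dm_susceptibility > threshold else "low")
           for r in records]
    return out, threshold


def summarize_replicates(rates: list[float]) -> dict:
    """Mean ± s.d. over independently fitted replicates."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no replicates")
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size)}
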