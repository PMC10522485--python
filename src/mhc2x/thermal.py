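"""Melting-temperature determination from thermal-shift curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .synthetic import MeltCurve, melt_sigmoid

__all__ = ["TmEstimate", "fit_melt"]


@dataclass
class TmEstimate:
    tm: float  # °C
    slope: float  # °C
    lower: float
    upper: float
    stderr: float  # s.e. of tm
    residual_variance: float = 0.0


def fit_melt(curve: MeltCurve, truncate_after_max: bool = False) -> TmEstimate:
    """Least-squares Boltzmann-sigmoid fit of a melt curve.

    With ``truncate_after_max`` the points past the global fluorescence
    maximum (the dye-dissociation tail) are dropped before fitting.
    Raises :class:`FitFailureError` if the fit does not converge or the
    fitted midpoint lies outside the measured temperature range.
    """
    t, y = curve.temperatures, curve.fluorescence
    if t.size < 8 or (t[-1] - t[0]) < 20:
        raise InsufficientDataError("melt curve needs ≥ 8 points spanning ≥ 20 °C")
    if np.ptp(y) == 0:
        raise InvalidParameterError("fluorescence is constant")

    if truncate_after_max:
        imax = int(np.argmax(y))
        if imax >= 7:  # keep at least the minimum viable curve
            t, y = t[:imax + 1], y[:imax + 1]

    lo0, hi0 = float(y.min()), float(y.max())
    # midpoint guess: temperature where the curve crosses half-height
    half = lo0 + 0.5 * (hi0 - lo0)
    above = np.nonzero(y >= half)[0]
    tm0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    p0 = [lo0, hi0, tm0, max((t[-1] - t[0]) / 20.0, 0.5)]
    try:
        popt, pcov = curve_fit(
            lambda tt, lo, hi, tm, sl: melt_sigmoid(tt, lo, hi, tm, sl),
            t, y, p0=p0, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError("melt-curve fit did not converge", {"p0": p0}) from exc
    lower, upper, tm, slope = (float(v) for v in popt)
    if slope < 0:  # reparameterize the mirrored solution
        lower, upper, slope = upper, lower, -slope
    if not (t[0] <= tm <= t[-1]):
        raise FitFailureError(
            f"fitted Tm {tm:.1f} °C outside measured range [{t[0]:.1f}, {t[-1]:.1f}]",
            {"tm": tm})
    if upper < lower:
        raise FitFailureError("fitted curve is decreasing (no unfolding transition)",
                              {"lower": lower, "upper": upper})
    resid = y - melt_sigmoid(t, lower, upper, tm, slope)
    dof = max(t.size - 4, 1)
    rv = float(resid @ resid / dof)
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.inf
    return TmEstimate(tm=tm, slope=slope, lower=lower, upper=upper,
                      stderr=se, residual_variance=rv)
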