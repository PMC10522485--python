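"""NMR observables: chemical-shift perturbations, intensity-ratio
classification, CPMG R2eff conversion, and two-state dispersion fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .synthetic import DispersionCurve, cpmg_two_state

__all__ = [
    "PeakTable",
    "DispersionFit",
    "csp",
    "classify_intensity_ratios",
    "r2eff",
    "fit_dispersion",
]

N15_WEIGHT = 0.15  # ¹⁵N scaling in the combined shift change
EXCHANGE_THRESHOLD = 2.0  # s⁻¹ dispersion amplitude above which a group "exchanges"


@dataclass
class PeakTable:
    """Per-residue peak quantities with and without binding partner."""

    chains: list[str]  # "alpha" | "beta"
    residues: list[int]
    intensity: np.ndarray  # I, with DM
    intensity_ref: np.ndarray  # I0, without DM

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.intensity_ref = np.asarray(self.intensity_ref, dtype=float)
        n = len(self.chains)
        if not (len(self.residues) == self.intensity.size == self.intensity_ref.size == n):
            raise InvalidParameterError("peak table columns must have equal length")
        if np.any(self.intensity < 0) or np.any(self.intensity_ref < 0):
            raise InvalidParameterError("intensities must be nonnegative")
        if len(set(zip(self.chains, self.residues))) != n:
            raise InvalidParameterError("residue identifiers must be unique per chain")


@dataclass
class DispersionFit:
    model: str  # "flat" | "two_state"
    r2_0: float
    phi: float | None
    kex: float | None
    dispersion_amplitude: float
    exchanging: bool
    aicc_flat: float = np.nan
    aicc_two_state: float = np.nan
    params_stderr: dict = field(default_factory=dict)


def csp(delta_h: float, delta_n: float) -> float:
    """Combined ¹H/¹⁵N chemical shift perturbation (ppm).

    sqrt(Δδ(¹H)² + (0.15·Δδ(¹⁵N))²)
    """
    return float(np.sqrt(delta_h ** 2 + (N15_WEIGHT * delta_n) ** 2))


def classify_intensity_ratios(table: PeakTable) -> dict:
    """Classify residues by attenuation of I/I0 on binding.

    strong:      r < 0.5
    significant: 0.5 ≤ r < (mean − s.d.)
    unaffected:  otherwise
    Residues with I0 = 0 are flagged unassessable and excluded from the
    mean/s.d. statistics (computed over all finite ratios).
    """
    assessable = table.intensity_ref > 0
    if int(assessable.sum()) < 3:
        raise InsufficientDataError("need ≥ 3 residues with I0 > 0")
    ratios = np.full(table.intensity.size, np.nan)
    ratios[assessable] = table.intensity[assessable] / table.intensity_ref[assessable]
    finite = ratios[np.isfinite(ratios)]
    mean, sd = float(finite.mean()), float(finite.std(ddof=1))
    cut = mean - sd
    classes = []
    for ok, r in zip(assessable, ratios):
        if not ok:
            classes.append("unassessable")
        elif r < 0.5:
            classes.append("strong")
        elif r < cut:
            classes.append("significant")
        else:
            classes.append("unaffected")
    return {"ratios": ratios, "classes": classes, "mean": mean, "sd": sd,
            "threshold": cut}


def r2eff(i_cpmg: float, i0: float, t_cpmg: float) -> float:
    """Effective transverse relaxation rate (1/T_CPMG)·ln(I0/I_CPMG), s⁻¹.

    Returns a negative value (with no error) if I > I0; callers should
    treat that as a warning condition.
    """
    if i0 <= 0 or i_cpmg <= 0:
        raise InvalidParameterError("intensities must be positive")
    if t_cpmg <= 0:
        raise InvalidParameterError("t_cpmg must be positive")
    return float(np.log(i0 / i_cpmg) / t_cpmg)


def _aicc(n: int, k: int, rss: float) -> float:
    # small-sample-corrected information criterion for Gaussian residuals
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return float(aic)


def fit_dispersion(curve: DispersionCurve, *, average_duplicates: bool = True) -> DispersionFit:
    """Fit flat vs two-site fast-exchange models and pick by AICc.

    ``dispersion_amplitude`` is the fitted R2eff at the lowest measured
    frequency minus R2_0; a group is called exchanging when that
    amplitude exceeds 2 s⁻¹. Duplicate frequencies (repeat error-check
    points) are averaged before fitting.
    """
    nu, r2 = curve.freqs, curve.r2eff
    if average_duplicates:
        uniq = np.unique(nu)
        r2 = np.array([r2[nu == u].mean() for u in uniq])
        nu = uniq
    if nu.size < 6:
        raise InsufficientDataError("dispersion fit needs ≥ 6 distinct frequencies")

    order = np.argsort(nu)
    nu, r2 = nu[order], r2[order]
    n = nu.size

    # flat model
    r2_flat = float(r2.mean())
    rss_flat = float(np.sum((r2 - r2_flat) ** 2))
    aicc_flat = _aicc(n, 1, rss_flat)

    # two-state model
    amp0 = max(r2[0] - r2[-1], 0.1)
    kex0 = 4.0 * float(np.median(nu))
    p0 = [float(r2[-1]), amp0 * kex0, kex0]
    two_ok = True
    try:
        popt, pcov = curve_fit(cpmg_two_state, nu, r2, p0=p0,
                               bounds=([0, 0, 1e-6], [np.inf] * 3), maxfev=50000)
    except RuntimeError:
        two_ok = False
    if two_ok:
        rss_two = float(np.sum((r2 - cpmg_two_state(nu, *popt)) ** 2))
        aicc_two = _aicc(n, 3, rss_two)
    else:
        aicc_two = np.inf

    if not two_ok and not np.isfinite(aicc_flat):
        raise FitFailureError("neither dispersion model converged")

    if aicc_two < aicc_flat:
        r2_0, phi, kex = (float(v) for v in popt)
        amplitude = float(cpmg_two_state(np.array([nu[0]]), r2_0, phi, kex)[0] - r2_0)
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.inf] * 3
        return DispersionFit(model="two_state", r2_0=r2_0, phi=phi, kex=kex,
                             dispersion_amplitude=amplitude,
                             exchanging=amplitude > EXCHANGE_THRESHOLD,
                             aicc_flat=aicc_flat, aicc_two_state=aicc_two,
                             params_stderr={"r2_0": float(se[0]), "phi": float(se[1]),
                                            "kex": float(se[2])})
    return DispersionFit(model="flat", r2_0=r2_flat, phi=None, kex=None,
                         dispersion_amplitude=0.0, exchanging=False,
                         aicc_flat=aicc_flat, aicc_two_state=aicc_two)
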