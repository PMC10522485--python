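"""Equilibrium binding energetics: Kd fitting and double-mutant-cycle coupling.

Titrations are fitted with the exact ligand-depletion (quadratic)
binding model — mandatory here because the probe concentration is
comparable to the dissociation constants of interest. Free energies use
ΔG = RT·ln(Kd_ii/Kd_i) and coupling energies propagate Kd standard
errors to first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .synthetic import BindingIsotherm, fraction_bound_depletion

__all__ = ["KdEstimate", "MutantCycle", "fit_kd", "delta_g", "coupling_energy"]

R_GAS = 8.314  # J mol⁻¹ K⁻¹


@dataclass
class KdEstimate:
    kd: float  # nM
    stderr: float
    residual_variance: float = 0.0
    warning: str | None = None


@dataclass
class MutantCycle:
    """Quartet of dissociation constants (nM) with standard errors."""

    kd_wt: float
    kd_mt1: float
    kd_mt2: float
    kd_mt12: float
    se_wt: float = 0.0
    se_mt1: float = 0.0
    se_mt2: float = 0.0
    se_mt12: float = 0.0
    labels: tuple[str, str, str, str] = ("wt", "mt1", "mt2", "mt12")

    def __post_init__(self):
        for kd in (self.kd_wt, self.kd_mt1, self.kd_mt2, self.kd_mt12):
            if kd <= 0:
                raise InvalidParameterError("all Kd values must be positive")


def fit_kd(isotherm: BindingIsotherm) -> KdEstimate:
    """Fit Kd from a titration by the exact ligand-depletion model."""
    r, f = isotherm.receptor_concs, isotherm.fraction_bound
    if r.size < 6:
        raise InsufficientDataError("Kd fit needs at least 6 titration points")
    if np.unique(r).size != r.size:
        raise InvalidParameterError("receptor concentrations must be distinct")
    probe = isotherm.probe_conc

    warning = None
    if np.all(f > 0.95):
        warning = "isotherm saturated; Kd poorly identified"

    # Kd guess: receptor concentration nearest half-saturation
    kd0 = float(r[np.argmin(np.abs(f - 0.5))]) or float(np.median(r))
    try:
        popt, pcov = curve_fit(
            lambda rr, kd: fraction_bound_depletion(rr, kd, probe),
            r, f, p0=[max(kd0, 1e-6)], bounds=(1e-12, np.inf), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError("Kd fit did not converge") from exc
    kd = float(popt[0])
    if kd <= 2e-12:
        warning = "Kd at lower bound"
    resid = f - fraction_bound_depletion(r, kd, probe)
    dof = max(r.size - 1, 1)
    rv = float(resid @ resid / dof)
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
    return KdEstimate(kd=kd, stderr=se, residual_variance=rv, warning=warning)


def delta_g(kd_num: float, kd_den: float, temperature: float = 298.15) -> float:
    """Interaction free energy R·T·ln(kd_num/kd_den), in kJ/mol."""
    if kd_num <= 0 or kd_den <= 0:
        raise InvalidParameterError("Kd values must be positive")
    return R_GAS * temperature * np.log(kd_num / kd_den) / 1000.0


def coupling_energy(cycle: MutantCycle, temperature: float = 298.15) -> tuple[float, float]:
    """Double-mutant-cycle coupling energy ΔΔG with first-order error.

    ΔΔG = ΔG12 − (ΔG1 + ΔG2) = RT·ln(Kd12·Kdwt / (Kd1·Kd2)); the
    propagated standard error is RT·sqrt(Σ (se_x/Kd_x)²).
    """
    rt = R_GAS * temperature / 1000.0
    ddg = rt * np.log(cycle.kd_mt12 * cycle.kd_wt / (cycle.kd_mt1 * cycle.kd_mt2))
    rel = [cycle.se_wt / cycle.kd_wt, cycle.se_mt1 / cycle.kd_mt1,
           cycle.se_mt2 / cycle.kd_mt2, cycle.se_mt12 / cycle.kd_mt12]
    err = rt * float(np.sqrt(np.sum(np.square(rel))))
    return float(ddg), err
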