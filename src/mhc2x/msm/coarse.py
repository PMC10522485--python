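"""Metastable-state thermodynamics and coarse kinetics.

Populations sum stationary weights over crisply assigned microstates;
relative free energies are −RT·ln(p/p_ref) against the most populated
metastable state; coarse rates are inverse mean first-passage times on
the microstate transition matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import InsufficientDataError
from .estimation import MSMResult
from .pcca import UNASSIGNED, MetastableModel

__all__ = ["metastable_thermo", "metastable_rates", "mfpt"]

R_GAS = 8.314  # J mol⁻¹ K⁻¹


def _assigned_states(metastable: MetastableModel) -> list[np.ndarray]:
    return [np.nonzero(metastable.assignments == m)[0]
            for m in range(metastable.n_metastable)]


def metastable_thermo(msm: MSMResult, metastable: MetastableModel,
                      temperature: float = 300.0) -> dict:
    """Populations and relative free energies (kJ/mol) of metastable states."""
    pi = msm.stationary_distribution
    groups = _assigned_states(metastable)
    if sum(1 for g in groups if g.size) < 2:
        raise InsufficientDataError("need crisp assignments for ≥ 2 metastable states")
    pops = np.array([pi[g].sum() if g.size else 0.0 for g in groups])
    unassigned = float(pi[metastable.assignments == UNASSIGNED].sum())
    ref = int(np.argmax(pops))
    rt = R_GAS * temperature / 1000.0
    with np.errstate(divide="ignore"):
        g_vals = np.where(pops > 0, -rt * np.log(pops / pops[ref]), np.inf)
    return {"populations": pops, "free_energies": g_vals, "reference": ref,
            "unassigned_population": unassigned, "temperature": temperature}


def mfpt(T: np.ndarray, target: np.ndarray, lag: int = 1) -> np.ndarray:
    """Mean first-passage time (in frames) from every state to a target set.

    Solves m_i = lag + Σ_j T_ij m_j for i outside the target, m_i = 0
    inside. Unreachable states get +inf.
    """
    n = T.shape[0]
    target = np.asarray(target, dtype=int)
    m = np.zeros(n)
    outside = np.setdiff1d(np.arange(n), target)
    if outside.size == 0:
        return m
    A = np.eye(outside.size) - T[np.ix_(outside, outside)]
    b = np.full(outside.size, float(lag))
    try:
        m[outside] = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        m[outside] = np.inf
    m[m < 0] = np.inf  # numerically unreachable
    return m


def metastable_rates(msm: MSMResult, metastable: MetastableModel,
                     frame_time: float | None = None) -> dict:
    """Pairwise metastable rates as inverse π-weighted MFPTs.

    rate(A→B) = 1 / MFPT(A→B) with MFPT averaged over the source states
    weighted by stationary probability restricted to A. Reported per
    physical time unit when ``frame_time`` (time per frame) is given,
    else per frame.
    """
    T, pi = msm.transition_matrix, msm.stationary_distribution
    groups = _assigned_states(metastable)
    live = [m for m, g in enumerate(groups) if g.size]
    if len(live) < 2:
        raise InsufficientDataError("need ≥ 2 crisply assigned metastable states")
    ft = frame_time if frame_time is not None else msm.frame_stride
    nm = metastable.n_metastable
    rates = np.zeros((nm, nm))
    mfpts = np.full((nm, nm), np.nan)
    for b in live:
        m_to_b = mfpt(T, groups[b], lag=msm.lag)
        for a in live:
            if a == b:
                continue
            src = groups[a]
            w = pi[src] / pi[src].sum()
            m_ab = float(w @ m_to_b[src])
            mfpts[a, b] = m_ab * ft
            if np.isfinite(m_ab) and m_ab > 0:
                rates[a, b] = 1.0 / (m_ab * ft)
            else:
                warnings.warn(f"metastable state {b} unreachable from {a}; rate set to 0",
                              stacklevel=2)
    return {"rates": rates, "mfpts": mfpts, "frame_time": ft}
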