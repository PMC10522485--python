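"""Reversible maximum-likelihood Markov state model estimation.

Counts are collected with a sliding window at the lag, restricted to the
largest strongly connected component, and the reversible transition
matrix is obtained by the standard detailed-balance fixed-point
iteration on the edge weights x_ij:

    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)

which converges to the maximizer of the reversible likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ..errors import DisconnectedDataError, InvalidParameterError
from ..synthetic import DiscreteTrajectorySet

__all__ = ["MSMResult", "count_matrix", "estimate_msm"]


@dataclass
class MSMResult:
    lag: int  # frames
    transition_matrix: np.ndarray  # over the active set
    stationary_distribution: np.ndarray
    count_matrix: np.ndarray  # full (n_states × n_states)
    active_set: np.ndarray  # microstate indices in the active set
    n_states_full: int
    frame_stride: float = 1.0
    implied_timescales: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def lag_time(self) -> float:
        """Lag in physical units."""
        return self.lag * self.frame_stride


def count_matrix(dtrajs: DiscreteTrajectorySet, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the lag."""
    if lag < 1:
        raise InvalidParameterError("lag must be ≥ 1")
    n = dtrajs.n_states
    c = np.zeros((n, n))
    for traj in dtrajs.trajectories:
        if traj.size <= lag:
            continue
        np.add.at(c, (traj[:-lag], traj[lag:]), 1.0)
    return c


def _largest_scc(c: np.ndarray) -> np.ndarray:
    graph = csr_matrix((c > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # keep the component with the most counts
    best, best_weight = 0, -1.0
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        w = c[np.ix_(idx, idx)].sum()
        if w > best_weight:
            best, best_weight = comp, w
    return np.nonzero(labels == best)[0]


def _reversible_mle(c: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 100000) -> tuple[np.ndarray, np.ndarray]:
    c_sym = c + c.T
    ci = c.sum(axis=1)
    x = c_sym.copy()
    x /= x.sum()
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        xi_new = x_new.sum(axis=1)
        delta = np.max(np.abs(xi_new - xi) / np.maximum(xi_new, 1e-300))
        x = x_new
        if delta < tol:
            break
    pi = x.sum(axis=1)
    return x / pi[:, None], pi / pi.sum()


def estimate_msm(dtrajs: DiscreteTrajectorySet, lag: int,
                 n_timescales: int | None = None) -> MSMResult:
    """Estimate a reversible MSM at the given lag (in frames)."""
    c = count_matrix(dtrajs, lag)
    if c.sum() == 0:
        raise DisconnectedDataError("no transition pairs at this lag")
    active = _largest_scc(c)
    if active.size == 0:
        raise DisconnectedDataError("empty connected set")
    if active.size < dtrajs.n_states:
        warnings.warn(f"active set restricted to {active.size}/{dtrajs.n_states} "
                      "microstates", stacklevel=2)
    c_active = c[np.ix_(active, active)]
    if active.size == 1:
        T = np.array([[1.0]])
        pi = np.array([1.0])
    else:
        T, pi = _reversible_mle(c_active)

    its = _implied_timescales(T, lag, n_timescales)
    return MSMResult(lag=lag, transition_matrix=T, stationary_distribution=pi,
                     count_matrix=c, active_set=active,
                     n_states_full=dtrajs.n_states,
                     frame_stride=dtrajs.frame_stride, implied_timescales=its)


def _implied_timescales(T: np.ndarray, lag: int,
                        n_timescales: int | None) -> np.ndarray:
    vals = np.linalg.eigvals(T)
    vals = np.real(vals[np.argsort(-np.abs(vals))])
    vals = vals[1:]  # drop the stationary eigenvalue
    if n_timescales is not None:
        vals = vals[:n_timescales]
    with np.errstate(divide="ignore", invalid="ignore"):
        its = np.where((vals > 0) & (vals < 1), -lag / np.log(vals), np.nan)
    return its
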