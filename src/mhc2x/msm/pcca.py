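"""PCCA+ metastable decomposition of a reversible transition matrix.

Memberships are built from the top right eigenvectors by the inner
simplex algorithm: the rows of the eigenvector matrix are (near) a
simplex whose vertices correspond to maximally metastable microstates;
picking the most spread-out rows as vertices and inverting gives fuzzy
membership vectors, which are then projected onto the feasible set
(nonnegative, rows summing to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ..errors import DecompositionError, InvalidParameterError
from .estimation import MSMResult

__all__ = ["MetastableModel", "pcca"]

UNASSIGNED = -1


@dataclass
class MetastableModel:
    memberships: np.ndarray  # microstates × metastable, rows sum to 1
    assignments: np.ndarray  # crisp metastable index or UNASSIGNED (-1)
    n_metastable: int
    crisp_cutoff: float

    @property
    def assigned_mask(self) -> np.ndarray:
        return self.assignments != UNASSIGNED


def _right_eigenvectors(msm: MSMResult, m: int) -> np.ndarray:
    T, pi = msm.transition_matrix, msm.stationary_distribution
    if np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) > 1e-8:
        raise DecompositionError("transition matrix is not reversible w.r.t. its "
                                 "stationary distribution")
    sqrt_pi = np.sqrt(pi)
    s = sqrt_pi[:, None] * T / sqrt_pi[None, :]
    s = (s + s.T) / 2
    vals, vecs = scipy.linalg.eigh(s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if m < T.shape[0] and abs(vals[m - 1] - vals[m]) < 1e-12:
        raise DecompositionError(
            f"degenerate eigenvalues at the requested cut ({vals[m-1]:.12f}); "
            f"{m} metastable states not supported by the spectrum")
    psi = vecs[:, :m] / sqrt_pi[:, None]
    # fix the trivial eigenvector to the constant 1
    psi[:, 0] = 1.0
    return psi


def _inner_simplex_vertices(psi: np.ndarray) -> list[int]:
    n, m = psi.shape
    ortho = psi.copy()
    idx = []
    # first vertex: row farthest from the origin
    norms = np.linalg.norm(ortho, axis=1)
    idx.append(int(np.argmax(norms)))
    ortho -= ortho[idx[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        nxt = int(np.argmax(norms))
        idx.append(nxt)
        v = ortho[nxt]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise DecompositionError("eigenvector rows do not span a simplex")
        v = v / nv
        ortho -= np.outer(ortho @ v, v)
    return idx


def pcca(msm: MSMResult, n_metastable: int, crisp_cutoff: float = 0.5) -> MetastableModel:
    """PCCA+ memberships and crisp assignments.

    A microstate is crisply assigned to its maximal-membership
    metastable state iff that membership strictly exceeds
    ``crisp_cutoff``; otherwise it is left unassigned.
    """
    n = msm.transition_matrix.shape[0]
    if not 2 <= n_metastable <= n:
        raise InvalidParameterError("need 2 ≤ n_metastable ≤ number of active microstates")
    if not 0 <= crisp_cutoff < 1:
        raise InvalidParameterError("crisp_cutoff must be in [0, 1)")

    psi = _right_eigenvectors(msm, n_metastable)
    vertices = _inner_simplex_vertices(psi)
    try:
        a = np.linalg.inv(psi[vertices])
    except np.linalg.LinAlgError as exc:
        raise DecompositionError("simplex vertex matrix is singular") from exc
    chi = psi @ a

    # feasibility projection: clip and renormalize
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1)
    if np.any(rows <= 0):
        raise DecompositionError("feasibility projection produced an empty membership row")
    chi /= rows[:, None]

    best = np.argmax(chi, axis=1)
    best_val = chi[np.arange(n), best]
    # strictly-above rule; a 1e-9 guard keeps exact-tie memberships (e.g. a
    # perfectly symmetric bridge state at 50/50) unassigned despite float noise
    assignments = np.where(best_val - crisp_cutoff > 1e-9, best,
                           UNASSIGNED).astype(np.int64)
    return MetastableModel(memberships=chi, assignments=assignments,
                           n_metastable=n_metastable, crisp_cutoff=crisp_cutoff)
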