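"""Time-lagged independent component analysis.

Solves the generalized eigenproblem C_τ v = λ C_0 v for the mean-free
instantaneous covariance C_0 and the symmetrized time-lagged covariance
C_τ, after ridge-regularized whitening of C_0. Eigenvalues sort the
components by autocorrelation at the lag; the leading components are the
slowest linear coordinates of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ..errors import InvalidParameterError, NumericalFailureError
from ..synthetic import FeatureTrajectory

__all__ = ["TicaModel", "tica"]

RIDGE_SCALE = 1e-9  # ridge added to C0 as RIDGE_SCALE·trace/dim
RANK_TOL = 1e-10  # relative eigenvalue cutoff when whitening


@dataclass
class TicaModel:
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # features × n_components, columns are TICs
    mean: np.ndarray
    lag: int
    projections: list[np.ndarray]  # one (frames × n_components) array per input

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(data) - self.mean) @ self.components


def _as_arrays(features) -> list[np.ndarray]:
    out = []
    items = features if isinstance(features, (list, tuple)) else [features]
    for f in items:
        arr = f.data if isinstance(f, FeatureTrajectory) else np.atleast_2d(np.asarray(f, float))
        out.append(arr)
    return out


def tica(features, lag: int, n_components: int | None = None) -> TicaModel:
    """Estimate a TICA projection from one or more feature trajectories."""
    if lag < 1:
        raise InvalidParameterError("lag must be ≥ 1")
    trajs = _as_arrays(features)
    dim = trajs[0].shape[1]
    usable = [t for t in trajs if t.shape[0] > lag]
    if not usable:
        raise InvalidParameterError("no trajectory longer than the lag")
    n_pairs = sum(t.shape[0] - lag for t in usable)
    if n_pairs <= dim:
        raise InvalidParameterError("need more usable frames than features")

    # mean over both ends of every lagged pair (keeps C_tau symmetric in
    # expectation under reversibility)
    total = np.zeros(dim)
    for t in usable:
        total += t[:-lag].sum(axis=0) + t[lag:].sum(axis=0)
    mean = total / (2 * n_pairs)

    c0 = np.zeros((dim, dim))
    ct = np.zeros((dim, dim))
    for t in usable:
        x0 = t[:-lag] - mean
        xt = t[lag:] - mean
        c0 += x0.T @ x0 + xt.T @ xt
        ct += x0.T @ xt
    c0 /= 2 * n_pairs
    ct = (ct + ct.T) / (2 * n_pairs)

    ridge = RIDGE_SCALE * np.trace(c0) / dim
    c0 += ridge * np.eye(dim)

    evals, evecs = scipy.linalg.eigh(c0)
    keep = evals > RANK_TOL * evals.max()
    if not np.any(keep):
        raise NumericalFailureError("C0 is rank-deficient beyond regularization")
    w = evecs[:, keep] / np.sqrt(evals[keep])  # whitening transform

    m = w.T @ ct @ w
    m = (m + m.T) / 2
    lam, v = scipy.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam, v = lam[order], v[:, order]
    comps = w @ v
    if n_components is not None:
        lam, comps = lam[:n_components], comps[:, :n_components]

    projections = [(t - mean) @ comps for t in trajs]
    return TicaModel(eigenvalues=lam, components=comps, mean=mean, lag=lag,
                     projections=projections)
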