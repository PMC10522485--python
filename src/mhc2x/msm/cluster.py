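"""Microstate definition by k-means clustering of projected trajectories."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from ..errors import InvalidParameterError
from ..synthetic import DiscreteTrajectorySet

__all__ = ["cluster_microstates"]


def cluster_microstates(projected, k: int, seed: int, max_iter: int = 300,
                        frame_stride: float = 1.0) -> tuple[DiscreteTrajectorySet, np.ndarray]:
    """Cluster projected frames into k microstates (k-means++, seeded).

    Accepts one array or a list of (frames × dims) arrays; returns the
    per-trajectory integer assignments and the cluster centers.
    """
    trajs = projected if isinstance(projected, (list, tuple)) else [projected]
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajs]
    lengths = [t.shape[0] for t in trajs]
    stacked = np.vstack(trajs)
    if k > stacked.shape[0]:
        raise InvalidParameterError("k exceeds the number of frames")
    if k < 1:
        raise InvalidParameterError("k must be ≥ 1")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(stacked)
    split = np.split(labels, np.cumsum(lengths)[:-1])
    dtrajs = DiscreteTrajectorySet(trajectories=[s.astype(np.int64) for s in split],
                                   n_states=k, frame_stride=frame_stride)
    return dtrajs, km.cluster_centers_
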