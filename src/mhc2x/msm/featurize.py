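"""Pairwise-distance featurization around an anchor residue."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidParameterError
from ..synthetic import FeatureTrajectory

__all__ = ["extract_pair_distances"]


def extract_pair_distances(coords, residue_ids, reference_coords, reference_ids,
                           anchor_residue, radius: float = 15.0,
                           frame_stride: float = 1.0) -> FeatureTrajectory:
    """All pairwise Cα distances among atoms near an anchor residue.

    Parameters
    ----------
    coords : (frames, atoms, 3) array of Cα coordinates in Å.
    residue_ids : per-atom residue identifiers matching ``reference_ids``.
    reference_coords : (ref_atoms, 3) reference Cα coordinates used to
        select the neighborhood.
    reference_ids : residue identifiers of the reference atoms.
    anchor_residue : identifier of the anchor; selection keeps residues
        whose reference Cα lies within ``radius`` Å of the anchor Cα.

    Returns a :class:`FeatureTrajectory` with m·(m−1)/2 distance features
    for m selected atoms, in a fixed recorded order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise InvalidParameterError("coords must be (frames, atoms, 3)")
    residue_ids = list(residue_ids)
    reference_ids = list(reference_ids)
    ref = np.asarray(reference_coords, dtype=float)
    if anchor_residue not in reference_ids:
        raise InvalidParameterError(f"anchor residue {anchor_residue!r} absent from reference")
    anchor_xyz = ref[reference_ids.index(anchor_residue)]
    near = {rid for rid, xyz in zip(reference_ids, ref)
            if np.linalg.norm(xyz - anchor_xyz) <= radius}
    sel = [i for i, rid in enumerate(residue_ids) if rid in near]
    if len(sel) < 2:
        raise InvalidParameterError("selection has fewer than 2 atoms")
    pairs = [(sel[a], sel[b]) for a in range(len(sel)) for b in range(a + 1, len(sel))]
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    d = np.linalg.norm(coords[:, i_idx, :] - coords[:, j_idx, :], axis=2)
    names = [f"d({residue_ids[i]},{residue_ids[j]})" for i, j in pairs]
    return FeatureTrajectory(data=d, frame_stride=frame_stride, feature_names=names)
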