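"""Bootstrap uncertainties for metastable populations, free energies and rates.

Trajectories are the resampling unit. Each replicate re-estimates the
MSM (and its PCCA+ decomposition) on the fixed microstate definitions;
replicate metastable states are matched to the full-data model by
maximal population overlap before accumulating statistics. Confidence
intervals are 1σ (sample standard deviation over replicates).
"""

from __future__ import annotations

import numpy as np

from ..errors import InsufficientDataError, Mhc2xError
from ..synthetic import DiscreteTrajectorySet
from .coarse import metastable_rates, metastable_thermo
from .estimation import estimate_msm
from .pcca import UNASSIGNED, MetastableModel, pcca

__all__ = ["bootstrap_msm"]


def _match_labels(ref_groups_full: list[np.ndarray], rep_model: MetastableModel,
                  rep_active: np.ndarray, rep_pi: np.ndarray, nm: int) -> np.ndarray:
    """Map replicate metastable labels onto the reference labels.

    Overlap(a_rep, b_ref) = replicate stationary mass of microstates in
    both sets; greedy assignment on descending overlap.
    """
    overlap = np.zeros((nm, nm))
    for a in range(nm):
        micro_rep = rep_active[rep_model.assignments == a]  # full-space indices
        mass = dict(zip(rep_active, rep_pi))
        for b in range(nm):
            common = np.intersect1d(micro_rep, ref_groups_full[b])
            overlap[a, b] = sum(mass[i] for i in common)
    mapping = np.full(nm, -1, dtype=int)
    taken = set()
    for _ in range(nm):
        a, b = np.unravel_index(np.argmax(overlap), overlap.shape)
        mapping[a] = b
        overlap[a, :] = -1
        overlap[:, b] = -1
        taken.add(b)
    return mapping


def bootstrap_msm(dtrajs: DiscreteTrajectorySet, lag: int, n_metastable: int,
                  n_boot: int = 100, seed: int = 0, temperature: float = 300.0,
                  crisp_cutoff: float = 0.5, frame_time: float | None = None) -> dict:
    """1σ bootstrap CIs for metastable populations, free energies and rates."""
    trajs = dtrajs.trajectories
    if len(trajs) < 2:
        raise InsufficientDataError("bootstrap needs ≥ 2 trajectories to resample")

    full_msm = estimate_msm(dtrajs, lag)
    full_meta = pcca(full_msm, n_metastable, crisp_cutoff)
    full_thermo = metastable_thermo(full_msm, full_meta, temperature)
    full_rates = metastable_rates(full_msm, full_meta, frame_time)
    ref_groups_full = [full_msm.active_set[full_meta.assignments == m]
                       for m in range(n_metastable)]

    rng = np.random.default_rng(seed)
    nm = n_metastable
    pops, gs, rates = [], [], []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(trajs), size=len(trajs))
        rep = DiscreteTrajectorySet(trajectories=[trajs[i] for i in pick],
                                    n_states=dtrajs.n_states,
                                    frame_stride=dtrajs.frame_stride)
        try:
            msm_r = estimate_msm(rep, lag)
            meta_r = pcca(msm_r, nm, crisp_cutoff)
            mapping = _match_labels(ref_groups_full, meta_r, msm_r.active_set,
                                    msm_r.stationary_distribution, nm)
            relabeled = np.where(meta_r.assignments == UNASSIGNED, UNASSIGNED,
                                 mapping[meta_r.assignments])
            meta_r = MetastableModel(memberships=meta_r.memberships[:, np.argsort(mapping)],
                                     assignments=relabeled.astype(np.int64),
                                     n_metastable=nm, crisp_cutoff=crisp_cutoff)
            th = metastable_thermo(msm_r, meta_r, temperature)
            rt = metastable_rates(msm_r, meta_r, frame_time)
        except Mhc2xError:
            dropped += 1
            continue
        pops.append(th["populations"])
        gs.append(th["free_energies"])
        rates.append(rt["rates"])

    if not pops:
        raise InsufficientDataError("all bootstrap replicates failed")
    pops = np.array(pops)
    gs = np.array(gs)
    gs[~np.isfinite(gs)] = np.nan
    rates = np.array(rates)
    ddof = 1 if len(pops) > 1 else 0
    return {
        "populations": full_thermo["populations"],
        "populations_ci": pops.std(axis=0, ddof=ddof),
        "free_energies": full_thermo["free_energies"],
        "free_energies_ci": np.nanstd(gs, axis=0, ddof=ddof),
        "rates": full_rates["rates"],
        "rates_ci": rates.std(axis=0, ddof=ddof),
        "reference": full_thermo["reference"],
        "temperature": temperature,
        "n_replicates": len(pops),
        "n_dropped": dropped,
    }
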