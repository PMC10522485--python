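"""Cα superposition and RMSD between pMHCII crystal structures.

Chains are paired by best sequence identity, residues by global pairwise
sequence alignment, and the optimal rigid-body superposition is the
SVD (Kabsch) solution with the proper-rotation sign correction.
Iterative outlier rejection (drop pairs deviating more than
``reject_factor`` × current RMSD, refit) mimics structure-viewer
alignment behavior; disable it for exact whole-set Kabsch RMSDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["CaStructure", "SuperpositionResult", "read_ca_structure", "kabsch",
           "superpose"]


@dataclass
class CaStructure:
    """Cα trace: per chain, residue numbers, one-letter sequence, coordinates."""

    chains: dict[str, dict] = field(default_factory=dict)
    # chains[chain_id] = {"resnums": [...], "sequence": str, "coords": (n, 3) array}

    def add_chain(self, chain_id: str, resnums: list[int], sequence: str,
                  coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise InvalidParameterError("coordinates must be finite")
        if len(resnums) != len(sequence) or coords.shape != (len(resnums), 3):
            raise InvalidParameterError("chain fields must have consistent lengths")
        self.chains[chain_id] = {"resnums": list(resnums), "sequence": sequence,
                                 "coords": coords}


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int  # retained pairs
    n_pairs_initial: int
    cycles: int


def read_ca_structure(path: str) -> CaStructure:
    """Read Cα atoms from a PDB file (first model, altloc '' or 'A')."""
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", path).get_models())
    out = CaStructure()
    for chain in model:
        resnums, letters, coords = [], [], []
        for res in chain:
            if res.id[0] != " ":  # skip HETATM / waters
                continue
            if "CA" not in res:
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = ca.disordered_get("A") if ca.disordered_has_id("A") else ca.selected_child
            resname = res.get_resname()
            letters.append(protein_letters_3to1.get(resname, "X"))
            resnums.append(res.id[1])
            coords.append(ca.get_coord())
        if resnums:
            out.add_chain(chain.id, resnums, "".join(letters),
                          np.array(coords, dtype=float))
    return out


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation + translation of mobile onto target.

    Returns (rotation, translation, rmsd); the transform maps mobile
    points as ``p @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _aligned_index_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def _pair_chains(mobile: CaStructure, target: CaStructure) -> list[tuple[str, str]]:
    """Greedy chain pairing by best alignment identity."""
    scores = []
    aligner = _make_aligner()
    for cm, dm in mobile.chains.items():
        for ct, dt in target.chains.items():
            score = aligner.score(dm["sequence"], dt["sequence"])
            scores.append((score, cm, ct))
    scores.sort(reverse=True)
    used_m, used_t, out = set(), set(), []
    for _, cm, ct in scores:
        if cm in used_m or ct in used_t:
            continue
        out.append((cm, ct))
        used_m.add(cm)
        used_t.add(ct)
    return out


def superpose(mobile: CaStructure, target: CaStructure, max_cycles: int = 5,
              reject_factor: float = 2.0) -> SuperpositionResult:
    """Superpose Cα traces and report RMSD with optional outlier rejection.

    ``max_cycles=0`` disables rejection (plain Kabsch over all pairs).
    """
    xm_list, xt_list = [], []
    for cm, ct in _pair_chains(mobile, target):
        dm, dt = mobile.chains[cm], target.chains[ct]
        for i, j in _aligned_index_pairs(dm["sequence"], dt["sequence"]):
            xm_list.append(dm["coords"][i])
            xt_list.append(dt["coords"][j])
    if len(xm_list) < 3:
        raise InsufficientDataError("fewer than 3 residue pairs after pairing")
    xm = np.array(xm_list)
    xt = np.array(xt_list)
    n_initial = xm.shape[0]

    rot, trans, rmsd = kabsch(xm, xt)
    keep = np.ones(n_initial, dtype=bool)
    cycles = 0
    for _ in range(max_cycles):
        if rmsd < 1e-6:  # already at coordinate precision; nothing to reject
            break
        moved = xm[keep] @ rot.T + trans
        dev = np.linalg.norm(moved - xt[keep], axis=1)
        bad = dev > reject_factor * rmsd
        if not np.any(bad) or (keep.sum() - bad.sum()) < 3:
            break
        idx = np.nonzero(keep)[0][bad]
        keep[idx] = False
        rot, trans, rmsd = kabsch(xm[keep], xt[keep])
        cycles += 1
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_pairs=int(keep.sum()), n_pairs_initial=n_initial,
                               cycles=cycles)
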