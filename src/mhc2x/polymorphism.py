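"""Per-position normalized Shannon-entropy polymorphism scores.

The score of one alignment column is

    C = (−Σ_α ρ_α·log2 ρ_α) / log2(min(N, K))

with ρ_α = n_α/N over the N non-gap residues in the column and K the
number of residue types (default 20). Conserved columns score 0; a
maximally diverse column scores 1.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .synthetic import AMINO_ACIDS, MultipleAlignment

__all__ = ["position_entropy", "profile_entropy"]

GAP_CHARS = "-."


def position_entropy(counts: dict[str, int] | Counter, k_types: int = 20) -> float:
    """Normalized entropy score of one column from residue-type counts."""
    n = sum(int(c) for c in counts.values())
    if n < 2:
        raise InvalidParameterError("column needs at least 2 residues (denominator is "
                                    "zero for N = 1)")
    if k_types < 2:
        raise InvalidParameterError("k_types must be at least 2")
    rho = np.array([c for c in counts.values() if c > 0], dtype=float) / n
    h = float(-(rho * np.log2(rho)).sum())
    return h / np.log2(min(n, k_types))


def profile_entropy(alignment: MultipleAlignment, k_types: int = 20) -> pd.DataFrame:
    """Entropy score for every alignment column.

    Gaps are excluded from each column's count; all-gap columns (or
    columns with a single residue) get a missing score. Positions are
    reported both as 1-based alignment columns and in the ungapped
    coordinates of the first sequence (NaN where the first sequence has
    a gap), so scores can be mapped onto structure residue numbers.
    """
    if len(alignment.sequences) < 2:
        raise InvalidParameterError("alignment needs at least 2 sequences")
    ref = alignment.sequences[0]
    rows = []
    ref_pos = 0
    for col in range(alignment.n_columns):
        residues = [s[col] for s in alignment.sequences if s[col] not in GAP_CHARS]
        in_ref = ref[col] not in GAP_CHARS
        if in_ref:
            ref_pos += 1
        counts = Counter(residues)
        if len(residues) < 2:
            score = np.nan
        else:
            score = position_entropy(counts, k_types=k_types)
        rows.append({"column": col + 1,
                     "ref_position": ref_pos if in_ref else np.nan,
                     "score": score})
    return pd.DataFrame(rows)
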