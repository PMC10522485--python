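"""Group-level statistics: pooled t-test, OLS with R², grouped correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError

__all__ = ["GroupSummary", "pooled_t_test", "linear_fit", "grouped_or_correlation"]


@dataclass
class GroupSummary:
    """Either raw values or (n, mean, sem) summary of one group."""

    label: str = ""
    n: int | None = None
    mean: float | None = None
    sem: float | None = None
    values: np.ndarray | None = None

    def resolved(self) -> tuple[int, float, float]:
        """Return (n, mean, sd)."""
        if self.values is not None:
            v = np.asarray(self.values, dtype=float)
            if v.size < 2:
                raise InsufficientDataError("group needs n ≥ 2")
            return int(v.size), float(v.mean()), float(v.std(ddof=1))
        if self.n is None or self.mean is None or self.sem is None:
            raise InvalidParameterError("group needs either values or n/mean/sem")
        if self.n < 2:
            raise InsufficientDataError("group needs n ≥ 2")
        return int(self.n), float(self.mean), float(self.sem * np.sqrt(self.n))


def pooled_t_test(g1: GroupSummary, g2: GroupSummary) -> dict:
    """Two-sample Student t-test with pooled variance (two-sided).

    s.d. is recovered from s.e.m. via sd = sem·sqrt(n) when summaries
    are given; raw values give identical results.
    """
    n1, m1, s1 = g1.resolved()
    n2, m2, s2 = g2.resolved()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se if se > 0 else 0.0
    p = 1.0 if t == 0 else float(2.0 * sps.t.sf(abs(t), df))
    return {"t": float(t), "df": int(df), "p": p}


def linear_fit(x, y) -> dict:
    """Ordinary least squares y = a·x + b with R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("linear fit needs ≥ 3 points")
    if np.ptp(x) == 0:
        raise InvalidParameterError("x is constant; fit is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": float(r2)}


def grouped_or_correlation(table, predictor: str = "susceptibility") -> dict:
    """Per-group OLS of odds ratio on a predictor, split by association flag.

    ``table`` is a DataFrame-like with columns ``odds_ratio``,
    ``associated`` (bool) and the predictor column (``susceptibility``
    or ``ms1_population``). Groups with fewer than 3 allotypes are
    skipped with a warning entry.
    """
    col = {"susceptibility": "susceptibility", "ms1_population": "ms1_population"}.get(predictor)
    if col is None:
        raise InvalidParameterError(f"unknown predictor {predictor!r}")
    out = {}
    for flag, name in ((True, "associated"), (False, "not_associated")):
        sub = table[table["associated"] == flag]
        if len(sub) < 3:
            out[name] = {"skipped": True, "n": int(len(sub)),
                         "warning": "fewer than 3 allotypes in group"}
            continue
        fit = linear_fit(sub[col].to_numpy(), sub["odds_ratio"].to_numpy())
        fit["n"] = int(len(sub))
        out[name] = fit
    return out
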