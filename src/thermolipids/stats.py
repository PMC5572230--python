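"""Two-sided Spearman rank-correlation screen with significance tiers.

Lipid indices are screened against in-situ temperature with Spearman's
rank correlation: rho is the Pearson correlation of mid-ranks (ties
averaged), and the two-sided p-value comes from exact enumeration of all
n! rank permutations for small tie-free samples, falling back to the
Student-t approximation t = rho * sqrt((n-2)/(1-rho^2)) otherwise.  The
exact method doubles as the oracle for the approximation.  Results carry
the conventional significance tiers (p < 0.001 / 0.01 / 0.05 / n.s.,
strict inequalities).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "spearman",
    "tier",
    "correlation_screen",
    "EXACT_N_MAX",
]

#: largest tie-free n for which the permutation null is fully enumerated
EXACT_N_MAX = 9

TIERS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass(frozen=True)
class CorrelationResult:
    """One index-temperature correlation."""

    index_name: str
    rho: float
    p_two_sided: float
    n: int
    tier: str
    method: str  # exact_permutation | t_approximation | undefined

    @property
    def defined(self) -> bool:
        return self.method != "undefined"


def tier(p: float) -> str:
    """Significance tier of a two-sided p-value (strict thresholds)."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    for threshold, label in TIERS:
        if p < threshold:
            return label
    return "ns"


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan
    return float(rx @ ry) / denom


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of rank orderings."""
    n = len(rx)
    perms = _perm_matrix(n)
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * (ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, index_name: str = "", method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation of two paired vectors.

    Pairs with a missing value in either vector are dropped.  ``method``
    is ``auto`` (exact enumeration for tie-free n <= 9, t-approximation
    otherwise), ``exact`` or ``t``.  Zero variance in either vector leaves
    rho undefined (flagged in the result rather than raising).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("spearman(%s): zero variance, rho undefined", index_name or "?")
        return CorrelationResult(index_name, math.nan, math.nan, n, "ns", "undefined")

    rx = sps.rankdata(x)  # mid-ranks
    ry = sps.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    tie_free = len(set(rx)) == n and len(set(ry)) == n

    if method == "auto":
        use_exact = tie_free and n <= EXACT_N_MAX
    elif method == "exact":
        if n > EXACT_N_MAX:
            raise ValueError(f"exact enumeration supported for n <= {EXACT_N_MAX}")
        use_exact = True
    elif method == "t":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        p = _exact_p(rx, ry, rho)
        meth = "exact_permutation"
    else:
        if abs(rho) >= 1.0 - 1e-12:
            # t statistic diverges; report the exact enumeration bound
            p = 2.0 / math.factorial(n)
            meth = "t_approximation"
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
            meth = "t_approximation"
    p = min(p, 1.0)
    return CorrelationResult(index_name, rho, p, n, tier(p), meth)


def correlation_screen(
    index_table: pd.DataFrame,
    temperatures: pd.Series | dict,
    method: str = "auto",
) -> pd.DataFrame:
    """Correlate every index against per-sample temperature.

    index_table
        Long format ``sample_id, index_name, value`` (extra columns
        ignored), one row per (sample, index).
    temperatures
        Mapping sample_id -> temperature in deg C.

    Returns one row per index: ``index_name, rho, p_two_sided, n, tier,
    method`` plus a supplementary Benjamini-Hochberg ``p_bh`` column
    (the tiers themselves are uncorrected).  Indices with fewer than 3
    complete pairs or zero variance are reported with the ``undefined``
    method; all-missing indices are skipped with a log entry.
    """
    temps = pd.Series(temperatures, dtype=float)
    results: list[CorrelationResult] = []
    for name, grp in index_table.groupby("index_name", sort=True):
        merged = grp.set_index("sample_id")["value"].reindex(temps.index)
        vals = merged.to_numpy(float)
        t = temps.to_numpy(float)
        keep = ~(np.isnan(vals) | np.isnan(t))
        if keep.sum() == 0:
            logger.info("correlation_screen: index %s all-missing, skipped", name)
            continue
        if keep.sum() < 3:
            results.append(
                CorrelationResult(name, math.nan, math.nan, int(keep.sum()), "ns",
                                  "undefined")
            )
            continue
        results.append(spearman(t[keep], vals[keep], index_name=name, method=method))
    out = pd.DataFrame(
        [
            (r.index_name, r.rho, r.p_two_sided, r.n, r.tier, r.method)
            for r in results
        ],
        columns=["index_name", "rho", "p_two_sided", "n", "tier", "method"],
    )
    defined = out["method"] != "undefined"
    out["p_bh"] = np.nan
    if defined.any():
        out.loc[defined, "p_bh"] = sps.false_discovery_control(
            out.loc[defined, "p_two_sided"].to_numpy(), method="bh"
        )
    return out
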