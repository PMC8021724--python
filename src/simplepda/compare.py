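"""Two-group comparison layer: Mann–Whitney U, Fisher exact, chi-square.

Continuous variables are summarised as median (range) and compared with the
Mann–Whitney U test (exact enumeration on small samples, tie-corrected
normal approximation otherwise); categorical variables as n (%) with Fisher's
exact test when any expected cell is below 5, Pearson chi-square otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "mann_whitney",
    "fisher_exact",
    "chi_square_2x2",
    "summarize_groups",
]

#: Enumerate the exact Mann–Whitney null when C(n, n_a) is at most this.
EXACT_ENUM_LIMIT = 10_000


@dataclass
class GroupSummary:
    variable: str
    kind: str                      # "continuous" or "binary"
    group_a: str                   # e.g. "62.5% / median 15 (10-23)"
    group_b: str
    test: str
    p_value: float


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, str]:
    """Mann–Whitney U with a two-sided p-value.

    Exact p by full enumeration of group assignments (tie-safe) whenever
    C(n_a + n_b, n_a) <= 10^4; otherwise the normal approximation with tie
    correction. Returns ``(U_a, p, method)`` where ``U_a`` counts pairs won
    by ``sample_a`` (ties 1/2) and ``method`` is ``"exact"`` or
    ``"asymptotic"``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = _u_statistic(ranks[:na], na)
    mu = na * nb / 2.0

    if comb(na + nb, na) <= EXACT_ENUM_LIMIT:
        # exact two-sided p: mass of assignments at least as extreme as observed
        obs_dev = abs(u_a - mu)
        idx = range(na + nb)
        hits = 0
        total = 0
        for subset in combinations(idx, na):
            u = _u_statistic(ranks[list(subset)], na)
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                hits += 1
        return u_a, hits / total, "exact"

    # tie-corrected normal approximation (no continuity correction)
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_a, 1.0, "asymptotic"
    z = (u_a - mu) / np.sqrt(var)
    return u_a, float(2 * stats.norm.sf(abs(z))), "asymptotic"


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    return t


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (probability-mass method) for a 2x2 table."""
    t = _check_2x2(table)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (no continuity correction by default)."""
    t = _check_2x2(table)
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def _median_range(x: np.ndarray) -> str:
    return f"{np.median(x):g} ({np.min(x):g}–{np.max(x):g})"


def _n_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.0f}%)"


def summarize_groups(
    frame: pd.DataFrame,
    variables: dict[str, str],
    label_col: str = "label",
    case_value: object = "case",
) -> list[GroupSummary]:
    """Table-style two-group summary of per-infant variables.

    ``variables`` maps column name -> kind ("continuous" or "binary").
    Continuous rows report median (range) per group with a Mann–Whitney p;
    binary rows report n (%) with Fisher's exact test when any expected cell
    count is below 5 and Pearson chi-square otherwise.
    """
    is_case = frame[label_col] == case_value
    if is_case.all() or not is_case.any():
        raise ValueError("both groups must be non-empty")
    out: list[GroupSummary] = []
    for var, kind in variables.items():
        if var not in frame.columns:
            raise KeyError(f"unknown variable: {var!r}")
        col = frame[var]
        a, b = col[is_case], col[~is_case]
        if kind == "continuous":
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                p, test = 1.0, "mann-whitney (degenerate)"
            else:
                _, p, method = mann_whitney(a.to_numpy(), b.to_numpy())
                test = f"mann-whitney ({method})"
            out.append(GroupSummary(var, kind, _median_range(a.to_numpy()),
                                    _median_range(b.to_numpy()), test, p))
        elif kind == "binary":
            ka, kb = int(a.astype(bool).sum()), int(b.astype(bool).sum())
            table = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                p, test = 1.0, "degenerate"
            else:
                expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
                if (expected < 5).any():
                    p, test = fisher_exact(table), "fisher"
                else:
                    _, p = chi_square_2x2(table)
                    test = "chi-square"
            out.append(GroupSummary(var, kind, _n_pct(ka, len(a)),
                                    _n_pct(kb, len(b)), test, p))
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
    return out


def summaries_to_frame(rows: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "kind": [r.kind for r in rows],
            "hspda_group": [r.group_a for r in rows],
            "no_pda_group": [r.group_b for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
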