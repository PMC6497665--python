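"""Nonparametric comparison of behaviour indices.

The five indices are strongly dependent (they are computed from the same
encounters), so the comparison is deliberately modest: Anderson-Darling as
the normality screen, Spearman rank correlation between index pairs,
two-sided Wilcoxon-Mann-Whitney on the index means, and step-down
Bonferroni-Holm over the family of pairwise tests (10 pairs for 5 indices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

INDEX_COLUMNS = ("mmai", "mbi_agg", "ai", "mbi_pcf", "mmpi")


@dataclass(frozen=True)
class ADResult:
    statistic: float
    p_band: str
    reject_at_05: bool


def anderson_darling(values) -> ADResult:
    """Anderson-Darling normality test; reports a p band from the standard
    critical-value table rather than an exact p."""
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError(f"Anderson-Darling needs n >= 8, got n={values.size}")
    res = scipy.stats.anderson(values, dist="norm")
    crit = res.critical_values  # at significance levels 15, 10, 5, 2.5, 1 (%)
    sig = res.significance_level / 100.0
    exceeded = res.statistic > crit
    if not exceeded.any():
        band = f"p > {sig[0]:g}"
    elif exceeded.all():
        band = f"p < {sig[-1]:g}"
    else:
        k = int(np.argmin(exceeded == False))  # noqa: E712 — first True
        band = f"{sig[k]:g} < p < {sig[k - 1]:g}" if k > 0 else f"p < {sig[0]:g}"
    return ADResult(
        statistic=float(res.statistic),
        p_band=band,
        reject_at_05=bool(res.statistic > crit[2]),
    )


def spearman_matrix(index_table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rho matrix over the table's columns."""
    cols = list(index_table.columns)
    rho = np.ones((len(cols), len(cols)))
    for i, j in itertools.combinations(range(len(cols)), 2):
        r = scipy.stats.spearmanr(
            index_table.iloc[:, i], index_table.iloc[:, j], nan_policy="omit"
        ).statistic
        rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=cols, columns=cols)


def mwu(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p: exact for small tie-free samples,
    tie-corrected normal approximation otherwise (scipy's auto policy)."""
    return float(scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def pairwise_mwu(index_table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of two-sided MWU p-values over the table's columns."""
    cols = list(index_table.columns)
    p = np.ones((len(cols), len(cols)))
    for i, j in itertools.combinations(range(len(cols)), 2):
        x = index_table.iloc[:, i].dropna()
        y = index_table.iloc[:, j].dropna()
        p[i, j] = p[j, i] = mwu(x, y)
    return pd.DataFrame(p, index=cols, columns=cols)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values (monotone, capped at 1)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method="holm")[1]


@dataclass(frozen=True)
class ComparisonReport:
    """Pairwise index comparison within one data-set × encounter-type block."""

    pairs: pd.DataFrame  # index_a, index_b, rho, p_rho, p_mwu, p_holm
    means: pd.Series
    m: int  # Holm family size

    def summary(self) -> str:
        lines = [
            f"pairwise index comparison ({self.m} pairs; "
            "MWU two-sided, tie-corrected; Holm family = all pairs)",
            "index means: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.means.items()),
        ]
        for _, r in self.pairs.iterrows():
            star = "*" if r.p_holm < 0.05 else ""
            lines.append(
                f"  {r.index_a} vs {r.index_b}: rho={r.rho:+.3f} "
                f"(p={r.p_rho:.3g}), MWU p={r.p_mwu:.3g}, Holm p={r.p_holm:.3g}{star}"
            )
        return "\n".join(lines)


def compare_indices(index_table: pd.DataFrame) -> ComparisonReport:
    """Full pairwise comparison of index columns (default: the five indices).

    Holm correction is applied to the MWU p-values across the family of all
    pairs in the table; rho p-values are reported unadjusted.
    """
    cols = [c for c in INDEX_COLUMNS if c in index_table.columns] or list(
        index_table.columns
    )
    rows = []
    for a, b in itertools.combinations(cols, 2):
        x = index_table[a].dropna()
        y = index_table[b].dropna()
        sp = scipy.stats.spearmanr(index_table[a], index_table[b], nan_policy="omit")
        rows.append(
            {
                "index_a": a,
                "index_b": b,
                "rho": float(sp.statistic),
                "p_rho": float(sp.pvalue),
                "p_mwu": mwu(x, y),
            }
        )
    pairs = pd.DataFrame(rows)
    pairs["p_holm"] = holm_adjust(pairs["p_mwu"].to_numpy())
    return ComparisonReport(
        pairs=pairs, means=index_table[cols].mean(), m=len(pairs)
    )
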