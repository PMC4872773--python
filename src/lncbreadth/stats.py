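"""Thin statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(overlap: int, universe: int, term: int, drawn: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, term, drawn)."""
    if overlap > min(term, drawn):
        raise ValueError("overlap exceeds min(term size, set size)")
    return float(sps.hypergeom.sf(overlap - 1, universe, term, drawn))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small groups (n <= 25 each, no ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def fisher_exact(table, alternative: str = "two-sided") -> float:
    return float(sps.fisher_exact(table, alternative=alternative)[1])
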