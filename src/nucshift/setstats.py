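"""Gene-set overlap statistics.

The probability of exactly x common genes between a set of n and a set of
D drawn from a universe of N is hypergeometric,

    P(X = x) = C(D, x) C(N - D, n - x) / C(N, n),

computed here in log-binomial arithmetic so it stays exact to machine
precision for genome-sized universes.  Enrichment p-values are the upper
tail P(X >= x).  Also provided: Venn partition counts and the RNA-seq
gene-selection filter (strictly over 1.5-fold change, FDR strictly below
10%) that produces the compared sets.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "OverlapQuery",
    "hypergeom_pmf",
    "overlap_pvalue",
    "venn_counts",
    "filter_gene_table",
]


@dataclass(frozen=True)
class OverlapQuery:
    """Overlap of set 1 (size n) and set 2 (size D) in a universe of N."""

    N: int
    D: int
    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.D <= self.N and 0 <= self.n <= self.N):
            raise ValueError("need 0 <= D, n <= N")
        if not 0 <= self.x <= min(self.n, self.D):
            raise ValueError("need 0 <= x <= min(n, D)")
        if self.x < self.n - (self.N - self.D):
            raise ValueError("x below the feasible overlap range")


def _log_binom(a: int, b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pmf(q: OverlapQuery) -> float:
    """Exact P(X = x) via log-binomials."""
    logp = (
        _log_binom(q.D, q.x)
        + _log_binom(q.N - q.D, q.n - q.x)
        - _log_binom(q.N, q.n)
    )
    return float(np.exp(logp))


def overlap_pvalue(q: OverlapQuery, tail: str = "enrichment") -> float:
    """Tail probability of the observed overlap.

    ``tail='enrichment'`` (default) gives P(X >= x); ``'depletion'``
    gives P(X <= x).
    """
    hi = min(q.n, q.D)
    lo = max(0, q.n - (q.N - q.D))
    if tail == "enrichment":
        ks = np.arange(q.x, hi + 1)
    elif tail == "depletion":
        ks = np.arange(lo, q.x + 1)
    else:
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    logs = (
        _log_binom(q.D, ks)
        + _log_binom(q.N - q.D, q.n - ks)
        - _log_binom(q.N, q.n)
    )
    return float(min(1.0, np.exp(logsumexp(logs))))


def venn_counts(set_a, set_b) -> dict[str, int]:
    """Partition counts {only_a, only_b, both}; inputs deduplicated."""
    la, lb = list(set_a), list(set_b)
    a, b = set(la), set(lb)
    if len(a) != len(la) or len(b) != len(lb):
        warnings.warn("duplicate ids removed from Venn input", stacklevel=2)
    both = a & b
    return {"only_a": len(a - both), "only_b": len(b - both), "both": len(both)}


def filter_gene_table(
    table: pd.DataFrame,
    min_fc: float = 1.5,
    max_fdr: float = 0.10,
    fc_scale: str = "ratio",
    gene_col: str = "gene",
    fc_col: str = "fold_change",
    fdr_col: str = "fdr",
) -> dict[str, set[str]]:
    """Select differentially expressed genes from a fold-change/FDR table.

    Keeps genes with fold change strictly over ``min_fc`` (in either
    direction) and FDR strictly below ``max_fdr``; boundary rows are
    excluded.  ``fc_scale`` declares whether the column holds a signed
    ratio (negative = down) or a log2 ratio.  Returns {'up': ..., 'down':
    ..., 'all': ...} gene-id sets.
    """
    for col in (gene_col, fc_col, fdr_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r} in gene table")
    fc = table[fc_col].astype(float)
    if fc_scale == "ratio":
        magnitude = fc.abs()
        up = fc > 0
    elif fc_scale == "log2":
        magnitude = np.exp2(fc.abs())
        up = fc > 0
    else:
        raise ValueError("fc_scale must be 'ratio' or 'log2'")
    keep = (magnitude > min_fc) & (table[fdr_col].astype(float) < max_fdr)
    genes = table[gene_col]
    return {
        "up": set(genes[keep & up]),
        "down": set(genes[keep & ~up]),
        "all": set(genes[keep]),
    }
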