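"""Nucleosome shift detection between two conditions.

Calls from two conditions are matched one-to-one when their 147 bp
footprints overlap by at least 73 bp, which is equivalent to a dyad
distance of at most 74 bp.  Each matched pair is tested for a positional
shift with Welch's two-sample t-test built from the per-call summary
statistics (position, dyad SD, occupancy); a pair is flagged significant
at p < alpha (default 0.01, two-sided, uncorrected).  Shifts are signed
relative to the gene: positive means the nucleosome moved downstream,
away from the TSS.

The Welch test treats every raw dyad as one observation of the
nucleosome's position, so n is the call's occupancy.  By default the
position entering the test is the footprint dyad *mean* (equivalent to
running Welch on the raw dyad multisets, which keeps null p-values
uniform); ``position_stat='peak'`` uses the reported smoothed-peak dyad
instead.  The reported shift itself is always the peak-to-peak distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MAX_MATCH_DISTANCE",
    "match_calls",
    "welch_from_summary",
    "signed_shift",
    "run_shift_analysis",
]

#: |dyad_B - dyad_A| <= 74 bp <=> footprint overlap >= 73 bp.
MAX_MATCH_DISTANCE = 74


def match_calls(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, max_distance: int = MAX_MATCH_DISTANCE
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One-to-one matching of calls by footprint overlap.

    Candidate pairs (|dyad difference| <= ``max_distance``) are accepted
    greedily by smallest distance; ties are broken toward the smaller
    genomic coordinates, symmetrically in the two inputs.  Returns
    (pairs, unmatched_a, unmatched_b); ``pairs`` has one row per match
    with the indices and summary statistics of both calls, the genomic
    ``delta`` (B - A) and the footprint ``overlap`` = 147 - |delta|.
    """
    pair_rows = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for chrom in sorted(set(calls_a["chrom"]) | set(calls_b["chrom"])):
        a = calls_a[calls_a["chrom"] == chrom]
        b = calls_b[calls_b["chrom"] == chrom]
        if a.empty or b.empty:
            continue
        a_pos = a["dyad"].to_numpy()
        b_pos = b["dyad"].to_numpy()
        cand = []
        # calls are sparse (>=147 bp apart), so each A call has at most
        # one or two B candidates; enumerate via searchsorted windows
        order_b = np.argsort(b_pos, kind="stable")
        b_sorted = b_pos[order_b]
        for ia, pa in enumerate(a_pos):
            lo = np.searchsorted(b_sorted, pa - max_distance, side="left")
            hi = np.searchsorted(b_sorted, pa + max_distance, side="right")
            for k in range(lo, hi):
                ib = int(order_b[k])
                d = int(b_pos[ib] - pa)
                cand.append((abs(d), min(pa, b_pos[ib]), max(pa, b_pos[ib]), ia, ib, d))
        cand.sort()
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        for _, _, _, ia, ib, d in cand:
            if ia in taken_a or ib in taken_b:
                continue
            taken_a.add(ia)
            taken_b.add(ib)
            ra = a.iloc[ia]
            rb = b.iloc[ib]
            used_a.add(a.index[ia])
            used_b.add(b.index[ib])
            pair_rows.append(
                {
                    "chrom": chrom,
                    "dyad_a": int(ra["dyad"]),
                    "dyad_b": int(rb["dyad"]),
                    "mean_a": float(ra["dyad_mean"]),
                    "mean_b": float(rb["dyad_mean"]),
                    "sd_a": float(ra["dyad_sd"]),
                    "sd_b": float(rb["dyad_sd"]),
                    "occ_a": int(ra["occupancy"]),
                    "occ_b": int(rb["occupancy"]),
                    "delta": int(d),
                    "overlap": 147 - abs(int(d)),
                }
            )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "chrom", "dyad_a", "dyad_b", "mean_a", "mean_b",
            "sd_a", "sd_b", "occ_a", "occ_b", "delta", "overlap",
        ],
    )
    unmatched_a = calls_a.loc[~calls_a.index.isin(used_a)]
    unmatched_b = calls_b.loc[~calls_b.index.isin(used_b)]
    return pairs.sort_values(["chrom", "dyad_a"], ignore_index=True), unmatched_a, unmatched_b


def welch_from_summary(m1, s1, n1, m2, s2, n2):
    """Welch's t, Welch-Satterthwaite df and two-sided p from summaries.

    Vectorized; returns NaN triples where the pair is untestable (an
    occupancy below 2, or both SDs zero).
    """
    m1, s1, n1, m2, s2, n2 = (np.asarray(x, dtype=float) for x in (m1, s1, n1, m2, s2, n2))
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    denom = v1 + v2
    testable = (n1 >= 2) & (n2 >= 2) & (denom > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(denom)
        df = denom**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(testable, t, np.nan)
    df = np.where(testable, df, np.nan)
    p = np.where(testable, p, np.nan)
    return t, df, p


def signed_shift(delta, strand):
    """Gene-relative shift: positive = moved away from the TSS.

    ``delta`` is B.dyad - A.dyad in genome coordinates; minus-strand
    genes flip the sign.
    """
    sign = np.where(np.asarray(strand) == "-", -1, 1)
    return np.asarray(delta) * sign


def run_shift_analysis(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    genome,
    alpha: float = 0.01,
    position_stat: str = "mean",
    occupancy_cap: int | None = None,
    upstream_slack: int = 30,
) -> pd.DataFrame:
    """Match -> Welch test -> gene assignment -> signed shift -> flag.

    Gene and array-position (+1, +2, ...) labels come from assigning the
    condition-A calls to genes.  ``occupancy_cap`` optionally caps the n
    entering the Welch test (sensitivity mode).  Returns one row per
    matched pair; summary counts (tested / significant / untestable /
    unmatched) live in ``result.attrs['summary']``.
    """
    from .metagene import assign_to_genes

    if position_stat not in ("mean", "peak"):
        raise ValueError("position_stat must be 'mean' or 'peak'")
    pairs, unmatched_a, unmatched_b = match_calls(calls_a, calls_b)
    if pairs.empty:
        res = pairs.assign(
            t=[], df=[], p=[], gene_id=[], strand=[], position_index=[],
            signed_shift=[], significant=[], untestable=[],
        )
        res.attrs["summary"] = {
            "pairs": 0, "tested": 0, "significant": 0, "untestable": 0,
            "unmatched_a": len(unmatched_a), "unmatched_b": len(unmatched_b),
        }
        return res

    if position_stat == "mean":
        m1, m2 = pairs["mean_a"], pairs["mean_b"]
    else:
        m1, m2 = pairs["dyad_a"].astype(float), pairs["dyad_b"].astype(float)
    n1 = pairs["occ_a"].to_numpy()
    n2 = pairs["occ_b"].to_numpy()
    if occupancy_cap is not None:
        n1 = np.minimum(n1, occupancy_cap)
        n2 = np.minimum(n2, occupancy_cap)
    t, df, p = welch_from_summary(m1, pairs["sd_a"], n1, m2, pairs["sd_b"], n2)

    res = pairs.copy()
    res["t"] = t
    res["df"] = df
    res["p"] = p
    res["untestable"] = np.isnan(p)

    # gene / +k assignment via the condition-A call positions
    a_index = assign_to_genes(calls_a, genome, upstream_slack=upstream_slack)
    key = a_index[["chrom", "dyad", "gene_id", "position_index"]].drop_duplicates(
        ["chrom", "dyad"]
    )
    res = res.merge(
        key, left_on=["chrom", "dyad_a"], right_on=["chrom", "dyad"], how="left"
    ).drop(columns="dyad")
    strand_of = dict(zip(genome.genes["gene_id"], genome.genes["strand"]))
    strand = res["gene_id"].map(strand_of)
    res["strand"] = strand
    res["signed_shift"] = np.where(
        strand.notna(), signed_shift(res["delta"], strand.fillna("+")), np.nan
    )
    res["significant"] = (~res["untestable"]) & (res["p"] < alpha)

    testable = int((~res["untestable"]).sum())
    if testable:
        res["fdr_bh"] = np.nan
        res.loc[~res["untestable"], "fdr_bh"] = stats.false_discovery_control(
            res.loc[~res["untestable"], "p"].to_numpy(), method="bh"
        )
    else:
        res["fdr_bh"] = np.nan
    res.attrs["summary"] = {
        "pairs": len(res),
        "tested": testable,
        "significant": int(res["significant"].sum()),
        "untestable": int(res["untestable"].sum()),
        "unmatched_a": len(unmatched_a),
        "unmatched_b": len(unmatched_b),
    }
    return res
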