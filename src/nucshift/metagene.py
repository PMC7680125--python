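"""Gene-level nucleosome indexing, filters and +1-aligned metagene profiles.

Calls are assigned to genes as +1, +2, ... counting downstream from the
TSS (with a small upstream slack for the +1), genes are filtered to those
long enough to carry a full array, and the two conditions' dyad-density
tracks are averaged across genes after aligning every gene at its
wild-type +1 dyad and orienting it in the direction of transcription.
The per-position summary of repositioning is the median signed shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_to_genes",
    "filter_genes",
    "select_shifted_genes",
    "MetageneProfile",
    "metagene_profile",
    "median_shift_by_position",
]


def assign_to_genes(
    calls: pd.DataFrame, genome, upstream_slack: int = 30
) -> pd.DataFrame:
    """Label calls +1, +2, ... per gene.

    A call belongs to a gene when its dyad lies between ``TSS -
    upstream_slack`` and the TES, measured along the direction of
    transcription; the call closest downstream of the TSS is the +1.
    Returns one row per (gene, call): gene_id, chrom, strand, dyad,
    position_index.  Genes with no calls are absent (their count is in
    ``result.attrs['n_genes_without_calls']``).
    """
    rows = []
    empty = 0
    for _, g in genome.genes.iterrows():
        sub = calls[calls["chrom"] == g["chrom"]]
        if g["strand"] == "+":
            lo, hi = g["tss"] - upstream_slack, g["tes"]
            sel = sub[(sub["dyad"] >= lo) & (sub["dyad"] <= hi)]
            sel = sel.sort_values("dyad")
        else:
            lo, hi = g["tes"], g["tss"] + upstream_slack
            sel = sub[(sub["dyad"] >= lo) & (sub["dyad"] <= hi)]
            sel = sel.sort_values("dyad", ascending=False)
        if sel.empty:
            empty += 1
            continue
        for k, (_, c) in enumerate(sel.iterrows(), start=1):
            rows.append(
                (g["gene_id"], g["chrom"], g["strand"], int(c["dyad"]), k)
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "dyad", "position_index"]
    )
    out.attrs["n_genes_without_calls"] = empty
    return out


def filter_genes(
    index: pd.DataFrame,
    genome,
    min_length: int = 560,
    min_nucleosomes: int = 4,
) -> set[str]:
    """Genes long enough and covered enough for metagene analysis.

    Keeps genes with |TES - TSS| strictly greater than ``min_length``
    (560 bp excludes genes too short for a four-nucleosome array) and at
    least ``min_nucleosomes`` assigned calls, requiring a defined TSS and
    TES.
    """
    counts = index.groupby("gene_id").size()
    keep: set[str] = set()
    for _, g in genome.genes.iterrows():
        if pd.isna(g["tss"]) or pd.isna(g["tes"]):
            continue
        if abs(int(g["tes"]) - int(g["tss"])) <= min_length:
            continue
        if counts.get(g["gene_id"], 0) >= min_nucleosomes:
            keep.add(g["gene_id"])
    return keep


def select_shifted_genes(
    shift_results: pd.DataFrame,
    positions=(1, 2, 3, 4),
    alpha: float = 0.01,
) -> set[str]:
    """Genes with >= 1 significantly shifted nucleosome at the given
    array positions (p < alpha, untestable pairs never qualify)."""
    r = shift_results
    hit = (
        r["gene_id"].notna()
        & r["position_index"].isin(list(positions))
        & (~r["untestable"])
        & (r["p"] < alpha)
    )
    return set(r.loc[hit, "gene_id"])


@dataclass
class MetageneProfile:
    """+1-aligned average dyad density for two conditions.

    ``offsets`` are bp relative to the condition-A +1 dyad along the
    direction of transcription; ``mean_a``/``mean_b`` the across-gene
    average normalized dyad density; ``n_per_offset`` how many genes
    contributed at each offset (genes running off a chromosome end are
    skipped per offset).
    """

    offsets: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    n_per_offset: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "n": self.n_per_offset,
            }
        )


def metagene_profile(
    track_a,
    track_b,
    index: pd.DataFrame,
    gene_set: set[str],
    offsets=range(-200, 801),
) -> MetageneProfile:
    """Average both tracks across genes, anchored at the A +1 dyad.

    Both conditions are aligned on the *condition-A* +1 dyad so that any
    repositioning in condition B shows up as peak displacement.  Offsets
    increase downstream regardless of strand.
    """
    offsets = np.asarray(list(offsets), dtype=int)
    anchors = index[(index["position_index"] == 1) & index["gene_id"].isin(gene_set)]
    if anchors.empty:
        raise ValueError("empty gene set for metagene profile")
    sum_a = np.zeros(offsets.size)
    sum_b = np.zeros(offsets.size)
    n = np.zeros(offsets.size, dtype=int)
    for _, g in anchors.iterrows():
        direction = 1 if g["strand"] == "+" else -1
        pos = g["dyad"] + direction * offsets
        va = track_a.values[g["chrom"]]
        vb = track_b.values[g["chrom"]]
        ok = (pos >= 0) & (pos < va.size)
        pa = np.full(offsets.size, np.nan)
        pb = np.full(offsets.size, np.nan)
        pa[ok] = va[pos[ok]]
        pb[ok] = vb[pos[ok]]
        use = ok & ~np.isnan(pa) & ~np.isnan(pb)
        sum_a[use] += pa[use]
        sum_b[use] += pb[use]
        n[use] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.where(n > 0, sum_a / n, np.nan)
        mean_b = np.where(n > 0, sum_b / n, np.nan)
    return MetageneProfile(
        offsets=offsets,
        mean_a=mean_a,
        mean_b=mean_b,
        n_per_offset=n,
        n_genes=len(anchors),
    )


def median_shift_by_position(
    shift_results: pd.DataFrame,
    gene_set: set[str],
    positions=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Median signed shift per array position over a gene set.

    Cells with no contributing pairs are absent, not zero.  The mean is
    reported alongside for diagnostics.
    """
    r = shift_results[
        shift_results["gene_id"].isin(gene_set)
        & shift_results["position_index"].isin(list(positions))
        & shift_results["signed_shift"].notna()
    ]
    rows = []
    for k in positions:
        vals = r.loc[r["position_index"] == k, "signed_shift"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        rows.append(
            {
                "position_index": k,
                "median_shift": float(np.median(vals)),
                "mean_shift": float(np.mean(vals)),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["position_index", "median_shift", "mean_shift", "n"])
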