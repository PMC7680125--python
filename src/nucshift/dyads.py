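"""Dyad density maps from paired-end MNase fragments.

A fragment protects ~147 bp around the nucleosome dyad, so the dyad is
estimated as the fragment midpoint: ``floor((start + end - 1) / 2)`` on a
0-based half-open interval, i.e. the centre of the closed base range,
rounded down for even lengths.  Dyads falling in excluded regions (the
repetitive rDNA locus in the original study) are removed before building
the per-bp track, and excluded positions are masked out of the
normalization denominator rather than zero-filled.  After normalization
the mean track value over non-excluded positions is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RRNA_LOCUS_SACCER3",
    "DyadTrack",
    "fragments_to_dyads",
    "filter_regions",
    "build_track",
    "pool_dyads",
]

#: The repetitive rDNA locus excluded in the original analysis
#: (chrXII:451275-469084 in 1-based inclusive coordinates), expressed
#: 0-based half-open.
RRNA_LOCUS_SACCER3 = ("chrXII", 451274, 469084)


def fragments_to_dyads(fragments: pd.DataFrame) -> pd.DataFrame:
    """Midpoints of paired-end fragments.

    ``fragments`` needs chrom/start/end columns (0-based half-open);
    condition and replicate columns are carried through when present.
    """
    if len(fragments) and (fragments["start"] >= fragments["end"]).any():
        raise ValueError("fragments must satisfy start < end")
    dyads = pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "pos": (fragments["start"] + fragments["end"] - 1) // 2,
        }
    )
    for col in ("condition", "replicate"):
        if col in fragments.columns:
            dyads[col] = fragments[col]
    return dyads


def _exclusion_frame(exclusions) -> pd.DataFrame:
    if exclusions is None:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if isinstance(exclusions, pd.DataFrame):
        return exclusions
    return pd.DataFrame(list(exclusions), columns=["chrom", "start", "end"])


def filter_regions(dyads: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Drop dyads inside half-open exclusion intervals.

    The number removed is recorded in ``result.attrs['n_removed']``.
    """
    excl = _exclusion_frame(exclusions)
    keep = np.ones(len(dyads), dtype=bool)
    for _, r in excl.iterrows():
        hit = (
            (dyads["chrom"] == r["chrom"])
            & (dyads["pos"] >= r["start"])
            & (dyads["pos"] < r["end"])
        )
        keep &= ~hit.to_numpy()
    out = dyads.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int(len(dyads) - keep.sum())
    return out


@dataclass
class DyadTrack:
    """Per-chromosome normalized dyad density with an exclusion mask.

    ``values[chrom]`` holds one float per bp; excluded positions carry
    NaN (a sentinel, not zero).  ``norm_factor`` is total dyads divided
    by non-excluded genome length, so values are counts / norm_factor
    and the non-excluded mean is 1.
    """

    values: dict[str, np.ndarray]
    excluded: dict[str, np.ndarray]
    norm_factor: float
    n_dyads: int

    def mean_nonexcluded(self) -> float:
        total, count = 0.0, 0
        for chrom, v in self.values.items():
            ok = ~self.excluded[chrom]
            total += float(v[ok].sum())
            count += int(ok.sum())
        return total / count

    def get(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos])


def build_track(dyads: pd.DataFrame, genome, exclusions=None) -> DyadTrack:
    """Bin dyads per bp and normalize to the mean genome-wide coverage.

    Dyads inside exclusion regions are filtered first; excluded positions
    are masked (NaN) and do not enter the normalization denominator.
    """
    excl = _exclusion_frame(exclusions)
    dyads = filter_regions(dyads, excl)
    if len(dyads) == 0:
        raise ValueError("no dyads left to build a track from")

    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    nonexcl_length = 0
    for chrom, length in genome.chromosomes.items():
        m = np.zeros(length, dtype=bool)
        for _, r in excl.iterrows():
            if r["chrom"] == chrom:
                m[max(0, int(r["start"])): min(length, int(r["end"]))] = True
        mask[chrom] = m
        nonexcl_length += int(length - m.sum())
        sub = dyads.loc[dyads["chrom"] == chrom, "pos"].to_numpy()
        if (len(sub) and ((sub < 0).any() or (sub >= length).any())):
            raise ValueError(f"dyad positions outside chromosome {chrom}")
        counts = np.bincount(sub, minlength=length).astype(float)
        values[chrom] = counts

    total = int(len(dyads))
    norm = total / nonexcl_length
    for chrom in values:
        values[chrom] /= norm
        values[chrom][mask[chrom]] = np.nan
    return DyadTrack(values=values, excluded=mask, norm_factor=norm, n_dyads=total)


def pool_dyads(
    dyad_lists: list[pd.DataFrame],
    genome,
    exclusions=None,
    mode: str = "raw",
) -> DyadTrack:
    """Pool replicate dyad lists into one track.

    ``mode='raw'`` (default) concatenates raw dyads before normalizing,
    the reading used throughout; ``mode='mean-of-normalized'`` averages
    per-replicate normalized tracks instead.
    """
    if mode == "raw":
        return build_track(pd.concat(dyad_lists, ignore_index=True), genome, exclusions)
    if mode != "mean-of-normalized":
        raise ValueError("mode must be 'raw' or 'mean-of-normalized'")
    tracks = [build_track(d, genome, exclusions) for d in dyad_lists]
    first = tracks[0]
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    return DyadTrack(
        values=values,
        excluded=first.excluded,
        norm_factor=float(np.mean([t.norm_factor for t in tracks])),
        n_dyads=sum(t.n_dyads for t in tracks),
    )
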