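"""Greedy nucleosome calling on a smoothed dyad track.

The dyad track is convolved with a unit-sum Gaussian kernel (truncated at
+/-4 sigma) and stereotypic nucleosome positions are picked greedily: the
global maximum of the smoothed signal becomes a call, a 147 bp
centre-to-centre exclusion zone is suppressed around it, and the process
repeats.  Each call carries the peak position, the raw dyads' sample
standard deviation ("fuzziness") and count ("occupancy") inside the
147 bp footprint [dyad-73, dyad+73], and the mean raw dyad position.

Footprints of accepted calls are disjoint by construction (centres at
least 147 bp apart), so every raw dyad is counted by at most one call.
Candidates whose footprint occupancy falls below ``min_occupancy`` are
rejected but still suppress their window; ties in the greedy maximum are
broken toward the smallest coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = ["FOOTPRINT_HALF_WIDTH", "smooth_track", "call_nucleosomes", "assign_statistics"]

#: Half-width of the 147 bp nucleosome footprint, [dyad-73, dyad+73].
FOOTPRINT_HALF_WIDTH = 73


def smooth_track(track, sigma: float = 20.0) -> dict[str, np.ndarray]:
    """Gaussian-smooth a dyad track (or a {chrom: array} dict).

    Excluded (NaN) positions contribute zero to the convolution and stay
    NaN in the output.  The kernel is truncated at +/-4 sigma and
    normalized to unit sum, so a flat track smooths to itself away from
    the edges.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    values = track if isinstance(track, dict) else track.values
    out = {}
    for chrom, v in values.items():
        filled = np.nan_to_num(v, nan=0.0)
        sm = gaussian_filter1d(filled, sigma=sigma, mode="constant", cval=0.0, truncate=4.0)
        sm[np.isnan(v)] = np.nan
        out[chrom] = sm
    return out


def _dyads_in_window(sorted_pos: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Raw dyads with lo <= pos <= hi (closed interval)."""
    i = np.searchsorted(sorted_pos, lo, side="left")
    j = np.searchsorted(sorted_pos, hi, side="right")
    return sorted_pos[i:j]


def assign_statistics(dyad: int, sorted_pos: np.ndarray) -> tuple[int, float, float]:
    """Occupancy, dyad SD and dyad mean over the 147 bp footprint.

    The SD is the n-1 sample formula; by convention it is 0 when fewer
    than two dyads support the call.
    """
    window = _dyads_in_window(
        sorted_pos, dyad - FOOTPRINT_HALF_WIDTH, dyad + FOOTPRINT_HALF_WIDTH
    )
    occ = int(window.size)
    if occ == 0:
        return 0, 0.0, float(dyad)
    sd = float(np.std(window, ddof=1)) if occ >= 2 else 0.0
    return occ, sd, float(window.mean())


def call_nucleosomes(
    smoothed: dict[str, np.ndarray],
    raw_dyads: pd.DataFrame,
    exclusion_width: int = 147,
    min_occupancy: int = 10,
    max_calls: int | None = None,
) -> pd.DataFrame:
    """Greedy peak selection with a centre-to-centre exclusion zone.

    A new call is forbidden within ``exclusion_width`` bp of any earlier
    candidate (|delta dyad| < exclusion_width), so accepted 147 bp
    footprints at worst abut.  Candidates with footprint occupancy below
    ``min_occupancy`` are rejected (they still suppress their window).

    Returns a frame sorted by (chrom, dyad) with columns chrom, dyad,
    dyad_sd, occupancy, score, dyad_mean, untestable.
    """
    rows = []
    for chrom in sorted(smoothed):
        sig = np.nan_to_num(smoothed[chrom], nan=0.0).copy()
        pos = np.sort(
            raw_dyads.loc[raw_dyads["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
        )
        n_kept = 0
        while True:
            if max_calls is not None and n_kept >= max_calls:
                break
            i = int(np.argmax(sig))  # ties -> smallest coordinate
            height = sig[i]
            if height <= 0:
                break
            occ, sd, mean = assign_statistics(i, pos)
            if occ >= min_occupancy:
                rows.append((chrom, i, sd, occ, float(height), mean, occ < 2))
                n_kept += 1
            lo = max(0, i - (exclusion_width - 1))
            sig[lo: i + exclusion_width] = 0.0
    calls = pd.DataFrame(
        rows,
        columns=["chrom", "dyad", "dyad_sd", "occupancy", "score", "dyad_mean", "untestable"],
    )
    return calls.sort_values(["chrom", "dyad"], ignore_index=True)
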