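"""Synthetic inputs for the nucleosome-repositioning pipeline.

Everything the downstream stages consume can be generated here with seeded
reproducibility: a gene-annotated genome, a ground-truth nucleosome map with
programmed condition-specific dyad shifts, paired-end MNase-like fragment
sets, Hill-shaped binding titrations, and saturating-exponential remodeling
or ATPase time courses.

Coordinates are 0-based throughout.  A gene's TSS and TES are inclusive
positions; for a minus-strand gene TSS > TES.  "Downstream" always means
along the direction of transcription (increasing coordinate on the plus
strand, decreasing on the minus strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "TrueNucleosomeMap",
    "PlacementError",
    "make_genome",
    "place_nucleosomes",
    "apply_shifts",
    "simulate_fragments",
    "simulate_titration",
    "simulate_timecourse",
]


class PlacementError(ValueError):
    """Requested genes cannot be packed onto the genome without overlap."""


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a gene table.

    ``genes`` columns: gene_id, chrom, strand (+/-), tss, tes.
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss", "tes"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for _, row in g.iterrows():
            length = self.chromosomes[row["chrom"]]
            if not (0 <= row["tss"] < length and 0 <= row["tes"] < length):
                raise ValueError(f"gene {row['gene_id']} outside chromosome")
            if row["tss"] == row["tes"]:
                raise ValueError(f"gene {row['gene_id']} has TSS == TES")
            if row["strand"] == "+" and not row["tss"] < row["tes"]:
                raise ValueError(f"+ strand gene {row['gene_id']} needs TSS < TES")
            if row["strand"] == "-" and not row["tss"] > row["tes"]:
                raise ValueError(f"- strand gene {row['gene_id']} needs TSS > TES")

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))


@dataclass
class TrueNucleosomeMap:
    """Ground-truth nucleosomes for one condition.

    ``entries`` columns: chrom, dyad, fuzziness_sd, weight, gene_id,
    position_index (+1, +2, ... counted from the TSS; <NA> for orphans).
    """

    entries: pd.DataFrame
    condition: str = "WT"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        e = self.entries
        if len(e):
            if (e["fuzziness_sd"] < 0).any():
                raise ValueError("fuzziness_sd must be >= 0")
            if (e["weight"] < 0).any():
                raise ValueError("occupancy weight must be >= 0")


def _gene_lengths(rng: np.random.Generator, n: int, min_len: int) -> np.ndarray:
    # Uniform between the minimum and twice the minimum keeps packing simple
    # while still exercising the >560 bp gene-length filter downstream.
    return rng.integers(min_len, 2 * min_len + 1, size=n)


def make_genome(
    n_chromosomes: int,
    chromosome_length: int,
    n_genes: int,
    min_gene_length: int = 1000,
    seed: int = 0,
    intergenic_gap: int = 300,
) -> GenomeAnnotation:
    """Lay out non-overlapping genes on equally sized chromosomes.

    Genes never overlap (on either strand) and each carries a well-defined
    TSS and TES.  Strands are drawn at random but both strands are always
    represented when two or more genes are placed.  Deterministic for a
    given seed.

    Raises
    ------
    PlacementError
        If the requested genes cannot fit at the requested lengths.
    """
    if n_chromosomes < 1 or chromosome_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": int(chromosome_length) for i in range(n_chromosomes)}
    if n_genes == 0:
        genes = pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss", "tes"])
        return GenomeAnnotation(chroms, genes)

    lengths = _gene_lengths(rng, n_genes, min_gene_length)
    strands = rng.choice(["+", "-"], size=n_genes)
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "+" if strands[-1] == "-" else "-"

    # Sequential packing, round-robin over chromosomes via a cursor each.
    cursors = {c: intergenic_gap for c in chroms}
    rows = []
    order = list(chroms)
    ci = 0
    for k in range(n_genes):
        placed = False
        for _ in range(len(order)):
            chrom = order[ci % len(order)]
            start = cursors[chrom]
            end = start + int(lengths[k])  # half-open gene body
            if end + intergenic_gap <= chroms[chrom]:
                cursors[chrom] = end + intergenic_gap
                if strands[k] == "+":
                    tss, tes = start, end - 1
                else:
                    tss, tes = end - 1, start
                rows.append((f"g{k + 1:04d}", chrom, strands[k], tss, tes))
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise PlacementError(
                f"could not place gene {k + 1}/{n_genes} of length {lengths[k]} bp"
            )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    return GenomeAnnotation(chroms, genes)


def place_nucleosomes(
    genome: GenomeAnnotation,
    nfr_length: int = 140,
    spacing: int = 165,
    n_per_gene: int = 4,
    fuzziness_sd: float = 20.0,
    occupancy_weights: list[float] | None = None,
    condition: str = "WT",
) -> TrueNucleosomeMap:
    """Place regular +1..+N nucleosome arrays downstream of every TSS.

    The +k dyad sits at ``TSS + nfr_length/2 + (k-1)*spacing`` measured
    along the direction of transcription, emulating the promoter-proximal
    arrays whose spacing the remodeler maintains in vivo.  Nucleosomes
    falling off a chromosome end are dropped (counted in ``n_dropped``).
    """
    if n_per_gene < 1:
        raise ValueError("n_per_gene must be >= 1")
    if spacing < 147:
        warnings.warn(
            f"spacing {spacing} bp is below the 147 bp nucleosome footprint; "
            "adjacent nucleosomes will overlap",
            stacklevel=2,
        )
    if occupancy_weights is None:
        occupancy_weights = [1.0] * n_per_gene
    if len(occupancy_weights) != n_per_gene:
        raise ValueError("occupancy_weights must have n_per_gene entries")

    half_nfr = int(round(nfr_length / 2))
    rows = []
    dropped = 0
    for _, g in genome.genes.iterrows():
        direction = 1 if g["strand"] == "+" else -1
        chrom_len = genome.chromosomes[g["chrom"]]
        for k in range(1, n_per_gene + 1):
            dyad = g["tss"] + direction * (half_nfr + (k - 1) * spacing)
            if not 0 <= dyad < chrom_len:
                dropped += 1
                continue
            rows.append(
                (g["chrom"], int(dyad), float(fuzziness_sd),
                 float(occupancy_weights[k - 1]), g["gene_id"], k)
            )
    if dropped:
        warnings.warn(f"{dropped} nucleosomes fell outside chromosome bounds", stacklevel=2)
    entries = pd.DataFrame(
        rows, columns=["chrom", "dyad", "fuzziness_sd", "weight", "gene_id", "position_index"]
    )
    return TrueNucleosomeMap(entries, condition=condition, n_dropped=dropped)


def apply_shifts(
    nmap: TrueNucleosomeMap,
    shift_spec: dict[int, int],
    genome: GenomeAnnotation,
    condition: str | None = None,
) -> TrueNucleosomeMap:
    """Displace chosen array positions along the direction of transcription.

    ``shift_spec`` maps position index (+2, +3, ...) to a signed shift in
    bp; positive moves the nucleosome downstream, i.e. away from the TSS,
    so minus-strand genes move toward smaller coordinates.
    """
    strand_of = dict(zip(genome.genes["gene_id"], genome.genes["strand"]))
    entries = nmap.entries.copy()
    if shift_spec and len(entries):
        direction = entries["gene_id"].map(strand_of).map({"+": 1, "-": -1})
        shift = entries["position_index"].map(shift_spec).fillna(0).astype(int)
        entries["dyad"] = entries["dyad"] + direction * shift
    return TrueNucleosomeMap(
        entries,
        condition=condition if condition is not None else nmap.condition,
        n_dropped=nmap.n_dropped,
    )


def simulate_fragments(
    nmap: TrueNucleosomeMap,
    genome: GenomeAnnotation,
    fragments_per_unit_weight: int = 300,
    fragment_length_mean: float = 147.0,
    fragment_length_sd: float = 10.0,
    seed: int = 0,
    replicate: int = 0,
) -> pd.DataFrame:
    """Draw mononucleosome-sized paired-end fragments around true dyads.

    Each entry contributes ``round(weight * fragments_per_unit_weight)``
    fragments.  A fragment's dyad is Normal(true dyad, fuzziness_sd)
    rounded to an integer; its length is Normal(mean, sd) rounded with a
    50 bp floor.  The fragment is laid out so that the midpoint convention
    of the dyad-track stage, ``floor((start + end - 1)/2)``, recovers the
    drawn dyad exactly.  Fragments sticking out of a chromosome are
    clipped and flagged.

    Returns a BED-like frame: chrom, start, end, condition, replicate,
    clipped.
    """
    if fragment_length_mean < 1:
        raise ValueError("fragment_length_mean must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for _, e in nmap.entries.iterrows():
        n = int(round(e["weight"] * fragments_per_unit_weight))
        if n == 0:
            continue
        dyads = np.rint(rng.normal(e["dyad"], e["fuzziness_sd"], size=n)).astype(np.int64)
        lengths = np.rint(
            rng.normal(fragment_length_mean, fragment_length_sd, size=n)
        ).astype(np.int64)
        lengths = np.maximum(lengths, 50)
        start = dyads - (lengths - 1) // 2
        end = start + lengths
        chrom_len = genome.chromosomes[e["chrom"]]
        clipped = (start < 0) | (end > chrom_len)
        start = np.clip(start, 0, chrom_len - 1)
        end = np.clip(end, start + 1, chrom_len)
        parts.append(
            pd.DataFrame(
                {"chrom": e["chrom"], "start": start, "end": end, "clipped": clipped}
            )
        )
    if parts:
        frags = pd.concat(parts, ignore_index=True)
    else:
        frags = pd.DataFrame(columns=["chrom", "start", "end", "clipped"])
    frags["condition"] = nmap.condition
    frags["replicate"] = replicate
    return frags[["chrom", "start", "end", "condition", "replicate", "clipped"]]


def hill(conc, kd: float, h: float):
    """Fraction bound on the Hill curve f([E]) = [E]^H / (K_D^H + [E]^H)."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    out[pos] = conc[pos] ** h / (kd**h + conc[pos] ** h)
    return out


def simulate_titration(
    kd: float,
    h: float,
    concentrations,
    noise_sd: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-curve binding titration with Gaussian noise on fraction bound.

    Returns columns: concentration (nM), fraction_bound, replicate,
    clipped (True where the noisy value fell outside [0, 1] and was
    clipped back in).
    """
    if kd <= 0 or h <= 0:
        raise ValueError("kd and h must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(list(concentrations), dtype=float)
    rows = []
    for r in range(replicates):
        f = hill(conc, kd, h) + rng.normal(0.0, noise_sd, size=conc.size)
        clipped = (f < 0) | (f > 1)
        f = np.clip(f, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {"concentration": conc, "fraction_bound": f,
                 "replicate": r, "clipped": clipped}
            )
        )
    return pd.concat(rows, ignore_index=True)


def saturating_exponential(t, v0: float, plateau: float):
    """A(1 - exp(-(v0/A) t)): analytic slope at t = 0 equals v0."""
    t = np.asarray(t, dtype=float)
    if v0 == 0:
        return np.zeros_like(t)
    return plateau * (1.0 - np.exp(-(v0 / plateau) * t))


def simulate_timecourse(
    v0: float,
    plateau: float,
    times,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Remodeling/ATPase time course on a saturating exponential.

    ``times`` must be nonnegative and strictly increasing.  The signal is
    floored at zero after adding Gaussian noise.  Columns: time_s,
    signal_nM.
    """
    if v0 < 0 or plateau <= 0:
        raise ValueError("need v0 >= 0 and plateau > 0")
    t = np.asarray(list(times), dtype=float)
    if (t < 0).any() or (np.diff(t) <= 0).any():
        raise ValueError("times must be nonnegative and strictly increasing")
    rng = np.random.default_rng(seed)
    signal = saturating_exponential(t, v0, plateau)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=t.size)
    signal = np.maximum(signal, 0.0)
    return pd.DataFrame({"time_s": t, "signal_nM": signal})


#: Time grid (seconds) used for the single-round remodeling assays.
REMODELING_TIMES_S = (0, 10, 20, 40, 80, 160, 320, 640)
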