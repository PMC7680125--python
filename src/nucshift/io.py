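"""File-format ingest and emit shared by all pipeline stages.

All genomic coordinates are 0-based half-open internally.  BED and
bedGraph are native; GFF3 (1-based, inclusive) is converted on ingest at
a single site, :func:`to_zero_based_interval`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dyads import DyadTrack
from .synth import GenomeAnnotation, TrueNucleosomeMap

__all__ = [
    "to_zero_based_interval",
    "write_fragments_bed", "read_fragments_bed",
    "read_exclusions_bed",
    "write_genome_tsv", "read_genome_tsv",
    "write_genes_gff3", "read_genes_gff3",
    "write_nucleosome_map_tsv",
    "write_calls_tsv", "read_calls_tsv",
    "write_track_bedgraph", "read_track_bedgraph",
]


def to_zero_based_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError("invalid 1-based inclusive interval")
    return start_1based - 1, end_1based


# -- fragments / exclusions (BED) -------------------------------------------


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    """6-column BED: chrom, start, end, name=condition.replicate, 0, '.'"""
    out = pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "start": fragments["start"],
            "end": fragments["end"],
            "name": fragments["condition"].astype(str)
            + "."
            + fragments["replicate"].astype(str),
            "score": 0,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    name = bed["name"].astype(str).str.rsplit(".", n=1, expand=True)
    bed["condition"] = name[0]
    bed["replicate"] = pd.to_numeric(name[1], errors="coerce").fillna(0).astype(int)
    return bed[["chrom", "start", "end", "condition", "replicate"]]


def read_exclusions_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )


# -- genome annotation -------------------------------------------------------


def write_genome_tsv(genome: GenomeAnnotation, path) -> None:
    """Genes plus chromosome sizes in one TSV (sizes as '#chrom=len' headers)."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom, length in genome.chromosomes.items():
            fh.write(f"#chromsize\t{chrom}\t{length}\n")
        genome.genes.to_csv(fh, sep="\t", index=False)


def read_genome_tsv(path) -> GenomeAnnotation:
    path = Path(path)
    chroms: dict[str, int] = {}
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#chromsize"):
                _, chrom, length = line.rstrip("\n").split("\t")
                chroms[chrom] = int(length)
                header_lines += 1
            else:
                break
    genes = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return GenomeAnnotation(chroms, genes)


def write_genes_gff3(genome: GenomeAnnotation, path) -> None:
    """Genes as GFF3 (1-based inclusive, per the format)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genome.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for _, g in genome.genes.iterrows():
            lo = min(g["tss"], g["tes"]) + 1
            hi = max(g["tss"], g["tes"]) + 1
            fh.write(
                f"{g['chrom']}\tnucshift\tgene\t{lo}\t{hi}\t.\t{g['strand']}\t.\t"
                f"ID={g['gene_id']}\n"
            )


def read_genes_gff3(path) -> GenomeAnnotation:
    chroms: dict[str, int] = {}
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _, length = line.split()
                chroms[chrom] = int(length)
                continue
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[2] != "gene":
                continue
            start0, end0 = to_zero_based_interval(int(f[3]), int(f[4]))
            strand = f[6]
            gene_id = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ).get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            if strand == "+":
                tss, tes = start0, end0 - 1
            else:
                tss, tes = end0 - 1, start0
            rows.append((gene_id, f[0], strand, tss, tes))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    if not chroms:
        # fall back to spans implied by the genes themselves
        for _, g in genes.iterrows():
            hi = max(g["tss"], g["tes"]) + 1
            chroms[g["chrom"]] = max(chroms.get(g["chrom"], 0), hi)
    return GenomeAnnotation(chroms, genes)


def write_nucleosome_map_tsv(nmap: TrueNucleosomeMap, path) -> None:
    nmap.entries.assign(condition=nmap.condition).to_csv(path, sep="\t", index=False)


# -- calls -------------------------------------------------------------------


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["footprint_start"] = out["dyad"] - 73
    out["footprint_end"] = out["dyad"] + 73 + 1  # half-open
    out.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t")
    return calls.drop(columns=[c for c in ("footprint_start", "footprint_end") if c in calls])


# -- tracks (bedGraph) -------------------------------------------------------


def _runs(values: np.ndarray):
    """(start, end, value) runs of equal value, skipping NaN stretches."""
    n = values.size
    with np.errstate(invalid="ignore"):
        edges = np.flatnonzero(
            np.diff(np.nan_to_num(values, nan=np.inf), prepend=np.nan) != 0
        )
    starts = edges
    ends = np.append(edges[1:], n)
    for s, e in zip(starts, ends):
        v = values[s]
        if not np.isnan(v):
            yield int(s), int(e), float(v)


def write_track_bedgraph(track: DyadTrack, path, mask_path=None) -> None:
    """4-column bedGraph of value runs; excluded positions are omitted
    (optionally emitted to ``mask_path`` as BED)."""
    with Path(path).open("w") as fh:
        for chrom in sorted(track.values):
            for s, e, v in _runs(track.values[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
    if mask_path is not None:
        with Path(mask_path).open("w") as fh:
            for chrom in sorted(track.excluded):
                m = track.excluded[chrom].astype(np.int8)
                for s, e, v in _runs(m.astype(float)):
                    if v == 1.0:
                        fh.write(f"{chrom}\t{s}\t{e}\n")


def read_track_bedgraph(path, genome: GenomeAnnotation, mask_path=None) -> DyadTrack:
    values = {c: np.full(length, 0.0) for c, length in genome.chromosomes.items()}
    bg = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for _, r in bg.iterrows():
        values[r["chrom"]][int(r["start"]): int(r["end"])] = r["value"]
    excluded = {c: np.zeros(length, dtype=bool) for c, length in genome.chromosomes.items()}
    if mask_path is not None:
        mask = pd.read_csv(
            mask_path, sep="\t", header=None, names=["chrom", "start", "end"]
        )
        for _, r in mask.iterrows():
            excluded[r["chrom"]][int(r["start"]): int(r["end"])] = True
            values[r["chrom"]][int(r["start"]): int(r["end"])] = np.nan
    # raw dyad count and normalization factor are not recoverable from a
    # normalized bedGraph; mark them as unknown
    return DyadTrack(values=values, excluded=excluded, norm_factor=np.nan, n_dyads=0)
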