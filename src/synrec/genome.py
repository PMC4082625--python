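"""Shared genomic containers: assemblies, genes and the ortholog table.

Coordinates are 0-based half-open throughout the library (BED convention);
1-based inclusive coordinates appear only in human-readable report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical column order of an ortholog table
ORTHOLOG_COLUMNS = [
    "gene_id",
    "ref_chrom", "ref_start", "ref_end", "ref_strand",
    "tgt_chrom", "tgt_start", "tgt_end", "tgt_strand",
]


@dataclass(frozen=True)
class Gene:
    """A gene interval on one genome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class GenomeAssembly:
    """Chromosome lengths plus assembly-gap (N-run) intervals.

    N-runs mark centromeres in the synthetic genomes; the masking stage
    builds its pericentromeric windows around them.
    """

    lengths: dict[str, int]
    n_runs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
            for (s, e) in self.n_runs.get(chrom, []):
                if not (0 <= s < e <= length):
                    raise ValueError(f"chromosome {chrom}: N-run [{s}, {e}) outside [0, {length})")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def total_bp(self) -> int:
        return sum(self.lengths.values())


def validate_ortholog_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an ortholog table and return it sorted by reference coordinates.

    One row per gene; start < end on both genomes; strands in {+, -}.
    """
    missing = [c for c in ORTHOLOG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicated gene_id(s) in ortholog table: {dups[:5]}")
    for side in ("ref", "tgt"):
        bad = table[table[f"{side}_start"] >= table[f"{side}_end"]]
        if len(bad):
            raise ValueError(f"{side} interval with start >= end for gene(s) "
                             f"{bad['gene_id'].tolist()[:5]}")
        if not table[f"{side}_strand"].isin(["+", "-"]).all():
            raise ValueError(f"{side}_strand must be '+' or '-'")
    return (table[ORTHOLOG_COLUMNS]
            .sort_values(["ref_chrom", "ref_start"], kind="mergesort")
            .reset_index(drop=True))


def swap_reference(table: pd.DataFrame) -> pd.DataFrame:
    """Exchange reference and target genomes of an ortholog table."""
    swapped = table.rename(columns={
        f"ref_{f}": f"tgt_{f}" for f in ("chrom", "start", "end", "strand")
    } | {
        f"tgt_{f}": f"ref_{f}" for f in ("chrom", "start", "end", "strand")
    })
    return validate_ortholog_table(swapped)


def clipped_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the overlap between two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union a list of half-open intervals into sorted disjoint intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
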