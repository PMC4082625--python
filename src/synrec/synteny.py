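"""Homologous synteny block (HSB) detection and evolutionary breakpoint
regions (EBRs) from orthologous gene order.

Two genomes are compared through a table of orthologous genes carrying
coordinates and strand on both sides.  An HSB is a maximal run of
reference-ordered markers that stay on one chromosome pair, keep a single
strand relation, stay monotone in target order (ascending for same-orientation
blocks, descending for inverted ones) and never jump farther than a
configurable gap on either genome.  The intervals between consecutive HSBs on
a chromosome are the EBR candidates; candidates larger than 4 Mbp are assembly
"gaps" rather than breakpoint evidence and are excluded downstream.

A marker-bounded narrowing step tightens each EBR to the innermost flanking
ortholog coordinates; no sequence alignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .genome import GenomeAssembly, swap_reference, validate_ortholog_table

MAX_EBR_BP = 4_000_000  # larger inter-block intervals are assembly gaps


@dataclass
class HSB:
    hsb_id: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: str           # "same" | "inverted"
    marker_count: int
    marker_ids: list[str] = field(default_factory=list)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def tgt_span(self) -> int:
        return self.tgt_end - self.tgt_start


@dataclass
class EBR:
    genome: str                # "ref" | "tgt"
    chrom: str
    start: int
    end: int
    flank_hsb_ids: tuple[str | None, str | None] = (None, None)
    detector: str = "chain"    # "chain" | "narrowed" | "merged"
    status: str = "candidate"  # candidate | gap | telomeric | centromeric | retained
    flagged: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EBR") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def _relation(row) -> str:
    return "same" if row.ref_strand == row.tgt_strand else "flipped"


def _extends(block_rows: list, row, max_gap: int) -> bool:
    """Can ``row`` extend the chain ``block_rows`` under the chaining rules?"""
    last = block_rows[-1]
    first = block_rows[0]
    if row.ref_chrom != last.ref_chrom or row.tgt_chrom != last.tgt_chrom:
        return False
    if _relation(row) != _relation(first):
        return False
    # gap rule on the reference genome: an indel leaves a gap on one genome
    # only, and must surface as an EBR only in the direction where that
    # genome is the reference
    if row.ref_start - last.ref_end > max_gap:
        return False
    # monotone target order, direction tied to the strand relation
    if _relation(first) == "same":
        return row.tgt_start > last.tgt_start
    return row.tgt_start < last.tgt_start


def detect_hsbs(orthologs: pd.DataFrame,
                min_markers: int = 2,
                max_marker_gap_bp: int = MAX_EBR_BP) -> list[HSB]:
    """Greedy chaining of reference-ordered orthologs into synteny blocks.

    Markers are scanned in reference order; the current block is extended
    while the next marker shares the chromosome pair and strand relation,
    continues the block's monotone target order, and lies within
    ``max_marker_gap_bp`` of the previous marker on the reference genome.
    Blocks shorter than ``min_markers`` are dropped (a single out-of-order
    marker cannot found a block).
    """
    table = validate_ortholog_table(orthologs)
    if table.empty:
        return []

    blocks: list[list] = []
    current: list = []
    for row in table.itertuples(index=False):
        if current and _extends(current, row, max_marker_gap_bp):
            current.append(row)
        else:
            if current:
                blocks.append(current)
            current = [row]
    blocks.append(current)

    out: list[HSB] = []
    for rows in blocks:
        if len(rows) < min_markers:
            continue
        orient = "same" if _relation(rows[0]) == "same" else "inverted"
        out.append(HSB(
            hsb_id=f"hsb_{len(out)}",
            ref_chrom=rows[0].ref_chrom,
            ref_start=min(r.ref_start for r in rows),
            ref_end=max(r.ref_end for r in rows),
            tgt_chrom=rows[0].tgt_chrom,
            tgt_start=min(r.tgt_start for r in rows),
            tgt_end=max(r.tgt_end for r in rows),
            orientation=orient,
            marker_count=len(rows),
            marker_ids=[r.gene_id for r in rows],
        ))
    return out


def derive_ebrs(hsbs: list[HSB],
                assembly: GenomeAssembly | None = None,
                max_ebr_bp: int = MAX_EBR_BP,
                genome: str = "ref") -> list[EBR]:
    """Inter-block intervals per chromosome; > ``max_ebr_bp`` become "gaps".

    Terminal intervals (chromosome end to first/last HSB) are not EBRs and
    are not emitted.
    """
    if assembly is not None:
        for h in hsbs:
            length = assembly.lengths.get(h.ref_chrom)
            if length is None or h.ref_end > length or h.ref_start < 0:
                raise ValueError(f"HSB {h.hsb_id} outside chromosome bounds on {h.ref_chrom}")
    by_chrom: dict[str, list[HSB]] = {}
    for h in hsbs:
        by_chrom.setdefault(h.ref_chrom, []).append(h)
    ebrs: list[EBR] = []
    for chrom, blocks in by_chrom.items():
        blocks = sorted(blocks, key=lambda h: h.ref_start)
        for left, right in zip(blocks, blocks[1:]):
            start, end = left.ref_end, right.ref_start
            if end < start:
                raise ValueError(f"overlapping HSBs {left.hsb_id}/{right.hsb_id} on {chrom}")
            status = "candidate" if end - start <= max_ebr_bp else "gap"
            ebrs.append(EBR(genome=genome, chrom=chrom, start=start, end=end,
                            flank_hsb_ids=(left.hsb_id, right.hsb_id), status=status))
    return ebrs


def narrow_ebr(ebr: EBR, hsbs: list[HSB], orthologs: pd.DataFrame) -> EBR:
    """Tighten EBR bounds to the innermost flanking ortholog coordinates.

    Never widens; an EBR with a missing flank is returned unchanged with its
    ``flagged`` bit set.
    """
    by_id = {h.hsb_id: h for h in hsbs}
    left = by_id.get(ebr.flank_hsb_ids[0]) if ebr.flank_hsb_ids[0] else None
    right = by_id.get(ebr.flank_hsb_ids[1]) if ebr.flank_hsb_ids[1] else None
    if left is None or right is None:
        return replace(ebr, flagged=True)
    table = orthologs.set_index("gene_id")
    left_inner = int(table.loc[left.marker_ids, "ref_end"].max())
    right_inner = int(table.loc[right.marker_ids, "ref_start"].min())
    new_start = max(ebr.start, left_inner)
    new_end = min(ebr.end, right_inner)
    if new_end < new_start:   # flanks touch inside the EBR; degenerate, keep original
        return replace(ebr, flagged=True)
    return replace(ebr, start=new_start, end=new_end, detector="narrowed")


def run_direction(orthologs: pd.DataFrame,
                  assembly: GenomeAssembly | None = None,
                  min_markers: int = 2,
                  max_marker_gap_bp: int = MAX_EBR_BP,
                  max_ebr_bp: int = MAX_EBR_BP,
                  genome: str = "ref") -> tuple[list[HSB], list[EBR]]:
    """detect -> derive -> narrow with one genome as reference."""
    hsbs = detect_hsbs(orthologs, min_markers=min_markers,
                       max_marker_gap_bp=max_marker_gap_bp)
    ebrs = derive_ebrs(hsbs, assembly, max_ebr_bp=max_ebr_bp, genome=genome)
    table = validate_ortholog_table(orthologs)
    return hsbs, [narrow_ebr(e, hsbs, table) for e in ebrs]


def dual_reference_run(orthologs: pd.DataFrame,
                       ref_assembly: GenomeAssembly | None = None,
                       tgt_assembly: GenomeAssembly | None = None,
                       **params) -> dict:
    """Full pipeline run in both directions, as in human-macaque comparisons:
    once with each genome as the reference; coordinates are native to each.
    """
    ref_hsbs, ref_ebrs = run_direction(orthologs, ref_assembly, genome="ref", **params)
    swapped = swap_reference(orthologs)
    tgt_hsbs, tgt_ebrs = run_direction(swapped, tgt_assembly, genome="tgt", **params)
    return {"ref_hsbs": ref_hsbs, "ref_ebrs": ref_ebrs,
            "tgt_hsbs": tgt_hsbs, "tgt_ebrs": tgt_ebrs}
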