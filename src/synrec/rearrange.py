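"""Merging, masking/filtering and classification of evolutionary breakpoint
regions (EBRs).

Follows the conservative post-processing used in pairwise primate genome
comparisons: EBR sets from two detectors are reconciled (intersection of
overlapping calls), EBRs falling in the 2 Mbp telomeric ends or in the 2 Mbp
flanks of assembly N-runs (centromeres) are excluded, candidates larger than
4 Mbp are treated as gaps, and the retained EBRs are classified by
rearrangement type (inversion / fusion / fission / indel / translocation /
complex) and by size class: macro when the rearranged region exceeds 1.4 Mbp,
micro otherwise (the equality case is micro).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import GenomeAssembly, clipped_overlap, merge_intervals
from .synteny import EBR, HSB

TELOMERE_BP = 2_000_000
CENTROMERE_FLANK_BP = 2_000_000
MACRO_THRESHOLD_BP = 1_400_000


@dataclass
class RegionMask:
    chrom: str
    telomeric: list[tuple[int, int]]
    centromeric: list[tuple[int, int]]


@dataclass
class ClassifiedRearrangement:
    kind: str              # inversion | fusion | fission | indel | translocation | complex
    size_class: str        # macro | micro
    chrom: str
    region_start: int
    region_end: int
    member_ebrs: list[EBR]

    @property
    def region_span(self) -> int:
        return self.region_end - self.region_start


def merge_ebr_sets(set_a: list[EBR], set_b: list[EBR], rule: str = "intersection") -> list[EBR]:
    """Reconcile two EBR sets from different detectors on one genome.

    EBRs overlapping by >= 1 bp are merged into a single record labelled
    ``merged``; with the default ``intersection`` rule its bounds are the
    narrower consensus, with ``union`` the envelope.  Non-overlapping EBRs
    pass through with their provenance.
    """
    if rule not in ("intersection", "union"):
        raise ValueError(f"unknown merge rule {rule!r}")
    genomes = {e.genome for e in set_a + set_b}
    if len(genomes) > 1:
        raise ValueError(f"mixed-genome merge input: {sorted(genomes)}")
    out: list[EBR] = []
    used_b: set[int] = set()
    for ea in set_a:
        partners = [(j, eb) for j, eb in enumerate(set_b) if ea.overlaps(eb)]
        if not partners:
            out.append(ea)
            continue
        start, end = ea.start, ea.end
        for j, eb in partners:
            used_b.add(j)
            if rule == "intersection":
                start, end = max(start, eb.start), min(end, eb.end)
            else:
                start, end = min(start, eb.start), max(end, eb.end)
        out.append(replace(ea, start=start, end=end, detector="merged"))
    out.extend(eb for j, eb in enumerate(set_b) if j not in used_b)
    return sorted(out, key=lambda e: (e.chrom, e.start, e.end))


def build_region_masks(assembly: GenomeAssembly,
                       telomere_bp: int = TELOMERE_BP,
                       centromere_flank_bp: int = CENTROMERE_FLANK_BP) -> dict[str, RegionMask]:
    """Telomeric ends plus pericentromeric flanks around every N-run.

    The centromeric mask includes the N-run itself.  A chromosome shorter
    than twice ``telomere_bp`` is entirely telomeric.
    """
    masks: dict[str, RegionMask] = {}
    for chrom, length in assembly.lengths.items():
        if length <= 2 * telomere_bp:
            telo = [(0, length)]
        else:
            telo = [(0, telomere_bp), (length - telomere_bp, length)]
        centro = [(max(0, s - centromere_flank_bp), min(length, e + centromere_flank_bp))
                  for s, e in assembly.n_runs.get(chrom, [])]
        masks[chrom] = RegionMask(chrom=chrom,
                                  telomeric=merge_intervals(telo),
                                  centromeric=merge_intervals(centro))
    return masks


def _mask_hit(ebr: EBR, mask: RegionMask | None) -> str | None:
    if mask is None:
        return None
    for label, intervals in (("telomeric", mask.telomeric), ("centromeric", mask.centromeric)):
        for s, e in intervals:
            if clipped_overlap(ebr.start, ebr.end, s, e) > 0:
                return label
    return None


def filter_ebrs(ebrs: list[EBR], masks: dict[str, RegionMask]) -> list[EBR]:
    """Apply the conservative filters: any overlap with a telomeric or
    centromeric mask excludes an EBR (relabelled accordingly); gaps stay
    excluded; everything else is retained.  Idempotent.
    """
    out: list[EBR] = []
    for e in ebrs:
        if e.status == "gap":
            out.append(e)
            continue
        hit = _mask_hit(e, masks.get(e.chrom))
        out.append(replace(e, status=hit if hit else "retained"))
    return out


def retained(ebrs: list[EBR]) -> list[EBR]:
    return [e for e in ebrs if e.status == "retained"]


def _size_class(span_bp: int) -> str:
    return "macro" if span_bp > MACRO_THRESHOLD_BP else "micro"


def classify_rearrangements(hsbs: list[HSB], ebrs: list[EBR]) -> list[ClassifiedRearrangement]:
    """Type each retained EBR by the flanking-block geometry.

    inversion  - an inverted block bracketed by two same-chromosome EBRs
                 (rearranged region = the inverted block span, bounded by the
                 inner EBR edges);
    fission    - the two flanking blocks map to different target chromosomes
                 and the target has more chromosomes than the reference;
    fusion     - same, with fewer target chromosomes;
    translocation - chromosome-pair change with equal chromosome counts;
    indel      - flanks collinear (same pair, same orientation, continuing
                 order): the EBR spans sequence present on one genome only;
    complex    - anything else, including EBRs missing a flank.

    Fusion/fission/translocation size classes use the span of the distal
    (moved) block as the rearranged region.
    """
    by_id = {h.hsb_id: h for h in hsbs}
    n_ref = len({h.ref_chrom for h in hsbs})
    n_tgt = len({h.tgt_chrom for h in hsbs})
    use = [e for e in ebrs if e.status in ("retained", "candidate")]

    # group EBRs around inverted blocks: an inversion owns its two flanking EBRs
    out: list[ClassifiedRearrangement] = []
    claimed: set[int] = set()
    for h in hsbs:
        if h.orientation != "inverted":
            continue
        left = [i for i, e in enumerate(use)
                if e.flank_hsb_ids[1] == h.hsb_id and e.chrom == h.ref_chrom]
        right = [i for i, e in enumerate(use)
                 if e.flank_hsb_ids[0] == h.hsb_id and e.chrom == h.ref_chrom]
        members = [use[i] for i in left + right]
        if not members:
            continue
        claimed.update(left + right)
        inner_start = use[left[0]].end if left else h.ref_start
        inner_end = use[right[0]].start if right else h.ref_end
        out.append(ClassifiedRearrangement(
            kind="inversion", size_class=_size_class(inner_end - inner_start),
            chrom=h.ref_chrom, region_start=inner_start, region_end=inner_end,
            member_ebrs=members))

    for i, e in enumerate(use):
        if i in claimed:
            continue
        left = by_id.get(e.flank_hsb_ids[0]) if e.flank_hsb_ids[0] else None
        right = by_id.get(e.flank_hsb_ids[1]) if e.flank_hsb_ids[1] else None
        if left is None or right is None:
            out.append(ClassifiedRearrangement("complex", _size_class(e.span),
                                               e.chrom, e.start, e.end, [e]))
            continue
        if left.tgt_chrom != right.tgt_chrom:
            if n_tgt > n_ref:
                kind = "fission"
            elif n_tgt < n_ref:
                kind = "fusion"
            else:
                kind = "translocation"
            moved = right  # the distal block is the moved region
            out.append(ClassifiedRearrangement(
                kind, _size_class(moved.ref_span), e.chrom,
                moved.ref_start, moved.ref_end, [e]))
        elif left.orientation == right.orientation == "same":
            # collinear flanks: sequence present in one genome only
            out.append(ClassifiedRearrangement("indel", _size_class(e.span),
                                               e.chrom, e.start, e.end, [e]))
        else:
            out.append(ClassifiedRearrangement("complex", _size_class(e.span),
                                               e.chrom, e.start, e.end, [e]))
    return out


def rearrangement_span(breakpoint_1: tuple[float, float],
                       breakpoint_2: tuple[float, float]) -> float:
    """Inner-edge distance between two breakpoint intervals, in Mbp.

    The two EBR intervals (given in Mbp on one chromosome) must be disjoint;
    the span of the rearranged region is the distance between the end of the
    proximal one and the start of the distal one.
    """
    (a_start, a_end), (b_start, b_end) = sorted([breakpoint_1, breakpoint_2])
    if b_start < a_end:
        raise ValueError("breakpoint intervals overlap")
    return b_start - a_end


def summarize_ebrs(ebrs: list[EBR]) -> dict:
    """Count/min/max/median EBR length summary (the Table-1 style numbers)."""
    import numpy as np
    spans = [e.span for e in ebrs if e.status == "retained"]
    if not spans:
        return {"n": 0, "min_bp": None, "max_bp": None, "median_bp": None}
    return {"n": len(spans), "min_bp": int(min(spans)), "max_bp": int(max(spans)),
            "median_bp": float(np.median(spans))}
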