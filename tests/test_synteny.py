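"""Synteny-block chaining and EBR derivation against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import MARKER_LEN, collinear_markers, make_table
from synrec.genome import GenomeAssembly
from synrec.synteny import (EBR, derive_ebrs, detect_hsbs, dual_reference_run,
                            narrow_ebr, run_direction)


# ---------------------------------------------------------------------------
# independent oracle: maximal contiguous runs under the written chaining rules
# ---------------------------------------------------------------------------

def oracle_blocks(table: pd.DataFrame, min_markers: int, max_gap: int):
    """Enumerate maximal contiguous runs of ref-sorted markers such that every
    adjacent pair (a) shares the chromosome pair, (b) shares the strand
    relation of the run's first marker, (c) is ascending in target order when
    strands agree and descending when they are flipped, and (d) has inter-
    marker distance <= max_gap on both genomes.  Written from the rules, not
    from the implementation."""
    rows = table.sort_values(["ref_chrom", "ref_start"], kind="mergesort").to_dict("records")

    def rel(r):
        return r["ref_strand"] == r["tgt_strand"]

    def pair_ok(a, b, first):
        if b["ref_chrom"] != a["ref_chrom"] or b["tgt_chrom"] != a["tgt_chrom"]:
            return False
        if rel(b) != rel(first):
            return False
        if b["ref_start"] - a["ref_end"] > max_gap:
            return False
        return b["tgt_start"] > a["tgt_start"] if rel(first) \
            else b["tgt_start"] < a["tgt_start"]

    runs = []
    i = 0
    while i < len(rows):
        j = i
        while j + 1 < len(rows) and pair_ok(rows[j], rows[j + 1], rows[i]):
            j += 1
        runs.append(rows[i:j + 1])
        i = j + 1
    out = []
    for run in runs:
        if len(run) < min_markers:
            continue
        out.append((tuple(r["gene_id"] for r in run),
                    "same" if rel(run[0]) else "inverted"))
    return out


def as_oracle_form(hsbs):
    return [(tuple(h.marker_ids), h.orientation) for h in hsbs]


def random_table(rng, n, n_chroms=1, flip_prob=0.3, gap_bp=100_000):
    perm = rng.permutation(n)
    markers = []
    for i in range(n):
        rc = f"c{rng.integers(1, n_chroms + 1)}"
        tc = f"c{rng.integers(1, n_chroms + 1)}"
        rel = "-" if rng.random() < flip_prob else "+"
        markers.append((rc, int(i * gap_bp), tc, int(perm[i] * gap_bp), rel))
    return make_table(markers)


class TestDetectHsbs:
    def test_collinear_identity(self):
        hsbs = detect_hsbs(make_table(collinear_markers(10)))
        assert len(hsbs) == 1
        assert hsbs[0].orientation == "same"
        assert hsbs[0].marker_count == 10

    def test_inverted_tail_splits_into_two_blocks(self):
        # markers 0-4 collinear; 5-9 with reversed target order and flipped strands
        markers = [("c1", i * 100_000, "c1", i * 100_000, "+") for i in range(5)]
        markers += [("c1", (5 + i) * 100_000, "c1", (9 - i) * 100_000, "-")
                    for i in range(5)]
        hsbs = detect_hsbs(make_table(markers))
        assert [h.orientation for h in hsbs] == ["same", "inverted"]
        assert [h.marker_count for h in hsbs] == [5, 5]

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_oracle_on_random_permutations(self, rng, n):
        for _ in range(150):
            table = random_table(rng, n, n_chroms=2)
            got = detect_hsbs(table, min_markers=2, max_marker_gap_bp=10**9)
            want = oracle_blocks(table, 2, 10**9)
            assert as_oracle_form(got) == want

    def test_matches_oracle_with_finite_gap(self, rng):
        for _ in range(150):
            table = random_table(rng, 8, gap_bp=200_000)
            got = detect_hsbs(table, min_markers=2, max_marker_gap_bp=450_000)
            want = oracle_blocks(table, 2, 450_000)
            assert as_oracle_form(got) == want

    def test_duplicate_gene_id_rejected(self):
        table = make_table(collinear_markers(3))
        table.loc[2, "gene_id"] = table.loc[1, "gene_id"]
        with pytest.raises(ValueError, match="duplicated"):
            detect_hsbs(table)

    def test_empty_table(self):
        assert detect_hsbs(make_table([])) == []

    def test_blocks_do_not_overlap_on_reference(self, rng):
        table = random_table(rng, 10, n_chroms=2)
        hsbs = sorted(detect_hsbs(table), key=lambda h: (h.ref_chrom, h.ref_start))
        for a, b in zip(hsbs, hsbs[1:]):
            if a.ref_chrom == b.ref_chrom:
                assert a.ref_end <= b.ref_start

    def test_decreasing_gap_never_merges_blocks(self, rng):
        for _ in range(30):
            table = random_table(rng, 10, gap_bp=150_000)
            loose = detect_hsbs(table, min_markers=1, max_marker_gap_bp=600_000)
            tight = detect_hsbs(table, min_markers=1, max_marker_gap_bp=250_000)
            assert len(tight) >= len(loose)


class TestDeriveEbrs:
    def test_adjacent_blocks_yield_candidate(self):
        markers = collinear_markers(3) + [("c1", 400_000 + i * 100_000,
                                           "c2", i * 100_000, "+") for i in range(3)]
        hsbs = detect_hsbs(make_table(markers))
        ebrs = derive_ebrs(hsbs)
        assert len(ebrs) == 1
        e = ebrs[0]
        assert e.status == "candidate"
        assert (e.start, e.end) == (200_000 + MARKER_LEN, 400_000)

    def test_large_separation_is_gap(self):
        markers = collinear_markers(3) + [("c1", 6_000_000 + i * 100_000,
                                           "c2", i * 100_000, "+") for i in range(3)]
        ebrs = derive_ebrs(detect_hsbs(make_table(markers)))
        assert [e.status for e in ebrs] == ["gap"]

    def test_single_block_chromosome_has_no_ebrs(self):
        assert derive_ebrs(detect_hsbs(make_table(collinear_markers(5)))) == []

    def test_hsb_outside_assembly_rejected(self):
        hsbs = detect_hsbs(make_table(collinear_markers(5)))
        tiny = GenomeAssembly(lengths={"c1": 100_000})
        with pytest.raises(ValueError, match="outside chromosome"):
            derive_ebrs(hsbs, tiny)


class TestNarrowEbr:
    def _fixture(self, left_inner_offset=0, right_inner_offset=0):
        markers = [("c1", 0, "c1", 0, "+"),
                   ("c1", 100_000 - left_inner_offset - MARKER_LEN,
                    "c1", 100_000, "+"),
                   ("c1", 500_000 + right_inner_offset, "c2", 0, "+"),
                   ("c1", 700_000, "c2", 100_000, "+")]
        table = make_table(markers)
        hsbs = detect_hsbs(table)
        ebrs = derive_ebrs(hsbs)
        assert len(ebrs) == 1
        return table, hsbs, ebrs[0]

    def test_fixed_point_when_markers_abut_bounds(self):
        table, hsbs, ebr = self._fixture()
        narrowed = narrow_ebr(ebr, hsbs, table)
        assert (narrowed.start, narrowed.end) == (ebr.start, ebr.end)
        assert narrowed.detector == "narrowed"

    def test_never_widens(self, rng):
        table, hsbs, ebr = self._fixture()
        import dataclasses
        wide = dataclasses.replace(ebr, start=ebr.start - 30_000, end=ebr.end + 30_000)
        narrowed = narrow_ebr(wide, hsbs, table)
        assert narrowed.start >= wide.start and narrowed.end <= wide.end
        assert narrowed.span == ebr.span  # tightened back to the marker bounds

    def test_missing_flank_flagged_unchanged(self):
        table, hsbs, ebr = self._fixture()
        import dataclasses
        orphan = dataclasses.replace(ebr, flank_hsb_ids=(None, ebr.flank_hsb_ids[1]))
        result = narrow_ebr(orphan, hsbs, table)
        assert result.flagged
        assert (result.start, result.end) == (orphan.start, orphan.end)


class TestDualReference:
    def test_collinear_no_ebrs_either_direction(self):
        res = dual_reference_run(make_table(collinear_markers(10)))
        assert res["ref_ebrs"] == [] and res["tgt_ebrs"] == []

    def test_single_inversion_two_ebrs_each_direction(self):
        markers = [("c1", i * 100_000, "c1", i * 100_000, "+") for i in range(4)]
        markers += [("c1", (4 + i) * 100_000, "c1", (7 - i) * 100_000, "-")
                    for i in range(4)]
        markers += [("c1", (8 + i) * 100_000, "c1", (8 + i) * 100_000, "+")
                    for i in range(4)]
        res = dual_reference_run(make_table(markers))
        assert len(res["ref_ebrs"]) == 2 and len(res["tgt_ebrs"]) == 2
        assert all(e.status == "candidate" for e in res["ref_ebrs"] + res["tgt_ebrs"])

    def test_deletion_breaks_reference_direction_only(self):
        # a 1 Mbp stretch present only on the reference genome
        markers = [("c1", i * 100_000, "c1", i * 100_000, "+") for i in range(5)]
        markers += [("c1", 1_400_000 + i * 100_000, "c1", 400_000 + (i + 1) * 100_000, "+")
                    for i in range(5)]
        res = dual_reference_run(make_table(markers), max_marker_gap_bp=500_000)
        assert len(res["ref_ebrs"]) == 1
        assert res["tgt_ebrs"] == []


def test_partition_invariant(rng):
    """Retained HSBs, EBR candidates and gaps tile the marker-covered span."""
    for _ in range(20):
        table = random_table(rng, 10, gap_bp=300_000)
        hsbs, ebrs = run_direction(table, min_markers=1, max_marker_gap_bp=10**9)
        by_chrom = {}
        for h in hsbs:
            by_chrom.setdefault(h.ref_chrom, []).append(("hsb", h.ref_start, h.ref_end))
        for e in ebrs:
            by_chrom.setdefault(e.chrom, []).append(("ebr", e.start, e.end))
        for chrom, pieces in by_chrom.items():
            pieces.sort(key=lambda t: (t[1], t[2]))
            for (k1, s1, e1), (k2, s2, e2) in zip(pieces, pieces[1:]):
                assert e1 <= s2 or (e1 == e2 and s1 == s2), "overlap in partition"
            hsb_pieces = [p for p in pieces if p[0] == "hsb"]
            covered = sum(e - s for _, s, e in pieces)
            span = max(e for _, s, e in hsb_pieces) - min(s for _, s, e in hsb_pieces)
            assert covered == span
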