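"""Tandem-repeat scan vs a brute-force oracle; window statistics and the
nonparametric region comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from synrec.genome import GenomeAssembly, clipped_overlap
from synrec.landscape import (compare_window_groups, find_tandem_repeats,
                              label_windows, mean_gene_density, window_scan)
from synrec.rearrange import RegionMask
from synrec.simulate import simulate_window_landscape
from synrec.synteny import EBR, HSB


# ---------------------------------------------------------------------------
# oracle: O(n^3) scan of every (start, period) pair with substring equality
# ---------------------------------------------------------------------------

def oracle_tandem_repeats(seq, min_period=2, max_period=100, min_copies=2):
    n = len(seq)
    candidates = []
    for period in range(min_period, min(max_period, n) + 1):
        for start in range(0, n - 2 * period + 1):
            unit = seq[start:start + period]
            if "N" in unit:
                continue
            # maximality to the left: same unit must not extend backwards
            if start >= 1 and seq[start - 1] == seq[start - 1 + period] and "N" not in seq[start - 1]:
                continue
            copies = 1
            while True:
                nxt = seq[start + copies * period: start + (copies + 1) * period]
                if nxt == unit and "N" not in nxt:
                    copies += 1
                else:
                    break
            # extend by trailing partial matches to mirror run maximality,
            # but report whole copies only
            if copies >= min_copies:
                candidates.append((start, start + copies * period, period, copies, unit))
    # dedupe (same region found at shifted starts is excluded by maximality)
    # selection: longest span, then smallest period, then leftmost
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[2], t[0]))
    accepted = []
    for cand in candidates:
        if any(cand[0] < e and s < cand[1] for s, e, *_ in accepted):
            continue
        accepted.append(cand)
    out = []
    for s, e, period, copies, unit in sorted(accepted):
        motif = min(unit[i:] + unit[:i] for i in range(period))
        out.append((s, e, period, copies, motif))
    return out


def as_tuples(trs):
    return [(t.start, t.end, t.period, t.copy_number, t.motif) for t in trs]


class TestFindTandemRepeats:
    def test_simple_dinucleotide(self):
        trs = find_tandem_repeats("ACACACAC")
        assert as_tuples(trs) == [(0, 8, 2, 4, "AC")]

    def test_embedded_tetramer(self, rng):
        flank1 = "GTTCGA"
        flank2 = "TTGAC"
        seq = flank1 + "ACGT" * 3 + flank2
        trs = find_tandem_repeats(seq)
        hits = [t for t in trs if t.period == 4]
        assert len(hits) == 1
        assert hits[0].copy_number == 3
        assert hits[0].motif == "ACGT"

    def test_homopolymer_reported_at_smallest_period(self):
        trs = find_tandem_repeats("AAAAAA")
        assert len(trs) == 1
        assert (trs[0].period, trs[0].motif) == (2, "AA")

    def test_n_breaks_runs(self):
        trs = find_tandem_repeats("ACACNACAC")
        assert all(t.end <= 4 or t.start >= 5 for t in trs)

    def test_empty_sequence(self):
        assert find_tandem_repeats("") == []

    def test_matches_oracle_exhaustively_two_letter(self):
        for length in range(4, 13):
            for bits in itertools.product("AC", repeat=length):
                seq = "".join(bits)
                got = as_tuples(find_tandem_repeats(seq))
                want = oracle_tandem_repeats(seq)
                assert got == want, seq

    def test_matches_oracle_on_random_strings(self, rng):
        for _ in range(400):
            length = int(rng.integers(5, 31))
            seq = "".join(rng.choice(list("ACGTN"), size=length,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            assert as_tuples(find_tandem_repeats(seq)) == oracle_tandem_repeats(seq), seq


class TestWindowScan:
    def test_tr_split_across_boundary_conserves_bp(self):
        asm = GenomeAssembly(lengths={"c1": 300_000})
        trs = {"c1": [(90_000, 110_000)]}
        win = window_scan(asm, trs)
        assert win["tr_bp"].tolist() == [10_000, 10_000, 0]
        assert win["tr_bp"].sum() == 20_000

    def test_gene_spanning_boundary_counted_twice(self):
        asm = GenomeAssembly(lengths={"c1": 300_000})
        genes = pd.DataFrame([("g1", "c1", 95_000, 105_000, "+")],
                             columns=["gene_id", "chrom", "start", "end", "strand"])
        win = window_scan(asm, genes=genes)
        assert win["gene_count"].tolist() == [1, 1, 0]

    def test_empty_chromosome_all_zero(self):
        win = window_scan(GenomeAssembly(lengths={"c1": 250_000}))
        assert (win["tr_bp"] == 0).all() and (win["gene_count"] == 0).all()
        # windows tile the chromosome exactly, last one short
        assert win["end"].iloc[-1] == 250_000
        assert (win["end"] - win["start"]).sum() == 250_000

    def test_window_tr_sum_equals_clipped_tr_lengths(self, rng):
        asm = GenomeAssembly(lengths={"c1": 1_000_000})
        starts = np.sort(rng.integers(0, 990_000, size=20))
        trs = {"c1": [(int(s), int(s + rng.integers(100, 9_000))) for s in starts]}
        win = window_scan(asm, trs)
        clipped = sum(clipped_overlap(s, e, 0, 1_000_000) for s, e in trs["c1"])
        overlap_free = []
        # windows double-count overlapping TR records; oracle must sum the same way
        assert win["tr_bp"].sum() == clipped
        del overlap_free


class TestLabelWindows:
    def _setup(self):
        asm = GenomeAssembly(lengths={"c1": 1_000_000})
        masks = {"c1": RegionMask("c1", telomeric=[(0, 150_000)],
                                  centromeric=[(400_000, 500_000)])}
        hsbs = [HSB("h0", "c1", 100_000, 900_000, "c1", 0, 800_000, "same", 10)]
        ebrs = [EBR(genome="ref", chrom="c1", start=100_000, end=160_000,
                    status="retained"),
                EBR(genome="ref", chrom="c1", start=699_999, end=720_000,
                    status="retained")]
        return asm, masks, hsbs, ebrs

    def test_precedence_and_boundaries(self):
        asm, masks, hsbs, ebrs = self._setup()
        win = label_windows(window_scan(asm), masks, hsbs, ebrs)
        labels = win.set_index("start")["label"]
        assert labels[100_000] == "telomere"      # overlaps telomere AND EBR
        assert labels[400_000] == "centromere"
        assert labels[600_000] == "EBR"           # 1 bp overlap at 699,999
        assert labels[200_000] == "HSB"
        assert labels[900_000] is None            # outside every feature


class TestGroupComparisons:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.poisson(5.0, size=200)
        win = pd.DataFrame({"tr_bp": np.concatenate([vals, vals]),
                            "gene_count": 0,
                            "label": ["A"] * 200 + ["B"] * 200})
        rep = compare_window_groups(win, "tr_bp", ["A", "B"])
        assert rep["test"] == "mannwhitneyu"
        assert rep["p_value"] > 0.9

    def test_planted_tr_excess_detected(self, rng):
        win = pd.DataFrame({
            "tr_bp": np.concatenate([rng.poisson(8000, 1000), rng.poisson(1500, 1000),
                                     rng.poisson(1500, 1000)]),
            "gene_count": 0,
            "label": ["telomere"] * 1000 + ["HSB"] * 1000 + ["EBR"] * 1000})
        rep = compare_window_groups(win, "tr_bp", ["telomere", "HSB", "EBR"])
        assert rep["test"] == "kruskal"
        assert rep["p_value"] < 1e-4

    def test_empty_group_named_in_error(self):
        win = pd.DataFrame({"tr_bp": [1.0], "gene_count": [0], "label": ["A"]})
        with pytest.raises(ValueError, match="'B'"):
            compare_window_groups(win, "tr_bp", ["A", "B"])

    def test_type_one_error_calibrated_under_null(self):
        """EBR and HSB windows drawn from one distribution: rejection at
        alpha = 0.05 stays near (never above ~2x) the nominal level."""
        rejections = 0
        n_seeds = 300
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            win = pd.DataFrame({
                "tr_bp": np.concatenate([r.poisson(1500, 60), r.poisson(1500, 60)]),
                "gene_count": 0,
                "label": ["EBR"] * 60 + ["HSB"] * 60})
            p = compare_window_groups(win, "tr_bp", ["EBR", "HSB"])["p_value"]
            rejections += p < 0.05
        assert rejections / n_seeds <= 0.09


class TestGeneDensity:
    def test_all_zero(self):
        win = pd.DataFrame({"gene_count": [0, 0], "label": ["EBR", "EBR"]})
        assert mean_gene_density(win, "EBR") == 0.0

    def test_arithmetic(self):
        win = pd.DataFrame({"gene_count": list(range(1, 11)), "label": ["HSB"] * 10})
        assert mean_gene_density(win, "HSB") == 5.5

    def test_missing_label_errors(self):
        win = pd.DataFrame({"gene_count": [1], "label": ["HSB"]})
        with pytest.raises(ValueError, match="EBR"):
            mean_gene_density(win, "EBR")

    def test_planted_double_rate_recovered(self, rng):
        asm = GenomeAssembly(lengths={"c1": 100_000_000})
        win = window_scan(asm)
        win["label"] = ["EBR" if i % 2 else "HSB" for i in range(len(win))]
        trs, genes = simulate_window_landscape(
            win, {"EBR": 0.0, "HSB": 0.0}, {"EBR": 2.0, "HSB": 1.0}, seed=4)
        scanned = window_scan(asm, trs, genes)
        scanned["label"] = win["label"]
        ebr_mean = mean_gene_density(scanned, "EBR")
        hsb_mean = mean_gene_density(scanned, "HSB")
        assert ebr_mean / hsb_mean == pytest.approx(2.0, rel=0.25)
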