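"""Tandem-repeat detection and 100-Kbp window landscapes.

Exact-match tandem repeats with unit size 2-100 bp are scanned directly from
sequence (the eTandem parameter regime); repeat base pairs and gene counts
are then accumulated in non-overlapping 100-Kbp windows, each window labelled
by its genomic context (telomere > centromere > EBR > HSB precedence), and
groups of windows are compared with the usual nonparametric tests
(Kruskal-Wallis for more than two groups, Mann-Whitney U for two).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAssembly, clipped_overlap
from .rearrange import RegionMask
from .synteny import EBR, HSB

WINDOW_BP = 100_000


@dataclass(frozen=True)
class TandemRepeat:
    chrom: str
    start: int
    end: int
    period: int
    copy_number: int
    motif: str


def _canonical_motif(unit: str) -> str:
    """Lexicographically least rotation of the repeat unit."""
    doubled = unit + unit
    return min(doubled[i:i + len(unit)] for i in range(len(unit)))


def find_tandem_repeats(sequence: str,
                        min_period: int = 2,
                        max_period: int = 100,
                        min_copies: int = 2,
                        chrom: str = "chr") -> list[TandemRepeat]:
    """Exact tandem repeats over {A,C,G,T}; N never matches and breaks runs.

    For each period k, maximal runs where s[i] == s[i-k] yield candidate
    repeats trimmed to whole copies.  Overlapping candidates across periods
    are reduced deterministically: longest span wins, ties to the smallest
    period, then leftmost start.  Homopolymers therefore surface at the
    smallest admissible period (motif "AA" under the default minimum of 2).
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[TandemRepeat] = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    for k in range(min_period, min(max_period, n - 1) + 1):
        match = (arr[k:] == arr[:-k]) & ~is_n[k:] & ~is_n[:-k]
        # maximal runs of True in `match`: a run [i0, i1) means seq[i0-k : i1+?]
        if not match.any():
            continue
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            region_start = int(run_start)          # first matched pos is run_start + k
            region_len = int(run_end - run_start) + k
            copies = region_len // k
            if copies < min_copies:
                continue
            end = region_start + copies * k
            unit = seq[region_start:region_start + k]
            candidates.append(TandemRepeat(chrom, region_start, end, k, copies,
                                           _canonical_motif(unit)))
    # overlap resolution: longest, then smallest period, then leftmost
    candidates.sort(key=lambda t: (-(t.end - t.start), t.period, t.start))
    accepted: list[TandemRepeat] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        if any(clipped_overlap(cand.start, cand.end, s, e) for s, e in occupied):
            continue
        accepted.append(cand)
        occupied.append((cand.start, cand.end))
    return sorted(accepted, key=lambda t: (t.start, t.period))


def window_scan(assembly: GenomeAssembly,
                tr_intervals: dict[str, list[tuple[int, int]]] | None = None,
                genes: pd.DataFrame | None = None,
                window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows (last may be short)
    and accumulate TR base pairs (clipped to the window) and the number of
    genes intersecting the window (presence/absence, so a boundary-spanning
    gene counts in every window it touches).
    """
    rows = []
    tr_intervals = tr_intervals or {}
    for chrom, length in assembly.lengths.items():
        starts = np.arange(0, length, window_bp)
        ends = np.minimum(starts + window_bp, length)
        trs = sorted(tr_intervals.get(chrom, []))
        gsub = genes[genes["chrom"] == chrom] if genes is not None else None
        for ws, we in zip(starts, ends):
            tr_bp = sum(clipped_overlap(int(ws), int(we), s, e) for s, e in trs)
            if gsub is None:
                gcount = 0
            else:
                gcount = int(((gsub["start"] < we) & (gsub["end"] > ws)).sum())
            rows.append((chrom, int(ws), int(we), tr_bp, gcount))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tr_bp", "gene_count"])


def label_windows(windows: pd.DataFrame,
                  masks: dict[str, RegionMask],
                  hsbs: list[HSB],
                  ebrs: list[EBR]) -> pd.DataFrame:
    """Assign each window its region label by any-overlap with precedence
    telomere > centromere > EBR > HSB; windows touching none are left
    unlabelled (NaN) and drop out of the group comparisons.
    """
    feature_sets: dict[str, dict[str, list[tuple[int, int]]]] = {
        "telomere": {}, "centromere": {}, "EBR": {}, "HSB": {}}
    for chrom, m in masks.items():
        feature_sets["telomere"][chrom] = list(m.telomeric)
        feature_sets["centromere"][chrom] = list(m.centromeric)
    for e in ebrs:
        if e.status in ("retained", "candidate"):
            feature_sets["EBR"].setdefault(e.chrom, []).append((e.start, e.end))
    for h in hsbs:
        feature_sets["HSB"].setdefault(h.ref_chrom, []).append((h.ref_start, h.ref_end))

    labels = []
    for row in windows.itertuples(index=False):
        label = None
        for name in ("telomere", "centromere", "EBR", "HSB"):
            ivs = feature_sets[name].get(row.chrom, [])
            if any(clipped_overlap(row.start, row.end, s, e) for s, e in ivs):
                label = name
                break
        labels.append(label)
    out = windows.copy()
    out["label"] = labels
    return out


def compare_window_groups(windows: pd.DataFrame,
                          value: str,
                          groups: list[str],
                          label_col: str = "label") -> dict:
    """Kruskal-Wallis (> 2 groups) or Mann-Whitney U (2 groups) on a window
    statistic across region labels.  Reports per-group n, the statistic and p.
    """
    if value not in ("tr_bp", "gene_count"):
        raise ValueError(f"unknown window value {value!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = []
    ns = {}
    for g in groups:
        vals = windows.loc[windows[label_col] == g, value].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {g!r} has zero windows")
        samples.append(vals)
        ns[g] = int(vals.size)
    if len(samples) == 2:
        test = "mannwhitneyu"
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    else:
        test = "kruskal"
        res = stats.kruskal(*samples)
    return {"test": test, "n": ns, "statistic": float(res.statistic),
            "p_value": float(res.pvalue)}


def mean_gene_density(windows: pd.DataFrame, label: str,
                      label_col: str = "label") -> float:
    """Mean gene count per 100-Kbp window among windows with ``label``."""
    sub = windows[windows[label_col] == label]
    if sub.empty:
        raise ValueError(f"no windows labelled {label!r}")
    return float(sub["gene_count"].mean())
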