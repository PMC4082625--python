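"""Chromosome-specific recombination analysis from synaptonemal-complex (SC)
measurements.

Each observation is one SC in one pachytene cell: its length in micrometres,
the centromere position, the MLH1 focus positions (one focus = one crossover,
and 1 CO = 50 cM) and any BAC marker signals used to anchor inversion
breakpoints on the axis.  The module computes signed relative focus positions
(p-arm negative, q-arm positive, as a percentage of total SC length from the
centromere), crossover densities per micrometre inside/outside marker-bounded
intervals, pericentromeric densities, a simulated-inversion control on a
collinear chromosome, cumulative recombination maps in 10% bins, and the
nonparametric inside-vs-outside comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CM_PER_CO = 50.0


@dataclass
class SCObservation:
    cell_id: str
    sc_id: str
    length_um: float
    centromere_um: float
    foci_um: list[float] = field(default_factory=list)
    bac_markers: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.centromere_um < self.length_um):
            raise ValueError(f"{self.cell_id}/{self.sc_id}: centromere must be interior")
        foci = sorted(self.foci_um)
        if foci != list(self.foci_um):
            self.foci_um = foci
        for x in self.foci_um:
            if not (0 <= x <= self.length_um):
                raise ValueError(f"{self.cell_id}/{self.sc_id}: focus {x} outside SC")

    def marker_position(self, marker_id: str) -> float | None:
        for mid, pos in self.bac_markers:
            if mid == marker_id:
                return pos
        return None


@dataclass
class DensityEstimate:
    region: str
    foci_per_um: float
    n_cells: int
    total_foci: int = 0
    total_um: float = 0.0


@dataclass
class RecombinationMap:
    chrom_id: str
    co_class: str
    bin_edges: np.ndarray        # signed % of SC from centromere
    frequency: np.ndarray
    cumulative: np.ndarray
    n_cells: int


def relative_positions(sc: SCObservation) -> list[float]:
    """Signed focus positions as % of total SC length from the centromere.

    p-arm (before the centromere) negative, q-arm positive; a focus exactly
    at the centromere is 0 and belongs to the q-arm by convention.
    """
    return [100.0 * (x - sc.centromere_um) / sc.length_um for x in sc.foci_um]


def genetic_length(cells: list[list[SCObservation]]) -> float:
    """Genetic map length in cM: mean total foci per cell x 50 (1 CO = 50 cM)."""
    if not cells:
        raise ValueError("no cells")
    totals = [sum(len(sc.foci_um) for sc in cell) for cell in cells]
    return float(np.mean(totals) * CM_PER_CO)


def _foci_in(sc: SCObservation, lo: float, hi: float) -> int:
    # closed-left convention: a focus exactly on a boundary counts inside
    return sum(1 for x in sc.foci_um if lo <= x < hi) + \
        sum(1 for x in sc.foci_um if x == hi == sc.length_um)


def co_density(scs: list[SCObservation],
               interval_of, region: str = "whole") -> DensityEstimate:
    """Pooled crossover density over an SC-resolvable interval.

    ``interval_of(sc)`` returns the (lo, hi) micrometre interval on that SC,
    or None to exclude the cell (e.g. missing BAC signal).  Density is
    pooled: total foci in the interval over total interval length.
    """
    total_foci = 0
    total_um = 0.0
    n = 0
    for sc in scs:
        iv = interval_of(sc)
        if iv is None:
            continue
        lo, hi = iv
        if hi < lo:
            raise ValueError("empty interval")
        total_foci += _foci_in(sc, lo, hi)
        total_um += hi - lo
        n += 1
    if total_um <= 0:
        raise ValueError(f"zero total interval length for region {region!r}")
    return DensityEstimate(region=region, foci_per_um=total_foci / total_um,
                           n_cells=n, total_foci=total_foci, total_um=total_um)


def per_cell_densities(scs: list[SCObservation], interval_of) -> list[float]:
    """Per-SC focus densities over an interval (for the rank tests)."""
    out = []
    for sc in scs:
        iv = interval_of(sc)
        if iv is None:
            continue
        lo, hi = iv
        if hi > lo:
            out.append(_foci_in(sc, lo, hi) / (hi - lo))
    return out


def whole_sc(sc: SCObservation) -> tuple[float, float]:
    return (0.0, sc.length_um)


def delimit_inversion(sc: SCObservation,
                      proximal_marker: str,
                      distal_marker: str) -> tuple[float, float] | None:
    """Micrometre interval between two axis markers bounding an inversion.

    ``"centromere"`` names the centromere signal; for a pericentric inversion
    both markers are BACs and the interval spans the centromere.  Returns
    None when a named BAC signal is missing on this SC (the cell is then
    excluded listwise from inversion estimates).
    """
    def pos(name: str) -> float | None:
        if name == "centromere":
            return sc.centromere_um
        return sc.marker_position(name)

    p, d = pos(proximal_marker), pos(distal_marker)
    if p is None or d is None:
        return None
    return (min(p, d), max(p, d))


def outside_interval_density(scs: list[SCObservation], interval_of,
                             region: str = "outside_inv") -> DensityEstimate:
    """Pooled density over the SC complement of an interval."""
    total_foci = 0
    total_um = 0.0
    n = 0
    for sc in scs:
        iv = interval_of(sc)
        if iv is None:
            continue
        lo, hi = iv
        inside = _foci_in(sc, lo, hi)
        total_foci += len(sc.foci_um) - inside
        total_um += sc.length_um - (hi - lo)
        n += 1
    if total_um <= 0:
        raise ValueError("zero outside length")
    return DensityEstimate(region=region, foci_per_um=total_foci / total_um,
                           n_cells=n, total_foci=total_foci, total_um=total_um)


def proportional_interval(rel_lo: float, rel_hi: float):
    """Interval spec anchored at the same relative SC position on every cell."""
    if not (0 <= rel_lo <= rel_hi <= 1):
        raise ValueError(f"proportional span [{rel_lo}, {rel_hi}] outside [0, 1]")

    def interval_of(sc: SCObservation) -> tuple[float, float]:
        return (rel_lo * sc.length_um, rel_hi * sc.length_um)

    return interval_of


def simulated_inversion_control(collinear_scs: list[SCObservation],
                                proportional_span: tuple[float, float]) -> DensityEstimate:
    """Density in a pseudo-inversion mapped onto a collinear chromosome.

    The span is the inverted region of a rearranged chromosome expressed as a
    fraction of SC length, anchored at the same relative position, so the
    collinear chromosome serves as a no-rearrangement control.
    """
    return co_density(collinear_scs, proportional_interval(*proportional_span),
                      region="simulated_inv")


def pericentromeric_density(scs: list[SCObservation],
                            fraction: float = 0.30) -> dict[str, DensityEstimate]:
    """Per-arm density within ``fraction`` of the arm length from the
    centromere towards the telomere (default 30%)."""
    def p_arm(sc: SCObservation) -> tuple[float, float]:
        return (sc.centromere_um * (1 - fraction), sc.centromere_um)

    def q_arm(sc: SCObservation) -> tuple[float, float]:
        return (sc.centromere_um, sc.centromere_um + fraction * (sc.length_um - sc.centromere_um))

    return {"p": co_density(scs, p_arm, region="pericentromeric_p"),
            "q": co_density(scs, q_arm, region="pericentromeric_q")}


def compare_densities(*groups: list[float]) -> dict:
    """Mann-Whitney U (two groups) or Kruskal-Wallis (more) on per-cell
    density lists; reports n per group, the statistic and p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) == 2:
        if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
            # identical constant samples: no evidence of difference
            return {"test": "mannwhitneyu", "n": [len(a) for a in arrays],
                    "statistic": float("nan"), "p_value": 1.0}
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        test = "mannwhitneyu"
    else:
        res = stats.kruskal(*arrays)
        test = "kruskal"
    return {"test": test, "n": [len(a) for a in arrays],
            "statistic": float(res.statistic), "p_value": float(res.pvalue)}


def cumulative_distribution(scs: list[SCObservation],
                            chrom_id: str,
                            co_class: str = "all") -> RecombinationMap:
    """Cumulative focus-position distribution in 10% bins from the centromere.

    ``co_class`` restricts to SCs carrying exactly 2 or 3 foci ("2", "3") or
    uses every SC ("all").  Positions are signed percentages of SC length
    (0 = centromere); bins span -100% to +100% in steps of 10.
    """
    if co_class not in ("2", "3", "all"):
        raise ValueError(f"co_class must be '2', '3' or 'all', got {co_class!r}")
    edges = np.arange(-100.0, 100.0 + 1e-9, 10.0)
    use = [sc for sc in scs
           if co_class == "all" or len(sc.foci_um) == int(co_class)]
    positions = [p for sc in use for p in relative_positions(sc)]
    freq, _ = np.histogram(positions, bins=edges)
    freq = freq.astype(float)
    cum = np.cumsum(freq)
    if cum[-1] > 0:
        cum = cum / cum[-1]
    return RecombinationMap(chrom_id=chrom_id, co_class=co_class,
                            bin_edges=edges, frequency=freq,
                            cumulative=cum, n_cells=len(use))
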