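"""Synthetic-data generators for every pipeline input, with known ground truth.

The full-scale inputs this package analyzes (ortholog tables from genome
annotation, window landscapes, functional annotations, spermatocyte MLH1
measurements) are emulated here so that every downstream operation can be
tested against planted truth:

* a rearranged genome pair: an ancestral genome A, a derived genome B obtained
  by applying a script of inversions / deletions / fissions / fusions /
  translocations, the resulting ortholog table, and the true breakpoint
  regions (marker-bounded) in both genomes' coordinates;
* window-level tandem-repeat and gene landscapes with configurable expected
  rates per region class;
* term annotations with planted enrichment at a configurable fold inside
  chosen neighborhoods;
* meiotic cells: synaptonemal complexes with crossover foci drawn from a
  thinned point process with hard-core interference, an obligate-crossover
  guarantee, and optional crossover suppression inside designated (inversion)
  intervals.

Coordinates are 0-based half-open.  All randomness flows from one seed;
subsystem generators use fixed offsets from it so partial reruns reproduce.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import GenomeAssembly, validate_ortholog_table
from .recombination import SCObservation

_SEED_GENOME = 0
_SEED_MEIOSIS = 1
_SEED_ANNOT = 2
_SEED_LANDSCAPE = 3
_SEED_SEQ = 4

DEFAULT_CENTROMERE_N_BP = 500_000


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementEvent:
    """One structural event, with intervals in ancestral (genome A) coordinates."""

    kind: str                       # inversion | indel | fission | fusion | translocation
    chrom: str
    start: int = 0
    end: int = 0
    chrom2: str | None = None       # fusion / translocation partner
    pos2: int = 0                   # translocation breakpoint on chrom2

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "indel", "fission", "fusion", "translocation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("inversion", "indel") and self.end <= self.start:
            raise ValueError(f"{self.kind} interval must be non-empty")

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class GeneratorConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 20_000_000
    n_genes: int = 400
    gene_spacing_model: str = "uniform"     # uniform | clustered
    rearrangement_script: list[RearrangementEvent] = field(default_factory=list)
    tr_rate_by_region: dict[str, float] = field(default_factory=lambda: {
        "telomere": 8000.0, "centromere": 8000.0, "HSB": 1500.0, "EBR": 1500.0})
    gene_rate_by_region: dict[str, float] = field(default_factory=lambda: {
        "telomere": 1.0, "centromere": 1.0, "HSB": 0.73, "EBR": 1.48})
    gene_length_bp: int = 5_000
    centromere_n_run_bp: int = DEFAULT_CENTROMERE_N_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0 or self.n_genes <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.gene_spacing_model not in ("uniform", "clustered"):
            raise ValueError(f"unknown gene_spacing_model {self.gene_spacing_model!r}")


@dataclass
class SimulatedComparison:
    assembly_a: GenomeAssembly
    assembly_b: GenomeAssembly
    orthologs: pd.DataFrame
    truth_ebrs_a: list[tuple[str, int, int]]
    truth_ebrs_b: list[tuple[str, int, int]]
    truth_events: list[RearrangementEvent]
    genes_a: pd.DataFrame           # all ancestral genes (incl. deleted in B)


def _place_genes(length: int, n: int, gene_len: int, forbidden: list[tuple[int, int]],
                 model: str, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping gene intervals avoiding forbidden regions (N-runs)."""
    allowed: list[tuple[int, int]] = []
    cursor = 0
    for fs, fe in sorted(forbidden) + [(length, length)]:
        if fs > cursor:
            allowed.append((cursor, fs))
        cursor = max(cursor, fe)
    total = sum(e - s for s, e in allowed)
    free = total - n * gene_len
    if free <= 0:
        raise ValueError("chromosome too short for requested gene count")
    if model == "uniform":
        cuts = np.sort(rng.uniform(0, free, size=n))
    else:  # clustered: beta(0.3, 0.3) piles genes near region ends
        cuts = np.sort(rng.beta(0.3, 0.3, size=n) * free)
    offsets = cuts + np.arange(n) * gene_len
    genes = []
    for off in offsets:
        pos = float(off)
        for s, e in allowed:
            span = e - s
            if pos < span:
                genes.append((int(s + pos), int(s + pos) + gene_len))
                break
            pos -= span
    return genes


def _validate_script(cfg: GeneratorConfig, assembly: GenomeAssembly,
                     genes_by_chrom: dict[str, list]) -> None:
    intervals: dict[str, list[tuple[int, int]]] = {}
    structural_chroms: set[str] = set()

    def add(chrom: str, s: int, e: int) -> None:
        if chrom not in assembly.lengths:
            raise ValueError(f"event references unknown chromosome {chrom!r}")
        if not (0 <= s <= e <= assembly.lengths[chrom]):
            raise ValueError(f"event interval [{s}, {e}) outside chromosome {chrom}")
        for (os_, oe) in intervals.get(chrom, []):
            if s < oe and os_ < e:
                raise ValueError(f"overlapping events on {chrom}: "
                                 f"[{s}, {e}) vs [{os_}, {oe})")
        intervals.setdefault(chrom, []).append((s, e))

    for ev in cfg.rearrangement_script:
        if ev.kind in ("inversion", "indel"):
            add(ev.chrom, ev.start, ev.end)
        elif ev.kind == "fission":
            add(ev.chrom, ev.start, ev.start)
            structural_chroms.add(ev.chrom)
        elif ev.kind == "fusion":
            for c in (ev.chrom, ev.chrom2):
                if c in structural_chroms:
                    raise ValueError(f"multiple structural events on {c}")
                structural_chroms.add(c)
            if ev.chrom2 not in assembly.lengths:
                raise ValueError(f"fusion partner {ev.chrom2!r} unknown")
        elif ev.kind == "translocation":
            add(ev.chrom, ev.start, ev.start)
            add(ev.chrom2, ev.pos2, ev.pos2)
            for c in (ev.chrom, ev.chrom2):
                if c in structural_chroms:
                    raise ValueError(f"multiple structural events on {c}")
                structural_chroms.add(c)


def simulate_genome_pair(cfg: GeneratorConfig) -> SimulatedComparison:
    """Build genome A, apply the rearrangement script to produce genome B,
    and return the ortholog table plus marker-bounded truth breakpoints.

    Event intervals are ancestral coordinates; intra-chromosomal events may
    not overlap and at most one inter-chromosomal event may touch a given
    chromosome.  A gene cut by an event boundary is treated as disrupted and
    dropped from the ortholog set.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_GENOME)
    chroms = [f"chrA{i + 1}" for i in range(cfg.n_chromosomes)]
    lengths = {c: cfg.chrom_length_bp for c in chroms}
    n_runs: dict[str, list[tuple[int, int]]] = {}
    for c in chroms:
        mid = cfg.chrom_length_bp // 2
        half = cfg.centromere_n_run_bp // 2
        n_runs[c] = [(mid - half, mid + half)]
    assembly_a = GenomeAssembly(lengths=dict(lengths), n_runs=copy.deepcopy(n_runs))

    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[0] += cfg.n_genes - sum(per_chrom)
    genes_a: dict[str, list[list]] = {}
    gid = 0
    for c, n in zip(chroms, per_chrom):
        placed = _place_genes(cfg.chrom_length_bp, n, cfg.gene_length_bp,
                              n_runs[c], cfg.gene_spacing_model, rng)
        genes_a[c] = [[f"g{gid + i:05d}", s, e, "+" if rng.random() < 0.5 else "-"]
                      for i, (s, e) in enumerate(placed)]
        gid += n

    _validate_script(cfg, assembly_a, genes_a)

    # genome B state: per chromosome -> dict(length, n_runs, genes)
    b: dict[str, dict] = {
        c: {"length": lengths[c], "n_runs": list(n_runs[c]),
            "genes": copy.deepcopy(genes_a[c])}
        for c in chroms}
    deleted: set[str] = set()
    bp_a: list[tuple[str, int]] = []            # ancestral breakpoints
    bp_b: list[list] = []                       # [chrom, pos], mutated in place

    def reflect(iv: tuple[int, int], s: int, e: int) -> tuple[int, int]:
        return (s + e - iv[1], s + e - iv[0])

    def drop_straddlers(st: dict, positions: list[int]) -> None:
        # a gene cut by a breakpoint is disrupted: absent from the ortholog set
        keep = []
        for g in st["genes"]:
            if any(g[1] < p < g[2] for p in positions):
                deleted.add(g[0])
            else:
                keep.append(g)
        st["genes"] = keep

    phase = {"inversion": 0, "indel": 1, "fission": 2, "fusion": 2, "translocation": 2}
    script = sorted(enumerate(cfg.rearrangement_script),
                    key=lambda t: (phase[t[1].kind], t[1].chrom, -t[1].start, t[0]))
    for _, ev in script:
        if ev.kind == "inversion":
            st = b[ev.chrom]
            drop_straddlers(st, [ev.start, ev.end])
            inside = [g for g in st["genes"] if ev.start <= g[1] and g[2] <= ev.end]
            outside = [g for g in st["genes"] if not (ev.start <= g[1] and g[2] <= ev.end)]
            for g in inside:
                g[1], g[2] = reflect((g[1], g[2]), ev.start, ev.end)
                g[3] = "-" if g[3] == "+" else "+"
            st["genes"] = sorted(outside + inside, key=lambda g: g[1])
            st["n_runs"] = sorted(
                reflect(run, ev.start, ev.end)
                if ev.start <= run[0] and run[1] <= ev.end else run
                for run in st["n_runs"])
            bp_a.extend([(ev.chrom, ev.start), (ev.chrom, ev.end)])
            bp_b.extend([[ev.chrom, ev.start], [ev.chrom, ev.end]])
        elif ev.kind == "indel":                # deletion from genome B
            st = b[ev.chrom]
            drop_straddlers(st, [ev.start, ev.end])
            size = ev.size_bp
            keep = []
            for g in st["genes"]:
                if ev.start <= g[1] and g[2] <= ev.end:
                    deleted.add(g[0])
                    continue
                if g[1] >= ev.end:
                    g[1] -= size
                    g[2] -= size
                keep.append(g)
            st["genes"] = keep
            st["n_runs"] = [(s - size, e - size) if s >= ev.end else (s, e)
                            for s, e in st["n_runs"] if not (ev.start <= s and e <= ev.end)]
            st["length"] -= size
            for p in bp_b:
                if p[0] == ev.chrom and p[1] >= ev.end:
                    p[1] -= size
            bp_a.append((ev.chrom, ev.start))
            bp_b.append([ev.chrom, ev.start])
        elif ev.kind == "fission":
            st = b.pop(ev.chrom)
            p = ev.start
            drop_straddlers(st, [p])
            part_a = {"length": p,
                      "n_runs": [r for r in st["n_runs"] if r[1] <= p],
                      "genes": [g for g in st["genes"] if g[2] <= p]}
            part_b = {"length": st["length"] - p,
                      "n_runs": [(s - p, e - p) for s, e in st["n_runs"] if s >= p],
                      "genes": [[g[0], g[1] - p, g[2] - p, g[3]]
                                for g in st["genes"] if g[1] >= p]}
            b[f"{ev.chrom}a"] = part_a
            b[f"{ev.chrom}b"] = part_b
            for q in bp_b:
                if q[0] == ev.chrom:
                    if q[1] <= p:
                        q[0] = f"{ev.chrom}a"
                    else:
                        q[0], q[1] = f"{ev.chrom}b", q[1] - p
            bp_a.append((ev.chrom, p))          # terminal in B: no B-side EBR
        elif ev.kind == "fusion":
            st1, st2 = b.pop(ev.chrom), b.pop(ev.chrom2)
            off = st1["length"]
            name = f"{ev.chrom}-{ev.chrom2}"
            b[name] = {"length": off + st2["length"],
                       "n_runs": st1["n_runs"] + [(s + off, e + off) for s, e in st2["n_runs"]],
                       "genes": st1["genes"] + [[g[0], g[1] + off, g[2] + off, g[3]]
                                                for g in st2["genes"]]}
            for q in bp_b:
                if q[0] == ev.chrom:
                    q[0] = name
                elif q[0] == ev.chrom2:
                    q[0], q[1] = name, q[1] + off
            bp_b.append([name, off])            # junction; terminal in A: no A-side EBR
        elif ev.kind == "translocation":        # reciprocal tail swap
            st1, st2 = b[ev.chrom], b[ev.chrom2]
            p1, p2 = ev.start, ev.pos2
            drop_straddlers(st1, [p1])
            drop_straddlers(st2, [p2])
            tail1 = [g for g in st1["genes"] if g[1] >= p1]
            tail2 = [g for g in st2["genes"] if g[1] >= p2]
            runs1 = [r for r in st1["n_runs"] if r[0] >= p1]
            runs2 = [r for r in st2["n_runs"] if r[0] >= p2]
            new1 = {"length": p1 + (st2["length"] - p2),
                    "n_runs": [r for r in st1["n_runs"] if r[1] <= p1]
                              + [(s - p2 + p1, e - p2 + p1) for s, e in runs2],
                    "genes": [g for g in st1["genes"] if g[2] <= p1]
                             + [[g[0], g[1] - p2 + p1, g[2] - p2 + p1, g[3]] for g in tail2]}
            new2 = {"length": p2 + (st1["length"] - p1),
                    "n_runs": [r for r in st2["n_runs"] if r[1] <= p2]
                              + [(s - p1 + p2, e - p1 + p2) for s, e in runs1],
                    "genes": [g for g in st2["genes"] if g[2] <= p2]
                             + [[g[0], g[1] - p1 + p2, g[2] - p1 + p2, g[3]] for g in tail1]}
            b[ev.chrom], b[ev.chrom2] = new1, new2
            bp_a.extend([(ev.chrom, p1), (ev.chrom2, p2)])
            bp_b.extend([[ev.chrom, p1], [ev.chrom2, p2]])

    # ortholog table over retained genes
    b_index: dict[str, tuple[str, int, int, str]] = {}
    for chrom, st in b.items():
        st["genes"].sort(key=lambda g: g[1])
        for g in st["genes"]:
            b_index[g[0]] = (chrom, g[1], g[2], g[3])
    rows = []
    for chrom in chroms:
        for g in genes_a[chrom]:
            if g[0] in deleted:
                continue
            tc, ts, te, tstr = b_index[g[0]]
            rows.append((g[0], chrom, g[1], g[2], g[3], tc, ts, te, tstr))
    orthologs = validate_ortholog_table(pd.DataFrame(rows, columns=[
        "gene_id", "ref_chrom", "ref_start", "ref_end", "ref_strand",
        "tgt_chrom", "tgt_start", "tgt_end", "tgt_strand"]))

    def marker_bounded(chrom: str, pos: int, genes: list[list]) -> tuple[str, int, int]:
        prev_end = max((g[2] for g in genes if g[2] <= pos), default=pos)
        next_start = min((g[1] for g in genes if g[1] >= pos), default=pos)
        return (chrom, int(prev_end), int(max(next_start, prev_end)))

    retained_a = {c: [g for g in genes_a[c] if g[0] not in deleted] for c in chroms}
    truth_a = sorted({marker_bounded(c, p, retained_a[c]) for c, p in bp_a})
    truth_b = sorted({marker_bounded(c, p, b[c]["genes"]) for c, p in bp_b})

    assembly_b = GenomeAssembly(
        lengths={c: st["length"] for c, st in b.items()},
        n_runs={c: sorted(st["n_runs"]) for c, st in b.items()})
    genes_a_df = pd.DataFrame(
        [(g[0], c, g[1], g[2], g[3]) for c in chroms for g in genes_a[c]],
        columns=["gene_id", "chrom", "start", "end", "strand"])
    return SimulatedComparison(
        assembly_a=assembly_a, assembly_b=assembly_b, orthologs=orthologs,
        truth_ebrs_a=truth_a, truth_ebrs_b=truth_b,
        truth_events=list(cfg.rearrangement_script), genes_a=genes_a_df)


# ---------------------------------------------------------------------------
# window landscape
# ---------------------------------------------------------------------------

def simulate_window_landscape(windows: pd.DataFrame,
                              tr_rate_by_region: dict[str, float],
                              gene_rate_by_region: dict[str, float],
                              seed: int = 0,
                              gene_length_bp: int = 1_000,
                              ) -> tuple[dict[str, list[tuple[int, int]]], pd.DataFrame]:
    """Plant TR intervals and genes into labelled windows at Poisson rates.

    ``windows`` carries chrom/start/end/label; rates are expected TR bp and
    expected gene count per 100-Kbp window for each label.  Features are kept
    strictly inside their window so window statistics recover the rates
    exactly.
    """
    rng = np.random.default_rng(seed + _SEED_LANDSCAPE)
    tr: dict[str, list[tuple[int, int]]] = {}
    gene_rows = []
    gid = 0
    for row in windows.itertuples(index=False):
        label = getattr(row, "label", None)
        span = row.end - row.start
        scale = span / 100_000
        tr_bp = int(min(span, rng.poisson(tr_rate_by_region.get(label, 0.0) * scale)))
        if tr_bp > 0:
            off = int(rng.integers(0, span - tr_bp + 1))
            tr.setdefault(row.chrom, []).append((row.start + off, row.start + off + tr_bp))
        n_genes = int(rng.poisson(gene_rate_by_region.get(label, 0.0) * scale))
        glen = min(gene_length_bp, span)
        for _ in range(n_genes):
            off = int(rng.integers(0, span - glen + 1))
            gene_rows.append((f"lg{gid:06d}", row.chrom, row.start + off,
                              row.start + off + glen, "+"))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return tr, genes


def synthesize_sequence(assembly: GenomeAssembly,
                        tr_intervals: dict[str, list[tuple[int, int]]] | None = None,
                        seed: int = 0) -> dict[str, str]:
    """Random nucleotide sequence per chromosome with N-runs at assembly gaps
    and exact tandem repeats filling the given intervals (unit size 2-6 bp)."""
    rng = np.random.default_rng(seed + _SEED_SEQ)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for chrom, length in assembly.lengths.items():
        arr = alphabet[rng.integers(0, 4, size=length)].copy()
        for s, e in (tr_intervals or {}).get(chrom, []):
            period = int(rng.integers(2, 7))
            unit = alphabet[rng.integers(0, 4, size=period)]
            reps = np.tile(unit, (e - s) // period + 1)[: e - s]
            arr[s:e] = reps
        for s, e in assembly.n_runs.get(chrom, []):
            arr[s:e] = ord("N")
        out[chrom] = arr.tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# annotations with planted enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTerm:
    term_id: str
    fold: float                     # over-representation inside the neighborhood
    neighborhood: tuple[str, int, int]
    base_rate: float = 0.02         # background membership probability

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError(f"planted fold must be >= 1, got {self.fold}")


@dataclass
class AnnotationConfig:
    n_background_terms: int = 20
    background_rate: float = 0.02   # per-gene membership probability per term
    seed: int = 0


def simulate_annotations(genes: pd.DataFrame,
                         planted_terms: list[PlantedTerm],
                         config: AnnotationConfig) -> pd.DataFrame:
    """Assign term memberships: background terms uniformly at random, planted
    terms over-represented at the configured fold inside their neighborhood.

    Returns a (gene_id, term_id) table; empty gene input yields an empty table.
    """
    rng = np.random.default_rng(config.seed + _SEED_ANNOT)
    rows: list[tuple[str, str]] = []
    if genes.empty:
        return pd.DataFrame(columns=["gene_id", "term_id"])
    for t in range(config.n_background_terms):
        mask = rng.random(len(genes)) < config.background_rate
        rows.extend((g, f"BG{t:04d}") for g in genes.loc[mask, "gene_id"])
    for pt in planted_terms:
        chrom, s, e = pt.neighborhood
        inside = ((genes["chrom"] == chrom)
                  & (genes["start"] < e) & (genes["end"] > s))
        prob = np.where(inside, min(1.0, pt.fold * pt.base_rate), pt.base_rate)
        mask = rng.random(len(genes)) < prob
        rows.extend((g, pt.term_id) for g in genes.loc[mask, "gene_id"])
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

@dataclass
class MeiosisConfig:
    n_cells: int = 100
    sc_length_um: list[float] = field(default_factory=lambda: [10.0])
    centromere_rel_pos: list[float] | float = 0.4
    per_sc_expected_co: list[float] | float = 1.76
    interference_min_spacing: float = 0.20      # fraction of SC length
    obligate_co: bool = True
    suppression_intervals: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    suppression_factor: float = 1.0
    bac_markers: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.suppression_factor <= 1.0):
            raise ValueError("suppression_factor must be in [0, 1]")
        for sc, ivs in self.suppression_intervals.items():
            for lo, hi in ivs:
                if not (0.0 <= lo <= hi <= 1.0):
                    raise ValueError(f"suppression interval [{lo}, {hi}] outside [0, 1]"
                                     f" on SC {sc}")
        for c in self._centromeres():
            if not (0.0 < c < 1.0):
                raise ValueError("centromere_rel_pos must be in (0, 1)")

    def _listify(self, v) -> list[float]:
        n = len(self.sc_length_um)
        return list(v) if isinstance(v, (list, tuple)) else [float(v)] * n

    def _centromeres(self) -> list[float]:
        return self._listify(self.centromere_rel_pos)

    def _expectations(self) -> list[float]:
        return self._listify(self.per_sc_expected_co)


def _ztp_rate(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean`` (>= 1)."""
    if mean <= 1.0 + 1e-9:
        return 0.0      # ZTP degenerates to a point mass at 1

    def f(lam: float) -> float:
        return lam / (1.0 - np.exp(-lam)) - mean

    return float(brentq(f, 1e-9, max(50.0, 2 * mean)))


def _sample_ztp(lam: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw by inverse CDF (stable for small rates)."""
    if lam <= 0.0:
        return 1
    u = float(rng.random()) * -np.expm1(-lam)   # u ~ U(0, 1 - e^-lam)
    cum = 0.0
    pk = lam * np.exp(-lam)                     # P[X = 1] numerator term
    k = 1
    while True:
        cum += pk
        if u <= cum or k > 1000:
            return k
        k += 1
        pk *= lam / k


def _place_foci(n: int, suppression: list[tuple[float, float]], factor: float,
                min_spacing: float, rng: np.random.Generator) -> list[float]:
    """Hard-core placement of n foci on [0, 1] with suppression thinning.

    A configuration with pairwise gaps >= ``min_spacing`` is drawn directly:
    uniform order statistics on the free length plus fixed gaps (so the count
    is never lost to packing failures; counts beyond the packing bound are
    clamped to it).  Each placed focus inside a suppression interval then
    survives with probability ``factor`` — genuine intensity thinning."""
    if n <= 0:
        return []
    if min_spacing > 0:
        n = min(n, int(1.0 / min_spacing) + 1)
    free = 1.0 - (n - 1) * min_spacing
    base = np.sort(rng.uniform(0.0, free, size=n))
    positions = base + min_spacing * np.arange(n)
    kept = []
    for u in positions:
        if any(lo <= u <= hi for lo, hi in suppression):
            if rng.random() >= factor:
                continue                # thinned out: focus removed
        kept.append(float(u))
    return kept


def simulate_meiotic_cells(config: MeiosisConfig) -> list[SCObservation]:
    """Simulate MLH1 foci on every SC of every cell.

    Crossover counts are drawn per SC from a Poisson (zero-truncated when the
    obligate-crossover rule is on) whose rate is solved so the post-truncation
    mean equals the configured per-SC expectation; positions come from the
    thinned hard-core process of :func:`_place_foci`.  When obligate crossover
    is on and an SC ends with zero foci (all thinned), the whole SC is
    resampled.  BAC marker positions are copied from the configuration.
    """
    rng = np.random.default_rng(config.seed + _SEED_MEIOSIS)
    lengths = config.sc_length_um
    centromeres = config._centromeres()
    expectations = config._expectations()
    if not (len(lengths) == len(centromeres) == len(expectations)):
        raise ValueError("per-SC parameter lists must share one length")
    rates = [(_ztp_rate(m) if config.obligate_co else m) for m in expectations]

    out: list[SCObservation] = []
    for cell in range(config.n_cells):
        for sc_idx, (length, cen, rate) in enumerate(zip(lengths, centromeres, rates)):
            suppression = config.suppression_intervals.get(sc_idx, [])
            while True:
                n = _sample_ztp(rate, rng) if config.obligate_co \
                    else int(rng.poisson(rate))
                foci = _place_foci(n, suppression, config.suppression_factor,
                                   config.interference_min_spacing, rng)
                if foci or not config.obligate_co:
                    break
            out.append(SCObservation(
                cell_id=f"cell{cell:04d}",
                sc_id=f"sc{sc_idx:02d}",
                length_um=length,
                centromere_um=cen * length,
                foci_um=[u * length for u in foci],
                bac_markers=[(mid, rel * length)
                             for mid, rel in config.bac_markers.get(sc_idx, [])]))
    return out


def group_cells(observations: list[SCObservation]) -> list[list[SCObservation]]:
    """Group a flat SC list by cell (insertion order preserved)."""
    cells: dict[str, list[SCObservation]] = {}
    for sc in observations:
        cells.setdefault(sc.cell_id, []).append(sc)
    return list(cells.values())
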