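"""End-to-end pipeline: simulate -> detect -> classify -> landscape ->
enrich -> recomb -> report, driven by one structured configuration.

Every stage writes its outputs under the configured output directory and
contributes to a JSON summary report (EBR count summary, window-landscape
comparisons, annotation clusters, recombination density table).  With a
fixed seed the whole run is deterministic, byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrichment as enr
from . import io as sio
from . import landscape as lsc
from . import rearrange as rea
from . import recombination as rec
from . import simulate as sim
from . import synteny as syn

log = logging.getLogger("synrec")

STAGES = ["simulate", "detect", "classify", "landscape", "enrich", "recomb"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "synrec_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    generator: dict = field(default_factory=dict)       # GeneratorConfig overrides
    meiosis: dict = field(default_factory=dict)         # MeiosisConfig overrides
    detection: dict = field(default_factory=dict)       # min_markers / gap / max_ebr_bp
    masks: dict = field(default_factory=dict)           # telomere_bp / centromere_flank_bp
    landscape: dict = field(default_factory=dict)       # window_bp
    enrichment: dict = field(default_factory=dict)      # flank_bp / kappa_min / ...
    verbosity: str = "INFO"

    _SECTION_KEYS = {
        "generator": {f.name for f in dataclasses.fields(sim.GeneratorConfig)},
        "meiosis": {f.name for f in dataclasses.fields(sim.MeiosisConfig)},
        "detection": {"min_markers", "max_marker_gap_bp", "max_ebr_bp"},
        "masks": {"telomere_bp", "centromere_flank_bp"},
        "landscape": {"window_bp"},
        "enrichment": {"flank_bp", "kappa_min", "min_genes", "max_genes", "alpha"},
    }

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for section, allowed in self._SECTION_KEYS.items():
            unknown = set(getattr(self, section)) - allowed
            if unknown:
                raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _default_rearrangement_script() -> list[sim.RearrangementEvent]:
    # one macro pericentric inversion on chromosome 1 (spans the centromere)
    return [sim.RearrangementEvent("inversion", "chrA1", 6_000_000, 14_000_000)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; later stages reuse earlier results.

    Returns the summary report (also written as ``report.json``).  A stage
    error propagates and halts downstream stages.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages),
                    "parameters": config.to_dict()}
    want = set(config.stages)

    # --- simulate ---------------------------------------------------------
    gen_kwargs = dict(config.generator)
    if "rearrangement_script" not in gen_kwargs:
        gen_kwargs["rearrangement_script"] = _default_rearrangement_script()
    gen_cfg = sim.GeneratorConfig(seed=config.seed, **gen_kwargs)
    comparison = sim.simulate_genome_pair(gen_cfg)
    log.info("simulated %d orthologs, %d truth EBRs (A)",
             len(comparison.orthologs), len(comparison.truth_ebrs_a))
    if "simulate" in want:
        sio.write_ortholog_table(comparison.orthologs, out / "orthologs.tsv")
        sio.write_assembly(comparison.assembly_a, out / "assembly_A.tsv")
        sio.write_assembly(comparison.assembly_b, out / "assembly_B.tsv")
        sio.write_genes(comparison.genes_a, out / "genes_A.tsv")
        with open(out / "truth_ebrs_A.bed", "w") as fh:
            for chrom, s, e in comparison.truth_ebrs_a:
                fh.write(f"{chrom}\t{s}\t{e}\ttruth\t{e - s}\t.\n")
        report["simulate"] = {"n_orthologs": int(len(comparison.orthologs)),
                              "n_truth_ebrs_a": len(comparison.truth_ebrs_a),
                              "n_truth_ebrs_b": len(comparison.truth_ebrs_b)}
    if not (want - {"simulate"}):
        _write_report(report, out)
        return report

    # --- detect -----------------------------------------------------------
    det = dict(config.detection)
    result = syn.dual_reference_run(comparison.orthologs,
                                    ref_assembly=comparison.assembly_a,
                                    tgt_assembly=comparison.assembly_b, **det)
    if "detect" in want:
        sio.write_hsbs_bed(result["ref_hsbs"], out / "hsbs_A.bed")
        sio.write_ebrs_bed(result["ref_ebrs"], out / "ebrs_A.bed")
        sio.write_ebrs_bed(result["tgt_ebrs"], out / "ebrs_B.bed")
        report["detect"] = {"n_hsbs_a": len(result["ref_hsbs"]),
                            "n_ebrs_a": len(result["ref_ebrs"]),
                            "n_hsbs_b": len(result["tgt_hsbs"]),
                            "n_ebrs_b": len(result["tgt_ebrs"])}
    if not (want - {"simulate", "detect"}):
        _write_report(report, out)
        return report

    # --- classify ---------------------------------------------------------
    masks = rea.build_region_masks(comparison.assembly_a, **config.masks)
    filtered = rea.filter_ebrs(result["ref_ebrs"], masks)
    retained = rea.retained(filtered)
    classified = rea.classify_rearrangements(result["ref_hsbs"], retained)
    if "classify" in want:
        sio.write_masks_bed(masks, out / "masks_A.bed")
        sio.write_ebrs_bed(filtered, out / "ebrs_A_filtered.bed")
        with open(out / "classification.tsv", "w") as fh:
            fh.write("kind\tsize_class\tchrom\tregion_start\tregion_end\tspan_bp\n")
            for c in classified:
                s1, e1 = sio.to_report_coords(c.region_start, c.region_end)
                fh.write(f"{c.kind}\t{c.size_class}\t{c.chrom}\t{s1}\t{e1}\t{c.region_span}\n")
        report["classify"] = {"summary": rea.summarize_ebrs(filtered),
                              "by_kind": {c.kind: sum(1 for x in classified
                                                      if x.kind == c.kind)
                                          for c in classified}}
    if not (want - {"simulate", "detect", "classify"}):
        _write_report(report, out)
        return report

    # --- landscape --------------------------------------------------------
    windows = lsc.window_scan(comparison.assembly_a, window_bp=config.landscape.get(
        "window_bp", lsc.WINDOW_BP))
    labelled = lsc.label_windows(windows, masks, result["ref_hsbs"], retained)
    tr_ivs, lgenes = sim.simulate_window_landscape(
        labelled, gen_cfg.tr_rate_by_region, gen_cfg.gene_rate_by_region,
        seed=config.seed)
    scanned = lsc.window_scan(comparison.assembly_a, tr_ivs, lgenes,
                              window_bp=config.landscape.get("window_bp", lsc.WINDOW_BP))
    scanned["label"] = labelled["label"]
    if "landscape" in want:
        scanned.to_csv(out / "windows.tsv", sep="\t", index=False)
        present = [g for g in ("telomere", "centromere", "EBR", "HSB")
                   if (scanned["label"] == g).any()]
        report["landscape"] = {
            "tr_by_region": lsc.compare_window_groups(scanned, "tr_bp", present)
            if len(present) >= 2 else None,
            "gene_density": {g: lsc.mean_gene_density(scanned, g) for g in present},
        }
    if not (want - {"simulate", "detect", "classify", "landscape"}):
        _write_report(report, out)
        return report

    # --- enrich -----------------------------------------------------------
    enrich_par = dict(config.enrichment)
    flank = enrich_par.pop("flank_bp", enr.DEFAULT_FLANK_BP)
    foreground = enr.genes_in_ebr_neighborhoods(comparison.genes_a, retained, flank)
    background = enr.build_background(comparison.genes_a, masks)
    planted = []
    if comparison.truth_ebrs_a:
        chrom, s, e = comparison.truth_ebrs_a[0]
        planted = [sim.PlantedTerm("PLANTED", fold=8.0,
                                   neighborhood=(chrom, max(0, s - flank), e + flank))]
    annotations = sim.simulate_annotations(
        comparison.genes_a, planted, sim.AnnotationConfig(seed=config.seed))
    terms = enr.score_terms(foreground, background, annotations)
    clusters = enr.cluster_terms(terms, **enrich_par)
    if "enrich" in want:
        sio.write_annotations(annotations, out / "annotations.tsv")
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("cluster\tenrichment_score\tterms\tn_genes\n")
            for i, c in enumerate(clusters):
                terms_s = ";".join(t.term_id for t in c.member_terms)
                fh.write(f"{i}\t{c.enrichment_score:.4f}\t{terms_s}\t{len(c.member_genes)}\n")
        report["enrich"] = {
            "n_foreground": len(foreground), "n_background": len(background),
            "clusters": [{"es": round(c.enrichment_score, 4),
                          "terms": sorted(t.term_id for t in c.member_terms)}
                         for c in clusters]}
    if not (want - set(STAGES[:-1])):
        _write_report(report, out)
        return report

    # --- recomb -----------------------------------------------------------
    mei_kwargs = dict(config.meiosis)
    mei_kwargs.setdefault("sc_length_um", [10.0])
    mei_kwargs.setdefault("suppression_intervals", {0: [(0.3, 0.6)]})
    mei_kwargs.setdefault("suppression_factor", 0.1)
    mei_kwargs.setdefault("per_sc_expected_co", 2.0)
    mei_cfg = sim.MeiosisConfig(seed=config.seed, **mei_kwargs)
    scs = sim.simulate_meiotic_cells(mei_cfg)
    sio.write_foci_csv(scs, out / "foci.csv")
    cells = sim.group_cells(scs)
    sup = mei_cfg.suppression_intervals.get(0, [])
    density_rows = []
    first_sc = [c[0] for c in cells]
    whole = rec.co_density(first_sc, rec.whole_sc, region="whole")
    entry = {"chrom": "sc00", "n": whole.n_cells,
             "foci_per_sc": whole.total_foci / whole.n_cells,
             "foci_per_um": whole.foci_per_um}
    if sup:
        interval_of = rec.proportional_interval(*sup[0])
        inside = rec.co_density(first_sc, interval_of, region="inside_inv")
        outside = rec.outside_interval_density(first_sc, interval_of)
        test = rec.compare_densities(rec.per_cell_densities(first_sc, interval_of),
                                     _outside_per_cell(first_sc, interval_of))
        entry |= {"inside_inv": inside.foci_per_um, "outside_inv": outside.foci_per_um,
                  "p_inside_vs_outside": test["p_value"]}
    density_rows.append(entry)
    cmap = rec.cumulative_distribution(first_sc, "sc00", "all")
    try:  # plots are best-effort; the TSV map is the canonical output
        from .plots import plot_cumulative_map
        plot_cumulative_map(cmap, out / "recombination_map.png")
    except Exception as err:  # pragma: no cover
        log.warning("plot generation skipped: %s", err)
    with open(out / "recombination_map.tsv", "w") as fh:
        fh.write("bin_start_pct\tbin_end_pct\tfrequency\tcumulative\n")
        for i in range(len(cmap.frequency)):
            fh.write(f"{cmap.bin_edges[i]:.0f}\t{cmap.bin_edges[i + 1]:.0f}\t"
                     f"{cmap.frequency[i]:.0f}\t{cmap.cumulative[i]:.6f}\n")
    with open(out / "density_table.tsv", "w") as fh:
        cols = ["chrom", "n", "foci_per_sc", "foci_per_um",
                "inside_inv", "outside_inv", "p_inside_vs_outside"]
        fh.write("\t".join(cols) + "\n")
        for r in density_rows:
            fh.write("\t".join(_fmt(r.get(c)) for c in cols) + "\n")
    report["recomb"] = {
        "genetic_length_cM": rec.genetic_length(cells),
        "mean_foci_per_cell": sum(len(sc.foci_um) for sc in scs) / len(cells),
        "density_table": density_rows}
    _write_report(report, out)
    return report


def _outside_per_cell(scs, interval_of):
    out = []
    for sc in scs:
        iv = interval_of(sc)
        if iv is None:
            continue
        lo, hi = iv
        length = sc.length_um - (hi - lo)
        if length > 0:
            inside = sum(1 for x in sc.foci_um if lo <= x < hi)
            out.append((len(sc.foci_um) - inside) / length)
    return out


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
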