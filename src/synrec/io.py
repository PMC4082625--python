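"""Readers and writers for the pipeline's plain-text formats.

Orthologs, annotations and assembly dictionaries travel as TSV; intervals
(HSBs, EBRs, masks, tandem repeats) as BED with 0-based half-open
coordinates; genomes as FASTA; meiotic measurements as CSV with
semicolon-separated position lists.  Every writer/reader pair round-trips
canonicalized records losslessly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import ORTHOLOG_COLUMNS, GenomeAssembly, validate_ortholog_table
from .landscape import TandemRepeat
from .rearrange import RegionMask
from .recombination import SCObservation
from .synteny import EBR, HSB


# -- ortholog table ---------------------------------------------------------

def write_ortholog_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_ortholog_table(table).to_csv(path, sep="\t", index=False)


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=ORTHOLOG_COLUMNS)
    if table.empty:
        return pd.DataFrame(columns=ORTHOLOG_COLUMNS)
    missing = [c for c in ORTHOLOG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # locate offending rows so the error carries a line number (+2: header, 1-based)
    for side in ("ref", "tgt"):
        bad = table.index[table[f"{side}_start"] >= table[f"{side}_end"]]
        if len(bad):
            raise ValueError(f"{path}: line {bad[0] + 2}: {side} interval start >= end")
        bad = table.index[~table[f"{side}_strand"].isin(["+", "-"])]
        if len(bad):
            raise ValueError(f"{path}: line {bad[0] + 2}: invalid {side}_strand")
    dup = table.index[table["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: line {dup[0] + 2}: duplicated gene_id")
    return validate_ortholog_table(table)


# -- assembly dictionary ----------------------------------------------------

def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    """Sequence dictionary: chrom, length, semicolon-joined N-run intervals."""
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tn_runs\n")
        for chrom, length in assembly.lengths.items():
            runs = ";".join(f"{s}-{e}" for s, e in assembly.n_runs.get(chrom, []))
            fh.write(f"{chrom}\t{length}\t{runs}\n")


def read_assembly(path: str | Path) -> GenomeAssembly:
    lengths: dict[str, int] = {}
    n_runs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: missing assembly header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            chrom, length = parts[0], int(parts[1])
            lengths[chrom] = length
            runs = []
            if len(parts) > 2 and parts[2]:
                for chunk in parts[2].split(";"):
                    s, e = chunk.split("-")
                    runs.append((int(s), int(e)))
            n_runs[chrom] = runs
    return GenomeAssembly(lengths=lengths, n_runs=n_runs)


# -- BED --------------------------------------------------------------------

def write_ebrs_bed(ebrs: list[EBR], path: str | Path) -> None:
    """BED6: name = detector/status, score = span, strand = '.'"""
    with open(path, "w") as fh:
        for e in sorted(ebrs, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t"
                     f"{e.detector}/{e.status}\t{e.span}\t.\n")


def read_ebrs_bed(path: str | Path, genome: str = "ref") -> list[EBR]:
    out: list[EBR] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed BED row at line {lineno}")
            detector, status = parts[3].split("/")
            out.append(EBR(genome=genome, chrom=parts[0], start=int(parts[1]),
                           end=int(parts[2]), detector=detector, status=status))
    return out


def write_hsbs_bed(hsbs: list[HSB], path: str | Path) -> None:
    """BED6 on the reference genome; strand encodes orientation."""
    with open(path, "w") as fh:
        for h in sorted(hsbs, key=lambda x: (x.ref_chrom, x.ref_start)):
            strand = "+" if h.orientation == "same" else "-"
            fh.write(f"{h.ref_chrom}\t{h.ref_start}\t{h.ref_end}\t"
                     f"{h.hsb_id}\t{h.marker_count}\t{strand}\n")


def write_masks_bed(masks: dict[str, RegionMask], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(masks):
            m = masks[chrom]
            for label, ivs in (("telomeric", m.telomeric), ("centromeric", m.centromeric)):
                for s, e in ivs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\t{e - s}\t.\n")


def write_tandem_repeats_bed(trs: list[TandemRepeat], path: str | Path) -> None:
    """BED: name = canonical motif, score = copy number."""
    with open(path, "w") as fh:
        for t in trs:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.motif}\t{t.copy_number}\t.\n")


# -- FASTA ------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- foci CSV ---------------------------------------------------------------

def write_foci_csv(observations: list[SCObservation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "sc_id", "sc_length_um", "centromere_um",
                         "focus_positions", "bac_markers"])
        for sc in observations:
            foci = ";".join(f"{x:.6g}" for x in sc.foci_um)
            bacs = ";".join(f"{mid}:{pos:.6g}" for mid, pos in sc.bac_markers)
            writer.writerow([sc.cell_id, sc.sc_id, f"{sc.length_um:.6g}",
                             f"{sc.centromere_um:.6g}", foci, bacs])


def read_foci_csv(path: str | Path) -> list[SCObservation]:
    out: list[SCObservation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                foci = [float(x) for x in row["focus_positions"].split(";") if x]
                bacs = []
                for chunk in row["bac_markers"].split(";"):
                    if chunk:
                        mid, pos = chunk.rsplit(":", 1)
                        bacs.append((mid, float(pos)))
                out.append(SCObservation(
                    cell_id=row["cell_id"], sc_id=row["sc_id"],
                    length_um=float(row["sc_length_um"]),
                    centromere_um=float(row["centromere_um"]),
                    foci_um=foci, bac_markers=bacs))
            except (KeyError, ValueError, TypeError) as err:
                raise ValueError(f"{path}: malformed row at line {lineno}: {err}") from err
    return out


# -- annotations ------------------------------------------------------------

def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "term_id"])
    for col in ("gene_id", "term_id"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return table


# -- genes ------------------------------------------------------------------

def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return table


def to_report_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive, for human-readable reports."""
    return start + 1, end
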