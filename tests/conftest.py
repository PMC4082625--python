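import numpy as np
import pandas as pd
import pytest

from synrec.genome import GenomeAssembly

MARKER_LEN = 1_000


def make_table(markers, marker_len: int = MARKER_LEN) -> pd.DataFrame:
    """Compact ortholog-table builder.

    Each marker is (ref_chrom, ref_start, tgt_chrom, tgt_start, relation)
    with relation "+" (strands agree) or "-" (strands flipped); markers are
    ``marker_len`` bp long on both genomes.
    """
    rows = []
    for i, (rc, rs, tc, ts, rel) in enumerate(markers):
        rows.append((f"m{i:03d}", rc, rs, rs + marker_len, "+",
                     tc, ts, ts + marker_len, "+" if rel == "+" else "-"))
    return pd.DataFrame(rows, columns=[
        "gene_id", "ref_chrom", "ref_start", "ref_end", "ref_strand",
        "tgt_chrom", "tgt_start", "tgt_end", "tgt_strand"])


def collinear_markers(n: int, chrom: str = "c1", spacing: int = 100_000):
    return [(chrom, i * spacing, chrom, i * spacing, "+") for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240530)


@pytest.fixture
def small_assembly():
    return GenomeAssembly(
        lengths={"c1": 100_000_000},
        n_runs={"c1": [(49_750_000, 50_250_000)]})
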