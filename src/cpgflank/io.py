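"""FASTA / TSV readers and writers.

FASTA goes through Biopython.  Call matrices persist as TSV with a
``# region=<name>`` header comment, one row per molecule (metadata columns
then one 0/1/NA column per CpG site); the round trip is lossless for calls,
strata labels and conversion efficiencies.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import META_COLUMNS, MethylationCallMatrix


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, uppercased sequence) records; rejects empty sequences."""
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected a '>' FASTA header")
            break
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_call_matrix(matrix: MethylationCallMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# region={matrix.region_name}\n")
        matrix.df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_call_matrix(path: str | Path) -> MethylationCallMatrix:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# region="):
            raise ValueError(f"{path}: missing '# region=' header line")
        region_name = first.strip().split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    site_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        sites = [int(c) for c in site_cols]
    except ValueError as err:
        raise ValueError(f"{path}: site columns must be integer positions") from err
    if sites != sorted(sites):
        raise ValueError(f"{path}: site columns out of order")
    df["pass_filter"] = df["pass_filter"].astype(bool)
    for c in site_cols:
        df[c] = df[c].astype(float)
    return MethylationCallMatrix(region_name, sites, df)


def write_site_bed(matrix_or_sites, region_name: str, path: str | Path) -> None:
    """BED-like site definition table: region, start, end=start+2 (0-based)."""
    sites = (
        matrix_or_sites.sites
        if isinstance(matrix_or_sites, MethylationCallMatrix)
        else list(matrix_or_sites)
    )
    pd.DataFrame(
        {"region": region_name, "start": sites, "end": np.asarray(sites) + 2}
    ).to_csv(path, sep="\t", index=False, header=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
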