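"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* Genomic coordinates are 1-based inclusive inside the package (matching the
  per-cytosine report and GFF3); BED/bedGraph output converts to 0-based
  half-open at the boundary.
* Cytosine reports are 6-column TSV:
  ``chrom  pos  strand  count_methylated  count_unmethylated  context``.
* Count matrices are genes-as-rows TSV with a header row of sample ids.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from pyfaidx import Fasta

from .errors import MissingInputError, ValidationError

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "m", "u", "context"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise MissingInputError(f"required input does not exist: {path}")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            seq = genome[chrom]
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a genome FASTA into chromosome -> sequence (upper-cased)."""
    _require(path)
    fasta = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
    try:
        return {name: str(fasta[name][:]) for name in fasta.keys()}
    finally:
        fasta.close()


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path: str, source: str = "methexp") -> None:
    """Write gene models as GFF3 (1-based inclusive, feature ``gene``)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str) -> pd.DataFrame:
    """Read ``gene`` features from a GFF3 file into the internal gene table."""
    _require(path)
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValidationError(f"GFF3 gene without ID attribute: {line!r}")
            records.append(
                (gene_id, fields[0], int(fields[3]), int(fields[4]), fields[6])
            )
    return pd.DataFrame(records, columns=GENE_COLUMNS)


def write_bed6(genes: pd.DataFrame, path: str) -> None:
    """Write gene models as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t"
                f"{row.strand}\n"
            )


def read_bed6(path: str) -> pd.DataFrame:
    _require(path)
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str},
    )
    out = pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "start": bed["start0"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    )
    return out


# ---------------------------------------------------------------------------
# Cytosine reports
# ---------------------------------------------------------------------------

def write_cytosine_report(sites: pd.DataFrame, path: str) -> None:
    sites.to_csv(path, sep="\t", header=False, index=False, columns=CYTOSINE_COLUMNS)


def read_cytosine_report(path: str) -> pd.DataFrame:
    _require(path)
    sites = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=CYTOSINE_COLUMNS,
        dtype={
            "chrom": str,
            "pos": "int64",
            "strand": str,
            "m": "int64",
            "u": "int64",
            "context": str,
        },
    )
    if (sites["m"] < 0).any() or (sites["u"] < 0).any():
        raise ValidationError(f"negative read counts in {path}")
    return sites


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str) -> pd.DataFrame:
    _require(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_lengths(lengths: pd.Series, path: str) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path: str) -> pd.Series:
    _require(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table["length"]


def write_sample_sheet(sheet: pd.DataFrame, path: str) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    _require(path)
    sheet = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "genotype": str, "stage": str}
    )
    expected = {"sample_id", "genotype", "stage", "replicate"}
    missing = expected - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_annotation(path: str) -> pd.DataFrame:
    """Two-column gene -> term table (no header enforced; header tolerated)."""
    _require(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["gene_id", "term_id"]:
        table = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str
        )
    return table[["gene_id", "term_id"]]


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    annotation.to_csv(path, sep="\t", index=False, columns=["gene_id", "term_id"])


def write_bedgraph(track: pd.DataFrame, path: str, value_col: str = "mean_level") -> None:
    """Window track to bedGraph; rows with missing values are skipped."""
    kept = track.dropna(subset=[value_col])
    with open(path, "w") as fh:
        for row in kept.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{getattr(row, value_col):.6g}\n"
            )
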