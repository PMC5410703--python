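"""Readers and writers for per-cytosine methylation call tables and gene models.

The per-cytosine table is the allc-style dialect produced by methylpy-like
pipelines: seven tab-separated columns (chromosome, 1-based position, strand,
trinucleotide context, methylated read count, total read count, call flag),
no header by default. Trinucleotide strings are collapsed to the three
cytosine sequence-context classes CG / CHG / CHH (H = A, C or T) on input.

Gene models carry the coding interval (start codon to stop codon) used as the
"gene body" throughout; BED intervals are converted from 0-based half-open to
1-based inclusive, GFF3 CDS features are merged per gene to their outermost
span.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

#: canonical trinucleotide written for each context class when none is stored
_CANONICAL_TRI = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}

ALLC_COLUMNS = ["chrom", "pos", "strand", "tri", "mc", "cov", "call"]

RECORD_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


class AllcParseError(ValueError):
    """Raised when an allc-style table violates the record invariants."""


def collapse_context(tri: str) -> str:
    """Collapse a trinucleotide string (cytosine-first) to CG / CHG / CHH.

    H is any of A, C, T. Strings that are already a context class are passed
    through. Ambiguous bases (N) cannot be classified.
    """
    t = tri.upper()
    if t in CONTEXTS:
        return t
    if len(t) < 3 or t[0] != "C":
        raise ValueError(f"not a cytosine trinucleotide: {tri!r}")
    if t[1] == "G":
        return "CG"
    if t[1] in "ACT" and t[2] == "G":
        return "CHG"
    if t[1] in "ACT" and t[2] in "ACT":
        return "CHH"
    raise ValueError(f"ambiguous trinucleotide context: {tri!r}")


def _collapse_series(tri: pd.Series) -> pd.Series:
    mapping = {t: collapse_context(t) for t in tri.unique()}
    return tri.map(mapping)


def read_allc(path, header: bool = False) -> pd.DataFrame:
    """Read an allc-style TSV into a validated cytosine record frame.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with at least 6 columns: chrom, 1-based position,
        strand (+/−), trinucleotide context, methylated reads, total reads.
        A 7th call-flag column is tolerated and ignored. ``.gz`` transparent.
    header : bool
        Whether the first line is a header to skip.

    Returns
    -------
    DataFrame with columns chrom, pos, strand, context, mc, cov, sorted as on
    disk. Rows violating 0 ≤ mc ≤ cov, pos ≥ 1 or an unknown strand raise
    :class:`AllcParseError` naming the offending line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=0 if header else None,
            names=ALLC_COLUMNS,
            usecols=range(7),
            dtype={0: str, 2: str, 3: str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    except pd.errors.ParserError as exc:
        raise AllcParseError(f"{path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    offset = 2 if header else 1  # 1-based line number of first data row
    for col in ("pos", "mc", "cov"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad)[0]) + offset
            raise AllcParseError(f"{path}: non-numeric {col} at line {line}")
    checks = [
        (df["pos"] < 1, "position < 1"),
        (df["mc"] < 0, "negative methylated count"),
        (df["mc"] > df["cov"], "meth_reads > total_reads"),
        (~df["strand"].isin(["+", "-"]), "unknown strand"),
    ]
    for bad, msg in checks:
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + offset
            raise AllcParseError(f"{path}: {msg} at line {line}")
    try:
        context = _collapse_series(df["tri"])
    except ValueError as exc:
        raise AllcParseError(f"{path}: {exc}") from exc
    out = df[["chrom", "pos", "strand"]].copy()
    out["context"] = context
    out["mc"] = df["mc"].astype(np.int64)
    out["cov"] = df["cov"].astype(np.int64)
    out["pos"] = out["pos"].astype(np.int64)
    return out


def write_allc(records: pd.DataFrame, path) -> None:
    """Write cytosine records as a 7-column allc-style TSV (no header).

    A ``tri`` column is used when present; otherwise a canonical
    trinucleotide for the record's context class is written. The call flag
    is 1 when any methylated read was observed.
    """
    path = Path(path)
    df = records.copy()
    if "tri" not in df.columns:
        df["tri"] = df["context"].map(_CANONICAL_TRI)
    df["call"] = (df["mc"] > 0).astype(int)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df[ALLC_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def _validate_genes(genes: pd.DataFrame, source) -> pd.DataFrame:
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"{source}: duplicate gene ids: {', '.join(map(str, dups))}")
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene_id"].tolist()
        raise ValueError(f"{source}: empty interval for genes: {bad}")
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    # overlapping genes break interval assignment downstream; refuse early
    same = genes["chrom"].shift() == genes["chrom"]
    overlap = same & (genes["start"] <= genes["end"].shift())
    if overlap.any():
        bad = genes.loc[overlap, "gene_id"].tolist()
        raise ValueError(f"{source}: overlapping gene intervals at: {bad}")
    return genes


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation into 1-based inclusive gene models."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start0", "end0", "gene_id", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "strand": df["strand"],
            "start": df["start0"].astype(np.int64) + 1,
            "end": df["end0"].astype(np.int64),
        }
    )
    return _validate_genes(genes, path)


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3, merging CDS features per gene to the outermost start/stop."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        feats = cds if cds else [gene]
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": gene.seqid,
                "strand": gene.strand,
                "start": min(f.start for f in feats),
                "end": max(f.end for f in feats),
            }
        )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    return _validate_genes(genes, path)


def read_genes(path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 (format inferred from suffix)."""
    if fmt is None:
        name = str(path).removesuffix(".gz")
        fmt = "GFF3" if name.endswith((".gff", ".gff3")) else "BED"
    fmt = fmt.upper()
    if fmt == "BED":
        return read_bed(path)
    if fmt == "GFF3":
        return read_gff3(path)
    raise ValueError(f"unknown gene annotation format: {fmt}")


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write gene models as BED6 (0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start0": genes["start"] - 1,
            "end0": genes["end"],
            "gene_id": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models as minimal GFF3 gene + CDS feature pairs."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tgbmscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tgbmscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID=cds.{g.gene_id};Parent={g.gene_id}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an id → sequence dict."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


@dataclass(frozen=True)
class GeneModel:
    """One gene's coding interval, start codon to stop codon, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1
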