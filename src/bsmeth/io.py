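"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are 0-based half-open in memory.  Text reports that
carry single positions (the cytosine report and the count table) print them
1-based, matching the convention of genome browsers and of methylation
callers' per-cytosine reports; interval files are BED (0-based half-open).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

# Fixed float format so identical inputs give byte-identical outputs.
FLOAT_FORMAT = "%.10g"

CYTOSINE_REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "neighborhood"]
COUNT_TABLE_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "n_meth", "n_unmeth", "n_other", "level", "is_methylated",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {name: sequence}.

    Raises ValueError naming the file when no records parse.
    """
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"malformed or empty FASTA: {path}")
    return records


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_cytosine_report(sites: pd.DataFrame, path) -> None:
    """Cytosine report TSV: chrom, pos (1-based), strand, context, neighborhood."""
    out = sites[CYTOSINE_REPORT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    write_tsv(out, path)


def read_cytosine_report(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(CYTOSINE_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine report {path} missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["context"] = df["context"].fillna("NA")
    return df[CYTOSINE_REPORT_COLUMNS]


def write_count_table(counts: pd.DataFrame, path) -> None:
    """Per-sample count table: chrom, pos (1-based), strand, context, counts, level, call."""
    out = counts[COUNT_TABLE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out["is_methylated"] = out["is_methylated"].astype(int)
    write_tsv(out, path)


def read_count_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(COUNT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    df["context"] = df["context"].fillna("NA")
    df["is_methylated"] = df["is_methylated"].astype(bool)
    return df[COUNT_TABLE_COLUMNS]


def read_bed(path) -> pd.DataFrame:
    """BED6(+extras) reader.

    Returns chrom, start, end, name, score, strand plus any extra columns
    named extra1..extraN (the simulator uses extra1 for TE class / gene part).
    """
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line with <3 fields")
            rows.append(fields)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    width = max(len(r) for r in rows)
    names = ["chrom", "start", "end", "name", "score", "strand"][:width]
    names += [f"extra{i}" for i in range(1, width - len(names) + 1)]
    df = pd.DataFrame([r + [""] * (width - len(r)) for r in rows], columns=names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "name" not in df:
        df["name"] = [f"feat{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "+"
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"feat{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "+"
    for c in extra_cols or []:
        cols.append(c)
    out[cols].to_csv(path, sep="\t", index=False, header=False,
                     float_format=FLOAT_FORMAT)


def read_features(path) -> pd.DataFrame:
    """Read a gene/TE annotation (BED6+1 or GFF3) into the internal feature frame.

    Columns: chrom, start, end, name, strand, kind ('' unless given),
    te_class/part from the extra BED column when present.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    df = read_bed(path)
    df = df.rename(columns={"extra1": "label"})
    if "label" not in df:
        df["label"] = ""
    return df[["chrom", "start", "end", "name", "strand", "label"]]


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{ln}: GFF3 line with {len(f)} fields")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("ID") or attrs.get("Name") or f"{f[2]}_{ln}"
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name, f[6], f[2]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand", "label"])
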