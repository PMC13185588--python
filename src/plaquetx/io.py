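"""Plain-text readers and writers for the pipeline's tabular interchange.

Counts, sample sheets, truth tables, and DGE tables travel as TSV; catalogs
as FASTA (header ``>species|gene|ko``); masks as BED-like TSV; reads as
FASTQ (Phred+33, constant quality).
"""

from __future__ import annotations

import gzip

import pandas as pd

FEATURE_COLS = ["species_id", "gene_id", "ko_id"]


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.reset_index().to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in FEATURE_COLS})
    df["ko_id"] = df["ko_id"].fillna("")
    df = df.set_index(FEATURE_COLS)
    return df.astype(int)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.reset_index().to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in FEATURE_COLS})
    return df.set_index(FEATURE_COLS)


def write_dge(dge: pd.DataFrame, path) -> None:
    dge.to_csv(path, sep="\t", index=False)


def read_dge(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={**{c: str for c in FEATURE_COLS}, "contrast": str})


def write_labels(labels: pd.DataFrame, path) -> None:
    out = labels.reset_index()
    ga, gb = labels.attrs.get("groups", ("A", "B"))
    out.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"#groups={ga},{gb}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
        groups = tuple(first.split("=", 1)[1].split(",")) if first.startswith("#groups=") else ("A", "B")
        df = pd.read_csv(fh, sep="\t", dtype={c: str for c in FEATURE_COLS})
    df["ko_id"] = df["ko_id"].fillna("")
    df = df.set_index(FEATURE_COLS)
    df.attrs["groups"] = groups
    return df


def write_fastq(reads, path, quality: str = "I") -> None:
    """Write ``(name, sequence)`` pairs as FASTQ with constant quality."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path):
    """Yield ``(name, sequence)`` pairs from a (possibly gzipped) FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header.strip()[1:].split()[0], seq


def read_hierarchy(path) -> pd.DataFrame:
    """KO functional hierarchy TSV with columns ko, levelA, levelB, levelC."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "ko" not in df.columns or "levelA" not in df.columns:
        raise ValueError("hierarchy TSV needs at least columns ko, levelA")
    for col in ("levelB", "levelC"):
        if col not in df.columns:
            df[col] = ""
    return df
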