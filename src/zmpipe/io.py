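"""Shared readers and writers for the pipeline's plain-text formats.

Result tables are TSV with a single ``#``-prefixed header line, so outputs
diff cleanly and parse back through :func:`read_table`. Methylation calls
use a CX-report-like dialect: ``chrom, pos, strand, context, c, t`` with
0-based positions (a flag accepts 1-based input).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .methylome import CALL_COLUMNS


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        cols = (["index"] if index else []) + list(df.columns)
        fh.write("#" + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        return pd.read_csv(fh, sep="\t", names=header, **kwargs)


def read_methylation_calls(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a per-cytosine call table; ``one_based`` shifts positions down."""
    df = read_table(path)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[CALL_COLUMNS].copy()
    if one_based:
        df["pos"] = df["pos"] - 1
    return df


def write_methylation_calls(calls: pd.DataFrame, path: str | Path) -> None:
    write_table(calls[CALL_COLUMNS], path)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED of aligned read intervals (name/score columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return df[["chrom", "start", "end", "strand"]]


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    out = reads.assign(name=".", score=0)[["chrom", "start", "end", "name", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_sequences(path: str | Path) -> list[str]:
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip())
    return seqs


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()
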