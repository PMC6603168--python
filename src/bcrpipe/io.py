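"""FASTQ / FASTA / AIRR-TSV reading and writing.

FASTQ is Phred+33, plain or gzip.  Rearrangement tables are tab-separated
with AIRR-style column names and a single leading provenance comment line
(tool version, seed, parameters); :func:`read_airr` round-trips everything
:func:`write_airr` produces.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MalformedInputError
from .preprocess import SequencingRead

TOOL_VERSION = "bcrpipe 0.1.0"

_INT_COLUMNS = {
    "junction_length", "consensus_count", "duplicate_count", "umi_count",
    "max_reads_per_umi", "total_reads", "n_reads", "junction_start",
    "junction_end",
}
_FLOAT_COLUMNS = {"v_identity", "shm_percent", "mean_shm"}
_COORD_COLUMNS = {
    "fwr1_start", "fwr1_end", "cdr1_start", "cdr1_end", "fwr2_start",
    "fwr2_end", "cdr2_start", "cdr2_end", "fwr3_start", "fwr3_end",
    "fwr4_start", "fwr4_end", "core_start", "core_end",
}


def _opener(path):
    return gzip.open if str(path).endswith(".gz") else open


def read_fastq(path, orientation: str = "forward") -> list[SequencingRead]:
    """Parse a Phred+33 FASTQ file (gzip allowed) into SequencingReads."""
    reads = []
    with _opener(path)(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            lineno += 4
            if not header.startswith("@") or not plus.startswith("+"):
                raise MalformedInputError(f"{path}: bad record at line {lineno - 3}")
            if len(seq) != len(qual):
                raise MalformedInputError(
                    f"{path}: record {header[1:].strip()!r} (line {lineno - 3}): "
                    f"sequence/quality length mismatch"
                )
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
            if len(quals) and (quals.min() < 0 or quals.max() > 60):
                raise MalformedInputError(
                    f"{path}: record {header[1:].strip()!r}: quality outside [0,60]"
                )
            reads.append(SequencingRead(header[1:].split()[0], seq.upper(), quals,
                                        orientation))
    return reads


def read_fastq_pairs(fwd_path, rev_path):
    """Pair forward/reverse FASTQ by read id (trailing /1, /2 stripped)."""
    fwd = read_fastq(fwd_path, "forward")
    rev = read_fastq(rev_path, "reverse")

    def base_id(read):
        return read.read_id.rsplit("/", 1)[0]

    rev_by_id = {base_id(r): r for r in rev}
    pairs = []
    for f in fwd:
        mate = rev_by_id.get(base_id(f))
        if mate is not None:
            pairs.append((f, mate))
    return pairs


def write_fastq(reads, path) -> None:
    with _opener(path)(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_airr(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a rearrangement (or any pipeline) table as TSV with provenance."""
    prov = " ".join(f"{k}={v}" for k, v in (provenance or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_VERSION} {prov}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    """Read a table written by :func:`write_airr`, restoring dtypes."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in df.columns:
        if col in _INT_COLUMNS:
            df[col] = df[col].astype(int)
        elif col in _FLOAT_COLUMNS:
            df[col] = df[col].astype(float)
        elif col in _COORD_COLUMNS:
            df[col] = df[col].map(lambda v: pd.NA if v == "" else int(v))
    return df
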