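"""FASTA/TSV readers and writers used by every stage."""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from Bio import SeqIO

FASTA_WIDTH = 70


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write sequences wrapped at 70 columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_vienna(entries, path: str | os.PathLike) -> None:
    """Write fold results in Vienna text layout: header, sequence, then the
    dot-bracket string with the energy in parentheses."""
    with open(path, "w") as fh:
        for name, fold in entries:
            fh.write(f">{name}\n{fold.sequence}\n{fold.structure} ({fold.mfe:.2f})\n")
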