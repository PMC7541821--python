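"""Readers and writers for the pipeline's tabular dialects.

All tables are plain TSV with a header row.  Readers validate column
presence and value ranges and report the offending line; writers
round-trip byte-identically through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "parse_hits_tsv",
    "write_hits_tsv",
    "read_tsv",
    "write_tsv",
    "read_fasta_dir",
]

HITS_COLUMNS = ["qseqid", "orf_index", "rank", "stitle", "pident",
                "alignment_fraction", "subject_class"]


def parse_hits_tsv(path) -> pd.DataFrame:
    """Parse an ORF hit table (BLAST-tabular-like dialect)."""
    df = pd.read_csv(path, sep="\t", dtype={"qseqid": str, "stitle": str,
                                            "subject_class": str})
    missing = set(HITS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not 0 <= row["pident"] <= 100:
            raise ValueError(f"{path}:{line}: pident {row['pident']} outside [0,100]")
        if not 0 <= row["alignment_fraction"] <= 1:
            raise ValueError(f"{path}:{line}: alignment_fraction outside [0,1]")
        if row["rank"] < 1:
            raise ValueError(f"{path}:{line}: rank must be >= 1")
    return df[HITS_COLUMNS]


def write_hits_tsv(df: pd.DataFrame, path) -> None:
    df[HITS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta_dir(fasta_dir):
    """Read one FASTA per SAG; headers ``>{sag_id}|{contig_id}``.

    Returns a list of (sag_id, [(contig_id, sequence), ...]).
    """
    out = []
    for p in sorted(Path(fasta_dir).glob("*.fasta")):
        contigs = []
        sag_id = p.stem
        for rec in SeqIO.parse(str(p), "fasta"):
            if "|" in rec.id:
                sid, cid = rec.id.split("|", 1)
                sag_id = sid
            else:
                cid = rec.id
            contigs.append((cid, str(rec.seq).upper()))
        out.append((sag_id, contigs))
    return out
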