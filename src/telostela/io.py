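"""Reading and writing of reads and tables (FASTQ/FASTA via Biopython)."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass
class AmpliconRead:
    """One long read of a STELA amplicon."""

    read_id: str
    seq: str
    qual: Optional[list[int]] = None
    truth_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.seq)


def read_reads(path: str | Path) -> list[AmpliconRead]:
    """Load reads from FASTQ or FASTA (format decided by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(AmpliconRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path, default_q: int = 30) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = r.qual or [default_q] * len(r.seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
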