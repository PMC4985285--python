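"""File-format helpers: FASTA/FASTQ via Biopython, YAML configs, TSV tables."""

from __future__ import annotations

from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import PlatformProfile, Read, ReadSet


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_reads(readset: ReadSet, path) -> None:
    """FASTQ when qualities are present, FASTA otherwise."""
    path = Path(path)
    fastq = all(r.quality is not None for r in readset.reads) and readset.reads
    with open(path, "w") as handle:
        for read in readset.reads:
            if fastq:
                handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
            else:
                handle.write(f">{read.read_id}\n{read.sequence}\n")


def read_reads(path) -> ReadSet:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quality = None
        if fmt == "fastq":
            quality = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        reads.append(Read(read_id=rec.id, sequence=str(rec.seq), quality=quality))
    return ReadSet(tuple(reads), PlatformProfile())


def load_yaml(path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)
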