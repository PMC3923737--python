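"""FASTA/FASTQ readers and writers.

Parsing goes through Biopython's iterators; sequences are U-normalized on
read. Collapsed unique tags are written in the conventional
``>tag<i>_x<count>`` FASTA form used by small-RNA tools.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import normalize_rna


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str  # RNA alphabet, may contain N
    quality: str   # Phred+33

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"record {self.id!r}: sequence and quality lengths differ"
            )


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate FASTQ records, normalizing sequences to the RNA alphabet.

    Raises ValueError with the record index on malformed records.
    """
    with open(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record #{i} ({title})")
            yield FastqRead(title.split()[0], normalize_rna(seq), qual)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (id, sequence) pairs, U-normalized."""
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield title.split()[0], normalize_rna(seq)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


_TAG_HEADER = re.compile(r"^(?P<name>\S+?)_x(?P<count>\d+)$")


def write_tag_fasta(path: str | Path, tags) -> None:
    """Write collapsed tags as ``>tag<i>_x<count>`` FASTA."""
    write_fasta(path, ((f"tag{i}_x{t.count}", t.sequence) for i, t in enumerate(tags)))


def read_tag_fasta(path: str | Path):
    """Read a collapsed-tag FASTA back into SmallReadTag objects."""
    from .preprocess import SmallReadTag

    out = []
    for name, seq in read_fasta(path):
        m = _TAG_HEADER.match(name)
        count = int(m.group("count")) if m else 1
        out.append(SmallReadTag(sequence=seq, count=count))
    return out
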