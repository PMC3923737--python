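"""Sequence alphabet helpers.

The internal alphabet is RNA (A, C, G, U). FASTA/FASTQ inputs in the DNA
alphabet are normalized on read; lowercase is upper-cased.
"""
from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_TO_RNA = str.maketrans("Tt", "Uu")
_RC_RNA = str.maketrans("ACGUNacgun", "UGCANugcan")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.translate(_TO_RNA).upper()


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet (input may contain N)."""
    return seq.translate(_RC_RNA)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(c in "GCgc" for c in seq) / len(seq)


def phred_to_ascii(q: int) -> str:
    return chr(q + 33)


def mean_phred(quality_string: str) -> float:
    """Mean Phred score of a Phred+33 encoded quality string."""
    if not quality_string:
        raise ValueError("empty quality string")
    return sum(ord(c) - 33 for c in quality_string) / len(quality_string)
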