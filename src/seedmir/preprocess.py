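"""Raw sRNA read cleaning: quality, N, adapters, length; tag collapsing.

A read survives quality filtering iff its mean Phred score is at least the
threshold (boundary inclusive) and it contains no N. Adapter trimming removes
the longest read-suffix / adapter-prefix overlap of at least ``min_overlap``
nt with at most one mismatch per 10 nt (mirrored for 5' adapters). Reads are
then restricted to the 18-25 nt window and collapsed to unique tags.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import RNA_ALPHABET, mean_phred, normalize_rna
from .io import FastqRead


@dataclass(frozen=True)
class SmallReadTag:
    """A collapsed unique read sequence with its redundancy count."""

    sequence: str
    count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty tag sequence")
        if not set(self.sequence) <= RNA_ALPHABET:
            raise ValueError(f"tag alphabet outside ACGU: {self.sequence!r}")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_singleton(self) -> bool:
        return self.count == 1


def quality_filter(reads: Iterable[FastqRead], min_q: float = 13.0) -> list[FastqRead]:
    """Retain reads with mean Phred >= min_q and no N in the sequence."""
    out = []
    for r in reads:
        if "N" in r.sequence:
            continue
        if mean_phred(r.quality) >= min_q:
            out.append(r)
    return out


def _overlap_trim_len(seq: str, adapter: str, min_overlap: int, mismatch_per_10: int) -> int:
    """Length of the longest suffix(seq)/prefix(adapter) overlap passing the
    mismatch budget, or 0."""
    max_l = min(len(seq), len(adapter))
    for l in range(max_l, min_overlap - 1, -1):
        budget = (l // 10) * mismatch_per_10 if l >= 10 else 0
        mism = 0
        tail = seq[len(seq) - l:]
        ok = True
        for a, b in zip(tail, adapter[:l]):
            if a != b:
                mism += 1
                if mism > budget:
                    ok = False
                    break
        if ok:
            return l
    return 0


def trim_adapters(
    reads: Iterable[FastqRead],
    adapter_3p: str,
    adapter_5p: str = "",
    min_overlap: int = 6,
    mismatch_per_10: int = 1,
) -> list[FastqRead]:
    """Trim 3' (and optionally 5') adapter overlaps; untrimmed reads pass
    through unchanged."""
    a3 = normalize_rna(adapter_3p) if adapter_3p else ""
    a5 = normalize_rna(adapter_5p) if adapter_5p else ""
    out = []
    for r in reads:
        seq, qual = r.sequence, r.quality
        if a3:
            l = _overlap_trim_len(seq, a3, min_overlap, mismatch_per_10)
            if l:
                seq, qual = seq[:-l], qual[:-l]
        if a5 and seq:
            # mirror rule: longest prefix(read)/suffix(adapter) overlap
            l = _overlap_trim_len(seq[::-1], a5[::-1], min_overlap, mismatch_per_10)
            if l:
                seq, qual = seq[l:], qual[l:]
        if seq:
            out.append(FastqRead(r.id, seq, qual))
    return out


def length_filter(items, min_len: int = 18, max_len: int = 25):
    """Retain reads/tags with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [x for x in items
            if min_len <= len(getattr(x, "sequence", x)) <= max_len]


def collapse_tags(reads: Iterable[FastqRead | str]) -> list[SmallReadTag]:
    """Collapse cleaned reads to unique tags; counts conserve read totals.

    Sequences are U-normalized; tags are returned sorted by descending count,
    then sequence, so output is deterministic.
    """
    counts: Counter[str] = Counter()
    for r in reads:
        seq = normalize_rna(r if isinstance(r, str) else r.sequence)
        counts[seq] += 1
    return [SmallReadTag(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


@dataclass
class LengthDistribution:
    """Per-length read and unique-tag totals over a length window."""

    table: pd.DataFrame = field(repr=False)

    @classmethod
    def from_tags(cls, tags: Sequence[SmallReadTag],
                  min_len: int = 18, max_len: int = 25) -> "LengthDistribution":
        rows = []
        total = sum(t.count for t in tags)
        for l in range(min_len, max_len + 1):
            sub = [t for t in tags if t.length == l]
            reads = sum(t.count for t in sub)
            rows.append({
                "length": l,
                "reads": reads,
                "unique_tags": len(sub),
                "percent": round(100.0 * reads / total, 2) if total else 0.0,
            })
        return cls(pd.DataFrame(rows))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
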