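"""Conserved miRNA identification by perfect full-length identity.

A tag is a conserved (known) miRNA iff its sequence is byte-identical, after
U-normalization, to a mature reference sequence — same length, zero
mismatches. Family labels are parsed from miRBase-style identifiers with a
case-insensitive grammar: ``miR``/``MIR`` followed by the leading integer
(letter suffixes collapse, so miR166a and MIR166b both map to family MIR166).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._seq import normalize_rna
from .preprocess import SmallReadTag

_FAMILY_RE = re.compile(r"mir[-_]?0*(\d+)", re.IGNORECASE)


def parse_family(identifier: str) -> str | None:
    """Family label (e.g. ``MIR171``) from a mature reference id, or None."""
    m = _FAMILY_RE.search(identifier)
    return f"MIR{m.group(1)}" if m else None


@dataclass(frozen=True)
class MatureReference:
    id: str
    sequence: str  # RNA alphabet
    family: str | None = None

    @classmethod
    def from_record(cls, name: str, seq: str) -> "MatureReference":
        return cls(id=name, sequence=normalize_rna(seq), family=parse_family(name))


def load_mature_reference(path) -> list[MatureReference]:
    from .io import read_fasta

    return [MatureReference.from_record(n, s) for n, s in read_fasta(path)]


@dataclass(frozen=True)
class MatureMatch:
    tag: SmallReadTag
    reference: MatureReference


def match_mature(
    tags: Sequence[SmallReadTag], reference: Sequence[MatureReference]
) -> list[MatureMatch]:
    """All perfect full-length tag/reference identities (a tag may match
    several references; every hit is reported)."""
    if not reference:
        raise ValueError("empty mature reference")
    by_seq: dict[str, list[MatureReference]] = {}
    for ref in reference:
        by_seq.setdefault(ref.sequence, []).append(ref)
    out = []
    for tag in tags:
        for ref in by_seq.get(tag.sequence, ()):
            out.append(MatureMatch(tag, ref))
    return out


@dataclass(frozen=True)
class FamilySummary:
    family: str
    member_count: int   # distinct matched mature sequences
    total_reads: int


def summarize_families(matches: Iterable[MatureMatch]) -> pd.DataFrame:
    """One row per family: distinct matched sequences and read totals.

    A tag hitting several references of one family is counted once for that
    family, so family read totals never double count.
    """
    per_family: dict[str, dict[str, set | int]] = {}
    for m in matches:
        fam = m.reference.family or "unparsed"
        d = per_family.setdefault(fam, {"members": set(), "reads": {}})
        d["members"].add(m.tag.sequence)
        d["reads"][m.tag.sequence] = m.tag.count
    rows = [
        {
            "family": fam,
            "member_count": len(d["members"]),
            "total_reads": sum(d["reads"].values()),
        }
        for fam, d in sorted(per_family.items())
    ]
    return pd.DataFrame(rows, columns=["family", "member_count", "total_reads"])


def average_members_per_family(summary: pd.DataFrame) -> float:
    """Mean members per family (e.g. 177 members / 41 families ~ 4)."""
    if summary.empty:
        return 0.0
    return float(summary["member_count"].sum() / len(summary))
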