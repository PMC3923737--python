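"""Non-coding / organellar RNA filtering.

Cleaned tags are assigned to a contaminant class when the tag sequence occurs
exactly (zero mismatches) as a substring of any reference of that class, on
either strand. Multi-class hits resolve by a fixed priority order
(rRNA > tRNA > snRNA > snoRNA > cpRNA > mtRNA). Classified tags are removed
before miRNA prediction and a per-length, per-class summary is emitted.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp
from .preprocess import SmallReadTag

CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "cpRNA", "mtRNA")


@dataclass(frozen=True)
class ClassifiedTag:
    tag: SmallReadTag
    ncrna_class: str  # one of CLASS_PRIORITY or "none"


def percent(part: int, whole: int, decimals: int = 2) -> float:
    """part/whole as a percentage, rounded half-up to `decimals`."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    q = Decimal(part) * 100 / Decimal(whole)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def classify_tags(
    tags: Sequence[SmallReadTag],
    references: Mapping[str, Sequence[str]],
    max_mismatch: int = 0,
) -> list[ClassifiedTag]:
    """Assign each tag to the first class (priority order) with an exact
    substring hit on either strand; unmatched tags get class "none".

    `references` maps class name -> iterable of reference sequences (RNA
    alphabet). A nonzero `max_mismatch` enables a Hamming-tolerant scan; the
    default (0) matches the perfect-match convention used throughout.
    """
    if not references:
        raise ValueError("empty reference map")
    classes = [c for c in CLASS_PRIORITY if c in references]
    if not classes:
        raise ValueError(f"no known classes in reference map: {list(references)}")
    # Concatenate each class's references (both strands) with separators so a
    # single substring test covers all of them.
    haystacks = {}
    for c in classes:
        seqs = list(references[c])
        if not seqs:
            raise ValueError(f"class {c!r} has no reference sequences")
        both = seqs + [revcomp(s) for s in seqs]
        haystacks[c] = "#".join(both)

    out = []
    for tag in tags:
        assigned = "none"
        for c in classes:
            if max_mismatch == 0:
                hit = tag.sequence in haystacks[c]
            else:
                hit = any(
                    _hamming_hit(tag.sequence, s, max_mismatch)
                    for s in haystacks[c].split("#")
                )
            if hit:
                assigned = c
                break
        out.append(ClassifiedTag(tag, assigned))
    return out


def _hamming_hit(needle: str, hay: str, budget: int) -> bool:
    n = len(needle)
    for i in range(len(hay) - n + 1):
        mism = 0
        for a, b in zip(needle, hay[i:i + n]):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return True
    return False


def remove_classified(classified: Iterable[ClassifiedTag]) -> list[SmallReadTag]:
    """Retain exactly the tags with class "none"."""
    return [c.tag for c in classified if c.ncrna_class == "none"]


@dataclass
class FilterSummary:
    """Per-length (18-25) x per-class read totals and percentages, plus the
    "all filters" column and grand totals."""

    table: pd.DataFrame

    @classmethod
    def from_classified(
        cls,
        classified: Sequence[ClassifiedTag],
        min_len: int = 18,
        max_len: int = 25,
    ) -> "FilterSummary":
        rows = []
        for l in list(range(min_len, max_len + 1)) + ["Total"]:
            if l == "Total":
                sub = classified
            else:
                sub = [c for c in classified if c.tag.length == l]
            total = sum(c.tag.count for c in sub)
            row = {"length": l, "total_reads": total}
            allf = 0
            for cname in CLASS_PRIORITY:
                n = sum(c.tag.count for c in sub if c.ncrna_class == cname)
                allf += n
                row[cname] = n
                row[f"{cname}_pct"] = percent(n, total) if total else 0.0
            row["all_filters"] = allf
            row["all_filters_pct"] = percent(allf, total) if total else 0.0
            rows.append(row)
        grand = rows[-1]["total_reads"]
        for row in rows:
            row["total_pct"] = percent(row["total_reads"], grand) if grand else 0.0
        return cls(pd.DataFrame(rows))

    @property
    def retained_reads(self) -> int:
        t = self.table[self.table["length"] == "Total"].iloc[0]
        return int(t["total_reads"] - t["all_filters"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
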