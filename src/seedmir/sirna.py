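"""24-nt siRNA locus detection.

siRNA-producing loci show many dispersed read starts along a contig rather
than the one- or two-block pile-up of miRNA processing. A locus is called
when at least ``min_starts`` distinct 5' starts span at least ``min_span`` nt
and no single block (delta-nt start clustering) holds more than
``max_block_fraction`` of the locus reads. Contigs already carrying an
accepted pre-miRNA call are suppressed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .discovery import Anchor, detect_blocks
from .preprocess import SmallReadTag


@dataclass(frozen=True)
class SiRNALocus:
    contig: str
    start: int
    end: int
    distinct_starts: int
    total_reads: int
    largest_block_fraction: float
    strands: str  # "+", "-" or "+-"


def select_24nt(tags: Iterable[SmallReadTag]) -> list[SmallReadTag]:
    """Exactly the tags of length 24."""
    return [t for t in tags if t.length == 24]


def detect_sirna_loci(
    anchors: Sequence[Anchor],
    min_starts: int = 10,
    min_span: int = 100,
    max_block_fraction: float = 0.5,
    delta: int = 3,
    precursor_contigs: Iterable[str] = (),
) -> list[SiRNALocus]:
    """Call dispersed 24-nt loci per contig (strand-agnostic by default)."""
    suppressed = set(precursor_contigs)
    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig, []).append(a)
    loci = []
    for cid, c_anchors in sorted(by_contig.items()):
        if cid in suppressed:
            continue
        starts = {(a.start if a.strand == "+" else a.end) for a in c_anchors}
        if len(starts) < min_starts:
            continue
        lo = min(a.start for a in c_anchors)
        hi = max(a.end for a in c_anchors)
        if hi - lo < min_span:
            continue
        total = sum(a.count for a in c_anchors)
        blocks, _ = detect_blocks(c_anchors, delta=delta)
        biggest = max(b.total_reads for b in blocks)
        frac = biggest / total
        if frac > max_block_fraction:
            continue
        strands = "".join(s for s in "+-" if any(a.strand == s for a in c_anchors))
        loci.append(SiRNALocus(cid, lo, hi, len(starts), total, round(frac, 4), strands))
    return loci


def loci_to_table(loci: Sequence[SiRNALocus]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "contig": l.contig, "start": l.start, "end": l.end,
            "reads": l.total_reads, "starts": l.distinct_starts,
            "block_fraction": l.largest_block_fraction, "strands": l.strands,
        }
        for l in loci
    ])
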