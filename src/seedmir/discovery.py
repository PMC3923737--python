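"""Pre-miRNA discovery by block anchoring plus hairpin MFE/MFEI screening.

The procedure: collapse-cleaned tags are anchored to assembled contigs by
perfect match on either strand; per contig and strand, anchor 5' starts are
clustered into blocks (single linkage, delta nt); a contig strand whose reads
pile into one or two blocks is a candidate; windows around the blocks are
excised, folded, and accepted when the structure is a single stem-loop whose
|MFE| lies in the configured range, |MFEI| exceeds the threshold, at least
``min_reads`` reads anchor, and the dominant block sits in one arm of the
hairpin (at most ``max_loop_overlap`` nt into the terminal loop).

Candidate boundaries are refined with a ladder: the full stem-loop unit
containing the dominant block, then the miRNA/miRNA* duplex span padded by
``flank``, then the bare duplex span. The first boundary satisfying every
criterion is reported. DCL1 cuts at the duplex base, so true pre-miRNA ends
sit near the duplex — the ladder recovers the processed precursor when the
surrounding fold is a longer pri-miRNA stem.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import gc_percent, revcomp
from .folding import FoldingEngine, FoldError, hairpin_loops, pair_table, stemloop_span
from .preprocess import SmallReadTag

MIN_CANDIDATE_LEN = 50  # 2 x shortest mature (21ish) + minimum loop


@dataclass(frozen=True)
class Anchor:
    tag: SmallReadTag
    contig: str
    start: int       # 0-based, + strand coordinates of the contig
    end: int         # exclusive
    strand: str      # "+" or "-"

    @property
    def count(self) -> int:
        return self.tag.count


@dataclass
class Block:
    contig: str
    strand: str
    start: int
    end: int
    anchors: list[Anchor] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(a.count for a in self.anchors)


@dataclass
class PrecursorCall:
    contig: str
    strand: str
    start: int                     # candidate span on the contig, 0-based
    end: int
    sequence: str                  # candidate sequence, 5'->3' of its strand
    structure: str                 # dot-bracket
    mfe: float                     # kcal/mol (<= 0)
    gc_percent: float
    blocks: list[Block]
    total_reads: int
    mature_arm: str | None = None  # "5p" / "3p"
    canonical: SmallReadTag | None = None
    isomirs: list[tuple[SmallReadTag, str]] = field(default_factory=list)
    verdict: bool = False
    reject_reasons: list[str] = field(default_factory=list)
    criteria_flags: dict = field(default_factory=dict)
    known: bool | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def amfe(self) -> float:
        return self.mfe / self.length * 100.0

    @property
    def mfei_value(self) -> float:
        return mfei(self.mfe, self.length, self.gc_percent)


@dataclass
class DiscoveryConfig:
    """Thresholds for the acceptance screen.

    Presets: "strict" (|MFE| 40-100 kcal/mol, |MFEI| > 0.85) mirrors the
    published results criteria; "loose" (|MFE| 17-110, |MFEI| > 0.5) mirrors
    the methods wording.
    """

    mfe_min: float = 40.0
    mfe_max: float = 100.0
    mfei_min: float = 0.85
    min_reads: int = 10
    delta: int = 3
    block_containment: float = 0.90
    max_loop_overlap: int = 4
    flank: int = 20
    max_window: int = 300

    @classmethod
    def preset(cls, name: str) -> "DiscoveryConfig":
        if name == "strict":
            return cls()
        if name == "loose":
            return cls(mfe_min=17.0, mfe_max=110.0, mfei_min=0.5)
        raise ValueError(f"unknown preset {name!r}")


def mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimum folding free energy index: (MFE/length*100) / GC%."""
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_pct == 0:
        raise ZeroDivisionError("MFEI undefined at 0% GC")
    return (mfe / length * 100.0) / gc_pct


def anchor_tags(
    tags: Sequence[SmallReadTag], contigs: Mapping[str, str]
) -> list[Anchor]:
    """Every exact occurrence of every tag on either strand of the contigs.

    Coordinates are 0-based half-open on the + strand of the contig.
    """
    if not contigs:
        return []
    by_seq: dict[str, SmallReadTag] = {}
    for t in tags:
        by_seq[t.sequence] = t
    lengths = sorted({t.length for t in tags})
    out: list[Anchor] = []
    for cid, seq in contigs.items():
        n = len(seq)
        rc = revcomp(seq)
        for L in lengths:
            for i in range(n - L + 1):
                sub = seq[i:i + L]
                t = by_seq.get(sub)
                if t is not None:
                    out.append(Anchor(t, cid, i, i + L, "+"))
                sub = rc[i:i + L]
                t = by_seq.get(sub)
                if t is not None:
                    out.append(Anchor(t, cid, n - i - L, n - i, "-"))
    return out


def detect_blocks(
    anchors: Sequence[Anchor], delta: int = 3, containment: float = 0.90
) -> tuple[list[Block], dict[str, bool]]:
    """Single-linkage clustering of anchor 5' starts (within ``delta`` nt),
    per strand, for anchors sharing one contig.

    Returns the blocks and a per-strand pattern verdict: valid iff the top one
    or two blocks jointly contain at least ``containment`` of that strand's
    anchored reads. The 5' start of a - strand anchor is its ``end``
    coordinate.
    """
    if not anchors:
        return [], {}
    contigs = {a.contig for a in anchors}
    if len(contigs) > 1:
        raise ValueError("detect_blocks expects anchors from a single contig")
    blocks: list[Block] = []
    verdicts: dict[str, bool] = {}
    for strand in "+-":
        sa = [a for a in anchors if a.strand == strand]
        if not sa:
            continue
        key = (lambda a: a.start) if strand == "+" else (lambda a: a.end)
        sa.sort(key=lambda a: (key(a), a.start))
        groups: list[list[Anchor]] = [[sa[0]]]
        for a in sa[1:]:
            if key(a) - key(groups[-1][-1]) <= delta:
                groups[-1].append(a)
            else:
                groups.append([a])
        strand_blocks = [
            Block(a[0].contig, strand,
                  min(x.start for x in a), max(x.end for x in a), a)
            for a in groups
        ]
        blocks.extend(strand_blocks)
        total = sum(b.total_reads for b in strand_blocks)
        top2 = sorted((b.total_reads for b in strand_blocks), reverse=True)[:2]
        verdicts[strand] = total > 0 and sum(top2) >= containment * total
    return blocks, verdicts


def extract_windows(
    blocks: Sequence[Block],
    contig_len: int,
    max_len: int = 300,
    flank: int = 20,
) -> list[tuple[int, int]]:
    """Candidate windows (0-based half-open, clipped to the contig).

    Two-block case: the joint span padded by ``flank``. One-block case: two
    windows, each anchored at the block and extended up to ``max_len``
    leftwards and rightwards in turn (the hairpin may lie on either side).
    Windows shorter than the minimum foldable candidate are dropped.
    """
    if not blocks:
        return []
    out: list[tuple[int, int]] = []
    if len(blocks) >= 2:
        lo = min(b.start for b in blocks)
        hi = max(b.end for b in blocks)
        out.append((lo - flank, hi + flank))
    else:
        b = blocks[0]
        out.append((b.end + flank - max_len, b.end + flank))
        out.append((b.start - flank, b.start - flank + max_len))
    clipped = []
    for (s, e) in out:
        s, e = max(0, s), min(contig_len, e)
        if e - s >= MIN_CANDIDATE_LEN:
            clipped.append((s, e))
    return clipped


def _window_sequence(contig_seq: str, start: int, end: int, strand: str) -> str:
    w = contig_seq[start:end]
    return w if strand == "+" else revcomp(w)


def _to_window_coords(a: Anchor, wstart: int, wend: int, strand: str) -> tuple[int, int]:
    """Anchor span in window coordinates, 5'->3' of the window's strand."""
    if strand == "+":
        return a.start - wstart, a.end - wstart
    return wend - a.end, wend - a.start


def _check_candidate(
    seq: str,
    engine: FoldingEngine,
    cfg: DiscoveryConfig,
    block_span: tuple[int, int],
) -> dict:
    """Fold one candidate boundary and evaluate every criterion flag."""
    res: dict = {"sequence": seq}
    try:
        db, mfe = engine.fold(seq)
    except FoldError:
        res.update(flags={"fold_ok": False}, reasons=["fold_error"], ok=False)
        return res
    loops = hairpin_loops(db)
    gc = gc_percent(seq)
    flags = {
        "fold_ok": True,
        "single_hairpin": len(loops) == 1,
        "mfe_range": cfg.mfe_min <= abs(mfe) <= cfg.mfe_max,
        "mfei": abs(mfei(mfe, len(seq), gc)) > cfg.mfei_min if gc else False,
    }
    arm = None
    if len(loops) == 1:
        l1, l2 = loops[0]          # closing pair of the terminal loop
        loop_lo, loop_hi = l1 + 1, l2  # unpaired loop region, half-open
        b_lo, b_hi = block_span
        overlap = max(0, min(b_hi, loop_hi) - max(b_lo, loop_lo))
        in_5p = b_hi <= loop_hi
        in_3p = b_lo >= loop_lo
        flags["arm_overlap"] = overlap <= cfg.max_loop_overlap and (in_5p or in_3p)
        if flags["arm_overlap"]:
            arm = "5p" if in_5p else "3p"
    else:
        flags["arm_overlap"] = False
    res.update(
        structure=db, mfe=mfe, gc=gc, flags=flags, arm=arm,
        reasons=[k for k, v in flags.items() if not v],
        ok=all(flags.values()),
    )
    return res


def evaluate_candidate(
    window_seq: str,
    window_anchors: Sequence[tuple[int, int, int]],
    engine: FoldingEngine,
    cfg: DiscoveryConfig,
) -> dict:
    """Evaluate one excised window.

    ``window_anchors`` are (start, end, count) triples in window coordinates
    (5'->3' of the window strand). Returns a dict with the chosen candidate
    span (relative to the window), fold results, per-criterion flags, verdict
    and reject reasons.
    """
    total_reads = sum(c for (_, _, c) in window_anchors)
    min_reads_ok = total_reads >= cfg.min_reads
    base = {"total_reads": total_reads}
    if not window_anchors:
        return {**base, "ok": False, "reasons": ["min_reads"], "flags": {}}

    # dominant block span in window coordinates (anchors of the top block)
    top = max(window_anchors, key=lambda t: t[2])
    b_lo = min(s for (s, e, c) in window_anchors
               if abs(s - top[0]) <= cfg.delta)
    b_hi = max(e for (s, e, c) in window_anchors
               if abs(s - top[0]) <= cfg.delta)

    try:
        db0, _ = engine.fold(window_seq)
    except FoldError:
        return {**base, "ok": False, "reasons": ["fold_error"],
                "flags": {"fold_ok": False, "min_reads": min_reads_ok}}
    unit = stemloop_span(db0, b_lo, b_hi)
    if unit is None:
        return {**base, "ok": False, "reasons": ["unpaired_block"],
                "flags": {"fold_ok": True, "min_reads": min_reads_ok}}
    ua, ub = unit

    # duplex span: block positions plus their pairing partners in the window fold
    pt = pair_table(db0)
    pos = list(range(max(ua, b_lo), min(ub + 1, b_hi)))
    partners = [pt[k] for k in pos if pt[k] >= 0]
    if partners:
        d_lo = min(min(pos), min(partners))
        d_hi = max(max(pos), max(partners)) + 1
    else:
        d_lo, d_hi = b_lo, b_hi

    ladder = [
        (ua, ub + 1),
        (max(ua, d_lo - cfg.flank), min(ub + 1, d_hi + cfg.flank)),
        (d_lo, d_hi),
    ]
    best = None
    for (s, e) in ladder:
        if e - s < MIN_CANDIDATE_LEN:
            continue
        r = _check_candidate(window_seq[s:e], engine, cfg, (b_lo - s, b_hi - s))
        r["span"] = (s, e)
        if best is None:
            best = r
        if r["ok"]:
            best = r
            break
    if best is None:
        return {**base, "ok": False, "reasons": ["too_short"],
                "flags": {"fold_ok": True, "min_reads": min_reads_ok}}
    best["flags"]["min_reads"] = min_reads_ok
    if not min_reads_ok:
        best["reasons"] = best.get("reasons", []) + ["min_reads"]
    best["ok"] = best["ok"] and min_reads_ok
    return {**base, **best}


def assign_canonical(call: PrecursorCall, anchors: Sequence[Anchor]) -> PrecursorCall:
    """Designate the most frequent anchored tag as the miRNA (canonical) and
    the rest as isomiRs; ties break to the lexicographically smallest
    sequence. Arm labels come from position relative to the terminal loop."""
    inside = [a for a in anchors
              if a.contig == call.contig and a.strand == call.strand
              and a.start >= call.start and a.end <= call.end]
    if not inside:
        return call
    loops = hairpin_loops(call.structure)
    loop_mid = (loops[0][0] + loops[0][1]) // 2 if loops else call.length // 2

    def arm_of(a: Anchor) -> str:
        if call.strand == "+":
            lo = a.start - call.start
        else:
            lo = call.end - a.end
        return "5p" if lo + (a.end - a.start) / 2 <= loop_mid else "3p"

    ranked = sorted(inside, key=lambda a: (-a.count, a.tag.sequence))
    call.canonical = ranked[0].tag
    call.mature_arm = arm_of(ranked[0])
    seen = {ranked[0].tag.sequence}
    call.isomirs = []
    for a in ranked[1:]:
        if a.tag.sequence not in seen:
            seen.add(a.tag.sequence)
            call.isomirs.append((a.tag, arm_of(a)))
    return call


def classify_known_vs_novel(call: PrecursorCall, mature_sequences: set[str]) -> PrecursorCall:
    """Known iff the canonical tag perfectly matches a mature reference."""
    if call.canonical is not None:
        call.known = call.canonical.sequence in mature_sequences
    return call


def discover_precursors(
    tags: Sequence[SmallReadTag],
    contigs: Mapping[str, str],
    engine: FoldingEngine,
    cfg: DiscoveryConfig | None = None,
    mature_sequences: set[str] | None = None,
) -> tuple[list[PrecursorCall], list[PrecursorCall]]:
    """Run the full discovery procedure.

    Returns (accepted, rejected) PrecursorCall lists. Overlapping accepted
    candidates on one contig strand are deduplicated to the best-supported
    call (more anchored reads, then lower MFE).
    """
    cfg = cfg or DiscoveryConfig()
    anchors = anchor_tags(tags, contigs)
    by_contig: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig, []).append(a)

    accepted: list[PrecursorCall] = []
    rejected: list[PrecursorCall] = []
    for cid, c_anchors in sorted(by_contig.items()):
        cseq = contigs[cid]
        blocks, _ = detect_blocks(c_anchors, cfg.delta, cfg.block_containment)
        for strand in "+-":
            sblocks = sorted(
                (b for b in blocks if b.strand == strand),
                key=lambda b: -b.total_reads,
            )
            if not sblocks:
                continue
            top = [b for b in sblocks[:2] if b.total_reads >= 3] or sblocks[:1]
            windows = extract_windows(top, len(cseq), cfg.max_window, cfg.flank)
            if len(top) == 2:
                # the dominant block alone is a fallback candidate: the second
                # block may be unrelated background on a multi-locus contig
                windows += extract_windows(top[:1], len(cseq),
                                           cfg.max_window, cfg.flank)
            seen_windows = set()
            for (ws, we) in windows:
                if (ws, we) in seen_windows:
                    continue
                seen_windows.add((ws, we))
                # block pattern is judged on the excised locus: one or two
                # blocks must jointly hold the containment share of the
                # window's reads on this strand
                w_strand_anchors = [a for a in c_anchors
                                    if a.strand == strand
                                    and a.start >= ws and a.end <= we]
                if not _window_pattern_ok(w_strand_anchors, cfg.delta,
                                          cfg.block_containment, strand):
                    continue
                wseq = _window_sequence(cseq, ws, we, strand)
                w_anchors = []
                for a in c_anchors:
                    if a.strand == strand and a.start >= ws and a.end <= we:
                        lo, hi = _to_window_coords(a, ws, we, strand)
                        w_anchors.append((lo, hi, a.count))
                res = evaluate_candidate(wseq, w_anchors, engine, cfg)
                span = res.get("span")
                if span is None:
                    continue
                s, e = span
                if strand == "+":
                    c_start, c_end = ws + s, ws + e
                else:
                    c_start, c_end = we - e, we - s
                call = PrecursorCall(
                    contig=cid, strand=strand, start=c_start, end=c_end,
                    sequence=res.get("sequence", wseq[s:e]),
                    structure=res.get("structure", ""),
                    mfe=res.get("mfe", 0.0),
                    gc_percent=res.get("gc", gc_percent(wseq[s:e])),
                    blocks=top, total_reads=res["total_reads"],
                    mature_arm=res.get("arm"),
                    verdict=res["ok"], reject_reasons=res.get("reasons", []),
                    criteria_flags=res.get("flags", {}),
                )
                if call.verdict:
                    call = assign_canonical(call, c_anchors)
                    if mature_sequences is not None:
                        call = classify_known_vs_novel(call, mature_sequences)
                    accepted.append(call)
                else:
                    rejected.append(call)

    return _dedup_calls(accepted), rejected


def _window_pattern_ok(anchors: Sequence[Anchor], delta: int,
                       containment: float, strand: str) -> bool:
    """One or two 5'-start blocks must jointly hold ``containment`` of the
    window's reads (the miRNA processing signature; dispersed siRNA-like or
    degradation pile-ups fail)."""
    if not anchors:
        return False
    starts = sorted((a.start if strand == "+" else a.end, a.count)
                    for a in anchors)
    totals = [starts[0][1]]
    prev = starts[0][0]
    for s, c in starts[1:]:
        if s - prev <= delta:
            totals[-1] += c
        else:
            totals.append(c)
        prev = s
    top2 = sorted(totals, reverse=True)[:2]
    return sum(top2) >= containment * sum(totals)


def _dedup_calls(calls: list[PrecursorCall]) -> list[PrecursorCall]:
    """Collapse overlapping calls on a contig to the best-supported one.

    Strand is deliberately ignored: a hairpin whose arms happen to be exactly
    palindromic anchors its mature tag on both strands and yields the same
    locus in both orientations; the orientation with more anchored reads wins.
    """
    calls = sorted(calls, key=lambda c: (-c.total_reads, c.mfe, c.contig, c.start))
    kept: list[PrecursorCall] = []
    for c in calls:
        if any(k.contig == c.contig and c.start < k.end and k.start < c.end
               for k in kept):
            continue
        kept.append(c)
    return sorted(kept, key=lambda c: (c.contig, c.start))


def calls_to_table(accepted: Sequence[PrecursorCall],
                   rejected: Sequence[PrecursorCall] = ()):
    """PrecursorCall table with all criterion flags, as a DataFrame."""
    import pandas as pd

    rows = []
    for c in list(accepted) + list(rejected):
        rows.append({
            "contig": c.contig, "strand": c.strand,
            "start": c.start, "end": c.end, "length": c.length,
            "mfe": c.mfe, "amfe": round(c.amfe, 2) if c.length else None,
            "mfei": round(c.mfei_value, 3) if c.gc_percent else None,
            "gc_percent": round(c.gc_percent, 2),
            "total_reads": c.total_reads,
            "mature_arm": c.mature_arm,
            "canonical": c.canonical.sequence if c.canonical else None,
            "canonical_count": c.canonical.count if c.canonical else None,
            "n_isomirs": len(c.isomirs),
            "known": c.known,
            "verdict": "accepted" if c.verdict else "rejected",
            "reject_reasons": ";".join(c.reject_reasons),
            **{f"flag_{k}": v for k, v in c.criteria_flags.items()},
        })
    return pd.DataFrame(rows)
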