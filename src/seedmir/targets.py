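"""miRNA target scanning with an additive expectation (penalty) score.

Every window of each transcript is compared with the reverse complement of
the mature miRNA. Per-position penalties: Watson-Crick pair 0, G:U wobble
0.5, mismatch 1, gap 2 (single-nucleotide bulges only); penalties are doubled
at miRNA positions 2-13 (numbered from the miRNA 5' end — the seed-proximal
core). A hit is reported when the summed expectation is at most the cutoff
(4.0 for canonical miRNAs; 5.0 is the conventional isomiR relaxation).
Overlapping hits collapse to the minimum-expectation window. A central
mismatch (miRNA positions 9-11) switches the inhibition hint from cleavage to
translation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import normalize_rna, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# raw per-position penalties, before seed doubling
_PAIR_PENALTY = np.ones((4, 4))
for a, b in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_PENALTY[_CODE[a], _CODE[b]] = 0.0
for a, b in (("G", "U"), ("U", "G")):
    _PAIR_PENALTY[_CODE[a], _CODE[b]] = 0.5
GAP_PENALTY = 2.0
SEED_SPAN = (2, 13)  # miRNA positions with doubled penalties, inclusive


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int            # transcript coordinates, 0-based half-open
    end: int
    strand: str           # relative to transcript orientation
    expectation: float    # sum of seed-weighted penalties
    penalties: tuple[float, ...]   # raw penalty per miRNA position, 5'->3'
    alignment: tuple[str, str, str]  # miRNA 3'->5', match line, target 5'->3'
    inhibition: str       # "cleavage" | "translation"


_LUT = np.full(256, -1, dtype=np.int8)
for base, code in _CODE.items():
    _LUT[ord(base)] = code


def _codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _seed_multiplier(m: int) -> np.ndarray:
    mult = np.ones(m)
    lo, hi = SEED_SPAN
    mult[lo - 1:hi] = 2.0
    return mult


def _match_line(raw: np.ndarray) -> str:
    """Match line over the site 5'->3' (| pair, o G:U wobble, space otherwise),
    from the raw per-miRNA-position penalties."""
    chars = []
    for p in raw[::-1]:  # reverse: miRNA shown 3'->5' over the site
        chars.append("|" if p == 0 else ("o" if p == 0.5 else " "))
    return "".join(chars)


def scan_targets(
    mature: str,
    transcripts: Mapping[str, str],
    max_expectation: float = 4.0,
    mirna_id: str = "miRNA",
    both_strands: bool = True,
    allow_bulges: bool = True,
) -> list[TargetHit]:
    """All target sites of one mature miRNA with expectation <= cutoff."""
    mature = normalize_rna(mature)
    if not 18 <= len(mature) <= 25:
        raise ValueError(f"mature length {len(mature)} outside 18-25 nt")
    mi = _codes(mature)
    if (mi < 0).any():
        raise ValueError("mature sequence outside ACGU")
    m = len(mature)
    mult = _seed_multiplier(m)
    hits: list[TargetHit] = []
    for tid, tseq in transcripts.items():
        tseq = normalize_rna(tseq)
        strands = [("+", tseq)]
        if both_strands:
            strands.append(("-", revcomp(tseq)))
        for strand, seq in strands:
            t = _codes(seq)
            n = len(seq)
            if n >= m:
                win = np.lib.stride_tricks.sliding_window_view(t, m)
                raw = np.empty_like(win, dtype=float)
                for p in range(m):
                    # miRNA position p+1 faces site index m-1-p
                    raw[:, p] = _PAIR_PENALTY[mi[p], win[:, m - 1 - p]]
                exp = raw @ mult
                for idx in np.nonzero(exp <= max_expectation)[0]:
                    s = int(idx)
                    hits.append(_make_hit(mirna_id, tid, s, s + m, strand, n,
                                          mature, seq[s:s + m], raw[idx],
                                          float(exp[idx])))
            if allow_bulges and n >= m - 1:
                hits.extend(
                    _scan_bulged(mi, t, mult, mature, seq, mirna_id, tid,
                                 strand, n, max_expectation))
    return dedup_hits(hits)


def _scan_bulged(mi, t, mult, mature, seq, mirna_id, tid, strand, n, cutoff):
    """Single-nucleotide bulges: one unopposed nt in the target (window m+1)
    or one unopposed miRNA base (window m-1)."""
    m = len(mi)
    lo, hi = SEED_SPAN
    out = []
    # target bulge: the site has m+1 nt; site index j pairs with nothing
    if n >= m + 1:
        win = np.lib.stride_tricks.sliding_window_view(t, m + 1)
        for j in range(1, m):  # interior bulge positions only
            sub = np.concatenate([win[:, :j], win[:, j + 1:]], axis=1)
            raw = np.empty_like(sub, dtype=float)
            for p in range(m):
                raw[:, p] = _PAIR_PENALTY[mi[p], sub[:, m - 1 - p]]
            gp = m - j  # gap sits after miRNA position m-j
            gap_term = GAP_PENALTY * (2.0 if lo <= gp <= hi else 1.0)
            exp = raw @ mult + gap_term
            for idx in np.nonzero(exp <= cutoff)[0]:
                s = int(idx)
                out.append(_make_hit(mirna_id, tid, s, s + m + 1, strand, n,
                                     mature, seq[s:s + m + 1], raw[idx],
                                     float(exp[idx])))
    # miRNA bulge: the site has m-1 nt; miRNA position p0+1 is unopposed
    if n >= m - 1:
        win = np.lib.stride_tricks.sliding_window_view(t, m - 1)
        for p0 in range(1, m - 1):
            keep = [p for p in range(m) if p != p0]
            raw = np.zeros((win.shape[0], m))
            for col, p in enumerate(keep):
                raw[:, p] = _PAIR_PENALTY[mi[p], win[:, m - 2 - col]]
            gap_term = GAP_PENALTY * (2.0 if lo <= p0 + 1 <= hi else 1.0)
            weighted = raw @ mult - raw[:, p0] * mult[p0]  # p0 has no pairing
            raw[:, p0] = GAP_PENALTY
            exp = weighted + gap_term
            for idx in np.nonzero(exp <= cutoff)[0]:
                s = int(idx)
                out.append(_make_hit(mirna_id, tid, s, s + m - 1, strand, n,
                                     mature, seq[s:s + m - 1], raw[idx],
                                     float(exp[idx])))
            raw[:, p0] = 0.0
    return out


def _make_hit(mirna_id, tid, s, e, strand, n, mature, site, raw, expectation):
    if strand == "-":
        s, e = n - e, n - s
    central = raw[8:11]  # miRNA positions 9-11, raw penalties
    inh = "translation" if np.any(central >= 1.0) else "cleavage"
    return TargetHit(
        mirna_id=mirna_id, transcript_id=tid, start=int(s), end=int(e),
        strand=strand, expectation=round(float(expectation), 3),
        penalties=tuple(float(p) for p in raw),
        alignment=(mature[::-1], _match_line(raw), site),
        inhibition=inh,
    )


def dedup_hits(hits: Sequence[TargetHit]) -> list[TargetHit]:
    """Collapse overlapping hits (same miRNA/transcript/strand) to the
    minimum-expectation window."""
    kept: list[TargetHit] = []
    for h in sorted(hits, key=lambda h: (h.expectation, h.start, h.end - h.start)):
        clash = any(
            k.mirna_id == h.mirna_id and k.transcript_id == h.transcript_id
            and k.strand == h.strand and h.start < k.end and k.start < h.end
            for k in kept
        )
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.mirna_id, h.transcript_id, h.start))


def targets_per_mirna_summary(hits: Sequence[TargetHit]) -> pd.DataFrame:
    """Per-miRNA target counts; the overall mean targets/miRNA is stored in
    ``df.attrs["mean_targets_per_mirna"]`` (printed to one decimal)."""
    if not hits:
        return pd.DataFrame(columns=["mirna", "n_targets"])
    per: dict[str, set[str]] = {}
    for h in hits:
        per.setdefault(h.mirna_id, set()).add(h.transcript_id)
    df = pd.DataFrame(
        [{"mirna": k, "n_targets": len(v)} for k, v in sorted(per.items())]
    )
    df.attrs["mean_targets_per_mirna"] = round(float(df["n_targets"].mean()), 1)
    return df


def hits_to_table(hits: Sequence[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "mirna": h.mirna_id, "transcript": h.transcript_id,
            "start": h.start, "end": h.end, "strand": h.strand,
            "expectation": h.expectation, "inhibition": h.inhibition,
            "alignment_mirna_3to5": h.alignment[0],
            "match_line": h.alignment[1],
            "alignment_target_5to3": h.alignment[2],
        }
        for h in hits
    ])
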