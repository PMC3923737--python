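"""Synthetic sequencing fixtures with a machine-readable truth ledger.

The generator emulates a seed small-RNA study: hairpin pre-miRNAs embedded in
assembled mRNA contigs, mature reads piling in one or two blocks with isomiR
end-heterogeneity, ncRNA contaminants at class-specific rates, dispersed
24-nt siRNA loci, a fixed appended 3' adapter, and three developmental-stage
mRNA libraries with known per-feature fold changes. Every emitted read is
labelled in the truth ledger, so each downstream stage can be scored against
ground truth without any external download.

Defaults mirror a mature-seed sRNA study: precursor lengths 70-250 nt with the
miRNA/miRNA* duplex placed loop-proximally (DCL1 cuts at the duplex base),
GC 38-48%, ncRNA class rates equal to the observed library composition
(rRNA 6.94%, tRNA 0.60%, snRNA 0.02%, snoRNA 0.005%, cpRNA 1.90%,
mtRNA 0.25%), and a 24-nt-rich length mix contributed by siRNA loci.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import normalize_rna, phred_to_ascii, revcomp
from .io import FastqRead, write_fasta, write_fastq

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "cpRNA", "mtRNA")
# conserved plant miRNA family numbers used for synthetic "known" annotations
_PLANT_FAMILIES = (156, 157, 159, 160, 162, 164, 166, 167, 168, 169, 171,
                   172, 319, 390, 393, 394, 396, 397, 398, 403, 408, 472, 845)
ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter (DNA)

# includes stage-exclusive patterns (a transcript detected in one stage only)
_FOLD_PATTERNS = ((1, 1, 8), (8, 1, 1), (1, 8, 1), (1, 4, 4), (4, 4, 1),
                  (1, 0, 0), (0, 0, 1))


@dataclass
class SynthConfig:
    """Knobs of the synthetic study. All randomness flows from ``seed``."""

    seed: int = 0
    n_precursors: int = 57  # a realistic first-catalog size (41 known + 16 novel)
    precursor_len_range: tuple[int, int] = (70, 250)
    gc_range: tuple[float, float] = (0.38, 0.48)
    mature_len_range: tuple[int, int] = (20, 24)
    isomir_offset_sd: float = 0.5
    reads_per_precursor_range: tuple[int, int] = (5, 500)
    ncrna_class_rates: dict = field(default_factory=lambda: {
        "rRNA": 0.0694, "tRNA": 0.0060, "snRNA": 0.0002,
        "snoRNA": 0.00005, "cpRNA": 0.0190, "mtRNA": 0.0025,
    })
    degradation_rate: float = 0.10
    n_stages: int = 3
    stage_fold_changes: dict = field(default_factory=dict)  # filled at build
    read_quality_mean: int = 30
    # generator extensions
    min_loop: int = 8
    arm_mismatch_rate: float = 0.10
    loop_offset_range: tuple[int, int] = (2, 22)  # duplex distance from loop
    known_fraction: float = 0.72  # 41 of the 57 default precursors annotated
    both_arms_fraction: float = 0.7
    minus_strand_fraction: float = 0.3
    low_quality_rate: float = 0.02
    n_base_rate: float = 0.005
    adapter_3p: str = ADAPTER_3P
    n_sirna_loci: int = 5
    sirna_reads_range: tuple[int, int] = (60, 400)
    n_targets: int = 15
    n_decoy_mature: int = 30
    mrna_read_len: int = 70
    mrna_base_abundance: float = 60.0
    mrna_depth_factors: tuple[float, ...] = (1.0, 0.85, 0.7)
    differential_fraction: float = 0.3

    def validate(self) -> None:
        for name in ("precursor_len_range", "mature_len_range",
                     "reads_per_precursor_range", "sirna_reads_range",
                     "loop_offset_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} not ordered: {(lo, hi)}")
        fracs = {
            "degradation_rate": self.degradation_rate,
            "known_fraction": self.known_fraction,
            "both_arms_fraction": self.both_arms_fraction,
            "low_quality_rate": self.low_quality_rate,
            "n_base_rate": self.n_base_rate,
            **{f"rate[{k}]": v for k, v in self.ncrna_class_rates.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if sum(self.ncrna_class_rates.values()) + self.degradation_rate > 1.0:
            raise ValueError("contaminant rates sum above 1")
        if self.n_stages != 3:
            raise ValueError("the study design has exactly three stages")
        lo, hi = self.gc_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"gc_range invalid: {self.gc_range}")


@dataclass
class PrecursorTruth:
    id: str
    contig: str
    strand: str
    start: int                  # precursor span on the contig (+ coords)
    end: int
    sequence: str               # precursor 5'->3'
    mature_5p: tuple[int, int]  # spans in precursor coordinates
    mature_3p: tuple[int, int]
    loop: tuple[int, int]
    dominant_arm: str
    canonical: str              # most frequent emitted mature tag (realized)
    known: bool
    family: str | None
    reference_mature: str | None = None  # the sequence planted in the mature
                                         # reference, when the precursor is
                                         # annotated as known
    n_reads: int = 0
    n_clean_reads: int = 0

    def mature_contig_spans(self) -> list[tuple[int, int]]:
        """Mature spans mapped to contig + strand coordinates."""
        out = []
        n = self.end - self.start
        for (lo, hi) in (self.mature_5p, self.mature_3p):
            if self.strand == "+":
                out.append((self.start + lo, self.start + hi))
            else:
                out.append((self.end - hi, self.end - lo))
        return out


@dataclass
class SynthTruth:
    precursors: list[PrecursorTruth]
    read_labels: list[tuple[str, str, bool]]  # (read id, label, clean)
    abundance: pd.DataFrame                   # expected counts, features x stages
    sites: pd.DataFrame                       # planted target sites
    sirna_loci: pd.DataFrame
    class_counts: dict

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        pd.DataFrame([{
            "id": p.id, "contig": p.contig, "strand": p.strand,
            "start": p.start, "end": p.end,
            "mature_5p_start": p.mature_5p[0], "mature_5p_end": p.mature_5p[1],
            "mature_3p_start": p.mature_3p[0], "mature_3p_end": p.mature_3p[1],
            "dominant_arm": p.dominant_arm, "canonical": p.canonical,
            "known": p.known, "family": p.family,
            "reference_mature": p.reference_mature,
            "n_reads": p.n_reads, "n_clean_reads": p.n_clean_reads,
        } for p in self.precursors]).to_csv(outdir / "truth_precursors.tsv",
                                            sep="\t", index=False)
        pd.DataFrame(self.read_labels, columns=["read_id", "label", "clean"]) \
            .to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.abundance.to_csv(outdir / "truth_abundance.tsv", sep="\t")
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.sirna_loci.to_csv(outdir / "truth_sirna.tsv", sep="\t", index=False)


# -- primitive generators -----------------------------------------------------

_BASES = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _exact_gc_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random sequence with exactly round(gc*n) G/C positions (keeps the
    hairpin's overall GC within the promised tolerance of the request)."""
    n_gc = int(round(gc * n))
    bases = np.concatenate([
        rng.choice(np.array(list("GC")), size=n_gc),
        rng.choice(np.array(list("AU")), size=n - n_gc),
    ])
    rng.shuffle(bases)
    return "".join(bases)


def generate_hairpin(
    rng: np.random.Generator,
    length: int,
    gc: float,
    mature_len: int,
    min_loop: int = 8,
    mismatch_rate: float = 0.10,
    loop_offset_range: tuple[int, int] = (2, 22),
) -> tuple[str, tuple[int, int], tuple[int, int], tuple[int, int]]:
    """One hairpin precursor: 5' arm, terminal loop, 3' arm (reverse
    complement of the 5' arm apart from the injected mismatch rate).

    The mature/star duplex sits loop-proximally: the mature 3' end lies
    ``d`` nt from the loop, d drawn from ``loop_offset_range``. Returns the
    sequence and the mature_5p, mature_3p and loop spans (0-based half-open).
    """
    if length < 2 * mature_len + min_loop:
        raise ValueError(
            f"length {length} too short for mature_len {mature_len} "
            f"with a {min_loop} nt loop")
    arm = (length - min_loop) // 2
    loop = length - 2 * arm
    arm5 = _exact_gc_seq(rng, arm, gc)
    a3 = list(revcomp(arm5))
    for i in range(len(a3)):
        if rng.random() < mismatch_rate:
            a3[i] = str(rng.choice([b for b in "ACGU" if b != a3[i]]))
    seq = arm5 + _exact_gc_seq(rng, loop, gc) + "".join(a3)

    d_lo, d_hi = loop_offset_range
    d_max = max(d_lo, min(d_hi, arm - mature_len))
    d = int(rng.integers(d_lo, d_max + 1)) if d_max > d_lo else d_lo
    m5_end = arm - d
    m5_start = m5_end - mature_len
    if m5_start < 0:
        m5_start, m5_end = 0, mature_len
    # mirrored star span on the 3' arm
    m3_start = length - m5_end
    m3_end = m3_start + mature_len
    if m3_end > length:
        m3_start, m3_end = length - mature_len, length
    return seq, (m5_start, m5_end), (m3_start, m3_end), (arm, arm + loop)


# -- world --------------------------------------------------------------------

@dataclass
class SynthWorld:
    """The genome-side ground truth shared by the sRNA and mRNA generators."""

    config: SynthConfig
    contigs: dict                     # contig id -> sequence (RNA alphabet)
    precursors: list[PrecursorTruth]
    mature_reference: list[tuple[str, str]]   # (miRBase-style id, sequence)
    ncrna_refs: dict                  # class -> list[(id, sequence)]
    sirna_loci: pd.DataFrame          # contig, start, end, n_reads
    sites: pd.DataFrame               # planted target sites
    feature_seqs: dict                # expression features -> sequence
    abundance: pd.DataFrame           # expected counts, features x L1..L3


def build_world(config: SynthConfig) -> SynthWorld:
    config.validate()
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    precursors: list[PrecursorTruth] = []
    mature_ref: list[tuple[str, str]] = []

    fam_cycle = list(_PLANT_FAMILIES)
    rng.shuffle(fam_cycle)
    letters = "abcdefghij"
    for i in range(config.n_precursors):
        length = int(rng.integers(config.precursor_len_range[0],
                                  config.precursor_len_range[1] + 1))
        gc = float(rng.uniform(*config.gc_range))
        mlen = int(rng.integers(config.mature_len_range[0],
                                config.mature_len_range[1] + 1))
        seq, m5, m3, loop = generate_hairpin(
            rng, length, gc, mlen, config.min_loop, config.arm_mismatch_rate,
            config.loop_offset_range)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        left = _random_seq(rng, int(rng.integers(150, 400)), gc)
        right = _random_seq(rng, int(rng.integers(150, 400)), gc)
        host = seq if strand == "+" else revcomp(seq)
        cid = f"contig{i:03d}"
        contigs[cid] = left + host + right
        dominant = "5p" if rng.random() < 0.5 else "3p"
        canonical = seq[slice(*m5)] if dominant == "5p" else seq[slice(*m3)]
        known = bool(rng.random() < config.known_fraction)
        family = None
        if known:
            fam = fam_cycle[i % len(fam_cycle)]
            family = f"MIR{fam}"
            ref_id = f"jcu-miR{fam}{letters[i % len(letters)]}-{dominant}"
            mature_ref.append((ref_id, canonical))
        precursors.append(PrecursorTruth(
            id=f"pre{i:03d}", contig=cid, strand=strand,
            start=len(left), end=len(left) + length, sequence=seq,
            mature_5p=m5, mature_3p=m3, loop=loop,
            dominant_arm=dominant, canonical=canonical,
            known=known, family=family,
            reference_mature=canonical if known else None))

    # decoy mature references (families without reads in the library)
    for j in range(config.n_decoy_mature):
        fam = fam_cycle[(j + 7) % len(fam_cycle)]
        mature_ref.append((
            f"ath-miR{fam}{letters[j % len(letters)]}-decoy",
            _random_seq(rng, int(rng.integers(20, 25)), 0.45)))

    # ncRNA class references
    ref_lens = {"rRNA": 1500, "tRNA": 80, "snRNA": 150,
                "snoRNA": 120, "cpRNA": 600, "mtRNA": 600}
    ncrna_refs = {
        c: [(f"{c}_ref{k}", _random_seq(rng, ref_lens[c], 0.5)) for k in range(3)]
        for c in NCRNA_CLASSES
    }

    # dispersed 24-nt siRNA loci on dedicated contigs
    sirna_rows = []
    for k in range(config.n_sirna_loci):
        clen = int(rng.integers(400, 600))
        cid = f"sirna_contig{k:02d}"
        contigs[cid] = _random_seq(rng, clen, 0.45)
        span = int(rng.integers(250, 350))
        start = int(rng.integers(0, clen - span))
        n_reads = int(rng.integers(config.sirna_reads_range[0],
                                   config.sirna_reads_range[1] + 1))
        sirna_rows.append({"contig": cid, "start": start,
                           "end": start + span, "n_reads": n_reads})
    sirna_loci = pd.DataFrame(sirna_rows)

    # target transcripts with planted complementarity sites
    site_rows = []
    known_prec = [p for p in precursors if p.known] or precursors
    for k in range(config.n_targets):
        tlen = int(rng.integers(400, 700))
        tid = f"target{k:02d}"
        tseq = list(_random_seq(rng, tlen, 0.45))
        p = known_prec[int(rng.integers(len(known_prec)))]
        site = list(revcomp(p.canonical))
        m = len(site)
        n_mut = int(rng.choice([0, 0, 0, 1, 2]))
        expectation = 0.0
        for _ in range(n_mut):
            mir_pos = int(rng.integers(3, m + 1))   # miRNA position, 1-based
            k_site = m - mir_pos                    # facing site index
            mir_base = p.canonical[mir_pos - 1]
            bad = [b for b in "ACGU"
                   if (mir_base, b) not in (("A", "U"), ("U", "A"),
                                            ("G", "C"), ("C", "G"),
                                            ("G", "U"), ("U", "G"))]
            site[k_site] = str(rng.choice(bad))
            expectation += 2.0 if 2 <= mir_pos <= 13 else 1.0
        pos = int(rng.integers(30, tlen - m - 30))
        tseq[pos:pos + m] = site
        contigs[tid] = "".join(tseq)
        site_rows.append({"mirna": p.id, "mature": p.canonical,
                          "transcript": tid, "start": pos, "end": pos + m,
                          "planted_expectation": expectation})
    sites = pd.DataFrame(site_rows)

    # stage abundances (expression features = precursors + targets)
    feature_seqs = {p.id: p.sequence for p in precursors}
    feature_seqs.update({t: contigs[t] for t in sites["transcript"].unique()})
    stages = [f"L{s+1}" for s in range(config.n_stages)]
    fold_map = dict(config.stage_fold_changes)
    rows = []
    for fid in feature_seqs:
        base = float(rng.lognormal(math.log(config.mrna_base_abundance), 0.6))
        if fid not in fold_map:
            if rng.random() < config.differential_fraction:
                fold_map[fid] = _FOLD_PATTERNS[int(rng.integers(len(_FOLD_PATTERNS)))]
            else:
                fold_map[fid] = (1, 1, 1)
        folds = fold_map[fid]
        rows.append({"feature": fid, **{
            stages[s]: base * folds[s] * config.mrna_depth_factors[s]
            for s in range(config.n_stages)}})
    abundance = pd.DataFrame(rows).set_index("feature")
    config.stage_fold_changes = fold_map

    return SynthWorld(config=config, contigs=contigs, precursors=precursors,
                      mature_reference=mature_ref, ncrna_refs=ncrna_refs,
                      sirna_loci=sirna_loci, sites=sites,
                      feature_seqs=feature_seqs, abundance=abundance)


# -- sRNA library -------------------------------------------------------------

def _draw_isomir_span(rng, m_lo, m_hi, bound, sd) -> tuple[int, int]:
    """Mature span with rounded-Gaussian end offsets, truncated so the read
    stays inside the precursor and within the 18-25 nt window."""
    for _ in range(12):
        o5 = int(np.rint(rng.normal(0.0, sd)))
        o3 = int(np.rint(rng.normal(0.0, sd)))
        s, e = m_lo + o5, m_hi + o3
        if 0 <= s < e <= bound and 18 <= e - s <= 25:
            return s, e
    return m_lo, m_hi


def generate_srna_library(
    world: SynthWorld, rng: np.random.Generator | None = None
) -> tuple[list[FastqRead], SynthTruth]:
    """The mature-seed sRNA library plus its truth ledger.

    Reads come from (a) mature/isomiR positions on the planted precursors,
    (b) dispersed 24-nt siRNA loci, (c) ncRNA references at class rates and
    (d) degradation fragments drawn per contig proportionally to transcript
    abundance. A fixed 3' adapter is appended; a configured fraction of reads
    is emitted low-quality or with an N for the cleaning stage to remove.
    """
    cfg = world.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    raw: list[tuple[str, str]] = []  # (sequence, label)

    lo, hi = cfg.reads_per_precursor_range
    for p in world.precursors:
        n = int(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        p.n_reads = n
        other = "3p" if p.dominant_arm == "5p" else "5p"
        if rng.random() < cfg.both_arms_fraction:
            dom_frac = rng.uniform(0.65, 0.9)
        else:
            dom_frac = 1.0
        L = len(p.sequence)
        for _ in range(n):
            arm = p.dominant_arm if rng.random() < dom_frac else other
            m_lo, m_hi = p.mature_5p if arm == "5p" else p.mature_3p
            s, e = _draw_isomir_span(rng, m_lo, m_hi, L, cfg.isomir_offset_sd)
            raw.append((p.sequence[s:e], f"mirna:{p.id}"))

    for row in world.sirna_loci.itertuples():
        contig = world.contigs[row.contig]
        for _ in range(row.n_reads):
            s = int(rng.integers(row.start, row.end - 24))
            frag = contig[s:s + 24]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            raw.append((frag, f"sirna:{row.contig}"))

    # contaminants: multinomial split over ncRNA classes + degradation
    n_signal = len(raw)
    rates = dict(cfg.ncrna_class_rates)
    rates["degradation"] = cfg.degradation_rate
    r_tot = sum(rates.values())
    n_extra = int(round(n_signal * r_tot / (1.0 - r_tot))) if r_tot else 0
    names = list(rates)
    if n_extra:
        counts = rng.multinomial(n_extra, np.array([rates[c] for c in names]) / r_tot)
    else:
        counts = [0] * len(names)

    # degradation pressure per contig follows transcript abundance
    deg_ids = list(world.contigs)
    mean_ab = world.abundance.mean(axis=1)
    prec_by_contig = {p.contig: p.id for p in world.precursors}
    weights = []
    for cid in deg_ids:
        if cid in prec_by_contig:
            weights.append(0.05 * float(mean_ab.get(prec_by_contig[cid], 1.0)))
        elif cid in mean_ab.index:
            weights.append(float(mean_ab[cid]))
        else:
            weights.append(0.05 * float(mean_ab.median()))
    wsum = sum(weights)
    deg_p = np.array(weights) / wsum

    for cname, n_c in zip(names, counts):
        for _ in range(int(n_c)):
            flen = int(rng.integers(18, 26))
            if cname == "degradation":
                cid = deg_ids[int(rng.choice(len(deg_ids), p=deg_p))]
                src = world.contigs[cid]
            else:
                rid, src = world.ncrna_refs[cname][int(rng.integers(3))]
            s = int(rng.integers(0, len(src) - flen))
            frag = src[s:s + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            raw.append((frag, cname))

    # assemble FASTQ: shuffle, append adapter, inject quality defects
    order = rng.permutation(len(raw))
    adapter = normalize_rna(cfg.adapter_3p)
    reads: list[FastqRead] = []
    labels: list[tuple[str, str, bool]] = []
    q_ok = phred_to_ascii(cfg.read_quality_mean)
    q_low = phred_to_ascii(8)
    clean_counts: dict[str, int] = {}
    tag_counts: dict[str, dict[str, int]] = {}
    for k, idx in enumerate(order):
        seq, label = raw[idx]
        rid = f"read{k:07d}"
        full = seq + adapter
        clean = True
        if rng.random() < cfg.low_quality_rate:
            qual = q_low * len(full)
            clean = False
        else:
            qual = q_ok * len(full)
        if clean and rng.random() < cfg.n_base_rate:
            pos = int(rng.integers(len(seq)))
            full = full[:pos] + "N" + full[pos + 1:]
            clean = False
        reads.append(FastqRead(rid, full, qual))
        labels.append((rid, label, clean))
        if clean and label.startswith("mirna:"):
            pid = label[6:]
            clean_counts[pid] = clean_counts.get(pid, 0) + 1
            tc = tag_counts.setdefault(pid, {})
            tc[seq] = tc.get(seq, 0) + 1
    for p in world.precursors:
        p.n_clean_reads = clean_counts.get(p.id, 0)
        tc = tag_counts.get(p.id)
        if tc:
            # the designation rule realized on the emitted library: the most
            # frequent clean tag is the canonical miRNA (ties lexicographic)
            p.canonical = min(tc, key=lambda s: (-tc[s], s))
            pos = p.sequence.find(p.canonical)
            if pos >= 0:
                mid = pos + len(p.canonical) / 2
                p.dominant_arm = "5p" if mid <= (p.loop[0] + p.loop[1]) / 2 else "3p"
            p.known = p.canonical in {s for _, s in world.mature_reference}

    class_counts: dict[str, int] = {}
    for _, label, _ in labels:
        key = label.split(":")[0]
        class_counts[key] = class_counts.get(key, 0) + 1

    truth = SynthTruth(
        precursors=world.precursors, read_labels=labels,
        abundance=world.abundance, sites=world.sites,
        sirna_loci=world.sirna_loci, class_counts=class_counts)
    return reads, truth


# -- mRNA libraries -----------------------------------------------------------

def generate_mrna_libraries(
    world: SynthWorld, rng: np.random.Generator | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Three stage libraries; per-feature read counts ~ Poisson(expected).

    Returns stage -> list of (read id, sequence); reads are uniform windows
    fully inside their source feature so feature counting recovers them.
    """
    cfg = world.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    out: dict[str, list[tuple[str, str]]] = {}
    for stage in world.abundance.columns:
        lib: list[tuple[str, str]] = []
        for fid, expected in world.abundance[stage].items():
            n = int(rng.poisson(expected))
            seq = world.feature_seqs[fid]
            rl = min(cfg.mrna_read_len, len(seq))
            for _ in range(n):
                s = int(rng.integers(0, len(seq) - rl + 1))
                lib.append((fid, seq[s:s + rl]))
        order = rng.permutation(len(lib))
        # read ids carry the source feature so fixtures are self-documenting
        out[stage] = [(f"{stage}_read{k:06d}|{lib[i][0]}", lib[i][1])
                      for k, i in enumerate(order)]
    return out


# -- orchestration ------------------------------------------------------------

def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def simulate(config: SynthConfig, outdir: str | Path) -> SynthTruth:
    """Generate the full fixture set under ``outdir`` and return the truth.

    Writes: srna_reads.fastq, contigs.fasta, mature_ref.fasta,
    ncrna_<class>.fasta, mrna_L<k>.fasta and the truth_*.tsv ledger.
    Identical configs (and seeds) give byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = build_world(config)
    reads, truth = generate_srna_library(world)
    write_fastq(outdir / "srna_reads.fastq",
                [FastqRead(r.id, to_dna(r.sequence), r.quality) for r in reads])
    write_fasta(outdir / "contigs.fasta",
                ((cid, to_dna(seq)) for cid, seq in world.contigs.items()))
    write_fasta(outdir / "mature_ref.fasta", world.mature_reference)
    for cname, refs in world.ncrna_refs.items():
        write_fasta(outdir / f"ncrna_{cname}.fasta",
                    ((rid, to_dna(s)) for rid, s in refs))
    mrna = generate_mrna_libraries(world)
    for stage, lib in mrna.items():
        write_fasta(outdir / f"mrna_{stage}.fasta",
                    ((rid, to_dna(s)) for rid, s in lib))
    truth.write(outdir)
    return truth


# -- scoring helpers -----------------------------------------------------------

def evaluate_discovery(
    accepted: Sequence, truth_precursors: Sequence[PrecursorTruth],
    min_reads: int = 10,
) -> dict:
    """Precision/recall of accepted precursor calls against planted truth.

    A planted precursor is recovered when an accepted call on its contig and
    strand overlaps one of its mature spans. Recall is over planted
    precursors with at least ``min_reads`` clean reads; precision counts a
    call as true when it overlaps any planted precursor (regardless of read
    support).
    """
    def call_matches(call, p: PrecursorTruth) -> bool:
        # orientation-agnostic: a palindromic hairpin cannot be oriented from
        # anchored reads alone, so either strand recovers the locus
        if call.contig != p.contig:
            return False
        return any(call.start < hi and lo < call.end
                   for (lo, hi) in p.mature_contig_spans())

    eligible = [p for p in truth_precursors if p.n_clean_reads >= min_reads]
    recovered = [p for p in eligible if any(call_matches(c, p) for c in accepted)]
    tp_calls = [c for c in accepted
                if any(call_matches(c, p) for p in truth_precursors)]
    return {
        "n_true": len(eligible),
        "n_called": len(accepted),
        "n_recovered": len(recovered),
        "recall": len(recovered) / len(eligible) if eligible else float("nan"),
        "precision": len(tp_calls) / len(accepted) if accepted else float("nan"),
    }
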