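"""End-to-end orchestration: clean -> filter -> conserved -> discover ->
quantify -> targets -> siRNA, with every intermediate written and a run
manifest recording configuration, versions and per-stage read conservation.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .conserved import (average_members_per_family, load_mature_reference,
                        match_mature, summarize_families)
from .discovery import (DiscoveryConfig, anchor_tags, calls_to_table,
                        discover_precursors)
from .expression import CountMatrix, call_differential, count_reads
from .folding import default_engine
from .io import read_fasta, read_fastq, write_fasta, write_tag_fasta
from .ncrna import FilterSummary, classify_tags, remove_classified
from .preprocess import (LengthDistribution, collapse_tags, length_filter,
                         quality_filter, trim_adapters)
from .sirna import detect_sirna_loci, loci_to_table, select_24nt
from .targets import hits_to_table, scan_targets, targets_per_mirna_summary

log = logging.getLogger("seedmir")


@dataclass
class PipelineConfig:
    srna_reads: str
    contigs: str
    mature_reference: str
    ncrna_references: dict        # class -> FASTA path
    mrna_libraries: dict = field(default_factory=dict)  # stage -> FASTA path
    outdir: str = "seedmir_out"
    seed: int = 0
    # preprocessing
    min_quality: float = 13.0
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_5p: str = ""
    min_len: int = 18
    max_len: int = 25
    # discovery
    preset: str = "strict"
    min_reads: int = 10
    # expression
    alpha: float = 0.001
    # targets
    max_expectation: float = 4.0
    isomir_max_expectation: float = 5.0
    # siRNA
    sirna_min_starts: int = 10
    sirna_min_span: int = 100
    sirna_max_block_fraction: float = 0.5

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len ({self.min_len}) > max_len ({self.max_len})")
        for a in (self.alpha,):
            if not 0 < a < 1:
                raise ValueError(f"alpha outside (0,1): {a}")
        if self.preset not in ("strict", "loose"):
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
        "conservation": {},
    }

    # 1. preprocess
    raw = list(read_fastq(cfg.srna_reads))
    n_raw = len(raw)
    cleaned = quality_filter(raw, cfg.min_quality)
    trimmed = trim_adapters(cleaned, cfg.adapter_3p, cfg.adapter_5p)
    sized = length_filter(trimmed, cfg.min_len, cfg.max_len)
    tags = collapse_tags(sized)
    n_sized = len(sized)
    assert sum(t.count for t in tags) == n_sized, "collapse lost reads"
    manifest["stages"]["preprocess"] = {
        "raw_reads": n_raw, "quality_pass": len(cleaned),
        "length_pass": n_sized, "unique_tags": len(tags),
        "singletons": sum(1 for t in tags if t.is_singleton),
    }
    manifest["conservation"]["collapse"] = True
    write_tag_fasta(out / "clean_tags.fasta", tags)
    LengthDistribution.from_tags(tags, cfg.min_len, cfg.max_len) \
        .to_tsv(out / "length_distribution.tsv")
    log.info("preprocess: %d raw -> %d clean reads, %d tags",
             n_raw, n_sized, len(tags))

    # 2. ncRNA filter
    refs = {c: [s for _, s in read_fasta(p)]
            for c, p in cfg.ncrna_references.items()}
    classified = classify_tags(tags, refs)
    summary = FilterSummary.from_classified(classified, cfg.min_len, cfg.max_len)
    summary.to_tsv(out / "ncrna_summary.tsv")
    retained = remove_classified(classified)
    removed_reads = sum(c.tag.count for c in classified if c.ncrna_class != "none")
    retained_reads = sum(t.count for t in retained)
    manifest["stages"]["ncrna_filter"] = {
        "removed_reads": removed_reads, "retained_reads": retained_reads,
    }
    manifest["conservation"]["ncrna_filter"] = (
        removed_reads + retained_reads == n_sized)
    write_tag_fasta(out / "filtered_tags.fasta", retained)
    log.info("ncRNA filter: removed %d reads, retained %d",
             removed_reads, retained_reads)

    # 3. conserved matching
    mature = load_mature_reference(cfg.mature_reference)
    matches = match_mature(retained, mature)
    fam = summarize_families(matches)
    fam.to_csv(out / "family_summary.tsv", sep="\t", index=False)
    manifest["stages"]["conserved"] = {
        "matched_tags": len({m.tag.sequence for m in matches}),
        "families": len(fam),
        "avg_members_per_family": round(average_members_per_family(fam), 2),
    }

    # 4. precursor discovery
    contigs = dict(read_fasta(cfg.contigs))
    engine = default_engine()
    mature_seqs = {m.sequence for m in mature}
    accepted, rejected = discover_precursors(
        retained, contigs, engine,
        DiscoveryConfig.preset(cfg.preset), mature_seqs)
    table = calls_to_table(accepted, rejected)
    table.to_csv(out / "precursor_calls.tsv", sep="\t", index=False)
    write_fasta(out / "precursors.fasta",
                ((f"{c.contig}:{c.start}-{c.end}({c.strand})", c.sequence)
                 for c in accepted))
    with open(out / "precursors.dotbracket", "w") as fh:
        for c in accepted:
            fh.write(f">{c.contig}:{c.start}-{c.end}({c.strand}) "
                     f"MFE={c.mfe:.2f}\n{c.sequence}\n{c.structure}\n")
    anchors = anchor_tags(retained, contigs)
    pd.DataFrame([{"contig": a.contig, "start": a.start, "end": a.end,
                   "strand": a.strand, "count": a.count} for a in anchors]) \
        .to_csv(out / "anchors.tsv", sep="\t", index=False)
    manifest["stages"]["discovery"] = {
        "accepted": len(accepted), "rejected": len(rejected),
        "known": sum(1 for c in accepted if c.known),
        "novel": sum(1 for c in accepted if c.known is False),
    }
    log.info("discovery: %d accepted (%d known), %d rejected",
             len(accepted), manifest["stages"]["discovery"]["known"],
             len(rejected))

    # 5. expression
    if cfg.mrna_libraries and accepted:
        features = {f"{c.contig}:{c.start}-{c.end}({c.strand})": c.sequence
                    for c in accepted}
        cols, sizes = {}, {}
        for stage, path in sorted(cfg.mrna_libraries.items()):
            lib = [s for _, s in read_fasta(path)]
            cols[stage] = count_reads(lib, features, max_mismatch=0)
            sizes[stage] = len(lib)
        matrix = CountMatrix(pd.DataFrame(cols),
                             lib_sizes=pd.Series(sizes, dtype=float))
        matrix.normalize_factors()
        matrix.to_tsv(out / "precursor_counts.tsv")
        calls = call_differential(matrix, alpha=cfg.alpha)
        calls.to_csv(out / "differential_calls.tsv", sep="\t", index=False)
        n_diff = (int(calls.groupby("feature")["differentially_represented"]
                      .any().sum()) if not calls.empty else 0)
        manifest["stages"]["expression"] = {
            "features": len(features),
            "tmm": {k: round(v, 4) for k, v in matrix.tmm.items()},
            "differentially_represented": n_diff,
        }

    # 6. target prediction (canonical miRNAs of accepted precursors)
    transcripts = {cid: seq for cid, seq in contigs.items()}
    all_hits = []
    for c in accepted:
        if c.canonical is None:
            continue
        mid = f"{c.contig}:{c.start}-{c.end}({c.strand})"
        all_hits.extend(scan_targets(c.canonical.sequence, transcripts,
                                     cfg.max_expectation, mirna_id=mid))
    hits_to_table(all_hits).to_csv(out / "target_hits.tsv", sep="\t", index=False)
    tsum = targets_per_mirna_summary(all_hits)
    tsum.to_csv(out / "targets_per_mirna.tsv", sep="\t", index=False)
    manifest["stages"]["targets"] = {
        "hits": len(all_hits),
        "mean_targets_per_mirna": tsum.attrs.get("mean_targets_per_mirna", 0.0),
    }

    # 7. siRNA loci
    tags24 = select_24nt(retained)
    anchors24 = [a for a in anchors if a.tag.length == 24]
    loci = detect_sirna_loci(
        anchors24, cfg.sirna_min_starts, cfg.sirna_min_span,
        cfg.sirna_max_block_fraction,
        precursor_contigs={c.contig for c in accepted})
    loci_to_table(loci).to_csv(out / "sirna_loci.tsv", sep="\t", index=False)
    manifest["stages"]["sirna"] = {
        "tags_24nt": len(tags24), "loci": len(loci),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
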