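# Methods

This note documents the models and procedures implemented in `seedmir`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Read cleaning and tag collapsing

Reads are retained when their **mean** Phred score is at least 13 (boundary
inclusive) and the sequence contains no `N`. The quality rule is applied to
the read mean rather than per base because the filter is a library-level
triage step; both the threshold and the statistic are configurable. 3'
adapters are trimmed by the longest read-suffix/adapter-prefix overlap of at
least 6 nt allowing one mismatch per 10 nt (mirrored for 5' adapters) —
common small-RNA practice; when a full-length adapter is present the insert
is recovered exactly. Cleaned reads are restricted to 18–25 nt (inclusive)
and collapsed to unique tags; the internal alphabet is RNA (`T`→`U` on read).
Collapse conserves read totals; every filter is idempotent.

## ncRNA filtering

A tag is assigned to rRNA, tRNA, snRNA, snoRNA, cpRNA or mtRNA when it occurs
*exactly* (zero mismatches, either strand) as a substring of a class
reference. Exact containment stands in for a short-read aligner run at zero
mismatches: it is reproducible and matches the perfect-match convention used
by every other stage. Multi-class hits resolve by a fixed priority (rRNA >
tRNA > snRNA > snoRNA > cpRNA > mtRNA — the order of the class columns in
the standard filtering report); classification is order-independent and a
configurable mismatch budget exists but defaults to 0. All six classes are
removed before miRNA prediction. Percentages in the filtering report are
rounded half-up to two decimals.

## Precursor discovery

The discovery procedure operationalizes the miRNA processing signature:

1. **Anchoring** — every exact occurrence of every tag on either strand of
   the assembled contigs (0-based half-open coordinates on the + strand).
2. **Blocks** — per contig and strand, anchor 5' starts are clustered by
   single linkage with δ = 3 nt. Dicer processing yields one or two sharp
   blocks; degradation and siRNA loci yield many.
3. **Windows** — two-block candidates take the joint block span ± 20 nt;
   one-block candidates take the block extended to 300 nt leftwards and
   rightwards in turn (the hairpin may lie on either side). When a strand has
   two blocks, the dominant block alone is also tried, in case the second
   block is unrelated background on a multi-locus contig.
4. **Pattern gate** — the one or two top blocks must jointly hold ≥ 90% of
   the window's anchored reads on that strand. The containment share is
   judged on the excised window, not the whole contig: a host contig is a
   full transcript, and distal fragments elsewhere on it say nothing about
   the locus. Judged contig-wide, any background read on a long contig would
   veto an otherwise perfect locus.
5. **Folding and boundary refinement** — the window is folded and the
   stem-loop unit containing the dominant block is located by descending the
   structure tree (through multibranch junctions, to the single hairpin unit
   overlapping the block). Candidate boundaries are then tried in a ladder:
   the full unit; the miRNA/miRNA* duplex span (block positions plus their
   pairing partners) padded by the 20-nt flank; the bare duplex span. The
   first boundary satisfying all criteria is reported. DCL1 cuts at the
   duplex base, so the processed precursor's ends sit near the duplex; the
   ladder recovers it when the genomic fold is a longer pri-miRNA stem.
6. **Acceptance criteria** — single hairpin (exactly one terminal loop);
   |MFE| within 40–100 kcal/mol and |MFEI| > 0.85 under the default
   ("strict") preset, or 17–110 and 0.5 under the "loose" preset; ≥ 10
   anchored reads; the dominant block inside one arm, overlapping the
   terminal loop by ≤ 4 nt. All flags are recorded per candidate, and
   re-checking an accepted call (re-fold, re-count) reproduces them.
7. **Canonical and isomiRs** — the most frequent anchored tag within the
   accepted span is the canonical miRNA (ties break to the lexicographically
   smallest sequence, for determinism); all other tags are isomiRs with arm
   labels from their position relative to the terminal loop. A canonical tag
   perfectly matching the mature reference makes the precursor *known*,
   otherwise *novel*.
8. **Deduplication** — overlapping accepted calls on one contig collapse to
   the best-supported one (more reads, then lower MFE), *ignoring strand*: a
   hairpin with exactly palindromic arms anchors its mature tag on both
   strands and produces the same locus in both orientations; the orientation
   cannot be decided from anchored reads.

Note that the strict MFE window has a structural consequence: at ~43% GC and
MFEI ≈ 0.9–1.6, hairpins shorter than roughly 90 nt fall below the 40
kcal/mol floor and are rejected regardless of read support. This is a
property of the criteria, not of the implementation, and it accounts for
essentially all recall loss on the synthetic fixtures.

### Folding engines

Folding is pluggable behind `fold(seq) -> (dot_bracket, mfe)`. The default
engine is ViennaRNA's MFE fold (python bindings): deterministic, fast, and
thermodynamically credible. A self-contained `SimpleStackEngine` ships as the
fallback: a dynamic program over stacking energies with hairpin/bulge/
interior-loop penalties and no multibranch loops, exactly enumerable on toy
sequences — the test suite validates it against exhaustive enumeration. No
engine is expected to reproduce any other folding program's absolute
energies; the acceptance criteria only use energy ranges, and the package
makes no bit-exactness promise across engines.

## Expression statistics

Feature counting increments a feature when a read aligns within it with at
most the configured number of substitutions (0 for precursors, 2 for target
transcripts; no indels), on either strand; multi-feature reads increment each
hit once. The two-mismatch path uses pigeonhole seeding (one of three read
chunks must match exactly) with full Hamming verification.

**TMM normalization** follows the trimmed mean of M-values construction:
log-ratios M and average log-abundances A over features nonzero in both
libraries, 30%/5% symmetric trimming by rank, inverse-delta-method weights,
factor = 2^(weighted mean of kept M), all factors rescaled to geometric mean
1. The reference library is the one whose upper-quartile count fraction is
closest to the across-library mean. The implementation was checked against
an independent straight-line transcription of the formulas (1e-10) and,
during development, against the reference R implementation (agreement to
six decimals).

**Audic–Claverie test**: the posterior of the second count given the first
is negative binomial, p(y'|x) = (n2/n1)^y' (x+y')!/(x! y'! (1+n2/n1)^(x+y'+1));
the two-sided p-value sums p(y'|x) over outcomes no more probable than the
observed one (computed in log space, far tail added analytically, capped at 1).

**NB exact test**: counts are scaled to the geometric mean of the effective
(TMM-adjusted) library sizes and rounded half-even; conditional on the pair
total s, the split under equal negative-binomial means with common dispersion
φ is negative hypergeometric, depending only on r = 1/φ, and φ = 0 reduces
exactly to the symmetric binomial split test. Two-sided p-values use the same
"no more probable than observed" rule. This is a deliberately simplified,
fully specified equivalent of the quantile-adjusted conditional machinery in
the standard R package: the analysis gate is a fixed dual-test α, which does
not require that package's exact p-values.

**Dispersion** is estimated per feature by the method of moments on
size-normalized counts, φ̂ = max(0, (s² − m̄)/m̄²), then shrunk toward the
across-feature median with a prior weight of 10 pseudo-features against the
feature's own n−1 degrees of freedom. Two caveats are documented rather than
hidden: (i) with one library per condition, a true fold change inflates the
feature's own moment estimate — dispersion and differential representation
are confounded in unreplicated designs, and the shrinkage only partially
protects against it; consequently moderate fold changes on three single
libraries often fail the NB gate while presence/absence patterns pass, which
matches how such dual-test screens behave in practice. (ii) the estimator
recovers a true φ only given enough degrees of freedom per feature; the
recovery simulation uses six libraries (mean estimate ≈ 0.26 at φ = 0.3),
while at three libraries the median-shrunk estimate is structurally biased
to ≈ 0.2 — a 2-degree-of-freedom limitation, not an implementation defect.

**Differential representation** requires p ≤ 0.001 in *both* tests, per
library pair (L1/L2, L2/L3, L1/L3). No multiple-testing correction is applied
to the gate; Benjamini–Hochberg q-values are reported per test for
information only. Under a 1000-feature null the dual gate flags well below
0.5% of features (both tests are discrete and conservative), and a planted
8-fold change at mean count 100 with equal sizes is flagged in ≥ 90% of
replicates.

## Target expectation scoring

Each transcript window (both orientations) is compared with the reverse
complement of the mature miRNA. Raw per-position penalties: Watson–Crick 0,
G:U wobble 0.5, mismatch 1, gap 2 (single-nucleotide bulges only, in either
strand); penalties are doubled at miRNA positions 2–13. A hit is kept when
the summed expectation is at most the cutoff (4.0 canonical, 5.0 the isomiR
relaxation); overlapping hits collapse to the minimum-expectation window. A
raw mismatch at miRNA positions 9–11 switches the inhibition hint from
cleavage to translation. The penalty constants follow the published defaults
of the expectation-scoring approach and are configurable; hit-for-hit
agreement with any web service version is not promised, and no target-site
accessibility (UPE) term is computed.

## siRNA loci

24-nt tags are anchored with the same machinery; a locus is called when at
least 10 distinct 5' starts span at least 100 nt and no δ=3 start block holds
more than 50% of the locus reads, on contigs without an accepted precursor
call. The literature describes this read-distribution signature qualitatively;
the three thresholds are this package's operationalization and are exposed in
the configuration.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Hairpins**: 70–250 nt, GC 38–48%, 8-nt minimum loop, 3' arm the reverse
  complement of the 5' arm with 10% injected mismatches. The miRNA/miRNA*
  duplex sits 2–21 nt from the terminal loop — the canonical loop-proximal
  geometry of DCL1 processing. (A duplex placed uniformly along a 250-nt
  near-perfect stem would imply |MFE| ≈ 150 kcal/mol windows that the strict
  criteria can never accept; loop-proximal placement reflects both biology
  and the energy scale of real precursors.) Default catalog: 57 precursors,
  72% carrying a mature sequence present in the reference — a realistic
  known/novel split for a first catalog in a non-model oilseed.
- **Reads**: per precursor, a log-uniform count in 5–500; 70% of precursors
  express both arms (dominant-arm share 0.65–0.9). IsomiR 5'/3' end offsets
  are independent rounded Gaussians (σ = 0.5 nt), truncated so reads stay
  inside the precursor and within 18–25 nt (the size-selected window); at
  σ = 0.5 the canonical form carries roughly half the reads, as typically
  observed. A fixed 3' adapter is appended to every read; 2% of reads are
  emitted low-quality (Q8) and 0.5% carry an `N`, for the cleaning stage to
  remove.
- **Contaminants**: ncRNA class rates default to the composition such
  size-selected seed libraries show (rRNA 6.94%, tRNA 0.60%, snRNA 0.02%,
  snoRNA 0.005%, cpRNA 1.90%, mtRNA 0.25%); degradation fragments (10%) are drawn per
  contig proportionally to transcript abundance — pri-miRNA hosts are lowly
  expressed, targets higher — because degradation arises from expressed
  transcripts, not uniformly from the assembly.
- **siRNA loci**: five dedicated contigs with 60–400 reads of 24 nt spread
  over 250–350 nt on both strands, giving the 24-nt-dominated length mix.
- **mRNA stages**: three libraries with per-feature counts Poisson around
  base × fold × depth (depth factors 1.0/0.85/0.7); 30% of features carry a
  fold pattern, including 8-fold shifts and stage-exclusive (present in one
  stage only) patterns, mirroring the kinds of changes such studies report.
- **Targets**: 15 transcripts with planted complementarity sites, most
  perfect, some carrying 1–2 engineered mismatches whose intended expectation
  is recorded arithmetically in the truth ledger.

Identical seeds give byte-identical FASTQ/FASTA/TSV output.

**What the fixtures do not show**: no per-cycle sequencing error model, no
adapter dimer/read-through artifacts beyond the fixed appended adapter, no
real secondary-structure families (arms are mutated reverse complements, not
miRBase hairpins), no genome-scale repeat structure, and the isomiR offset
law is a stand-in (no empirical distribution exists to fit). Passing the
recovery tests therefore demonstrates that the pipeline implements its own
criteria faithfully and recovers the geometry it assumes — not that it would
reproduce any particular study's catalog from raw reads.

## Problem sizes used in tests and the acceptance script

The default fixture is one 57-precursor study (~10–20k sRNA reads, ~15k mRNA
reads per stage); calibration simulations use 1000 null features (type-I),
200 planted 8-fold features (power), 500 features × 6 libraries (dispersion
recovery), a 50-case oracle grid for the exact tests, and 20-feature toy
matrices for TMM. These sizes give stable metrics at desk scale; all are
parameters, not constants.
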