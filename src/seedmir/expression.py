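"""Stage-wise feature counting and dual-test differential representation.

Counting: a read increments a feature when it aligns within the feature with
at most ``max_mismatch`` substitutions (no indels), on either strand.

Normalization: trimmed mean of M-values (TMM) scaling factors between
libraries, computed from log-ratios (M) and average log-abundances (A) over
features nonzero in both libraries, with symmetric trimming and
inverse-delta-method weighting; factors are rescaled to geometric mean 1.

Testing: a feature is differentially represented between two libraries iff
both an exact conditional negative-binomial test and the Audic-Claverie
digital-expression test give p <= alpha (default 0.001). Two-sided p-values
for both discrete tests sum the probabilities of outcomes no more probable
than the observed one. The NB machinery is a documented simplified
equivalent of edgeR's exact pipeline: counts are scaled to a common
effective library size, the test conditions on the pair total, and the
per-feature dispersion is a moment estimate shrunk toward the across-feature
median.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from ._seq import revcomp


@dataclass
class CountMatrix:
    """Features x libraries integer counts with sizes and TMM factors."""

    counts: pd.DataFrame                      # int counts, columns = libraries
    lib_sizes: pd.Series | None = None        # total mapped reads per library
    tmm: pd.Series | None = None              # TMM factors, geometric mean 1

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        if self.tmm is None:
            self.tmm = pd.Series(1.0, index=self.counts.columns)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.tmm

    def normalize_factors(self, **kwargs) -> pd.Series:
        self.tmm = tmm_factors(self, **kwargs)
        return self.tmm

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# lib_sizes\t" + "\t".join(
                f"{c}={int(self.lib_sizes[c])}" for c in self.libraries) + "\n")
            fh.write("# tmm\t" + "\t".join(
                f"{c}={self.tmm[c]:.6f}" for c in self.libraries) + "\n")
            self.counts.to_csv(fh, sep="\t")


# -- counting ----------------------------------------------------------------

def _count_exact(reads: Iterable[str], refs: Mapping[str, str]) -> pd.Series:
    reads = list(reads)
    lengths = sorted({len(r) for r in reads})
    index: dict[str, set[str]] = {}
    for fid, seq in refs.items():
        for L in lengths:
            for i in range(len(seq) - L + 1):
                index.setdefault(seq[i:i + L], set()).add(fid)
                index.setdefault(revcomp(seq[i:i + L]), set()).add(fid)
    counts = pd.Series(0, index=list(refs), dtype=int)
    for r in reads:
        for fid in index.get(r, ()):
            counts[fid] += 1
    return counts


def _count_mismatch(reads: list[str], refs: Mapping[str, str], budget: int) -> pd.Series:
    """Pigeonhole-seeded Hamming alignment: split each read into budget+1
    chunks; at least one chunk matches exactly, so exact chunk hits seed the
    verification."""
    counts = pd.Series(0, index=list(refs), dtype=int)
    cache: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def chunk_index(k: int):
        if k not in cache:
            idx: dict[str, list[tuple[str, int]]] = {}
            for fid, seq in refs.items():
                for strand_seq, strand in ((seq, "+"), (revcomp(seq), "-")):
                    for i in range(len(strand_seq) - k + 1):
                        idx.setdefault(strand_seq[i:i + k], []).append((fid + "\x00" + strand, i))
            cache[k] = idx
        return cache[k]

    ref_strands = {}
    for fid, seq in refs.items():
        ref_strands[fid + "\x00+"] = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_strands[fid + "\x00-"] = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)

    for r in reads:
        L = len(r)
        n_chunks = budget + 1
        k = L // n_chunks
        if k < 4:
            continue
        idx = chunk_index(k)
        rv = np.frombuffer(r.encode(), dtype=np.uint8)
        hits: set[str] = set()
        seen: set[tuple[str, int]] = set()
        for c in range(n_chunks):
            off = c * k
            for key, pos in idx.get(r[off:off + k], ()):
                start = pos - off
                if (key, start) in seen:
                    continue
                seen.add((key, start))
                ref = ref_strands[key]
                if start < 0 or start + L > len(ref):
                    continue
                if int((ref[start:start + L] != rv).sum()) <= budget:
                    hits.add(key.split("\x00")[0])
        for fid in hits:
            counts[fid] += 1
    return counts


def count_reads(
    reads: Iterable[str],
    references: Mapping[str, str],
    max_mismatch: int = 0,
) -> pd.Series:
    """Reads-per-feature counts; multi-feature reads increment each hit once;
    both strands are searched; only substitutions are tolerated."""
    if not references:
        raise ValueError("empty reference set")
    reads = list(reads)
    if max_mismatch == 0:
        return _count_exact(reads, references)
    return _count_mismatch(reads, references, max_mismatch)


# -- TMM ---------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a, weighted=True):
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    else:
        w = np.ones_like(m)
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """TMM scaling factors per library, rescaled to geometric mean 1.

    The reference library is the one whose upper-quartile count fraction is
    closest to the across-library mean (the convention of the cited method's
    reference implementation).
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    sizes = matrix.lib_sizes.astype(float)
    f75 = counts.apply(lambda col: np.quantile(col[col > 0], 0.75)
                       if (col > 0).any() else 0.0) / sizes
    ref_lib = (f75 - f75.mean()).abs().idxmin()
    factors = {}
    for lib in counts.columns:
        if lib == ref_lib:
            factors[lib] = 1.0
        else:
            factors[lib] = _tmm_pair(
                counts[lib].values, counts[ref_lib].values,
                sizes[lib], sizes[ref_lib], trim_m, trim_a, weighted)
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return f


# -- Audic-Claverie test ------------------------------------------------------

def ac_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library size n1) and
    y (library size n2).

    The posterior of the second count given the first is negative binomial:
    p(y'|x) = (n2/n1)^y' (x+y')! / (x! y'! (1+n2/n1)^(x+y'+1)); the two-sided
    p-value sums p(y'|x) over outcomes no more probable than the observed y,
    capped at 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)  # success prob of NB(r=x+1, p)
    r = x + 1
    dist = stats.nbinom(r, p)
    lp_obs = dist.logpmf(y)
    mean = r * (1 - p) / p
    sd = math.sqrt(r * (1 - p)) / p
    hi = int(max(y, mean + 40 * sd + 10, x + y + 10))
    ys = np.arange(0, hi + 1)
    lp = dist.logpmf(ys)
    incl = lp <= lp_obs + 1e-12
    if incl.all():
        return 1.0
    total = float(np.exp(logsumexp(lp[incl]))) if incl.any() else 0.0
    # upper tail beyond the enumeration window is monotone decreasing and, at
    # 40 sd, entirely below the observed pmf
    total += float(dist.sf(hi))
    return min(1.0, total)


# -- NB exact test -------------------------------------------------------------

def _round_half_even(v: float) -> int:
    return int(np.rint(v))


def nb_exact_test(x: int, y: int, n1: float, n2: float, dispersion: float = 0.0) -> float:
    """Exact conditional test of two counts under a negative binomial model.

    Counts are scaled to the geometric mean of the effective library sizes
    (rounded half-even). Conditional on the pair total s, the probability of
    a split (a, s-a) under equal NB means with common dispersion phi depends
    only on r = 1/phi (negative hypergeometric); phi = 0 reduces exactly to
    the symmetric binomial split test. Two-sided p sums splits no more
    probable than the observed one.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    common = math.sqrt(n1 * n2)
    xs = _round_half_even(x * common / n1)
    ys_ = _round_half_even(y * common / n2)
    s = xs + ys_
    if s == 0:
        return 1.0
    a = np.arange(0, s + 1)
    if dispersion == 0.0:
        lp = stats.binom(s, 0.5).logpmf(a)
    else:
        r = 1.0 / dispersion
        lp = (gammaln(a + r) - gammaln(a + 1)
              + gammaln(s - a + r) - gammaln(s - a + 1))
        lp -= logsumexp(lp)
    lp_obs = lp[xs]
    incl = lp <= lp_obs + 1e-12
    if incl.all():
        return 1.0
    return min(1.0, float(np.exp(logsumexp(lp[incl]))))


# -- dispersion ---------------------------------------------------------------

def estimate_dispersion(matrix: CountMatrix, prior_weight: float = 10.0) -> pd.Series:
    """Per-feature NB dispersion: method-of-moments on size-normalized counts,
    shrunk toward the across-feature median with ``prior_weight``
    pseudo-features (each feature's own estimate carries n_libraries - 1
    weight)."""
    counts = matrix.counts.values.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("dispersion needs >= 2 libraries")
    eff = matrix.effective_sizes().values
    scaled = counts / eff * eff.mean()
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), 0.0)
    med = float(np.median(raw))
    d = counts.shape[1] - 1
    shrunk = (prior_weight * med + d * raw) / (prior_weight + d)
    return pd.Series(shrunk, index=matrix.counts.index)


# -- differential calls --------------------------------------------------------

@dataclass(frozen=True)
class DifferentialCall:
    feature: str
    pair: tuple[str, str]
    p_nb: float
    p_ac: float
    alpha: float = 0.001

    @property
    def differentially_represented(self) -> bool:
        return self.p_nb <= self.alpha and self.p_ac <= self.alpha


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (reported for information only)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def call_differential(
    matrix: CountMatrix,
    alpha: float = 0.001,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise dual-test calls over all library pairs.

    Flag requires p <= alpha in BOTH the NB exact test and the A-C test. The
    returned frame carries both p-values, BH q-values per test (informational)
    and the flag.
    """
    libs = matrix.libraries
    if dispersion is None:
        dispersion = estimate_dispersion(matrix)
    eff = matrix.effective_sizes()
    rows = []
    for i in range(len(libs)):
        for j in range(i + 1, len(libs)):
            la, lb = libs[i], libs[j]
            for feat in matrix.counts.index:
                x = int(matrix.counts.at[feat, la])
                y = int(matrix.counts.at[feat, lb])
                phi = float(dispersion[feat])
                rows.append({
                    "feature": feat, "lib_a": la, "lib_b": lb,
                    "count_a": x, "count_b": y,
                    "p_nb": nb_exact_test(x, y, eff[la], eff[lb], phi),
                    "p_ac": ac_test(x, y, eff[la], eff[lb]),
                })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_nb"] = bh_qvalues(df["p_nb"].values)
        df["q_ac"] = bh_qvalues(df["p_ac"].values)
        df["differentially_represented"] = (df["p_nb"] <= alpha) & (df["p_ac"] <= alpha)
    return df
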