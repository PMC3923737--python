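"""RNA secondary-structure folding engines and dot-bracket utilities.

The folding engine is pluggable: anything with ``fold(seq) -> (dot_bracket,
mfe_kcal_mol)`` works. Two engines ship with the package:

* :class:`ViennaEngine` — ViennaRNA's MFE fold through its python bindings;
  deterministic and fast; the default when the bindings are importable.
* :class:`SimpleStackEngine` — a self-contained dynamic-programming folder
  with base-pair stacking energies and hairpin/bulge/interior-loop penalties.
  It forbids multibranch loops (every closed region is a single stem-loop
  chain), which keeps it exactly enumerable on toy sequences; it is the
  fallback engine and the one checked against an exhaustive oracle in tests.

No engine promises MFOLD's exact thermodynamics: the acceptance criteria of
the discovery stage only require energy ranges, not absolute agreement.
"""
from __future__ import annotations

from functools import lru_cache
from typing import Protocol

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


class FoldingEngine(Protocol):
    def fold(self, sequence: str) -> tuple[str, float]:
        """Return (dot-bracket structure, MFE in kcal/mol)."""
        ...


class FoldError(RuntimeError):
    pass


class ViennaEngine:
    """MFE folding via the ViennaRNA python bindings (import deferred)."""

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as e:  # pragma: no cover
            raise FoldError(
                "ViennaRNA python bindings not importable; use SimpleStackEngine "
                "or install the 'vienna' extra"
            ) from e
        self._rna = RNA

    def fold(self, sequence: str) -> tuple[str, float]:
        if not sequence:
            raise FoldError("cannot fold an empty sequence")
        db, mfe = self._rna.fold(sequence)
        return db, float(mfe)


# -- built-in folder ---------------------------------------------------------

# Symmetric stack strengths (kcal/mol, sign-flipped). A stack between two
# adjacent pairs scores -(w(p1)+w(p2))/2; a coarse average over the
# nearest-neighbor tables, adequate for range-based criteria on toys.
_PAIR_W = {("G", "C"): 3.2, ("C", "G"): 3.2,
           ("A", "U"): 2.1, ("U", "A"): 2.1,
           ("G", "U"): 1.2, ("U", "G"): 1.2}
_HAIRPIN_PENALTY = 5.5
_BULGE_PENALTY = 3.8
_INTERIOR_PENALTY = 4.6
_MIN_LOOP = 3
_MAX_INTERIOR = 12  # max unpaired nt across both sides of an interior loop


class SimpleStackEngine:
    """Deterministic stacking-energy folder without multibranch loops.

    DP over V(i,j) = best energy of a structure closed by pair (i,j), with
    transitions: hairpin loop, stack on (i+1, j-1), or bulge/interior loop to
    an inner pair (k,l) with at most ``_MAX_INTERIOR`` unpaired nt between.
    The exterior level takes the best non-overlapping set of stem-loops.
    Intended for short sequences (quadratic table with bounded loop scan).
    """

    def fold(self, sequence: str) -> tuple[str, float]:
        if not sequence:
            raise FoldError("cannot fold an empty sequence")
        s = sequence
        n = len(s)
        NEG = None  # "no structure possible"

        pairable = [[(s[i], s[j]) in _PAIR_W for j in range(n)] for i in range(n)]

        V = [[NEG] * n for _ in range(n)]
        Vtrace: dict[tuple[int, int], tuple] = {}
        for span in range(_MIN_LOOP + 2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                if not pairable[i][j]:
                    continue
                best, trace = _HAIRPIN_PENALTY, ("hairpin",)
                # stack / bulge / interior
                for k in range(i + 1, j):
                    gap_l = k - i - 1
                    if gap_l > _MAX_INTERIOR:
                        break
                    for l in range(j - 1, k, -1):
                        gap_r = j - l - 1
                        if gap_l + gap_r > _MAX_INTERIOR:
                            break
                        inner = V[k][l]
                        if inner is None:
                            continue
                        if gap_l == 0 and gap_r == 0:
                            pen = -(_PAIR_W[(s[i], s[j])] + _PAIR_W[(s[k], s[l])]) / 2
                        elif gap_l == 0 or gap_r == 0:
                            pen = _BULGE_PENALTY
                        else:
                            pen = _INTERIOR_PENALTY
                        e = inner + pen
                        if e < best:
                            best, trace = e, ("pair", k, l)
                V[i][j] = best
                Vtrace[(i, j)] = trace

        # exterior: W[j] = best energy of prefix s[0..j]
        W = [0.0] * (n + 1)
        Wtrace: list[tuple | None] = [None] * (n + 1)
        for j in range(1, n + 1):
            W[j] = W[j - 1]
            Wtrace[j] = None
            for i in range(0, j - _MIN_LOOP - 1):
                v = V[i][j - 1]
                if v is not None and v < 0 and W[i] + v < W[j]:
                    W[j] = W[i] + v
                    Wtrace[j] = (i, j - 1)

        db = ["."] * n
        j = n
        stems = []
        while j > 0:
            tr = Wtrace[j]
            if tr is None:
                j -= 1
            else:
                i, jj = tr
                stems.append((i, jj))
                j = i
        for (i, jj) in stems:
            self._traceback(i, jj, Vtrace, db)
        return "".join(db), round(W[n], 2)

    @staticmethod
    def _traceback(i, j, Vtrace, db):
        while True:
            db[i], db[j] = "(", ")"
            tr = Vtrace[(i, j)]
            if tr[0] == "hairpin":
                return
            _, k, l = tr
            i, j = k, l


@lru_cache(maxsize=1)
def default_engine() -> FoldingEngine:
    """ViennaRNA when importable, otherwise the built-in folder."""
    try:
        return ViennaEngine()
    except FoldError:  # pragma: no cover
        return SimpleStackEngine()


# -- dot-bracket utilities ---------------------------------------------------

def pair_table(db: str) -> list[int]:
    """Partner index per position (-1 when unpaired); raises on unbalanced."""
    pt = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[j], pt[i] = i, j
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def hairpin_loops(db: str) -> list[tuple[int, int]]:
    """Closing pairs (i, j) of terminal (hairpin) loops."""
    pt = pair_table(db)
    out = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            out.append((i, j))
    return out


def _children(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    out = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            out.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return out


def stemloop_span(db: str, block_lo: int, block_hi: int) -> tuple[int, int] | None:
    """Outermost closing pair of the single stem-loop unit overlapping the
    half-open interval [block_lo, block_hi).

    Walks the structure tree from the exterior: takes the child helix
    overlapping the block; descends through single-branch chains; recurses
    into multibranch junctions. Returns None when the block region is
    unpaired.
    """
    pt = pair_table(db)

    def descend(i: int, j: int) -> tuple[int, int] | None:
        chosen = None
        for (a, b) in _children(pt, i, j):
            if a < block_hi and b >= block_lo:
                chosen = (a, b)
                break
        if chosen is None:
            return None
        a, b = chosen
        lo, hi = a, b
        while True:
            kids = _children(pt, lo, hi)
            if not kids:
                return (a, b)
            if len(kids) == 1:
                lo, hi = kids[0]
            else:
                inner = descend(lo, hi)
                return inner if inner is not None else (a, b)

    return descend(-1, len(db))
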