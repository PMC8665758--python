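"""Independent oracles used by the test suite.

These deliberately avoid the implementation's algorithms: MEM enumeration
scans equality-matrix diagonals, chaining oracles enumerate every anchor
subset, and the alignment oracle is a textbook three-state affine DP.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from splicechain.mam import Mam
from splicechain.seeding import Mem

BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# MEM oracle: diagonal runs of the equality matrix
# ---------------------------------------------------------------------------

def bruteforce_mems(ref: str, read: str, min_length: int) -> set[tuple[int, int, int, int]]:
    """All maximal exact matches >= min_length as (a, b, c, d) tuples.

    Scans every diagonal of the full equality matrix for runs of matches
    (run boundaries located with np.diff on the padded diagonal).
    """
    if not ref or not read:
        return set()
    A = np.frombuffer(ref.encode(), dtype="S1")
    B = np.frombuffer(read.encode(), dtype="S1")
    eq = A[:, None] == B[None, :]
    out = set()
    n, m = len(ref), len(read)
    for diag in range(-(m - 1), n):
        i0 = max(diag, 0)
        j0 = i0 - diag
        d = np.diagonal(eq, offset=-diag).astype(np.int8)
        padded = np.concatenate(([0], d, [0]))
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_length:
                out.add((i0 + s, i0 + e, j0 + s, j0 + e))
    return out


# ---------------------------------------------------------------------------
# Chaining oracles: exhaustive subset enumeration
# ---------------------------------------------------------------------------

def chain_coverage_formula(chain: list[Mem]) -> int:
    total = 0
    prev_d = None
    for m in chain:
        if prev_d is None:
            total += m.d - m.c
        else:
            total += max(0, m.d - max(m.c, prev_d))
        prev_d = m.d
    return total


def best_mem_chain_bruteforce(mems: list[Mem]) -> int:
    """Maximum coverage over all precedence-respecting genome-disjoint subsets."""
    order = sorted(mems, key=lambda m: (m.a, m.c))
    best = 0
    n = len(order)
    for r in range(1, n + 1):
        for subset in combinations(range(n), r):
            chain = [order[i] for i in subset]
            ok = all(
                chain[i].a < chain[i + 1].a
                and chain[i].c < chain[i + 1].c
                and chain[i].b <= chain[i + 1].a
                for i in range(len(chain) - 1)
            )
            if ok:
                best = max(best, chain_coverage_formula(chain))
    return best


def mam_chain_score_formula(chain: list[Mam], lam: float, delta: float) -> float:
    total = 0.0
    prev = None
    for y in chain:
        v = y.d - y.c
        o = max(0, prev.d - y.c) if prev is not None else 0
        d = max(0, y.c - prev.d) if prev is not None else 0
        total += (v - o) * y.acc - lam * o - delta * d
        prev = y
    return total


def best_mam_chain_bruteforce(mams: list[Mam], lam: float, delta: float) -> float:
    order = sorted(mams, key=lambda m: (m.a, m.c))
    best = float("-inf")
    n = len(order)
    for r in range(1, n + 1):
        for subset in combinations(range(n), r):
            chain = [order[i] for i in subset]
            ok = all(
                chain[i].a < chain[i + 1].a and chain[i].c < chain[i + 1].c
                for i in range(len(chain) - 1)
            )
            if ok:
                best = max(best, mam_chain_score_formula(chain, lam, delta))
    return best


def random_mem_instance(rng, n_max: int = 12) -> list[Mem]:
    n = int(rng.integers(1, n_max + 1))
    mems = []
    for _ in range(n):
        a = int(rng.integers(0, 500))
        length = int(rng.integers(5, 60))
        c = int(rng.integers(0, 300))
        mems.append(Mem("c", a, a + length, c, c + length))
    return mems


def random_mam_instance(rng, n_max: int = 10) -> list[Mam]:
    n = int(rng.integers(1, n_max + 1))
    mams = []
    for _ in range(n):
        a = int(rng.integers(0, 500))
        glen = int(rng.integers(5, 80))
        c = int(rng.integers(0, 300))
        rlen = int(rng.integers(1, 80))
        acc = float(rng.uniform(0.6, 1.0))
        mams.append(Mam("c", a, a + glen, c, c + rlen, acc))
    return mams


# ---------------------------------------------------------------------------
# Affine semi-global (overlap) alignment oracle
# ---------------------------------------------------------------------------

def overlap_affine_score(
    ref: str, read: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> float:
    """Best overlap-alignment score; a gap of length k costs open + k*extend.

    End gaps (unaligned prefixes/suffixes of either sequence) are free;
    internal gaps are affine. Three-state DP, quadratic time.
    """
    n, m = len(ref), len(read)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in read (ref consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in ref (read consumed)
    M[:, 0] = 0.0  # free leading overhangs
    M[0, :] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else -mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend, X[i - 1, j] - gap_extend
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend, Y[i, j - 1] - gap_extend
            )
    best = max(
        float(np.max(M[n, :])),
        float(np.max(M[:, m])),
        float(np.max(X[n, :])),
        float(np.max(X[:, m])),
        float(np.max(Y[n, :])),
        float(np.max(Y[:, m])),
    )
    return max(best, 0.0)
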