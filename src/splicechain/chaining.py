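"""Collinear chaining: the two dynamic-programming passes of the aligner.

Pass one chains maximal exact matches (MEMs) to maximise read coverage,
forbidding genome overlap but allowing read overlap (counted once). Pass
two chains maximal approximate matches (MAMs) under a weighted objective
that rewards accuracy-weighted read coverage and penalises read overlap
(λ per nt) and read gaps (δ per nt) between consecutive anchors:

    score(S) = Σ_i (v(S[i]) − o(S[i−1], S[i]))·S[i].acc
                   − λ·o(S[i−1], S[i]) − δ·d(S[i−1], S[i])

with v(y) = y.d − y.c, o(x, y) = max{0, x.d − y.c},
d(x, y) = max{0, y.c − x.d}, and o = d = 0 against the sentinel start.

Both passes require *weak precedence*: strictly increasing genome start and
read start. Tracebacks break ties toward the closest predecessor (highest
index), which picks the nearest genomic coordinate among equals. Both DPs
are quadratic, which is ample at per-locus instance sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mam import Mam
from .seeding import Instance, Mem


@dataclass
class ChainConfig:
    """Chaining parameters.

    lam : per-nt penalty for read overlap between consecutive MAMs.
    delta : per-nt penalty for read distance between consecutive MAMs.
    dropoff : instances whose coverage upper bound falls below
        dropoff × best coverage found so far are skipped.
    max_alignments : cap on co-optimal solutions carried forward per read.
    """

    lam: float = 0.5
    delta: float = 0.1
    dropoff: float = 0.95
    max_alignments: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.delta <= 1.0):
            raise ValueError("lam and delta must lie in [0, 1]")
        if not (0.0 <= self.dropoff <= 1.0):
            raise ValueError("dropoff must lie in [0, 1]")


@dataclass
class MemChain:
    mems: list[Mem]
    coverage: int


@dataclass
class MamChain:
    mams: list[Mam]
    score: float


# ---------------------------------------------------------------------------
# MEM chaining (coverage objective)
# ---------------------------------------------------------------------------

def coverage(chain: list[Mem]) -> int:
    """Read nucleotides covered by a chain, consecutive overlaps counted once.

    The first anchor contributes its full read length; each successor
    contributes the part of its read interval beyond the predecessor's read
    end (clamped at zero). Requires weak precedence.
    """
    total = 0
    prev_d = None
    prev = None
    for m in chain:
        if prev is not None and not (prev.a < m.a and prev.c < m.c):
            raise ValueError("chain violates weak precedence")
        if prev_d is None:
            total += m.d - m.c
        else:
            total += max(0, m.d - max(m.c, prev_d))
        prev_d = m.d
        prev = m
    return total


def chain_mems(instance: Instance, config: ChainConfig | None = None) -> list[MemChain]:
    """All maximum-coverage collinear MEM chains of one instance.

    Genome overlap between chained MEMs is forbidden; read overlap is
    allowed and counted once. Co-optimal chains (frequent for duplicated
    genes) are each traced back, capped at ``max_alignments``; each
    traceback chooses the closest (highest-index) predecessor at ties.
    """
    config = config or ChainConfig()
    mems = sorted(instance.mems, key=lambda m: (m.a, m.c))
    n = len(mems)
    if n == 0:
        return []
    W = [0] * n
    back = [-1] * n
    for i, mi in enumerate(mems):
        W[i] = mi.d - mi.c
        for j in range(i - 1, -1, -1):  # descending: first best is closest
            mj = mems[j]
            if mj.a < mi.a and mj.c < mi.c and mj.b <= mi.a:
                cand = W[j] + max(0, mi.d - max(mi.c, mj.d))
                if cand > W[i]:
                    W[i] = cand
                    back[i] = j
    best = max(W)
    chains: list[MemChain] = []
    seen: set[tuple] = set()
    for i in range(n):
        if W[i] != best:
            continue
        path = []
        k = i
        while k != -1:
            path.append(mems[k])
            k = back[k]
        path.reverse()
        key = tuple((m.a, m.b, m.c, m.d) for m in path)
        if key not in seen:
            seen.add(key)
            chains.append(MemChain(path, best))
        if len(chains) >= config.max_alignments:
            break
    return chains


def rank_and_prune_instances(
    instances: list[Instance], config: ChainConfig | None = None
):
    """Solve instances in decreasing upper-bound order with drop-off pruning.

    Yields (instance, chains) for each solved instance. Once an instance's
    upper bound is below dropoff × best coverage achieved so far, it and
    every later instance are skipped. Equal bounds keep input order.
    """
    config = config or ChainConfig()
    order = sorted(
        range(len(instances)), key=lambda i: (-instances[i].upper_bound, i)
    )
    best_cov = 0
    solved = []
    for idx in order:
        inst = instances[idx]
        if best_cov and inst.upper_bound < config.dropoff * best_cov:
            break
        chains = chain_mems(inst, config)
        if chains:
            best_cov = max(best_cov, chains[0].coverage)
        solved.append((inst, chains))
    return solved


# ---------------------------------------------------------------------------
# MAM chaining (weighted objective)
# ---------------------------------------------------------------------------

def mam_link_weight(x: Mam | None, y: Mam, config: ChainConfig | None = None) -> float:
    """Marginal score of appending MAM ``y`` after ``x`` (None = sentinel)."""
    config = config or ChainConfig()
    v = y.d - y.c
    if x is None:
        o = 0
        d = 0
    else:
        o = max(0, x.d - y.c)
        d = max(0, y.c - x.d)
    return (v - o) * y.acc - config.lam * o - config.delta * d


def chain_score(chain: list[Mam], config: ChainConfig | None = None) -> float:
    config = config or ChainConfig()
    total = 0.0
    prev: Mam | None = None
    for m in chain:
        total += mam_link_weight(prev, m, config)
        prev = m
    return total


def chain_mams(mams: list[Mam], config: ChainConfig | None = None) -> MamChain:
    """Maximum-score MAM chain under weak precedence (quadratic DP).

    Anchors are sorted by genome start; W[i] is the best score of a chain
    ending at anchor i, maximised over predecessors with strictly smaller
    genome and read starts. Traceback starts from the maximum W and prefers
    the closest predecessor at ties.
    """
    config = config or ChainConfig()
    if not mams:
        return MamChain([], 0.0)
    A = sorted(mams, key=lambda m: (m.a, m.c, m.b, m.d))
    n = len(A)
    W = [0.0] * n
    back = [-1] * n
    for i in range(n):
        W[i] = mam_link_weight(None, A[i], config)
        for j in range(i - 1, -1, -1):
            if A[j].a < A[i].a and A[j].c < A[i].c:
                cand = W[j] + mam_link_weight(A[j], A[i], config)
                if cand > W[i]:
                    W[i] = cand
                    back[i] = j
    end = max(range(n), key=lambda i: (W[i], i))  # highest index at ties
    path = []
    k = end
    while k != -1:
        path.append(A[k])
        k = back[k]
    path.reverse()
    return MamChain(path, W[end])
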