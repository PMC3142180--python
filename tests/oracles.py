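"""Independent brute-force oracles used to check the implementation.

Everything here is written directly from first principles (exact rational
arithmetic, explicit enumeration) and deliberately shares no code with the
package under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(k: int, n: int, M: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, M, n), by exact summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(n, M) + 1):
        total += Fraction(comb(M, i) * comb(N - M, n - i), denom)
    return total


def binom_tail_exact(k: int, n: int, M: int, N: int) -> Fraction:
    """P(Y >= k) for Y ~ Binomial(n, M/N), by exact summation."""
    p = Fraction(M, N)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


def bh_quadratic(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values by the literal quadratic-time definition:
    q_i = min over j with p_(j) >= p_i of min(1, m * p_(j) / j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    sorted_p = [pvalues[i] for i in order]
    qvalues = [0.0] * m
    for i in range(m):
        candidates = [
            min(1.0, m * sorted_p[j] / (j + 1))
            for j in range(m)
            if sorted_p[j] >= pvalues[i]
        ]
        qvalues[i] = min(candidates)
    return qvalues


def path_distance(parent: dict[str, str], query: str, ref: str) -> int:
    """Taxonomic distance by explicit path enumeration: nodes from the
    query leaf (exclusive) to the lowest common ancestor (inclusive)."""
    if query == ref:
        return 0
    ref_chain = [ref]
    node = ref
    while parent[node] != node:
        node = parent[node]
        ref_chain.append(node)
    ref_side = set(ref_chain)
    count = 0
    node = query
    while True:
        node = parent[node]
        count += 1
        if node in ref_side:
            return count
        if parent[node] == node:
            raise AssertionError("ran past the root without a common ancestor")


def selection_oracle(
    parent: dict[str, str],
    gene_counts: dict[str, int],
    organisms: list[str],
    query: str,
    query_count: int,
    K: int,
    descending: bool,
) -> list[str]:
    """Reference-genome selection by direct application of the stated
    procedure: per distance class pick the organism with genome size most
    similar to the query's (name-lexicographic on ties), one representative
    per class before any class contributes a second."""
    candidates = [o for o in organisms if o != query]
    groups: dict[int, list[str]] = {}
    for org in candidates:
        groups.setdefault(path_distance(parent, query, org), []).append(org)
    for members in groups.values():
        members.sort(key=lambda o: (abs(gene_counts[o] - query_count), o))
    class_order = sorted(groups, reverse=descending)
    picked: list[str] = []
    depth = 0
    while len(picked) < K:
        took_any = False
        for d in class_order:
            if depth < len(groups[d]):
                picked.append(groups[d][depth])
                took_any = True
                if len(picked) == K:
                    return picked
        if not took_any:
            return picked
        depth += 1
    return picked


def best_transfer_oracle(
    rows: list[tuple[str, str, float, int]],
    annotated: set[str],
    e_cutoff: float,
    max_rank: int,
) -> dict[str, str]:
    """Per-query transfer by exhaustive scan over (query, subject, evalue,
    rank) rows: among rows passing all three predicates, pick min rank."""
    winners: dict[str, tuple[int, str]] = {}
    for query, subject, evalue, rank in rows:
        if evalue > e_cutoff or rank > max_rank or subject not in annotated:
            continue
        if query not in winners or rank < winners[query][0]:
            winners[query] = (rank, subject)
    return {q: s for q, (_, s) in winners.items()}
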