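"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact integer
arithmetic for the hypergeometric tail, exhaustive set-partition search for
the best-modularity partition, and direct pair-counting enumeration for the
Mann-Whitney permutation distribution.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact integer enumeration of the upper tail."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1) if n - j <= N - K)
    return num / comb(N, n)


def set_partitions(items):
    """All partitions of a list (restricted-growth recursion)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1:]
        yield [[first]] + partial


def modularity_direct(graph, blocks) -> float:
    """Q computed straight from the definition, per candidate partition."""
    m = graph.number_of_edges()
    q = 0.0
    for block in blocks:
        members = set(block)
        e_c = sum(1 for a, b in graph.edges if a in members and b in members)
        d_c = sum(d for v, d in graph.degree if v in members)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def best_partition_bruteforce(graph):
    """(best Q, best partition) over every set partition of the nodes."""
    best_q, best_blocks = -1.0, None
    for blocks in set_partitions(sorted(graph.nodes)):
        q = modularity_direct(graph, blocks)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, best_blocks


def mann_whitney_bruteforce(x, y):
    """(U, exact doubled-tail two-sided p) by enumerating every labeling of
    the pooled sample and counting x>y pairs (ties count one half)."""
    pooled = list(x) + list(y)
    nx_ = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    u_obs = u_of(frozenset(range(nx_)))
    us = [u_of(frozenset(c)) for c in combinations(range(len(pooled)), nx_)]
    lower = sum(1 for u in us if u <= u_obs + 1e-12) / len(us)
    upper = sum(1 for u in us if u >= u_obs - 1e-12) / len(us)
    return u_obs, min(1.0, 2.0 * min(lower, upper))
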