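"""Spectral modularity partitioning of the seed network.

The partition objective is Newman-Girvan modularity
``Q = sum_c [ e_c/m - (d_c/2m)^2 ]`` (e_c intra-module edges, d_c total degree
of module c, m total edges). Modules are found by recursive leading-eigenvector
bipartitioning of the modularity matrix ``B = A - k k^T / 2m``: a module is
split along the sign pattern of the leading eigenvector of the generalized
modularity matrix restricted to it, the split is refined by deterministic
single-vertex moves (Kernighan-Lin style), and recursion stops when no split
increases Q (the indivisibility test) or a part would fall below
``min_module_size``. Connected components are partitioned independently.

Everything here is deterministic for a fixed input graph regardless of node
insertion order: nodes are processed in sorted symbol order, the eigenvector
sign is fixed by making its largest-magnitude entry positive, and exact zero
entries are assigned to the group containing the lexicographically smallest
symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ValidationError

_EIG_TOL = 1e-9
_Q_TOL = 1e-12


def _as_graph(net):
    # accept a SeedNetwork or a bare networkx graph (nx.Graph has a `.graph`
    # attribute dict, so the isinstance check must come first)
    return net if isinstance(net, nx.Graph) else net.graph


@dataclass
class Clustering:
    """A partition of network nodes into modules.

    Module indices are contiguous 0..n_modules-1, labeled in decreasing size
    order (ties broken by smallest lexicographic member symbol). ``modules``
    holds the member lists, each sorted.
    """

    assignment: dict
    n_modules: int
    modularity: float
    modules: list

    def module_sizes(self) -> list:
        return [len(m) for m in self.modules]


def modularity(net, assignment) -> float:
    """Newman-Girvan modularity Q of a partition; fatal on an edgeless graph."""
    g = _as_graph(net)
    m = g.number_of_edges()
    if m == 0:
        raise ValidationError("modularity is undefined for an edgeless network")
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise ValidationError(f"assignment does not cover {len(missing)} nodes")
    intra, deg = {}, {}
    for a, b in g.edges:
        if assignment[a] == assignment[b]:
            intra[assignment[a]] = intra.get(assignment[a], 0) + 1
    for v, d in g.degree():
        c = assignment[v]
        deg[c] = deg.get(c, 0) + d
    q = 0.0
    for c in deg:
        q += intra.get(c, 0) / m - (deg[c] / (2.0 * m)) ** 2
    return q


def _fine_tune(B, s, max_passes=10):
    """Deterministic single-vertex refinement of a bipartition sign vector.

    Repeatedly performs Kernighan-Lin passes: every vertex is moved exactly
    once per pass in order of best improvement of s^T B s (ties toward the
    lowest index), and the best intermediate state of the pass is kept if it
    improves on the pass's starting state.
    """
    n = len(s)
    diag = np.diag(B)
    for _ in range(max_passes):
        s_start = s.copy()
        q_start = float(s @ B @ s)
        bs = B @ s
        moved = np.zeros(n, dtype=bool)
        best_q, best_state = q_start, None
        running = q_start
        for _step in range(n):
            # gain of flipping vertex v: s^TBs changes by -4 s_v (Bs)_v + 4 B_vv
            gains = -4.0 * s * bs + 4.0 * diag
            gains[moved] = -np.inf
            v = int(np.argmax(gains))
            running += gains[v]
            bs = bs - 2.0 * s[v] * B[:, v]
            s[v] = -s[v]
            moved[v] = True
            if running > best_q + _Q_TOL:
                best_q, best_state = running, s.copy()
        if best_state is None:
            return s_start
        s = best_state
        if best_q <= q_start + _Q_TOL:
            return s
    return s


def spectral_partition(net, min_module_size: int = 3) -> Clustering:
    """Partition a network into modules by recursive spectral bipartitioning.

    Returns a :class:`Clustering` whose recorded modularity equals
    :func:`modularity` recomputed on the assignment. An edgeless network
    yields singleton modules with modularity 0 by convention.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty network")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = nx.to_numpy_array(g, nodelist=nodes)
    k = A.sum(axis=1)
    two_m = float(k.sum())

    groups: list[np.ndarray] = []

    def split(idx: np.ndarray) -> None:
        if len(idx) < 2 or len(idx) < 2 * min_module_size:
            groups.append(idx)
            return
        # generalized modularity matrix for the subset
        Bg = A[np.ix_(idx, idx)] - np.outer(k[idx], k[idx]) / two_m
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        eigvals, eigvecs = np.linalg.eigh(Bg)
        if eigvals[-1] <= _EIG_TOL:
            groups.append(idx)  # indivisible
            return
        lead = eigvecs[:, -1]
        j = int(np.argmax(np.abs(lead)))
        if lead[j] < 0:
            lead = -lead
        s = np.where(lead > 0, 1.0, -1.0)
        zero = lead == 0.0
        if zero.any():
            # ties join the group holding the lexicographically smallest symbol
            s[zero] = 1.0 if zero[0] else s[0]
        s = _fine_tune(Bg, s)
        delta_q = float(s @ Bg @ s) / (2.0 * two_m)
        left = idx[s > 0]
        right = idx[s < 0]
        if delta_q <= _Q_TOL or len(left) < min_module_size or len(right) < min_module_size:
            groups.append(idx)
            return
        split(left)
        split(right)

    if two_m == 0:
        groups = [np.array([i]) for i in range(n)]
    else:
        for comp in nx.connected_components(g):
            split(np.array(sorted(index[v] for v in comp), dtype=int))

    member_lists = [sorted(nodes[i] for i in grp) for grp in groups]
    member_lists.sort(key=lambda mem: (-len(mem), mem[0]))
    assignment = {v: c for c, mem in enumerate(member_lists) for v in mem}
    q = modularity(g, assignment) if two_m > 0 else 0.0
    return Clustering(assignment=assignment, n_modules=len(member_lists),
                      modularity=q, modules=member_lists)


def cluster_table(net, clustering: Clustering):
    """Per-module tabulation: module index, size, seed count, member list.

    Sizes sum to the node count. Returns a pandas DataFrame in module order.
    """
    import pandas as pd

    is_seed = (net.is_seed if hasattr(net, "is_seed")
               else lambda v: bool(_as_graph(net).nodes[v].get("is_seed", False)))
    rows = []
    for c, members in enumerate(clustering.modules):
        rows.append({
            "module": c,
            "size": len(members),
            "n_seeds": sum(1 for v in members if is_seed(v)),
            "members": ",".join(members),
        })
    return pd.DataFrame(rows, columns=["module", "size", "n_seeds", "members"])
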