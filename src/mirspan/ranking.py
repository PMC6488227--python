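"""Target enrichment, the miRNA spanning score, family ranking, and gene-set
(hallmark-style) enrichment.

For each miRNA family the upper-tail hypergeometric test asks whether the
family's predicted targets land in the seed network (and in each cluster
module) more often than a uniform draw from the interactome universe would
give. The spanning score condenses this into a single ranking statistic

    S = B + (1 - p_net)

where ``B`` counts modules whose per-module enrichment p is below ``alpha``
(unadjusted — B is a descriptive breadth count) and ``p_net`` is the
network-wide enrichment p. Breadth across modules dominates; whole-network
enrichment breaks ties among families spanning equally many modules, so a
family regulating a diverse range of processes outranks an equally enriched
but module-confined one. The number of modules merely *containing* a target
(``clusters_with_targets``) is reported alongside as the presence-based
breadth measure.

The hallmark-style gene-set enrichment applies the same hypergeometric test to
the network's gene list against a GMT collection, with Benjamini-Hochberg FDR
across the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class EnrichmentResult:
    """One hypergeometric upper-tail test: k of n drawn hits among K of N."""

    N: int
    K: int
    n: int
    k: int
    p_value: float
    overlap_genes: frozenset = field(default_factory=frozenset)


@dataclass
class SpanningResult:
    """Per-family enrichment profile, spanning score and (once ranked) rank."""

    family_id: str
    network_enrichment: EnrichmentResult
    cluster_enrichments: list
    enriched_cluster_count: int
    clusters_with_targets: int
    spanning_score: float
    alpha: float
    rank: int | None = None


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); P(X >= 0) = 1 exactly.

    Bounds are validated: 0 <= k <= min(K, n), k <= K <= N, n <= N.
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(val) != val or val < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {val!r}")
    if K > N or n > N or k > K or k > n:
        raise ValidationError(
            f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    # sf is the complemented CDF, evaluated in a numerically stable way
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, 0.0))


def mirna_enrichment_profile(family, interactome, net, clustering, universe=None):
    """Cross-reference one family's targets to the clustered network.

    Universe N = interactome node count (or an explicit ``universe`` subset,
    e.g. interactome genes restricted to the target table's gene space);
    K = targets present in the universe. The network test draws n = network
    size with k = targets in the network; each per-module test draws that
    module's size. A family with no interactome targets yields p = 1
    everywhere (a valid result).
    """
    universe = interactome.nodes if universe is None else set(universe)
    N = len(universe)
    in_universe = frozenset(family.targets) & universe
    K = len(in_universe)
    net_nodes = net.nodes & universe
    net_overlap = in_universe & net_nodes
    network = EnrichmentResult(
        N=N, K=K, n=len(net_nodes), k=len(net_overlap),
        p_value=hypergeom_upper_tail(N, K, len(net_nodes), len(net_overlap)),
        overlap_genes=frozenset(net_overlap),
    )
    per_cluster = []
    for members in clustering.modules:
        in_module = set(members) & universe
        overlap = in_universe & in_module
        per_cluster.append(EnrichmentResult(
            N=N, K=K, n=len(in_module), k=len(overlap),
            p_value=hypergeom_upper_tail(N, K, len(in_module), len(overlap)),
            overlap_genes=frozenset(overlap),
        ))
    return network, per_cluster


def spanning_score(family_id, profile, alpha: float = 0.05) -> SpanningResult:
    """Combine a family's enrichment profile into the spanning score
    S = B + (1 - p_net)."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    network, per_cluster = profile
    b = sum(1 for r in per_cluster if r.p_value < alpha)
    with_targets = sum(1 for r in per_cluster if r.k > 0)
    score = b + (1.0 - network.p_value)
    return SpanningResult(
        family_id=family_id, network_enrichment=network,
        cluster_enrichments=list(per_cluster), enriched_cluster_count=b,
        clusters_with_targets=with_targets, spanning_score=score, alpha=alpha,
    )


def rank_families(results) -> list:
    """Rank spanning results: descending score, ties by smaller network p,
    then larger network overlap k, then family id. Rank 1 is the top; the
    order is deterministic under any permutation of the input."""
    ordered = sorted(results, key=lambda r: (
        -r.spanning_score,
        r.network_enrichment.p_value,
        -r.network_enrichment.k,
        r.family_id,
    ))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def ranking_table(ranked, families=None) -> pd.DataFrame:
    """Tabulate ranked spanning results (one row per family, rank order),
    including per-module k:p pairs."""
    seed_of = {}
    if families is not None:
        seed_of = {f.family_id: (f.seed_sequence or "") for f in families}
    rows = []
    for r in ranked:
        net = r.network_enrichment
        rows.append({
            "family_id": r.family_id,
            "seed_sequence": seed_of.get(r.family_id, ""),
            "K": net.K,
            "network_k": net.k,
            "p_net": net.p_value,
            "B": r.enriched_cluster_count,
            "clusters_with_targets": r.clusters_with_targets,
            "spanning_score": r.spanning_score,
            "rank": r.rank,
            "module_profile": ";".join(
                f"{e.k}:{e.p_value:.6g}" for e in r.cluster_enrichments),
        })
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> list:
    """Benjamini-Hochberg step-up adjustment; output order matches input."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps <= 0) | (ps > 1)) or np.any(~np.isfinite(ps)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(ps, method="fdr_bh")[1].tolist()


def hallmark_enrichment(genes, collection, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list against a gene-set collection.

    Query genes outside the universe are dropped (count reported in the
    ``n_query_dropped`` DataFrame attribute); one row per gene set that
    intersects the universe; BH-FDR across all tested sets; sorted by
    ascending p (ties by set name).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    query = set(genes)
    dropped = len(query - universe)
    query &= universe
    n = len(query)
    N = len(universe)
    rows = []
    for name, (_desc, members) in collection.sets.items():
        in_univ = members & universe
        if not in_univ:
            continue
        overlap = in_univ & query
        p = hypergeom_upper_tail(N, len(in_univ), n, len(overlap))
        rows.append({"set_name": name, "k": len(overlap), "K": len(in_univ),
                     "n": n, "N": N, "p_value": p,
                     "overlap_genes": ",".join(sorted(overlap))})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr_adjusted_p"] = bh_fdr(table["p_value"])
        table["neg_log10_p"] = -np.log10(table["p_value"])
        table = table.sort_values(["p_value", "set_name"], kind="mergesort",
                                  ignore_index=True)
    table.attrs["n_query_dropped"] = dropped
    return table
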