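"""Complex detection on a weighted PPI graph: dense cores plus attachments.

The core-attachment model views a complex as a dense, stable core decorated
with peripheral attachment proteins.  Cores are grown greedily under two
constraints evaluated on the weighted induced subgraph:

* weighted density ``2m / (|N| (|N| - 1)) >= lam`` where ``m`` is the sum of
  internal edge weights, and
* hop diameter (longest shortest path, unweighted hops) ``<= delta``.

Attachment candidates are the second-order neighbors of a core: every node
within two hops of a core member.  A candidate joins when its total edge
weight into the core reaches ``attach_ratio`` times the average weighted
internal degree of the core members, a weighted analogue of the classic
"connected to more than half the core" rule.  Expansion is single-round and
evaluated against the original core, so the result does not depend on the
order in which candidates are examined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .errors import ParameterError, ValidationError
from .io import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "Cluster",
    "weighted_density",
    "hop_diameter",
    "detect_cores",
    "expand_core",
    "deduplicate",
    "detect_complexes",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs for the full detection pipeline.

    Defaults are the reference configuration: blend alpha = 0.3, density
    floor lam = 0.7, diameter cap delta = 2, neighborhood-affinity match
    threshold t = 0.2.
    """

    alpha: float = 0.3
    lam: float = 0.7
    delta: int = 2
    t: float = 0.2
    min_core_size: int = 3
    attach_ratio: float = 0.5
    dedup_na: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 < self.lam <= 1.0):
            raise ParameterError(f"lam must be in (0, 1], got {self.lam}")
        if self.delta < 1:
            raise ParameterError(f"delta must be a positive integer, got {self.delta}")
        if not (0.0 < self.t <= 1.0):
            raise ParameterError(f"t must be in (0, 1], got {self.t}")
        if self.min_core_size < 2:
            raise ParameterError(f"min_core_size must be >= 2, got {self.min_core_size}")
        if not (0.0 < self.attach_ratio <= 1.0):
            raise ParameterError(f"attach_ratio must be in (0, 1], got {self.attach_ratio}")
        if not (0.0 < self.dedup_na <= 1.0):
            raise ParameterError(f"dedup_na must be in (0, 1], got {self.dedup_na}")


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    density: float
    diameter: float  # math.inf when the induced subgraph is disconnected
    stage: str = "core"  # "core" | "expanded"

    def __len__(self) -> int:
        return len(self.members)


def _edge_weight(g: nx.Graph, u: str, v: str) -> float:
    return g[u][v].get("weight", 1.0)


def weighted_density(g: nx.Graph, members: set[str] | frozenset[str]) -> float:
    """Mean pairwise weight of the induced subgraph: 2m / (|N| (|N| - 1))."""
    n = len(members)
    if n < 2:
        raise ValidationError("weighted density needs at least 2 members")
    if not set(members) <= set(g.nodes):
        raise ValidationError("members must all be nodes of the graph")
    m = sum(
        _edge_weight(g, u, v)
        for u, v in g.subgraph(members).edges()
    )
    return 2.0 * m / (n * (n - 1))


def hop_diameter(g: nx.Graph, members: set[str] | frozenset[str]) -> float:
    """Longest shortest path (in hops) inside the induced subgraph.

    0 for a singleton; ``inf`` when the induced subgraph is disconnected.
    """
    if not members:
        raise ValidationError("hop_diameter of an empty member set is undefined")
    sub = g.subgraph(members)
    if len(members) == 1:
        return 0.0
    diam = 0.0
    for src in sub.nodes:
        lengths = nx.single_source_shortest_path_length(sub, src)
        if len(lengths) < len(members):
            return math.inf
        diam = max(diam, max(lengths.values()))
    return float(diam)


def _weighted_degree(g: nx.Graph, v: str) -> float:
    return sum(_edge_weight(g, v, u) for u in g[v])


def detect_cores(g: nx.Graph, params: DetectionParams) -> list[Cluster]:
    """Greedy density-driven core search.

    Seeds are visited in decreasing weighted-degree order (ties broken by
    node ID).  A seed and its heaviest neighbor start a candidate set, which
    absorbs, one at a time, the adjacent node maximizing the resulting
    weighted density, as long as density >= lam and diameter <= delta hold.
    Candidates of size >= min_core_size that satisfy both constraints are
    kept; nodes already inside an accepted core are skipped as seeds (they
    may still join other clusters during expansion).  Fully deterministic.
    """
    if g.number_of_edges() == 0:
        return []
    order = sorted(g.nodes, key=lambda v: (-_weighted_degree(g, v), v))
    covered: set[str] = set()
    cores: list[Cluster] = []
    for seed in order:
        if seed in covered:
            continue
        nbrs = [u for u in g[seed]]
        if not nbrs:
            continue
        first = min(nbrs, key=lambda u: (-_edge_weight(g, seed, u), u))
        members: set[str] = {seed, first}
        m_sum = _edge_weight(g, seed, first)

        while True:
            frontier: set[str] = set()
            for v in members:
                frontier.update(u for u in g[v] if u not in members)
            best: str | None = None
            best_density = -1.0
            n_next = len(members) + 1
            for cand in sorted(frontier):
                gain = sum(
                    _edge_weight(g, cand, v) for v in members if g.has_edge(cand, v)
                )
                dens = 2.0 * (m_sum + gain) / (n_next * (n_next - 1))
                if dens < params.lam or dens <= best_density:
                    continue
                if hop_diameter(g, members | {cand}) > params.delta:
                    continue
                best, best_density = cand, dens
            if best is None:
                break
            m_sum += sum(_edge_weight(g, best, v) for v in members if g.has_edge(best, v))
            members.add(best)

        if len(members) < params.min_core_size:
            continue
        dens = weighted_density(g, members)
        diam = hop_diameter(g, members)
        if dens >= params.lam and diam <= params.delta:
            cores.append(Cluster(frozenset(members), dens, diam, stage="core"))
            covered |= members
    return cores


def expand_core(g: nx.Graph, core: Cluster, params: DetectionParams) -> Cluster:
    """Attach second-order neighbors that bind the core strongly enough.

    Candidates are nodes within two hops of any core member.  A candidate
    joins when its total edge weight into the core is at least
    ``attach_ratio`` times the core's average weighted internal degree.
    All candidates are judged against the original core (no chaining).
    """
    members = set(core.members)
    first_hop: set[str] = set()
    for v in members:
        first_hop.update(g[v])
    candidates: set[str] = set(first_hop)
    for v in first_hop:
        candidates.update(g[v])
    candidates -= members

    n = len(members)
    internal = sum(_edge_weight(g, u, v) for u, v in g.subgraph(members).edges())
    avg_internal_degree = 2.0 * internal / n if n else 0.0
    threshold = params.attach_ratio * avg_internal_degree

    attached = {
        cand
        for cand in candidates
        if (conn := sum(_edge_weight(g, cand, v) for v in members if g.has_edge(cand, v)))
        >= threshold
        and conn > 0.0
    }
    new_members = frozenset(members | attached)
    dens = weighted_density(g, new_members) if len(new_members) >= 2 else 0.0
    return Cluster(new_members, dens, hop_diameter(g, new_members), stage="expanded")


def _na(a: frozenset[str], b: frozenset[str]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def deduplicate(clusters: list[Cluster], params: DetectionParams) -> ComplexSet:
    """Drop near-duplicate clusters, keeping the larger of each pair.

    Clusters are processed in decreasing size; one is dropped when its
    neighborhood affinity with any already-kept cluster reaches
    ``dedup_na`` (exact duplicates have affinity 1 and always go).
    """
    ordered = sorted(clusters, key=lambda c: (-len(c.members), tuple(sorted(c.members))))
    kept: list[Cluster] = []
    dropped = 0
    for c in ordered:
        if any(_na(c.members, k.members) >= params.dedup_na for k in kept):
            dropped += 1
            continue
        kept.append(c)
    if dropped:
        logger.info("deduplication dropped %d near-duplicate cluster(s)", dropped)
    return ComplexSet(complexes=[c.members for c in kept], label="predicted")


def detect_complexes(
    g: nx.Graph,
    expr,
    params: DetectionParams | None = None,
    ra_enabled: bool = True,
    sns_enabled: bool = True,
) -> ComplexSet:
    """End-to-end pipeline: weight the graph, mine cores, expand, deduplicate.

    ``ra_enabled=False`` weights edges by expression correlation alone;
    ``sns_enabled=False`` skips second-order-neighbor expansion and returns
    the deduplicated cores.  Deterministic for identical inputs and params.
    """
    from .weighting import build_weighted_network

    params = params or DetectionParams()
    weighted = build_weighted_network(g, expr, alpha=params.alpha, ra_enabled=ra_enabled)
    cores = detect_cores(weighted, params)
    logger.info("found %d core cluster(s)", len(cores))
    if sns_enabled:
        clusters = [expand_core(weighted, c, params) for c in cores]
        added = sum(len(c.members) for c in clusters) - sum(len(c.members) for c in cores)
        logger.info("second-order expansion attached %d node(s)", added)
    else:
        clusters = cores
    return deduplicate(clusters, params)
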