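"""Master-regulator search on a directed regulatory network.

Each candidate node is evaluated by its radius-bounded downstream cone
(breadth-first shortest paths along edge direction), a distance-weighted
coverage score of the differential hits it reaches, and a permutation null
built from random gene sets of matched size. Candidates pass when the score,
the permutation Z-score, and the BH-adjusted empirical p-value all clear
their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .de import DifferentialList

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """Directed graph with edges oriented regulator -> target.

    ``gene_map`` maps node identifiers to gene identifiers (upper-cased);
    by default every node maps to itself.
    """

    graph: nx.DiGraph
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            logger.warning("dropping %d self-loop(s): %s", len(loops), loops[:5])
            self.graph.remove_edges_from(loops)
        if not self.gene_map:
            self.gene_map = {n: str(n).upper() for n in self.graph.nodes}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        gene_map: Mapping[str, str] | None = None,
    ) -> "RegulatoryNetwork":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, gene_map=dict(gene_map) if gene_map else {})

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if n in self.gene_map]

    def nodes_for_genes(self, genes: Iterable[str]) -> set[str]:
        wanted = {str(g).upper() for g in genes}
        return {
            n
            for n, g in self.gene_map.items()
            if str(g).upper() in wanted and n in self.graph
        }


@dataclass
class MRCandidate:
    node: str
    radius: int
    reached_hits: dict[str, int]  # hit node -> shortest distance (steps)
    score: float
    z_score: float
    p_value: float
    adj_p_value: float = float("nan")
    degenerate: bool = False


def downstream_cone(
    network: RegulatoryNetwork, node: str, radius: int = 10
) -> dict[str, int]:
    """Shortest-path distances (in steps) to nodes reachable within ``radius``.

    The node itself is excluded: distance 0 is not a target.
    """
    if node not in network.graph:
        raise KeyError(f"unknown node {node!r}")
    dist = nx.single_source_shortest_path_length(network.graph, node, cutoff=radius)
    dist.pop(node, None)
    return dist


def coverage_score(cone: Mapping[str, int], hits: Iterable[str]) -> float:
    """Distance-weighted hit coverage: sum of 1/d over reached hits, / |hits|.

    Lies in [0, 1]; equals 1 iff every hit is a direct (distance-1) target.
    """
    hits = set(hits)
    if not hits:
        raise ValueError("hits must be nonempty")
    total = sum(1.0 / cone[h] for h in hits if h in cone)
    return total / len(hits)


@dataclass
class NullSummary:
    null_scores: np.ndarray
    z_score: float
    p_value: float
    degenerate: bool


def permutation_null(
    network: RegulatoryNetwork,
    node: str,
    hit_count: int,
    observed: float,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    radius: int = 10,
    cone: Mapping[str, int] | None = None,
) -> NullSummary:
    """Null coverage scores for random gene sets of size ``hit_count``.

    Z = (observed - null mean) / null sd; when the null sd is zero the
    Z-score is reported as 0 with the degeneracy flag set. The empirical
    p-value uses the add-one estimator (1 + #{null >= observed}) / (1 + B).
    """
    rng = np.random.default_rng(rng)
    gene_nodes = network.gene_nodes
    if hit_count > len(gene_nodes) or hit_count < 1:
        raise ValueError(
            f"hit_count {hit_count} outside [1, {len(gene_nodes)}] gene-mapped nodes"
        )
    if cone is None:
        cone = downstream_cone(network, node, radius)
    weights = np.array([1.0 / cone[n] if n in cone else 0.0 for n in gene_nodes])

    # each permutation draws hit_count distinct gene nodes uniformly
    u = rng.random((n_permutations, len(gene_nodes)))
    idx = np.argpartition(u, hit_count - 1, axis=1)[:, :hit_count]
    null_scores = weights[idx].sum(axis=1) / hit_count

    sd = float(null_scores.std(ddof=0))
    if sd == 0.0:
        z, degenerate = 0.0, True
    else:
        z, degenerate = float((observed - null_scores.mean()) / sd), False
    p = (1.0 + int(np.sum(null_scores >= observed))) / (1.0 + n_permutations)
    return NullSummary(null_scores=null_scores, z_score=z, p_value=p, degenerate=degenerate)


def find_master_regulators(
    network: RegulatoryNetwork,
    de_list: DifferentialList | Iterable[str],
    radius: int = 10,
    score_min: float = 0.2,
    z_min: float = 1.0,
    fdr_max: float = 0.05,
    n_permutations: int = 1000,
    rng_seed: int | None = 0,
) -> list[MRCandidate]:
    """Evaluate every network node and keep those passing all three filters.

    Retained iff score >= ``score_min`` AND Z >= ``z_min`` AND BH-adjusted
    permutation p <= ``fdr_max``. Sorted by score descending, ties by
    Z descending, then node identifier.
    """
    entities = (
        de_list.entities if isinstance(de_list, DifferentialList) else set(de_list)
    )
    hit_nodes = network.nodes_for_genes(entities)
    if not hit_nodes:
        logger.warning("differential list maps to zero network nodes: empty result")
        return []
    rng = np.random.default_rng(rng_seed)

    candidates: list[MRCandidate] = []
    for node in sorted(network.graph.nodes):
        cone = downstream_cone(network, node, radius)
        reached = {h: cone[h] for h in hit_nodes if h in cone}
        score = coverage_score(cone, hit_nodes)
        null = permutation_null(
            network,
            node,
            hit_count=len(hit_nodes),
            observed=score,
            n_permutations=n_permutations,
            rng=rng,
            radius=radius,
            cone=cone,
        )
        candidates.append(
            MRCandidate(
                node=node,
                radius=radius,
                reached_hits=reached,
                score=score,
                z_score=null.z_score,
                p_value=null.p_value,
                degenerate=null.degenerate,
            )
        )

    _, qvals, _, _ = multipletests([c.p_value for c in candidates], method="fdr_bh")
    for cand, q in zip(candidates, qvals):
        cand.adj_p_value = float(q)

    kept = [
        c
        for c in candidates
        if c.score >= score_min and c.z_score >= z_min and c.adj_p_value <= fdr_max
    ]
    kept.sort(key=lambda c: (-c.score, -c.z_score, c.node))
    return kept
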