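"""Topological feature computation for mapped pathway instances.

Features describe how a pathway's member set S sits inside a seasonal
correlation network: per-node structural properties aggregated over S (on
the full network and on the conjunctive subgraph), edge betweenness over
the subgraph's links, link-prediction style pair measures over all
unordered member pairs, neighborhood set-cardinalities, community
co-residence, and scalar descriptors of the conjunctive and extended
subgraphs.

Distance conventions: hop counts by default; cost-weighted variants use
``cost = 1 - |r|`` so that strong correlations act as short distances
(signed weights would break shortest-path semantics).  Unreachable node
pairs get the sentinel distance ``|V|``.  Scalars that are mathematically
undefined on a degenerate subgraph (assortativity of a uniform-degree
graph, transitivity with no connected triple, ...) are emitted as 0 with
the corresponding ``missing_mask`` flag set, so the downstream learner
always sees finite values.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .catalog import FeatureCatalog, FeatureSpec, default_catalog
from .netbuild import CorrelationNetwork
from .pathmap import PathwayInstance, Subgraph, conjunctive_subgraph, extended_subgraph

__all__ = [
    "FeatureVector",
    "NeighborhoodFeatures",
    "CommunityFeatures",
    "SubgraphScalars",
    "node_property",
    "edge_betweenness",
    "pair_properties",
    "aggregate",
    "neighborhood_features",
    "detect_communities",
    "community_features",
    "subgraph_scalars",
    "featurize",
    "NetworkFeatureCache",
]


@dataclass
class FeatureVector:
    """Ordered per-instance feature values (catalog order x season order)."""

    instance_id: str
    values: np.ndarray
    missing_mask: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.values) == len(self.missing_mask) == len(self.names)):
            raise ValueError("values, mask and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (sentinel policy)")


@dataclass(frozen=True)
class NeighborhoodFeatures:
    intersection: int
    union: int
    distinct: int
    mixed: int


@dataclass(frozen=True)
class CommunityFeatures:
    co_residence_ratio: float
    n_communities_sg: int
    modularity_sg: float
    modularity_defined: bool


@dataclass(frozen=True)
class SubgraphScalars:
    diameter: float
    diameter_centrality: float
    global_clustering: float
    assortativity: float
    density: float
    #: per-scalar defined flags, same order as the fields above
    defined: tuple[bool, bool, bool, bool, bool]


# ---------------------------------------------------------------------------
# node properties


def _hop_lengths(graph: nx.Graph, source) -> dict:
    return nx.single_source_shortest_path_length(graph, source)


def _closeness(graph: nx.Graph, weight: str | None) -> dict:
    n = graph.number_of_nodes()
    out = {}
    for v in graph:
        if weight is None:
            lengths = _hop_lengths(graph, v)
        else:
            lengths = nx.single_source_dijkstra_path_length(graph, v, weight=weight)
        total = sum(lengths.get(u, n) for u in graph if u != v)
        out[v] = (n - 1) / total if total > 0 else 0.0
    return out


def _stress_centrality(graph: nx.Graph) -> dict:
    """Stress: number of shortest paths passing through each node.

    Counts each unordered endpoint pair {s, t} (s, t != v) once, summing
    sigma_st(v) = sigma_sv * sigma_vt over pairs with
    d(s, v) + d(v, t) = d(s, t).
    """
    nodes = list(graph)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[u] for u in graph.neighbors(v)] for v in nodes]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if not np.isfinite(dist[s, w]):
                    dist[s, w] = dist[s, v] + 1
                    queue.append(w)
                if dist[s, w] == dist[s, v] + 1:
                    sigma[s, w] += sigma[s, v]
    stress = {}
    for vi, v in enumerate(nodes):
        dv = dist[:, vi]
        through = (dv[:, None] + dv[None, :]) == dist
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        mask = through & np.isfinite(dist)
        mask[vi, :] = False
        mask[:, vi] = False
        np.fill_diagonal(mask, False)
        stress[v] = float(counts[mask].sum() / 2.0)
    return stress


def node_property(graph: nx.Graph, prop: str, weighting: str = "unweighted") -> dict:
    """Per-node value of a supported structural property."""
    key = (prop, weighting)
    if key == ("degree", "unweighted"):
        return dict(graph.degree())
    if key == ("weighted_degree", "signed"):
        return {v: sum(d.get("weight", 1.0) for _, _, d in graph.edges(v, data=True))
                for v in graph}
    if key == ("weighted_degree", "absolute"):
        return {v: sum(abs(d.get("weight", 1.0)) for _, _, d in graph.edges(v, data=True))
                for v in graph}
    if key == ("closeness", "unweighted"):
        return _closeness(graph, None)
    if key == ("closeness", "cost"):
        return _closeness(graph, "cost")
    if key == ("betweenness", "unweighted"):
        return nx.betweenness_centrality(graph, normalized=False)
    if key == ("betweenness", "cost"):
        return nx.betweenness_centrality(graph, normalized=False, weight="cost")
    if key == ("stress", "unweighted"):
        return _stress_centrality(graph)
    if key == ("clustering", "unweighted"):
        return nx.clustering(graph)
    if key == ("clustering", "absolute"):
        return nx.clustering(graph, weight="absweight")
    raise ValueError(f"unsupported node property {prop!r} with weighting {weighting!r}")


def edge_betweenness(graph: nx.Graph, weighting: str = "unweighted") -> dict:
    """Edge betweenness keyed by frozenset endpoint pair (pairs counted once)."""
    weight = None if weighting == "unweighted" else "cost"
    eb = nx.edge_betweenness_centrality(graph, normalized=False, weight=weight)
    return {frozenset(e): val for e, val in eb.items()}


# ---------------------------------------------------------------------------
# pair measures


def pair_properties(
    graph: nx.Graph,
    u,
    v,
    hop_dist: Mapping | None = None,
) -> tuple[float, float, float, float]:
    """(geodesic, jaccard, preferential attachment, friends) for a node pair.

    geodesic is the hop distance with sentinel |V| when unreachable;
    friends counts pairs (x, y) in Gamma(u) x Gamma(v) that coincide or are
    themselves linked.
    """
    if u == v:
        raise ValueError("pair measures need two distinct nodes")
    n = graph.number_of_nodes()
    if hop_dist is not None:
        geo = float(hop_dist.get(u, {}).get(v, n))
    else:
        try:
            geo = float(nx.shortest_path_length(graph, u, v))
        except nx.NetworkXNoPath:
            geo = float(n)
    gu, gv = set(graph.neighbors(u)), set(graph.neighbors(v))
    union = gu | gv
    jaccard = len(gu & gv) / len(union) if union else 0.0
    pref = float(len(gu) * len(gv))
    friends = 0
    for x in gu:
        for y in gv:
            if x == y or graph.has_edge(x, y):
                friends += 1
    return geo, jaccard, pref, float(friends)


def aggregate(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(sum, mean, m2, m3, m4) with population central moments."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty value list")
    mean = float(arr.mean())
    dev = arr - mean
    return (float(arr.sum()), mean, float(np.mean(dev ** 2)),
            float(np.mean(dev ** 3)), float(np.mean(dev ** 4)))


# ---------------------------------------------------------------------------
# neighborhood set-features


def neighborhood_features(graph: nx.Graph, s: Iterable) -> NeighborhoodFeatures:
    """Intersection / Union / Distinct / Mixed over member neighborhoods.

    Distinct counts nodes adjacent to exactly one member of S; Mixed (nodes
    adjacent to more than one member but not all) follows as U - I - D.
    """
    members = list(dict.fromkeys(s))
    if len(members) < 2:
        raise ValueError("neighborhood features need |S| >= 2")
    hoods = [set(graph.neighbors(v)) for v in members]
    union = set().union(*hoods)
    inter = set.intersection(*hoods)
    distinct = sum(1 for u in union if sum(u in h for h in hoods) == 1)
    return NeighborhoodFeatures(len(inter), len(union), distinct,
                                len(union) - len(inter) - distinct)


# ---------------------------------------------------------------------------
# community detection


def detect_communities(graph: nx.Graph, algorithm: str, seed: int = 0) -> list[set]:
    """Partition a graph's nodes into communities (unweighted topology).

    Edgeless graphs fall back to singleton communities; leading eigenvector
    is run on the largest connected component with singletons for the rest.
    """
    nodes = list(graph)
    if not nodes:
        return []
    if graph.number_of_edges() == 0:
        return [{v} for v in nodes]
    if algorithm == "leading_eigenvector":
        components = sorted(nx.connected_components(graph), key=len, reverse=True)
        giant = components[0]
        rest = [{v} for comp in components[1:] for v in comp]
        if len(giant) == 1:
            return [{v} for v in nodes]
        sub = graph.subgraph(giant)
        return _igraph_partition(sub, algorithm, seed) + rest
    return _igraph_partition(graph, algorithm, seed)


def _igraph_partition(graph: nx.Graph, algorithm: str, seed: int) -> list[set]:
    nodes = list(graph)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges()])
    ig.set_random_number_generator(random.Random(seed))
    if algorithm == "edge_betweenness":
        clustering = g.community_edge_betweenness().as_clustering()
    elif algorithm == "leading_eigenvector":
        opts = ig.ARPACKOptions()
        opts.maxiter = 500_000
        try:
            clustering = g.community_leading_eigenvector(arpack_options=opts)
        except ig.InternalError:
            # ARPACK occasionally fails to converge on near-degenerate
            # modularity matrices; fall back to greedy modularity
            # agglomeration for this graph (deterministic)
            clustering = g.community_fastgreedy().as_clustering()
    elif algorithm == "walktrap":
        clustering = g.community_walktrap().as_clustering()
    elif algorithm == "fast_greedy":
        clustering = g.community_fastgreedy().as_clustering()
    else:
        raise ValueError(f"unknown community algorithm {algorithm!r}")
    return [{nodes[i] for i in comm} for comm in clustering]


def community_features(
    graph: nx.Graph,
    s: Iterable,
    algorithm: str,
    full_partition: list[set] | None = None,
    seed: int = 0,
) -> CommunityFeatures:
    """Community co-residence of S plus the subgraph's own community structure.

    The co-residence ratio MAX_k |C_k intersect S| / |S| uses the partition
    of the full network; the community count and modularity are computed on
    the conjunctive subgraph's own partition.
    """
    members = set(s)
    if not members <= set(graph.nodes):
        raise ValueError("S must be a subset of the graph's nodes")
    if full_partition is None:
        full_partition = detect_communities(graph, algorithm, seed)
    ratio = max((len(c & members) for c in full_partition), default=0) / max(len(members), 1)
    sg = nx.Graph(graph.subgraph(members))
    sg_partition = detect_communities(sg, algorithm, seed)
    if sg.number_of_edges() > 0:
        modularity = float(nx.algorithms.community.modularity(sg, sg_partition))
        defined = True
    else:
        modularity, defined = 0.0, False
    return CommunityFeatures(float(ratio), len(sg_partition), modularity, defined)


# ---------------------------------------------------------------------------
# subgraph scalars


def subgraph_scalars(subgraph: Subgraph | nx.Graph) -> SubgraphScalars:
    """Diameter, mean eccentricity, transitivity, assortativity, density."""
    g = subgraph.graph if isinstance(subgraph, Subgraph) else subgraph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty subgraph")
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    if m == 0:
        return SubgraphScalars(0.0, 0.0, 0.0, 0.0, density,
                               (False, False, False, False, True))
    # eccentricity restricted to reachable nodes (largest finite value)
    ecc = []
    for v in g:
        lengths = _hop_lengths(g, v)
        ecc.append(max(lengths.values()))
    diameter = float(max(ecc))
    diameter_centrality = float(np.mean(ecc))
    triples = sum(d * (d - 1) / 2 for _, d in g.degree())
    if triples > 0:
        transitivity, trans_ok = float(nx.transitivity(g)), True
    else:
        transitivity, trans_ok = 0.0, False
    with np.errstate(invalid="ignore", divide="ignore"):
        assort = nx.degree_assortativity_coefficient(g)
    if np.isfinite(assort):
        assortativity, assort_ok = float(assort), True
    else:
        assortativity, assort_ok = 0.0, False
    return SubgraphScalars(diameter, diameter_centrality, transitivity,
                           assortativity, density,
                           (True, True, trans_ok, assort_ok, True))


# ---------------------------------------------------------------------------
# per-network caches and the featurizer


class NetworkFeatureCache:
    """Lazy cache of whole-network quantities reused across instances."""

    def __init__(self, network: CorrelationNetwork, seed: int = 0):
        self.network = network
        self.seed = seed
        self._node_values: dict = {}
        self._edge_betweenness: dict | None = None
        self._hop_dist: dict | None = None
        self._partitions: dict = {}

    def node_values(self, prop: str, weighting: str) -> dict:
        key = (prop, weighting)
        if key not in self._node_values:
            self._node_values[key] = node_property(self.network.graph, prop, weighting)
        return self._node_values[key]

    def edge_betweenness_values(self) -> dict:
        if self._edge_betweenness is None:
            self._edge_betweenness = edge_betweenness(self.network.graph)
        return self._edge_betweenness

    def hop_distances(self) -> dict:
        if self._hop_dist is None:
            self._hop_dist = dict(nx.all_pairs_shortest_path_length(self.network.graph))
        return self._hop_dist

    def partition(self, algorithm: str) -> list[set]:
        if algorithm not in self._partitions:
            self._partitions[algorithm] = detect_communities(
                self.network.graph, algorithm, self.seed)
        return self._partitions[algorithm]


_SCALAR_INDEX = {"diameter": 0, "diameter_centrality": 1, "global_clustering": 2,
                 "assortativity": 3, "density": 4}
_AGG_INDEX = {"sum": 0, "mean": 1, "m2": 2, "m3": 3, "m4": 4}


class _InstanceContext:
    """Per-(instance, season) computation state shared across catalog specs."""

    def __init__(self, instance: PathwayInstance, network: CorrelationNetwork,
                 cache: NetworkFeatureCache):
        self.network = network
        self.cache = cache
        self.s = sorted(instance.node_set)
        self.sg = conjunctive_subgraph(network, self.s)
        self.esg = extended_subgraph(network, self.s)
        self._node_aggs: dict = {}
        self._edge_aggs: dict = {}
        self._pair_aggs: dict = {}
        self._community: dict = {}
        self._scalars: dict = {}
        self._neighborhood: NeighborhoodFeatures | None = None

    def node_agg(self, prop: str, scope: str, weighting: str) -> tuple:
        key = (prop, scope, weighting)
        if key not in self._node_aggs:
            if scope == "full_graph":
                values = self.cache.node_values(prop, weighting)
                vals = [values[v] for v in self.s]
            else:
                values = node_property(self.sg.graph, prop, weighting)
                vals = [values[v] for v in self.s]
            self._node_aggs[key] = aggregate(vals)
        return self._node_aggs[key]

    def edge_agg(self, scope: str) -> tuple | None:
        if scope not in self._edge_aggs:
            edges = [frozenset(e) for e in self.sg.graph.edges()]
            if not edges:
                self._edge_aggs[scope] = None
            elif scope == "full_graph":
                eb = self.cache.edge_betweenness_values()
                self._edge_aggs[scope] = aggregate([eb[e] for e in edges])
            else:
                eb = edge_betweenness(self.sg.graph)
                self._edge_aggs[scope] = aggregate([eb[e] for e in edges])
        return self._edge_aggs[scope]

    def pair_agg(self, prop: str) -> tuple:
        if not self._pair_aggs:
            hop = self.cache.hop_distances()
            g = self.network.graph
            cols = {p: [] for p in ("geodesic", "jaccard", "pref_attachment", "friends")}
            for i in range(len(self.s)):
                for j in range(i + 1, len(self.s)):
                    geo, jac, pref, friends = pair_properties(g, self.s[i], self.s[j], hop)
                    cols["geodesic"].append(geo)
                    cols["jaccard"].append(jac)
                    cols["pref_attachment"].append(pref)
                    cols["friends"].append(friends)
            for p, vals in cols.items():
                self._pair_aggs[p] = aggregate(vals)
        return self._pair_aggs[prop]

    def neighborhood(self) -> NeighborhoodFeatures:
        if self._neighborhood is None:
            self._neighborhood = neighborhood_features(self.network.graph, self.s)
        return self._neighborhood

    def community(self, algorithm: str) -> CommunityFeatures:
        if algorithm not in self._community:
            self._community[algorithm] = community_features(
                self.network.graph, self.s, algorithm,
                full_partition=self.cache.partition(algorithm), seed=self.cache.seed)
        return self._community[algorithm]

    def scalars(self, scope: str) -> SubgraphScalars:
        if scope not in self._scalars:
            sub = self.sg if scope == "conjunctive" else self.esg
            self._scalars[scope] = subgraph_scalars(sub)
        return self._scalars[scope]


def _evaluate_spec(spec: FeatureSpec, ctx: _InstanceContext) -> tuple[float, bool]:
    """Return (value, masked) for one catalog entry."""
    if spec.family == "node_agg":
        return ctx.node_agg(spec.property, spec.scope, spec.weighting)[_AGG_INDEX[spec.aggregator]], False
    if spec.family == "edge_agg":
        aggs = ctx.edge_agg(spec.scope)
        if aggs is None:
            return 0.0, True
        return aggs[_AGG_INDEX[spec.aggregator]], False
    if spec.family == "pair_agg":
        return ctx.pair_agg(spec.property)[_AGG_INDEX[spec.aggregator]], False
    if spec.family == "neighborhood":
        nf = ctx.neighborhood()
        return float(getattr(nf, spec.property)), False
    if spec.family == "community":
        alg, prop = spec.property.split(":")
        cf = ctx.community(alg)
        if prop == "co_residence":
            return cf.co_residence_ratio, False
        if prop == "n_communities":
            return float(cf.n_communities_sg), False
        return cf.modularity_sg, not cf.modularity_defined
    if spec.family == "subgraph_scalar":
        sc = ctx.scalars(spec.scope)
        idx = _SCALAR_INDEX[spec.property]
        value = (sc.diameter, sc.diameter_centrality, sc.global_clustering,
                 sc.assortativity, sc.density)[idx]
        return value, not sc.defined[idx]
    raise ValueError(f"unknown feature family {spec.family!r}")


def featurize(
    instance: PathwayInstance,
    networks: Sequence[CorrelationNetwork],
    catalog: FeatureCatalog | None = None,
    caches: Mapping[str, NetworkFeatureCache] | None = None,
) -> FeatureVector:
    """Evaluate the full catalog on every seasonal network and concatenate.

    Season blocks follow the order of ``networks``; feature names are
    suffixed ``__<season>``.  Raises on ineligible instances.
    """
    if not instance.eligible:
        raise ValueError(f"instance {instance.instance_id} is not eligible (|S| < 2)")
    if catalog is None:
        catalog = default_catalog()
    values: list[float] = []
    mask: list[bool] = []
    names: list[str] = []
    for network in networks:
        cache = (caches or {}).get(network.season_label) or NetworkFeatureCache(network)
        ctx = _InstanceContext(instance, network, cache)
        for spec in catalog:
            val, masked = _evaluate_spec(spec, ctx)
            values.append(float(val))
            mask.append(masked)
            names.append(f"{spec.name}__{network.season_label}")
    return FeatureVector(instance.instance_id, np.array(values), np.array(mask), tuple(names))


def feature_names(catalog: FeatureCatalog, networks: Sequence[CorrelationNetwork]) -> list[str]:
    return [f"{spec.name}__{net.season_label}" for net in networks for spec in catalog]
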