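"""The per-network feature catalog.

Each seasonal network contributes a fixed, ordered list of 148 named
features per pathway instance.  The catalog is generated from a grammar of
(property x scope x weighting x aggregator) for the node/edge/pair
families, plus the neighborhood set-features, the community features, and
the subgraph scalars:

* node family: 10 property-variants x 2 scopes (full graph, conjunctive
  subgraph) x 5 aggregators (sum, mean, central moments 2-4)  = 100
* edge betweenness: 2 scopes x 5 aggregators                  =  10
* pair measures: 4 properties x sum/mean/m2                   =  12
* neighborhood: intersection, union, distinct, mixed          =   4
* community: 4 algorithms x (co-residence ratio, community
  count of SG, modularity of SG)                              =  12
* subgraph scalars: 5 scalars x (SG, ESG)                     =  10

The canonical order is the construction order above; it is frozen by the
round-trip tests and by the manifest serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import sha256
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "FeatureSpec",
    "FeatureCatalog",
    "default_catalog",
    "write_catalog",
    "read_catalog",
    "NODE_PROPERTY_VARIANTS",
    "COMMUNITY_ALGORITHMS",
    "SUBGRAPH_SCALARS",
]

AGGREGATORS = ("sum", "mean", "m2", "m3", "m4")

#: (property, weighting) pairs for per-node structural measures.
NODE_PROPERTY_VARIANTS: tuple[tuple[str, str], ...] = (
    ("degree", "unweighted"),
    ("weighted_degree", "signed"),
    ("weighted_degree", "absolute"),
    ("closeness", "unweighted"),
    ("closeness", "cost"),
    ("betweenness", "unweighted"),
    ("betweenness", "cost"),
    ("stress", "unweighted"),
    ("clustering", "unweighted"),
    ("clustering", "absolute"),
)

PAIR_PROPERTIES = ("geodesic", "jaccard", "pref_attachment", "friends")
PAIR_AGGREGATORS = ("sum", "mean", "m2")
NEIGHBORHOOD_PROPERTIES = ("intersection", "union", "distinct", "mixed")
COMMUNITY_ALGORITHMS = ("edge_betweenness", "leading_eigenvector", "walktrap", "fast_greedy")
COMMUNITY_PROPERTIES = (("co_residence", "full_graph"),
                        ("n_communities", "conjunctive"),
                        ("modularity", "conjunctive"))
SUBGRAPH_SCALARS = ("diameter", "diameter_centrality", "global_clustering",
                    "assortativity", "density")

_SCOPE_TOKEN = {"full_graph": "full", "conjunctive": "sg", "extended": "esg"}


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str       # node_agg | edge_agg | pair_agg | neighborhood | community | subgraph_scalar
    property: str
    scope: str        # full_graph | conjunctive | extended
    weighting: str    # unweighted | signed | absolute | cost
    aggregator: str   # sum | mean | m2 | m3 | m4 | none


@dataclass
class FeatureCatalog:
    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def per_network_count(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def manifest_hash(self) -> str:
        return sha256(manifest_text(self).encode()).hexdigest()


def _name(prop: str, weighting: str, scope: str, aggregator: str) -> str:
    base = prop if weighting == "unweighted" else f"{prop}_{weighting}"
    parts = [base, _SCOPE_TOKEN[scope]]
    if aggregator != "none":
        parts.append(aggregator)
    return "__".join(parts)


def default_catalog() -> FeatureCatalog:
    specs: list[FeatureSpec] = []
    for prop, weighting in NODE_PROPERTY_VARIANTS:
        for scope in ("full_graph", "conjunctive"):
            for agg in AGGREGATORS:
                specs.append(FeatureSpec(_name(prop, weighting, scope, agg),
                                         "node_agg", prop, scope, weighting, agg))
    for scope in ("full_graph", "conjunctive"):
        for agg in AGGREGATORS:
            specs.append(FeatureSpec(_name("edge_betweenness", "unweighted", scope, agg),
                                     "edge_agg", "edge_betweenness", scope, "unweighted", agg))
    for prop in PAIR_PROPERTIES:
        for agg in PAIR_AGGREGATORS:
            specs.append(FeatureSpec(_name(prop, "unweighted", "full_graph", agg),
                                     "pair_agg", prop, "full_graph", "unweighted", agg))
    for prop in NEIGHBORHOOD_PROPERTIES:
        specs.append(FeatureSpec(_name(prop, "unweighted", "full_graph", "none"),
                                 "neighborhood", prop, "full_graph", "unweighted", "none"))
    for alg in COMMUNITY_ALGORITHMS:
        for prop, scope in COMMUNITY_PROPERTIES:
            specs.append(FeatureSpec(_name(f"community_{alg}_{prop}", "unweighted", scope, "none"),
                                     "community", f"{alg}:{prop}", scope, "unweighted", "none"))
    for scalar in SUBGRAPH_SCALARS:
        for scope in ("conjunctive", "extended"):
            specs.append(FeatureSpec(_name(scalar, "unweighted", scope, "none"),
                                     "subgraph_scalar", scalar, scope, "unweighted", "none"))
    return FeatureCatalog(tuple(specs))


def manifest_text(catalog: FeatureCatalog) -> str:
    lines = ["name\tfamily\tproperty\tscope\tweighting\taggregator"]
    for s in catalog:
        lines.append("\t".join((s.name, s.family, s.property, s.scope, s.weighting, s.aggregator)))
    return "\n".join(lines) + "\n"


def write_catalog(catalog: FeatureCatalog, path: str | Path) -> None:
    Path(path).write_text(manifest_text(catalog))


def read_catalog(path: str | Path) -> FeatureCatalog:
    specs = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        name, family, prop, scope, weighting, agg = line.split("\t")
        specs.append(FeatureSpec(name, family, prop, scope, weighting, agg))
    return FeatureCatalog(tuple(specs))
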