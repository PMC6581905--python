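"""Mapping pathway compound sets onto correlation networks.

A pathway is treated purely as a set of compounds.  Its mapped instance is
the subset S of canonicalized compounds found in the common metabolite set
(the intersection of all seasonal node sets); an instance is eligible for
feature computation when |S| >= 2.  Two induced subgraphs represent the
instance in each season: the conjunctive subgraph (S and the edges among
its members) and the extended subgraph (S plus all neighbors of members,
with all edges among them).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .netbuild import CorrelationNetwork

__all__ = [
    "Pathway",
    "PathwayInstance",
    "Subgraph",
    "canonicalize_compound",
    "read_synonyms",
    "read_pathways",
    "write_instances",
    "map_pathway",
    "conjunctive_subgraph",
    "extended_subgraph",
    "generate_random_sets",
    "coverage_ks",
]

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
    "ε": "epsilon", "ω": "omega",
}

_SOURCES = {"positive_collection", "negative_collection", "candidate", "random"}


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    source: str
    compounds: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError(f"pathway {self.pathway_id} has no compounds")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown pathway source {self.source!r}")


@dataclass
class PathwayInstance:
    """A pathway mapped against the common metabolite set.

    ``node_set`` (S) is identical across seasons because it is defined
    against the season intersection; ``coverage`` is |S| divided by the
    number of listed compounds.
    """

    pathway: Pathway
    node_set: frozenset[str]
    coverage: float
    eligible: bool

    @property
    def instance_id(self) -> str:
        return self.pathway.pathway_id

    @property
    def size(self) -> int:
        return len(self.node_set)


@dataclass
class Subgraph:
    kind: str  # "conjunctive" | "extended"
    graph: nx.Graph
    parent_season: str


def canonicalize_compound(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Deterministic compound-name normalization.

    Case-folds, trims/collapses whitespace, and spells out Greek-letter
    prefixes ("β-Alanine" -> "beta-alanine"); an optional synonym table is
    applied last, itself keyed by canonical names.
    """
    s = re.sub(r"\s+", " ", name.strip()).casefold()
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin)
    if synonyms:
        s = synonyms.get(s, s)
    return s


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Two-column delimited synonym table (alias, canonical)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, canonical = re.split(r"[\t,]", line)[:2]
            table[canonicalize_compound(alias)] = canonicalize_compound(canonical)
    return table


def read_pathways(path: str | Path) -> list[Pathway]:
    """Read pathway definitions.

    Delimited format: columns pathway_id, name, source, compounds with the
    compound list semicolon-separated.  A ``.json`` file with a list of
    objects carrying the same keys is accepted equivalently.
    """
    path = Path(path)
    records: list[Pathway] = []
    if path.suffix.lower() == ".json":
        for obj in json.loads(path.read_text()):
            records.append(Pathway(str(obj["pathway_id"]), str(obj["name"]),
                                   str(obj["source"]), tuple(obj["compounds"])))
        return records
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if header is None:
                header = [p.strip().lower() for p in parts]
                continue
            row = dict(zip(header, parts))
            compounds = tuple(c for c in row["compounds"].split(";") if c.strip())
            records.append(Pathway(row["pathway_id"], row.get("name", row["pathway_id"]),
                                   row["source"], compounds))
    return records


def write_instances(instances: Sequence[PathwayInstance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\teligible\tsize\tcoverage\tmembers\n")
        for inst in instances:
            fh.write("%s\t%s\t%d\t%r\t%s\n" % (
                inst.instance_id, inst.eligible, inst.size, inst.coverage,
                ";".join(sorted(inst.node_set))))


def map_pathway(
    pathway: Pathway,
    networks: Sequence[CorrelationNetwork],
    common: set[str] | frozenset[str],
    synonyms: Mapping[str, str] | None = None,
    exclude: Iterable[str] | None = None,
) -> PathwayInstance:
    """Map a pathway's compounds onto the common metabolite set.

    Compounds are canonicalized (optional user exclusion list honored
    first), deduplicated, then matched against the canonical forms of the
    common metabolite ids; matched members keep the panel's original ids.
    The instance is eligible iff at least two compounds are found.
    """
    if not networks:
        raise ValueError("need at least one network")
    excluded = {canonicalize_compound(c, synonyms) for c in (exclude or ())}
    canon = []
    for c in pathway.compounds:
        cc = canonicalize_compound(c, synonyms)
        if cc not in excluded and cc not in canon:
            canon.append(cc)
    common_by_canon = {canonicalize_compound(m, synonyms): m for m in common}
    s = frozenset(common_by_canon[c] for c in canon if c in common_by_canon)
    coverage = len(s) / len(canon) if canon else 0.0
    return PathwayInstance(pathway, s, coverage, eligible=len(s) >= 2)


def conjunctive_subgraph(network: CorrelationNetwork, s: Iterable[str]) -> Subgraph:
    """SG: the subgraph induced by S alone, edge weights preserved."""
    s = set(s)
    if not s <= network.nodes:
        raise ValueError(f"nodes outside network: {sorted(s - network.nodes)}")
    return Subgraph("conjunctive", nx.Graph(network.graph.subgraph(s)), network.season_label)


def extended_subgraph(network: CorrelationNetwork, s: Iterable[str]) -> Subgraph:
    """ESG: the subgraph induced by S plus every neighbor of an S member.

    S itself is always included, so pathway members isolated in the season
    network are not dropped.
    """
    s = set(s)
    if not s <= network.nodes:
        raise ValueError(f"nodes outside network: {sorted(s - network.nodes)}")
    nodes = set(s)
    for v in s:
        nodes |= network.neighborhood(v)
    return Subgraph("extended", nx.Graph(network.graph.subgraph(nodes)), network.season_label)


def generate_random_sets(
    common: Iterable[str],
    count: int,
    size_min: int = 2,
    size_max: int = 18,
    seed: int | np.random.Generator = 0,
    exclude: Iterable[Iterable[str]] | None = None,
    id_prefix: str = "RAND",
) -> list[PathwayInstance]:
    """Random metabolite subsets of the common set, used as non-pathways.

    Each set's size is uniform on [size_min, size_max] and its members are
    drawn uniformly without replacement from the common set; any draw equal
    (as a set) to an excluded composition is redrawn.
    """
    pool = sorted(str(m) for m in common)
    if size_max > len(pool):
        raise ValueError("size_max exceeds the common metabolite set")
    if size_min < 1 or size_min > size_max:
        raise ValueError("invalid size range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excluded = {frozenset(e) for e in (exclude or ())}
    out: list[PathwayInstance] = []
    width = max(4, len(str(count)))
    while len(out) < count:
        size = int(rng.integers(size_min, size_max + 1))
        members = frozenset(rng.choice(pool, size=size, replace=False).tolist())
        if members in excluded:
            continue
        pid = f"{id_prefix}{len(out):0{width}d}"
        pw = Pathway(pid, pid, "random", tuple(sorted(members)))
        out.append(PathwayInstance(pw, members, 1.0, eligible=True))
    return out


def coverage_ks(coverages_a: Sequence[float], coverages_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of coverage lists."""
    if len(coverages_a) == 0 or len(coverages_b) == 0:
        raise ValueError("empty coverage list")
    res = stats.ks_2samp(coverages_a, coverages_b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
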