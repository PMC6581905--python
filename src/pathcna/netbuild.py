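"""Construction of weighted metabolite correlation networks.

A correlation network (CN) for one growing season is an undirected graph
whose nodes are the metabolites of that season's profile table and whose
edges carry the Pearson correlation coefficient ``r`` between the abundance
profiles of the two endpoint metabolites, negative values included.  Edges
whose correlation fails either the magnitude filter (``|r| > r_threshold``)
or the significance filter (``p < p_threshold``) are removed as spurious;
metabolites left without any edge remain as isolated nodes so that the node
set always equals the metabolite panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileMatrix",
    "CorrelationEstimate",
    "CorrelationNetwork",
    "read_profiles",
    "aggregate_replicates",
    "correlation_table",
    "build_network",
    "common_metabolites",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
    "read_edgelist",
]

#: Minimum number of pairwise-complete observations for a correlation to be
#: reported at all (keeps the t test at >= 2 degrees of freedom).
MIN_COMPLETE_PAIRS = 4


@dataclass
class ProfileMatrix:
    """A samples x metabolites abundance table for one season.

    ``data`` is a pandas DataFrame indexed by sample (or line) identifier
    with one column per metabolite; missing measurements are NaN.
    """

    data: pd.DataFrame
    season_label: str = "season"

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("profile matrix needs at least 2 samples and 2 metabolites")
        if self.data.columns.duplicated().any():
            raise ValueError("metabolite identifiers must be unique")
        if self.data.isna().all(axis=0).any():
            bad = self.data.columns[self.data.isna().all(axis=0)].tolist()
            raise ValueError(f"metabolites with no measurements: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def metabolite_ids(self) -> list[str]:
        return [str(m) for m in self.data.columns]


@dataclass(frozen=True)
class CorrelationEstimate:
    """Pearson correlation between two metabolites on pairwise-complete samples."""

    metabolite_a: str
    metabolite_b: str
    r: float
    p: float
    n_pairs: int


@dataclass
class CorrelationNetwork:
    """A season's thresholded correlation network.

    The underlying ``networkx.Graph`` stores, per edge, the signed
    correlation as ``weight``, its p-value as ``pvalue``, and two derived
    attributes used by distance-based features: ``absweight`` = |r| and
    ``cost`` = 1 - |r| (strong correlation = short distance).
    """

    season_label: str
    graph: nx.Graph
    r_threshold: float = 0.3
    p_threshold: float = 0.01

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighborhood(self, v: str) -> set[str]:
        """Gamma(v): all metabolites significantly correlated with v."""
        return set(self.graph.neighbors(v))


def read_profiles(path: str | Path, season_label: str | None = None) -> ProfileMatrix:
    """Read a delimited profile table (first column sample id, header row metabolites)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["", "NA", "NaN", "nan"])
    df = df.apply(pd.to_numeric, errors="coerce")
    return ProfileMatrix(df, season_label or path.stem)


def write_profiles(profile: ProfileMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    profile.data.to_csv(path, sep=sep, na_rep="NA")


def aggregate_replicates(raw: ProfileMatrix, grouping: Mapping[str, str]) -> ProfileMatrix:
    """Average biological replicates into one row per genotype line.

    ``grouping`` maps every sample id to its line id; cells average the
    non-missing replicate values, and a cell whose replicates are all
    missing stays missing.
    """
    if not grouping:
        raise ValueError("empty replicate grouping")
    missing = [s for s in raw.data.index if s not in grouping]
    if missing:
        raise ValueError(f"samples without line assignment: {missing}")
    lines = pd.Series({s: grouping[s] for s in raw.data.index})
    agg = raw.data.groupby(lines).mean()
    agg.index.name = raw.data.index.name
    return ProfileMatrix(agg, raw.season_label)


def correlation_table(profile: ProfileMatrix) -> list[CorrelationEstimate]:
    """All-pairs Pearson correlations on pairwise-complete observations.

    Pairs with fewer than ``MIN_COMPLETE_PAIRS`` complete observations or
    zero variance in either column are omitted rather than reported.  The
    p-value is the two-sided test from the t statistic with n-2 degrees of
    freedom, as given by :func:`scipy.stats.pearsonr`.
    """
    values = profile.data.to_numpy(dtype=float)
    mets = profile.metabolite_ids
    if len(mets) < 2:
        raise ValueError("need at least 2 metabolites")
    finite = np.isfinite(values)
    if finite.all():
        return _correlation_table_complete(values, mets)
    out: list[CorrelationEstimate] = []
    for i in range(len(mets)):
        for j in range(i + 1, len(mets)):
            mask = finite[:, i] & finite[:, j]
            n = int(mask.sum())
            if n < MIN_COMPLETE_PAIRS:
                continue
            x, y = values[mask, i], values[mask, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r = float(res.statistic)
            if not np.isfinite(r):
                continue
            out.append(CorrelationEstimate(mets[i], mets[j], r, float(res.pvalue), n))
    return out


def _correlation_table_complete(values: np.ndarray, mets: list[str]) -> list[CorrelationEstimate]:
    """Vectorized all-pairs Pearson for tables without missing entries."""
    n = values.shape[0]
    if n < MIN_COMPLETE_PAIRS:
        return []
    sd = values.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    if len(usable) < 2:
        return []
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values[:, usable], rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    out: list[CorrelationEstimate] = []
    for ii in range(len(usable)):
        for jj in range(ii + 1, len(usable)):
            rij = float(r[ii, jj])
            if not np.isfinite(rij):
                continue
            if abs(rij) >= 1.0:
                p = 0.0
            else:
                t = abs(rij) * np.sqrt(df / (1.0 - rij * rij))
                p = float(2.0 * stats.t.sf(t, df))
            out.append(CorrelationEstimate(mets[usable[ii]], mets[usable[jj]], rij, p, n))
    return out


def build_network(
    estimates: Iterable[CorrelationEstimate],
    metabolites: Iterable[str],
    r_threshold: float = 0.3,
    p_threshold: float = 0.01,
    season_label: str = "season",
) -> CorrelationNetwork:
    """Threshold a correlation table into a network.

    An edge is retained iff ``|r| > r_threshold`` and ``p < p_threshold``;
    a correlation failing either criterion is treated as spurious.  Every
    metabolite of the panel becomes a node, so isolated nodes are kept.
    """
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    metabolites = [str(m) for m in metabolites]
    if not metabolites:
        raise ValueError("empty metabolite set")
    g = nx.Graph()
    g.add_nodes_from(metabolites)
    for est in estimates:
        if est.metabolite_a == est.metabolite_b:
            continue
        if abs(est.r) > r_threshold and est.p < p_threshold:
            g.add_edge(
                est.metabolite_a,
                est.metabolite_b,
                weight=float(est.r),
                pvalue=float(est.p),
                absweight=abs(float(est.r)),
                cost=1.0 - abs(float(est.r)),
            )
    return CorrelationNetwork(season_label, g, r_threshold, p_threshold)


def network_from_profile(
    profile: ProfileMatrix, r_threshold: float = 0.3, p_threshold: float = 0.01
) -> CorrelationNetwork:
    """Convenience: correlation table + thresholding in one call."""
    return build_network(
        correlation_table(profile),
        profile.metabolite_ids,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        season_label=profile.season_label,
    )


def common_metabolites(networks: Sequence[CorrelationNetwork]) -> set[str]:
    """Metabolites present (as nodes) in every seasonal network."""
    if not networks:
        raise ValueError("need at least one network")
    common = set(networks[0].nodes)
    for net in networks[1:]:
        common &= net.nodes
    return common


# ---------------------------------------------------------------------------
# serialization


def write_graphml(network: CorrelationNetwork, path: str | Path) -> None:
    g = network.graph.copy()
    g.graph["season_label"] = network.season_label
    g.graph["r_threshold"] = network.r_threshold
    g.graph["p_threshold"] = network.p_threshold
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> CorrelationNetwork:
    g = nx.read_graphml(str(path))
    meta = dict(g.graph)
    return CorrelationNetwork(
        season_label=str(meta.get("season_label", Path(path).stem)),
        graph=g,
        r_threshold=float(meta.get("r_threshold", 0.3)),
        p_threshold=float(meta.get("p_threshold", 0.01)),
    )


def write_edgelist(network: CorrelationNetwork, path: str | Path) -> None:
    """4-column TSV (a, b, r, p); isolated nodes listed in a trailing comment."""
    with open(path, "w") as fh:
        fh.write("# season=%s r_threshold=%r p_threshold=%r\n"
                 % (network.season_label, network.r_threshold, network.p_threshold))
        isolated = sorted(n for n in network.graph.nodes if network.graph.degree(n) == 0)
        fh.write("# isolated=%s\n" % ";".join(isolated))
        fh.write("a\tb\tr\tp\n")
        for a, b, d in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']!r}\t{d['pvalue']!r}\n")


def read_edgelist(path: str | Path) -> CorrelationNetwork:
    season, r_t, p_t, isolated = Path(path).stem, 0.3, 0.01, []
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# season="):
                parts = dict(tok.split("=", 1) for tok in line[2:].split())
                season = parts["season"]
                r_t, p_t = float(parts["r_threshold"]), float(parts["p_threshold"])
            elif line.startswith("# isolated="):
                payload = line.split("=", 1)[1]
                isolated = [n for n in payload.split(";") if n]
            elif line and not line.startswith("#") and not line.startswith("a\tb"):
                a, b, r, p = line.split("\t")
                r = float(r)
                g.add_edge(a, b, weight=r, pvalue=float(p),
                           absweight=abs(r), cost=1.0 - abs(r))
    g.add_nodes_from(isolated)
    return CorrelationNetwork(season, g, r_t, p_t)
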