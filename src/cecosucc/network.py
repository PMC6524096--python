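"""Spearman co-occurrence networks and consecutive-age persistence graphs.

Within an age stratum, OTUs above a mean relative-abundance floor (default
1%) are correlated pairwise with Spearman's rho (average ranks for ties) on
per-sample relative abundances. An edge is kept when |rho| exceeds a
threshold (default 0.7) and the two-sided p-value (t approximation,
df = n - 2) is below a cap (default 2.32e-5); the sign is retained so
negative co-occurrences stay visible. Persistence across two consecutive
ages is the intersection graph: shared nodes, and shared same-signed edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tableio import CountTable

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["otu_a", "otu_b", "rho", "sign", "p_value"]


@dataclass
class CooccurrenceNetwork:
    """Simple undirected graph of OTU co-occurrences at one age."""

    age: int
    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @classmethod
    def from_components(cls, age: int, nodes, edges) -> "CooccurrenceNetwork":
        """Build directly from node ids and (otu_a, otu_b, rho) triples."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, rho in edges:
            if g.has_edge(a, b):
                raise ValueError(f"duplicate edge {a}-{b}")
            g.add_edge(a, b, rho=float(rho),
                       sign=int(np.sign(rho)), p_value=np.nan)
        return cls(age=age, graph=g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"otu_a": min(u, v), "otu_b": max(u, v), **d}
                for u, v, d in self.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return df.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    mean_degree: float
    sd_degree: float
    normalized_degree: float
    mean_betweenness: float
    diameter: float          # weighted (edge length 1 - |rho|), largest component
    hop_diameter: int        # unweighted, largest component


# ---------------------------------------------------------------------------
# Construction


def abundance_filter(table: CountTable, age: int,
                     min_fraction: float = 0.01) -> CountTable:
    """Restrict to the age's samples and to OTUs whose mean relative
    abundance across those samples is strictly above ``min_fraction``."""
    ids = table.samples_at_age(age)
    sub = table.subset_samples(ids)
    rel = sub.relative_abundance()
    keep = rel.mean(axis=1) > min_fraction
    return sub.subset_otus(rel.index[keep])


def spearman_edge_table(filtered: CountTable, rho_threshold: float = 0.7,
                        p_threshold: float = 2.32e-5,
                        bh_correct: bool = False) -> pd.DataFrame:
    """All OTU pairs with |Spearman rho| > threshold and p below the cap.

    Returns a frame with columns ``otu_a, otu_b, rho, sign, p_value``,
    ordered by OTU id. Pairs involving a constant abundance vector have
    undefined rho and are skipped with a warning.
    """
    n = len(filtered.sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples to correlate")
    rel = filtered.relative_abundance()
    otus = list(rel.index)
    x = rel.to_numpy()
    constant = np.array([np.ptp(row) == 0 for row in x])
    if constant.any():
        logger.warning("spearman_edge_table: %d constant OTUs skipped: %s",
                       constant.sum(),
                       [o for o, c in zip(otus, constant) if c])
    ok = np.flatnonzero(~constant)
    if len(ok) < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    res = stats.spearmanr(x[ok].T)
    if len(ok) == 2:   # scipy returns scalars for a single pair
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        pval = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, pval = res.statistic, res.pvalue
    rows = []
    for ii in range(len(ok)):
        for jj in range(ii + 1, len(ok)):
            i, j = int(ok[ii]), int(ok[jj])
            r, p = float(rho[ii, jj]), float(pval[ii, jj])
            if abs(r) > rho_threshold and p < p_threshold:
                rows.append({"otu_a": otus[i], "otu_b": otus[j], "rho": r,
                             "sign": int(np.sign(r)), "p_value": p})
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if bh_correct and len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)


def build_network(edges: pd.DataFrame, filtered: CountTable,
                  age: int) -> CooccurrenceNetwork:
    """Assemble the co-occurrence graph for one age stratum.

    Nodes are all abundance-filtered OTUs (isolates included; metrics drop
    them by default), annotated with mean relative abundance and taxonomy.
    """
    rel = filtered.relative_abundance()
    g = nx.Graph(age=age)
    for otu in filtered.otu_ids:
        attrs = {"mean_abundance": float(rel.loc[otu].mean())}
        if filtered.taxonomy is not None:
            attrs["family"] = str(filtered.taxonomy.loc[otu].get("family", ""))
            attrs["genus"] = str(filtered.taxonomy.loc[otu].get("genus", ""))
        g.add_node(otu, **attrs)
    for _, row in edges.iterrows():
        a, b = row["otu_a"], row["otu_b"]
        for node in (a, b):
            if node not in g:
                raise ValueError(f"edge references unfiltered OTU {node!r}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge {a}-{b}")
        g.add_edge(a, b, rho=float(row["rho"]), sign=int(row["sign"]),
                   p_value=float(row["p_value"]))
    return CooccurrenceNetwork(age=age, graph=g)


def network_from_table(table: CountTable, age: int,
                       min_fraction: float = 0.01,
                       rho_threshold: float = 0.7,
                       p_threshold: float = 2.32e-5) -> CooccurrenceNetwork:
    """Convenience: abundance filter -> edge table -> network for one age."""
    filtered = abundance_filter(table, age, min_fraction)
    edges = spearman_edge_table(filtered, rho_threshold, p_threshold)
    return build_network(edges, filtered, age)


# ---------------------------------------------------------------------------
# Metrics


def network_metrics(net: CooccurrenceNetwork,
                    drop_isolates: bool = True) -> NetworkMetrics:
    """Graph-level summary metrics.

    ``mean_degree`` is exactly ``2 E / N``. Betweenness is normalized by
    ``(N - 1)(N - 2) / 2``; the diameter uses edge length ``1 - |rho|`` on
    the largest connected component (the unweighted hop diameter is also
    reported).
    """
    g = net.graph.copy()
    if drop_isolates:
        g.remove_nodes_from(list(nx.isolates(g)))
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph (all nodes were isolates?)")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    betw = nx.betweenness_centrality(g, normalized=True)
    if e:
        for u, v, d in g.edges(data=True):
            d["length"] = 1.0 - abs(d.get("rho", 1.0))
        cc = max(nx.connected_components(g), key=len)
        sub = g.subgraph(cc)
        diameter = 0.0
        hop = 0
        for src, dists in nx.shortest_path_length(sub, weight="length"):
            diameter = max(diameter, max(dists.values()))
        for src, dists in nx.shortest_path_length(sub):
            hop = max(hop, max(dists.values()))
    else:
        diameter, hop = 0.0, 0
    return NetworkMetrics(
        n_nodes=n, n_edges=e,
        mean_degree=float(2 * e / n),
        sd_degree=float(degrees.std(ddof=1)) if n > 1 else 0.0,
        normalized_degree=float((degrees / (n - 1)).mean()) if n > 1 else 0.0,
        mean_betweenness=float(np.mean(list(betw.values()))),
        diameter=float(diameter), hop_diameter=int(hop))


# ---------------------------------------------------------------------------
# Persistence (intersection) graphs


def intersect_networks(net_a: CooccurrenceNetwork, net_b: CooccurrenceNetwork):
    """Intersection graph and conservation report of two age networks.

    Nodes: present in both parents. Edges: present in both parents with the
    same sign (a sign flip is not a persistent relationship); the retained
    edge carries the mean rho of the parents. Conservation rates are
    100 * |intersection| / |parent| for nodes and edges.
    """
    ga, gb = net_a.graph, net_b.graph
    nodes = sorted(set(ga.nodes) & set(gb.nodes))
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, **ga.nodes[n])
    for u, v, da in ga.edges(data=True):
        if u in g and v in g and gb.has_edge(u, v):
            db = gb.edges[u, v]
            if da.get("sign") == db.get("sign"):
                g.add_edge(u, v, rho=(da["rho"] + db["rho"]) / 2.0,
                           sign=da["sign"],
                           p_value=max(da.get("p_value", np.nan),
                                       db.get("p_value", np.nan)))
    inter = CooccurrenceNetwork(age=net_b.age, graph=g)

    def _rate(part: int, whole: int) -> float:
        return 100.0 * part / whole if whole else 0.0

    report = {
        "nodes": inter.n_nodes,
        "edges": inter.n_edges,
        "node_conservation_vs_a": _rate(inter.n_nodes, ga.number_of_nodes()),
        "node_conservation_vs_b": _rate(inter.n_nodes, gb.number_of_nodes()),
        "edge_conservation_vs_a": _rate(inter.n_edges, ga.number_of_edges()),
        "edge_conservation_vs_b": _rate(inter.n_edges, gb.number_of_edges()),
    }
    return inter, report


# ---------------------------------------------------------------------------
# Keystone ranking


def keystone_rank(net: CooccurrenceNetwork, top_k: int | None = None
                  ) -> pd.DataFrame:
    """Nodes ranked by degree (ties: betweenness, then OTU id).

    High-degree, high-betweenness OTUs are the keystone candidates.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    betw = nx.betweenness_centrality(g, normalized=True)
    rows = []
    for node in g.nodes:
        attrs = g.nodes[node]
        rows.append({"otu_id": node, "degree": g.degree(node),
                     "betweenness": betw[node],
                     "family": attrs.get("family", ""),
                     "genus": attrs.get("genus", ""),
                     "mean_abundance": attrs.get("mean_abundance", np.nan)})
    out = (pd.DataFrame(rows)
           .sort_values(["degree", "betweenness", "otu_id"],
                        ascending=[False, False, True])
           .reset_index(drop=True))
    return out.head(top_k) if top_k else out


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    g.graph["age"] = net.age
    for _, _, d in g.edges(data=True):
        d.pop("length", None)
        if isinstance(d.get("p_value"), float) and np.isnan(d["p_value"]):
            d["p_value"] = -1.0
    nx.write_graphml(g, str(path))


def read_graphml(path, age: int = -1) -> CooccurrenceNetwork:
    g = nx.read_graphml(str(path))
    age = int(g.graph.get("age", age))
    return CooccurrenceNetwork(age=age, graph=g)
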