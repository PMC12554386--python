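"""Co-occurrence networks on the most abundant taxa and their topology.

Edges are rank correlations between taxa across a group's samples that pass
both a magnitude threshold on |rho| and a multiplicity-adjusted significance
threshold; significance is computed on the unsigned correlation and the sign
is retained as an edge attribute. Topology metrics follow the usual closed
forms (average degree, density), average shortest-path length over connected
pairs only (hop counts), and the modularity of a deterministic greedy
agglomerative community partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from assemblage.io_tables import CommunityTable, filter_top_n, register_result
from assemblage.niche import GENERALIST, SPECIALIST, GuildClassification


@dataclass(frozen=True)
class Edge:
    otu_a: str
    otu_b: str
    rho: float
    q: float  # adjusted p-value
    sign: str  # '+' or '-'


@register_result
@dataclass(frozen=True)
class CoNetwork:
    """Guild-labellable nodes, signed weighted edges, and build parameters."""

    otu_ids: tuple[str, ...]  # candidate nodes after filtering
    abundance: tuple[float, ...]  # total counts per node
    edges: tuple[Edge, ...]
    method: str
    r_threshold: float
    p_threshold: float
    adjustment: str
    guild: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "abundance", tuple(self.abundance))
        edges = tuple(
            e if isinstance(e, Edge) else Edge(**e) if isinstance(e, dict) else Edge(*e)
            for e in self.edges
        )
        object.__setattr__(self, "edges", edges)
        seen = set()
        for e in edges:
            if e.otu_a == e.otu_b:
                raise ValueError(f"self-edge on {e.otu_a}")
            key = frozenset((e.otu_a, e.otu_b))
            if key in seen:
                raise ValueError(f"duplicate edge {e.otu_a}--{e.otu_b}")
            seen.add(key)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.otu_ids)
        for e in self.edges:
            g.add_edge(e.otu_a, e.otu_b, rho=e.rho, q=e.q, sign=e.sign)
        return g


@register_result
@dataclass(frozen=True)
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    avg_k: float
    density: float
    gd: float  # mean shortest-path hops over connected pairs; NaN if edgeless
    modularity: float  # NaN if edgeless
    pct_positive: float  # NaN if edgeless
    component_count: int
    diagnostics: tuple[str, ...] = ()


@register_result
@dataclass(frozen=True)
class EdgeTypeProportions:
    """Fractions of guild-labelled edges by endpoint guild pair."""

    gg: float
    gs: float
    ss: float
    n_edges_classified: int
    scope_n: int


def build_network(
    table: CommunityTable,
    n_top: int = 300,
    method: str = "spearman",
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    adjustment: str = "benjamini_hochberg",
    min_prevalence: float = 0.2,
    guilds: GuildClassification | None = None,
) -> CoNetwork:
    """All-pairs rank correlation network on the top-N most abundant taxa.

    Taxa occupying fewer than ``min_prevalence`` of samples or with zero
    variance are excluded (the latter with a warning). P-values come from the
    correlation method's asymptotic null and are adjusted across all tested
    pairs before thresholding.
    """
    if table.n_samples < 5:
        raise ValueError(
            f"correlations need >= 5 samples, got {table.n_samples}"
        )
    if method != "spearman":
        raise ValueError(f"unsupported correlation method {method!r}")
    if adjustment not in ("benjamini_hochberg", "none"):
        raise ValueError(f"unsupported adjustment {adjustment!r}")

    sub = filter_top_n(table, min(n_top, max(table.n_otus, 2)))
    prevalence = (sub.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    variances = sub.counts.var(axis=1)
    zero_var = keep & (variances == 0)
    if zero_var.any():
        names = [o for o, z in zip(sub.otu_ids, zero_var) if z]
        warnings.warn(
            f"excluding {len(names)} zero-variance OTUs: {names[:5]}", stacklevel=2
        )
        keep &= variances > 0
    sub = sub.subset(otus=[o for o, k in zip(sub.otu_ids, keep) if k])

    relab = sub.counts / sub.counts.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(relab.T)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)

    iu = np.triu_indices(sub.n_otus, k=1)
    p_flat = pval[iu]
    if adjustment == "benjamini_hochberg":
        q_flat = multipletests(p_flat, method="fdr_bh")[1]
    else:
        q_flat = p_flat
    r_flat = rho[iu]

    edges = []
    for (i, j, r, q) in zip(iu[0], iu[1], r_flat, q_flat):
        if abs(r) >= r_threshold and q < p_threshold:
            edges.append(
                Edge(
                    otu_a=sub.otu_ids[i],
                    otu_b=sub.otu_ids[j],
                    rho=float(r),
                    q=float(q),
                    sign="+" if r > 0 else "-",
                )
            )
    guild_labels = None
    if guilds is not None:
        lookup = dict(zip(guilds.otu_ids, guilds.guild))
        guild_labels = tuple(lookup.get(o, "non_significant") for o in sub.otu_ids)
    return CoNetwork(
        otu_ids=sub.otu_ids,
        abundance=tuple(float(t) for t in sub.counts.sum(axis=1)),
        edges=tuple(edges),
        method=method,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        adjustment=adjustment,
        guild=guild_labels,
    )


def topology(net: CoNetwork | nx.Graph) -> TopologyMetrics:
    """avgK, density, mean shortest path (connected pairs), greedy modularity.

    An edgeless network yields NaN for path length, modularity and positive
    fraction, with diagnostics naming the undefined metrics.
    """
    g = net.to_networkx() if isinstance(net, CoNetwork) else net
    n_nodes = g.number_of_nodes()
    if n_nodes < 2:
        raise ValueError(f"topology needs >= 2 nodes, got {n_nodes}")
    n_edges = g.number_of_edges()
    avg_k = 2.0 * n_edges / n_nodes
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1))
    components = list(nx.connected_components(g))
    diagnostics: list[str] = []

    if n_edges == 0:
        return TopologyMetrics(
            n_nodes=n_nodes,
            n_edges=0,
            avg_k=0.0,
            density=0.0,
            gd=math.nan,
            modularity=math.nan,
            pct_positive=math.nan,
            component_count=len(components),
            diagnostics=("gd undefined: no edges", "modularity undefined: no edges"),
        )

    # mean shortest-path hops over connected pairs only
    total = 0
    pairs = 0
    for comp in components:
        if len(comp) < 2:
            continue
        sg = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sg):
            total += sum(dists.values())
            pairs += len(dists) - 1
    gd = total / pairs if pairs else math.nan
    if len(components) > 1:
        diagnostics.append(
            f"gd averaged over connected pairs only ({len(components)} components)"
        )

    communities = nx.community.greedy_modularity_communities(g)
    modularity = nx.community.modularity(g, communities)

    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    if any(s is None for s in signs):
        pct_positive = math.nan
        diagnostics.append("pct_positive undefined: unsigned edges present")
    else:
        pct_positive = sum(s == "+" for s in signs) / len(signs)

    return TopologyMetrics(
        n_nodes=n_nodes,
        n_edges=n_edges,
        avg_k=avg_k,
        density=density,
        gd=float(gd),
        modularity=float(modularity),
        pct_positive=float(pct_positive),
        component_count=len(components),
        diagnostics=tuple(diagnostics),
    )


def edge_type_proportions(
    net: CoNetwork, guilds: GuildClassification, scope_n: int
) -> EdgeTypeProportions:
    """G-G / G-S / S-S proportions among guild-labelled edges.

    Restricted to the ``scope_n`` most abundant guild-labelled nodes; edges
    touching a non-significant node are excluded from the denominator.
    """
    lookup = dict(zip(guilds.otu_ids, guilds.guild))
    labelled = [
        (o, a)
        for o, a in zip(net.otu_ids, net.abundance)
        if lookup.get(o) in (GENERALIST, SPECIALIST)
    ]
    labelled.sort(key=lambda t: (-t[1], t[0]))
    scope = {o for o, _ in labelled[:scope_n]}

    gg = gs = ss = 0
    for e in net.edges:
        if e.otu_a not in scope or e.otu_b not in scope:
            continue
        la, lb = lookup[e.otu_a], lookup[e.otu_b]
        if la == GENERALIST and lb == GENERALIST:
            gg += 1
        elif la == SPECIALIST and lb == SPECIALIST:
            ss += 1
        else:
            gs += 1
    total = gg + gs + ss
    if total == 0:
        raise ValueError(
            "no edges with both endpoints guild-labelled inside the scope; "
            f"scope holds {len(scope)} of {len(labelled)} labelled nodes"
        )
    return EdgeTypeProportions(
        gg=gg / total,
        gs=gs / total,
        ss=ss / total,
        n_edges_classified=total,
        scope_n=scope_n,
    )


def write_graphml(net: CoNetwork, path) -> None:
    """GraphML export (Gephi-compatible) with rho/q/sign edge attributes."""
    g = net.to_networkx()
    if net.guild is not None:
        nx.set_node_attributes(g, dict(zip(net.otu_ids, net.guild)), "guild")
    nx.set_node_attributes(g, dict(zip(net.otu_ids, net.abundance)), "abundance")
    nx.write_graphml(g, path)
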