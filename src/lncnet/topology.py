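"""lncRNA-TF network assembly and topological statistics with permutation nulls.

The gene network merges significant lncRNA-TF ceRNA pairs with TF-TF
protein-protein-interaction edges into one simple undirected graph whose
nodes are typed (lncRNA / TF / m6A) and whose edges are typed (ceRNA / PPI /
coexpr / feedback).  Topology readouts are the degree-distribution power-law
fit, the mean local clustering coefficient, and the average shortest path
length of the largest component, each contrasted against an ensemble of
random networks ("permutation networks") with matched size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "TF", "m6A")
EDGE_TYPES = ("ceRNA", "PPI", "coexpr", "feedback")


def new_network() -> nx.Graph:
    return nx.Graph()


def add_typed_node(g: nx.Graph, node: str, node_type: str) -> None:
    if node_type not in NODE_TYPES:
        raise ValidationError(f"unknown node type {node_type!r}")
    existing = g.nodes[node].get("node_type") if node in g else None
    if existing is not None and existing != node_type:
        raise ValidationError(
            f"node {node!r} already typed {existing!r}, cannot retype {node_type!r}")
    g.add_node(node, node_type=node_type)


def add_typed_edge(g: nx.Graph, u: str, v: str, edge_type: str, **attrs) -> None:
    """Add/merge a typed edge.  A parallel edge of another type between the
    same pair collapses to one edge carrying both labels (comma-joined,
    sorted)."""
    if edge_type not in EDGE_TYPES:
        raise ValidationError(f"unknown edge type {edge_type!r}")
    if u == v:
        raise ValidationError(f"self-loop on {u!r} rejected")
    if g.has_edge(u, v):
        labels = set(g.edges[u, v]["edge_type"].split(",")) | {edge_type}
        g.edges[u, v].update(attrs)
        g.edges[u, v]["edge_type"] = ",".join(sorted(labels))
    else:
        g.add_edge(u, v, edge_type=edge_type, **attrs)


def validate_network(g: nx.Graph) -> nx.Graph:
    if any(u == v for u, v in g.edges):
        raise ValidationError("network contains self-loops")
    for node, data in g.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValidationError(f"node {node!r} lacks a valid node_type")
    for u, v, data in g.edges(data=True):
        labels = set(str(data.get("edge_type", "")).split(","))
        if not labels <= set(EDGE_TYPES):
            raise ValidationError(f"edge ({u!r}, {v!r}) has bad edge_type {data!r}")
    return g


def build_network(cerna_pairs: pd.DataFrame, ppi_edges=(), tf_ids=None) -> nx.Graph:
    """Merge significant ceRNA pairs and TF-TF PPI edges into one network.

    Only rows of ``cerna_pairs`` with ``significant == True`` are admitted.
    ``ppi_edges`` is an iterable of (tf_a, tf_b); both endpoints must be TFs,
    i.e. members of the pair table's TF column or of the optional ``tf_ids``
    whitelist.  The node set is the union of edge endpoints, so isolated
    nodes never appear.
    """
    g = new_network()
    known_tfs = set(tf_ids) if tf_ids is not None else set()
    known_lncs: set = set()
    if len(cerna_pairs):
        sig = cerna_pairs[cerna_pairs["significant"].astype(bool)]
        known_tfs |= set(cerna_pairs["tf_id"])
        known_lncs |= set(cerna_pairs["lnc_id"])
        for row in sig.itertuples(index=False):
            add_typed_node(g, row.lnc_id, "lncRNA")
            add_typed_node(g, row.tf_id, "TF")
            add_typed_edge(g, row.lnc_id, row.tf_id, "ceRNA", pcc=float(row.pcc))
    for a, b in ppi_edges:
        for x in (a, b):
            if x in known_lncs or (known_tfs and x not in known_tfs):
                raise ValidationError(f"PPI edge ({a!r}, {b!r}) touches non-TF id {x!r}")
        if a == b:
            raise ValidationError(f"self-interaction PPI edge on {a!r} rejected")
        add_typed_node(g, a, "TF")
        add_typed_node(g, b, "TF")
        add_typed_edge(g, a, b, "PPI")
    return validate_network(g)


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    r2: float
    intercept: float
    n_points: int


def fit_power_law(network: nx.Graph, binned: bool = False) -> PowerLawFit:
    """OLS fit of log10 P(k) on log10 k over the degree distribution.

    ``P(k)`` is the fraction of degree->=1 nodes with degree exactly ``k``;
    ``alpha`` is the negated slope and ``r2`` the coefficient of
    determination, mirroring the R^2-style scale-free readout.  With
    ``binned=True`` degrees are pooled into logarithmic (powers-of-two) bins
    and densities are divided by bin width; the default is unbinned.
    """
    degrees = np.array([d for _, d in network.degree() if d >= 1])
    if degrees.size == 0:
        raise DegenerateDataError("no nodes of positive degree")
    if binned:
        kmax = degrees.max()
        edges = [1]
        while edges[-1] <= kmax:
            edges.append(edges[-1] * 2)
        counts, _ = np.histogram(degrees, bins=edges)
        widths = np.diff(edges)
        centers = np.sqrt(np.array(edges[:-1]) * np.array(edges[1:]))
        mask = counts > 0
        ks = centers[mask]
        pk = counts[mask] / widths[mask] / degrees.size
    else:
        ks, counts = np.unique(degrees, return_counts=True)
        pk = counts / degrees.size
    if ks.size < 3:
        raise DegenerateDataError(
            f"need >= 3 distinct positive degrees, got {ks.size}")
    x = np.log10(ks.astype(float))
    y = np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(alpha=float(-slope), r2=float(r2),
                       intercept=float(intercept), n_points=int(ks.size))


def powerlaw_alpha_mle(network: nx.Graph, kmin: int = 1) -> float:
    """Secondary diagnostic: discrete maximum-likelihood power-law exponent
    (Hill-type estimator alpha = 1 + n / sum(ln(k / (kmin - 0.5))))."""
    degrees = np.array([d for _, d in network.degree() if d >= kmin])
    if degrees.size == 0:
        raise DegenerateDataError("no degrees at or above kmin")
    return float(1.0 + degrees.size / np.sum(np.log(degrees / (kmin - 0.5))))


def clustering_coefficient(network: nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes; nodes of degree < 2
    contribute 0 (they close no triangles)."""
    if network.number_of_nodes() == 0:
        raise DegenerateDataError("empty network")
    return float(nx.average_clustering(network, count_zeros=True))


def average_shortest_path(network: nx.Graph) -> float:
    """Mean unweighted shortest-path length over all node pairs of the
    largest connected component."""
    if network.number_of_nodes() == 0:
        raise DegenerateDataError("empty network")
    components = sorted(nx.connected_components(network), key=len, reverse=True)
    if not components or len(components[0]) < 2:
        raise DegenerateDataError("no connected component with >= 2 nodes")
    if len(components) > 1:
        logger.info("average_shortest_path computed on the largest of %d "
                    "components (%d nodes)", len(components), len(components[0]))
    return float(nx.average_shortest_path_length(network.subgraph(components[0])))


_STATISTICS = {
    "cc": clustering_coefficient,
    "aspl": average_shortest_path,
}


@dataclass
class PermutationResult:
    statistic: str
    scheme: str
    alternative: str
    observed: float
    p: float
    null_mean: float
    null_sd: float
    n_perm: int
    null_values: np.ndarray = field(repr=False)


def _null_graph(network: nx.Graph, scheme: str, rng: np.random.Generator) -> nx.Graph:
    n = network.number_of_nodes()
    e = network.number_of_edges()
    seed = int(rng.integers(0, 2 ** 31 - 1))
    if scheme == "gnm":
        h = nx.gnm_random_graph(n, e, seed=seed)
        assert h.number_of_nodes() == n and h.number_of_edges() == e
    elif scheme == "degree_preserving":
        h = nx.Graph(network)
        nswap = 10 * e
        if e >= 2 and n >= 4:
            nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap, seed=seed)
        deg_before = sorted(d for _, d in network.degree())
        deg_after = sorted(d for _, d in h.degree())
        assert deg_before == deg_after
    else:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    return h


def permutation_test(network: nx.Graph, statistic: str = "cc",
                     n_perm: int = 1000, scheme: str = "gnm",
                     alternative: str = "greater", seed: int = 0) -> PermutationResult:
    """Compare an observed network statistic with a null ensemble.

    ``gnm`` nulls are uniform simple graphs with identical node and edge
    counts; ``degree_preserving`` nulls rewire the observed graph by
    double-edge swaps (10 * |E| accepted swaps), preserving the degree
    sequence.  The add-one empirical p is
    ``(#{null >= observed} + 1) / (n_perm + 1)`` for ``alternative="greater"``
    and the mirror image for ``"less"``; it can never drop below
    ``1 / (n_perm + 1)``.
    """
    if statistic not in _STATISTICS:
        raise ValidationError(f"statistic must be one of {sorted(_STATISTICS)}")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = network.number_of_nodes()
    e = network.number_of_edges()
    if e > n * (n - 1) // 2:
        raise ValidationError("edge count exceeds the simple-graph maximum")
    stat = _STATISTICS[statistic]
    observed = stat(network)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        h = _null_graph(network, scheme, rng)
        try:
            nulls[i] = stat(h)
        except DegenerateDataError:
            nulls[i] = np.nan
    valid = nulls[~np.isnan(nulls)]
    if valid.size < n_perm:
        logger.warning("%d/%d null draws were degenerate for %s",
                       n_perm - valid.size, n_perm, statistic)
    if alternative == "greater":
        exceed = int(np.sum(valid >= observed))
    else:
        exceed = int(np.sum(valid <= observed))
    p = (exceed + 1) / (valid.size + 1)
    return PermutationResult(
        statistic=statistic, scheme=scheme, alternative=alternative,
        observed=float(observed), p=float(p),
        null_mean=float(valid.mean()) if valid.size else math.nan,
        null_sd=float(valid.std(ddof=1)) if valid.size > 1 else math.nan,
        n_perm=int(valid.size), null_values=nulls)


def extract_hubs(network: nx.Graph, fraction: float = 0.10) -> list:
    """Top ``ceil(fraction * n_nodes)`` nodes by degree; ties at the cutoff
    break by node id ascending for determinism."""
    if network.number_of_nodes() == 0:
        raise ValidationError("cannot extract hubs from an empty network")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction={fraction} outside (0, 1]")
    k = math.ceil(fraction * network.number_of_nodes())
    ranked = sorted(network.degree(), key=lambda nd: (-nd[1], str(nd[0])))
    return [node for node, _ in ranked[:k]]


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    powerlaw_alpha: float
    powerlaw_r2: float
    clustering_coeff: float
    avg_short_path: float
    perm_p_cc: float
    perm_p_aspl: float
    null_summaries: dict

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "powerlaw_alpha": self.powerlaw_alpha, "powerlaw_r2": self.powerlaw_r2,
            "clustering_coeff": self.clustering_coeff,
            "avg_short_path": self.avg_short_path,
            "perm_p_cc": self.perm_p_cc, "perm_p_aspl": self.perm_p_aspl,
            "null_summaries": self.null_summaries,
        }


def topology_report(network: nx.Graph, n_perm: int = 1000, scheme: str = "gnm",
                    seed: int = 0) -> tuple[TopologyReport, pd.DataFrame]:
    """Full topology readout: power-law fit, clustering coefficient and ASPL
    with their permutation p-values (clustering tested as larger than null,
    path length as smaller).  Also returns the null draws as a tidy table."""
    try:
        fit = fit_power_law(network)
    except DegenerateDataError as exc:
        logger.warning("power-law fit skipped: %s", exc)
        fit = PowerLawFit(alpha=math.nan, r2=math.nan,
                          intercept=math.nan, n_points=0)
    perm_cc = permutation_test(network, "cc", n_perm=n_perm, scheme=scheme,
                               alternative="greater", seed=seed)
    perm_aspl = permutation_test(network, "aspl", n_perm=n_perm, scheme=scheme,
                                 alternative="less", seed=seed + 1)
    report = TopologyReport(
        n_nodes=network.number_of_nodes(), n_edges=network.number_of_edges(),
        powerlaw_alpha=fit.alpha, powerlaw_r2=fit.r2,
        clustering_coeff=perm_cc.observed, avg_short_path=perm_aspl.observed,
        perm_p_cc=perm_cc.p, perm_p_aspl=perm_aspl.p,
        null_summaries={
            "cc": {"mean": perm_cc.null_mean, "sd": perm_cc.null_sd,
                   "n_perm": perm_cc.n_perm},
            "aspl": {"mean": perm_aspl.null_mean, "sd": perm_aspl.null_sd,
                     "n_perm": perm_aspl.n_perm},
        })
    nulls = pd.DataFrame({
        "draw": np.arange(max(len(perm_cc.null_values), len(perm_aspl.null_values))),
    })
    nulls["cc"] = pd.Series(perm_cc.null_values)
    nulls["aspl"] = pd.Series(perm_aspl.null_values)
    return report, nulls
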