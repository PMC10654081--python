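"""Co-occurrence networks of taxa and their stability.

Edges are strong, significant Spearman rank correlations between taxon
abundance profiles (|rho| > 0.7, P < 0.01 by default, no multiple-testing
correction -- the raw cutoff the field's network studies use).  Topology
summaries mirror the usual report: node/edge counts, degree statistics,
density, seeded-Louvain modularity, clustering, path metrics on the
largest component, and the ratio of negative to positive correlations.
Stability is probed two ways: a robustness curve (random node removal
with secondary extinction of neighbour-less nodes, area under the mean
remaining-fraction curve) and vulnerability (worst single-node drop in
global efficiency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError, ValidationError
from .table import CommunityTable

logger = logging.getLogger(__name__)


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_weighted_degree: float
    density: float
    modularity: float
    average_clustering_coefficient: float
    average_path_length: float
    diameter: float
    n_connected_components: int
    neg_pos_ratio: float  # percentage, 100 * negative / positive

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


@dataclass
class RobustnessCurve:
    removal_fractions: np.ndarray
    mean_remaining: np.ndarray
    sd_remaining: np.ndarray
    n_reps: int
    robustness_score: float  # area under the mean curve


# ---------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------

def correlation_screen(table: CommunityTable, rho_threshold: float = 0.7,
                       alpha: float = 0.01, fdr: bool = False) -> pd.DataFrame:
    """Spearman screen over all unordered taxon pairs.

    Average-rank ties, asymptotic two-sided t p-value; a pair is retained
    iff |rho| > rho_threshold and p < alpha (both strict).  The raw
    cutoff is the field's convention; ``fdr=True`` applies a
    Benjamini-Hochberg correction to the p-values first.  Constant taxon
    profiles are skipped with a log message.  Returns a tidy edge
    DataFrame (taxon_u, taxon_v, rho, p_value, sign).
    """
    if table.n_samples < 5:
        raise DataError(f"need >= 5 samples for correlation, got {table.n_samples}")
    values = table.matrix()
    variable = values.std(axis=1) > 0
    skipped = [t for t, v in zip(table.taxon_ids, variable) if not v]
    if skipped:
        logger.info("correlation_screen: skipped %d constant taxa", len(skipped))
    taxa = [t for t, v in zip(table.taxon_ids, variable) if v]
    sub = values[variable]
    if len(taxa) < 2:
        return pd.DataFrame(columns=["taxon_u", "taxon_v", "rho", "p_value", "sign"])
    rho, p = stats.spearmanr(sub.T)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu, ju = np.triu_indices(len(taxa), k=1)
    p_flat = p[iu, ju]
    if fdr:
        from statsmodels.stats.multitest import multipletests
        p_flat = multipletests(p_flat, method="fdr_bh")[1]
    keep = (np.abs(rho[iu, ju]) > rho_threshold) & (p_flat < alpha)
    edges = pd.DataFrame({
        "taxon_u": [taxa[i] for i in iu[keep]],
        "taxon_v": [taxa[j] for j in ju[keep]],
        "rho": rho[iu[keep], ju[keep]],
        "p_value": p[iu[keep], ju[keep]],
    })
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    return edges


def build_network(edges: pd.DataFrame, taxonomy: pd.DataFrame | None = None,
                  mean_ra: pd.Series | None = None) -> nx.Graph:
    """Undirected signed weighted graph from a screened edge list.

    Nodes are the edge endpoints only (candidate taxa with no retained
    correlation stay out); edge weight is |rho|.  Taxonomy ranks and mean
    relative abundance are attached as node attributes when given.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.taxon_u == row.taxon_v:
            continue  # no self-loops
        g.add_edge(row.taxon_u, row.taxon_v, rho=float(row.rho),
                   p_value=float(row.p_value), sign=row.sign,
                   weight=abs(float(row.rho)))
    if taxonomy is not None:
        for node in g.nodes:
            if node in taxonomy.index:
                for rank, val in taxonomy.loc[node].items():
                    g.nodes[node][str(rank)] = "" if pd.isna(val) else str(val)
    if mean_ra is not None:
        for node in g.nodes:
            if node in mean_ra.index:
                g.nodes[node]["mean_relative_abundance"] = float(mean_ra[node])
    return g


# ---------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------

def best_louvain_partition(g: nx.Graph, seed: int = 0, n_runs: int = 10):
    """Best-of-n seeded Louvain partitions on |rho| weights.

    Returns (partition as list of sets, modularity)."""
    best_q, best_part = -1.0, None
    for k in range(n_runs):
        part = nx.community.louvain_communities(g, weight="weight", seed=seed + k)
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return best_part, float(best_q)


def topology(g: nx.Graph, seed: int = 0) -> TopologyReport:
    """Topology parameters of a co-occurrence network.

    Path-based metrics (average path length, diameter) are computed on
    the largest connected component; an empty graph yields a zero report
    with a warning.
    """
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        logger.warning("topology: empty graph")
        return TopologyReport(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, np.nan)
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    n_pos = sum(s == "positive" for s in signs)
    n_neg = sum(s == "negative" for s in signs)
    neg_pos = 100.0 * n_neg / n_pos if n_pos else np.nan
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    wdegrees = np.array([d for _, d in g.degree(weight="weight")], dtype=float)
    _, q = best_louvain_partition(g, seed=seed)
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        apl, diam = 0.0, 0.0
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        average_degree=float(degrees.mean()),
        average_weighted_degree=float(wdegrees.mean()),
        density=float(nx.density(g)),
        modularity=q,
        average_clustering_coefficient=float(nx.average_clustering(g)),
        average_path_length=float(apl),
        diameter=diam,
        n_connected_components=len(components),
        neg_pos_ratio=float(neg_pos),
    )


def modular_structure_flag(modularity: float) -> bool:
    """Modularity above 0.4 is read as 'the network has modular structure'."""
    return modularity > 0.4


def focal_class_edges(g: nx.Graph, taxonomy: pd.DataFrame, focal_class: str,
                      rank: str = "class") -> dict[str, int]:
    """Signed intra/inter decomposition of edges touching a focal class.

    An edge is intra iff both endpoints belong to the focal class; the
    four counts partition all edges incident to at least one focal node.
    """
    labels = taxonomy[rank]
    if focal_class not in set(labels.dropna()):
        raise ValidationError(f"class {focal_class!r} not present in taxonomy")
    is_focal = {t: (labels.get(t) == focal_class) for t in g.nodes}
    counts = {"intra_positive": 0, "intra_negative": 0,
              "inter_positive": 0, "inter_negative": 0}
    for u, v, d in g.edges(data=True):
        fu, fv = is_focal[u], is_focal[v]
        if not (fu or fv):
            continue
        kind = "intra" if (fu and fv) else "inter"
        counts[f"{kind}_{'positive' if d['sign'] == 'positive' else 'negative'}"] += 1
    return counts


# ---------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------

def robustness(g: nx.Graph, step: float = 0.05, n_reps: int = 100,
               seed: int = 0) -> RobustnessCurve:
    """Random-removal robustness with secondary extinctions.

    For each removal fraction q on the grid 0..1 (step ``step``), remove
    round(qN) nodes uniformly at random, then iteratively delete nodes
    left with no neighbours; the remaining-connected fraction is
    survivors / N.  The robustness score is the trapezoidal area under
    the mean curve (1.0 would mean no node is ever lost).
    """
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} must divide 1")
    if n_reps < 2:
        raise ValidationError(f"n_reps must be >= 2, got {n_reps}")
    n = g.number_of_nodes()
    if n < 5:
        raise DataError(f"robustness needs >= 5 nodes, got {n}")
    nodes = list(g.nodes)
    fractions = np.round(np.arange(n_steps + 1) * step, 10)
    rng = np.random.default_rng(seed)
    remaining = np.ones((n_reps, fractions.size))
    for r in range(n_reps):
        order = rng.permutation(n)
        for qi, q in enumerate(fractions[1:], start=1):
            n_remove = int(round(q * n))
            h = g.copy()
            h.remove_nodes_from(nodes[i] for i in order[:n_remove])
            # secondary extinction: nodes with no remaining partner die
            while True:
                isolated = [v for v, d in h.degree() if d == 0]
                if not isolated:
                    break
                h.remove_nodes_from(isolated)
            remaining[r, qi] = h.number_of_nodes() / n
    mean = remaining.mean(axis=0)
    sd = remaining.std(axis=0, ddof=1)
    score = float(np.trapezoid(mean, fractions))
    return RobustnessCurve(removal_fractions=fractions, mean_remaining=mean,
                           sd_remaining=sd, n_reps=n_reps,
                           robustness_score=score)


def natural_connectivity(g: nx.Graph) -> float:
    """Alternative stability index: log mean eigenvalue exponential of the
    adjacency spectrum (insensitive to single-path redundancy)."""
    if g.number_of_nodes() == 0:
        raise DataError("empty graph")
    w = np.linalg.eigvalsh(nx.to_numpy_array(g, weight=None))
    return float(np.log(np.mean(np.exp(w - w.max()))) + w.max())


def vulnerability(g: nx.Graph) -> float:
    """Max over nodes of the relative global-efficiency drop (E - E_i)/E
    when that node is removed."""
    if g.number_of_nodes() < 3:
        raise DataError("vulnerability needs >= 3 nodes")
    e_global = nx.global_efficiency(g)
    if e_global == 0:
        raise DataError("graph has zero global efficiency")
    worst = -np.inf
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        worst = max(worst, (e_global - nx.global_efficiency(h)) / e_global)
    return float(worst)


# ---------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------

def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [{"taxon_u": u, "taxon_v": v, **d} for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
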