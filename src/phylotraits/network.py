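"""Significance-thresholded trait networks and their topology metrics.

For one site, every pair of traits is tested by Pearson correlation over
species means; pairs with p below the threshold (default 0.05, no
multiple-testing correction) become edges with integer weight
``floor(|r| * 10)`` and a recorded sign.  Traits with no significant partner
remain isolated nodes.  Path-based metrics (average path length,
betweenness) are computed on the unweighted graph — the integer weights
encode correlation strength, not distance — while node strength sums the
incident weights.  Unreachable node pairs are excluded from the average path
length; isolated nodes still count in the edge-density denominator.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, ValidationError

__all__ = [
    "pearson_with_p",
    "build_network",
    "node_metrics",
    "global_metrics",
    "TraitNetwork",
    "GlobalMetrics",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value.

    p is from ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of
    freedom.  Requires n >= 4 paired finite values and nonzero variance in
    both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 4:
        raise DesignError(f"need n >= 4 paired values, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in x or y; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclasses.dataclass
class TraitNetwork:
    """Weighted undirected trait graph for one site.

    ``graph`` is a :class:`networkx.Graph` whose node set always contains all
    traits (isolated ones included); each edge carries attributes
    ``r``, ``p``, ``weight`` (= floor(|r| * 10)) and ``sign`` (+1/-1).
    """

    site: int | str
    graph: nx.Graph
    alpha: float = 0.05

    @property
    def traits(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "trait_a": a,
                "trait_b": b,
                "r": d["r"],
                "p": d["p"],
                "weight": d["weight"],
                "sign": "+" if d["sign"] > 0 else "-",
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["trait_a", "trait_b", "r", "p", "weight", "sign"]
        )


def build_network(
    means: pd.DataFrame,
    site: int | str = "",
    alpha: float = 0.05,
    traits: list[str] | None = None,
) -> TraitNetwork:
    """Build the trait network from a species x trait mean matrix (one site).

    Correlations are computed on the raw species means.  A constant trait
    cannot enter any correlation and is kept as an isolated node with a
    warning.  Species rows with a missing value are dropped pairwise.
    """
    if traits is None:
        traits = [c for c in means.columns if c != "site"]
    if means.shape[0] < 4:
        raise DesignError("need >= 4 species to build a trait network")
    g = nx.Graph()
    g.add_nodes_from(traits)
    for a, b in itertools.combinations(traits, 2):
        pair = means[[a, b]].dropna()
        if len(pair) < 4:
            continue
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = pearson_with_p(x, y)
        if p < alpha:
            g.add_edge(
                a, b, r=r, p=p, weight=int(math.floor(abs(r) * 10)), sign=1 if r >= 0 else -1
            )
    for t in traits:
        col = means[t].dropna()
        if len(col) and np.ptp(col.to_numpy(float)) == 0:
            warnings.warn(f"trait {t!r} is constant; kept as isolated node", stacklevel=2)
    return TraitNetwork(site=site, graph=g, alpha=alpha)


def node_metrics(net: TraitNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, strength (sum of integer edge weights) and betweenness.

    Betweenness counts unweighted shortest paths between all other node
    pairs passing through the focal node, with fractional credit when a pair
    has several shortest paths (unnormalized).
    """
    g = net.graph if isinstance(net, TraitNetwork) else net
    betw = nx.betweenness_centrality(g, normalized=False, weight=None)
    rows = [
        {
            "trait": v,
            "degree": g.degree(v),
            "strength": sum(d.get("weight", 1) for _, _, d in g.edges(v, data=True)),
            "betweenness": betw[v],
        }
        for v in g.nodes
    ]
    return pd.DataFrame(rows)


@dataclasses.dataclass
class GlobalMetrics:
    edge_density: float
    average_path_length: float  # NaN when no finite-distance pair exists
    average_clustering: float  # NaN when no node has degree >= 2

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def global_metrics(net: TraitNetwork | nx.Graph) -> GlobalMetrics:
    """Edge density, average path length, and average clustering coefficient.

    Density counts all nodes (isolated included).  Average path length is the
    mean unweighted shortest-path distance over ordered pairs with finite
    distance; unreachable pairs are excluded, and the metric is NaN if no
    pair is connected.  The clustering coefficient averages local clustering
    over nodes of degree >= 2 only.
    """
    g = net.graph if isinstance(net, TraitNetwork) else net
    n = g.number_of_nodes()
    density = g.number_of_edges() / (n * (n - 1) / 2) if n > 1 else float("nan")

    total, pairs = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    apl = total / pairs if pairs else float("nan")

    clust = [c for v, c in nx.clustering(g).items() if g.degree(v) >= 2]
    acc = float(np.mean(clust)) if clust else float("nan")
    return GlobalMetrics(float(density), float(apl), acc)
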