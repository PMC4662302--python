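"""Population genetic graphs by conditional-independence edge pruning.

Populations are nodes; an edge is kept only where the genetic covariance
between two populations cannot be explained by the remaining populations.
The construction follows the Gaussian graphical-model recipe:

1. encode every individual as a multilocus allele-dosage vector (one
   coordinate per allele class, value in {0, 1/2, 1}; one reference class
   per locus is dropped to remove the within-locus sum constraint);
2. population centroids are the mean dosage vectors;
3. the among-population covariance of the centroids (populations as rows,
   dosage coordinates as observations) is standardized to a correlation
   matrix, whose (pseudo)inverse yields partial correlations
   ``r_ij.rest = -prec_ij / sqrt(prec_ii * prec_jj)``;
4. the edge-exclusion deviance ``EED_ij = -n ln(1 - r_ij.rest^2)`` (n =
   total individuals) is compared to the chi-square(1) critical value at
   ``alpha``; edges whose deviance exceeds it are retained.

Community structure of the retained (unweighted) topology is summarized by
the maximum Newman-Girvan modularity over the edge-betweenness divisive
dendrogram, ``Q = sum_c (e_c - a_c^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .popgen import MISSING, GenotypeTable, _CompactTable

logger = logging.getLogger(__name__)


@dataclass
class PopGraph:
    """Population graph with per-edge deviance and community structure."""

    graph: nx.Graph                 # retained edges only; nodes = populations
    edges: pd.DataFrame             # pop_i, pop_j, partial_r, eed, retained, weight
    alpha: float
    n_individuals: int
    modularity: float = np.nan
    communities: dict = field(default_factory=dict)  # population -> community id

    @property
    def populations(self) -> list:
        return list(self.graph.nodes)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def edge_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)

    def community_csv(self, path) -> None:
        pd.Series(self.communities, name="community").rename_axis(
            "population"
        ).to_csv(path)


def dosage_matrix(gt: GenotypeTable) -> tuple[np.ndarray, list]:
    """Individuals x allele-class dosage matrix (one class per locus dropped).

    Entries are allele counts / 2 in {0, 0.5, 1}; missing genotypes are NaN
    across the locus' coordinates.
    """
    comp = _CompactTable(gt)
    cols = []
    names = []
    for l in range(comp.L):
        k = comp.k[l]
        if k < 2:
            continue  # monomorphic locus carries no information
        block = np.zeros((comp.n, k))
        codes = comp.codes[:, l, :]
        for s in (0, 1):
            ok = codes[:, s] >= 0
            block[np.flatnonzero(ok), codes[ok, s]] += 0.5
        block[~comp.scored[:, l]] = np.nan
        cols.append(block[:, :-1])  # drop reference class
        names.extend(f"{gt.loci[l]}:{a}" for a in comp.allele_codes[l][:-1])
    if not cols:
        raise ValueError("no polymorphic loci")
    return np.concatenate(cols, axis=1), names


def build_popgraph(gt: GenotypeTable, alpha: float = 0.05,
                   ridge: float = 1e-8) -> PopGraph:
    """Build the conditional-independence population graph at level ``alpha``.

    Edge weights on retained edges are a conditional genetic distance,
    ``sqrt(1 - r_ij.rest^2)`` (small for strongly conditionally dependent
    pairs); community detection ignores the weights.  Near-singular
    correlation matrices fall back to a ridge-regularized pseudo-inverse
    (logged); exactly duplicated population centroids raise, naming the pair.
    """
    pops = gt.pop_names()
    P = len(pops)
    if P < 3:
        raise ValueError("need >= 3 populations for a population graph")
    X, _ = dosage_matrix(gt)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 polymorphic loci")
    pop_arr = np.asarray(gt.populations)
    centroids = np.vstack([
        np.nanmean(X[pop_arr == p], axis=0) for p in pops
    ])
    # a population entirely unscored at a locus: fall back to the grand mean
    nanmask = ~np.isfinite(centroids)
    if nanmask.any():
        logger.info("build_popgraph: filling %d unscored centroid coordinates",
                    int(nanmask.sum()))
        grand = np.nanmean(centroids, axis=0)
        centroids[nanmask] = np.broadcast_to(grand, centroids.shape)[nanmask]

    for i in range(P):
        for j in range(i + 1, P):
            if np.allclose(centroids[i], centroids[j], atol=1e-12):
                raise ValueError(
                    f"duplicate population centroids: {pops[i]!r} and {pops[j]!r}"
                )
    C = np.cov(centroids)  # P x P, dosage coordinates as observations
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)

    try:
        prec = np.linalg.inv(R)
        if not np.all(np.isfinite(prec)) or np.linalg.cond(R) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.info("build_popgraph: near-singular correlation matrix; "
                    "using ridge (%g) pseudo-inverse", ridge)
        prec = np.linalg.pinv(R + ridge * np.eye(P))

    dprec = np.sqrt(np.diag(prec))
    partial = -prec / np.outer(dprec, dprec)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip(partial, -0.9999999, 0.9999999)

    n = gt.n_individuals
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    rows = []
    g = nx.Graph()
    g.add_nodes_from(pops)
    for i in range(P):
        for j in range(i + 1, P):
            r = float(partial[i, j])
            eed = float(-n * np.log1p(-r * r))
            retained = eed > crit
            weight = float(np.sqrt(1.0 - r * r))
            rows.append((pops[i], pops[j], r, eed, retained, weight))
            if retained:
                g.add_edge(pops[i], pops[j], weight=weight,
                           partial_r=r, eed=eed)
    edges = pd.DataFrame(
        rows, columns=["pop_i", "pop_j", "partial_r", "eed", "retained", "weight"]
    )
    pg = PopGraph(graph=g, edges=edges, alpha=alpha, n_individuals=n)
    pg.modularity, pg.communities = modularity(pg)
    return pg


def modularity(g) -> tuple[float, dict]:
    """Maximum Newman-Girvan modularity over the divisive dendrogram.

    Edge-betweenness communities are computed on the unweighted retained
    topology (betweenness recomputed after every removal).  The candidate
    partitions are the single community, the connected components, and
    every level of the Girvan-Newman dendrogram; the best Q and its
    partition are returned.  An edgeless graph has modularity 0 (logged).
    """
    graph = g.graph if isinstance(g, PopGraph) else g
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        logger.info("modularity: edgeless graph; defined as 0")
        return 0.0, {v: 0 for v in nodes}

    candidates = [[set(nodes)]]
    comps = [set(c) for c in nx.connected_components(graph)]
    if len(comps) > 1:
        candidates.append(comps)
    for level in nx.algorithms.community.girvan_newman(graph):
        candidates.append([set(c) for c in level])

    best_q, best_part = -np.inf, None
    for part in candidates:
        q = nx.algorithms.community.modularity(graph, part, weight=None)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    communities = {}
    for cid, members in enumerate(sorted(best_part, key=lambda c: sorted(map(str, c)))):
        for v in members:
            communities[v] = cid
    return float(best_q), communities
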