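"""Confidence-thresholded protein-interaction networks.

Networks are built for the most-changed genes (fold cutoff or top quantile)
from STRING-style edge lists with a combined confidence score S in [0, 1]
(raw 0-1000 exports are auto-detected and rescaled).  Analysis follows the
usual sequence: connected components, hub labeling (degree strictly greater
than 5), spectral k-means clustering, and per-cluster gene-module
annotation with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .enrichment import bh_adjust, hypergeom_test

logger = logging.getLogger(__name__)

#: a node is a hub when its degree is strictly greater than this
HUB_DEGREE = 5


@dataclass
class NetworkClustering:
    """A partition of the graph's nodes into k clusters.

    `annotations` maps cluster id -> DataFrame of significantly enriched
    catalog modules (filled by `annotate_clusters`).
    """

    assignment: dict[str, int]
    k: int
    inertia: float = float("nan")
    annotations: dict[int, pd.DataFrame] = field(default_factory=dict)

    def members(self, cluster: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == cluster}


def load_graph(
    edges,
    score_threshold: float,
    node_subset: set[str] | None = None,
) -> nx.Graph:
    """Build the interaction graph from (protein1, protein2, score) rows.

    `edges` is an iterable of 3-tuples or a path to a TSV with those three
    columns (header allowed).  Any score > 1 anywhere in the input flags
    the STRING 0-1000 integer scale and all scores are divided by 1000.
    Only edges with S strictly greater than `score_threshold` are kept;
    self-loops are dropped and duplicate pairs keep the highest score.
    With `node_subset` the graph is induced on that set, and subset members
    absent from the edge list remain as isolated nodes.
    """
    if isinstance(edges, (str, bytes)) or hasattr(edges, "__fspath__"):
        rows = []
        with open(edges) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[:2] == ["protein1", "protein2"]:
                    continue
                if len(fields) < 3:
                    raise ValueError(f"malformed interaction row at line {lineno}: {line[:60]!r}")
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"malformed score at line {lineno}: {fields[2]!r}") from exc
                rows.append((fields[0], fields[1], score))
    else:
        rows = [(str(a), str(b), float(s)) for a, b, s in edges]

    scale = 1000.0 if any(s > 1.0 for _, _, s in rows) else 1.0
    g = nx.Graph()
    if node_subset is not None:
        g.add_nodes_from(node_subset)
    for a, b, s in rows:
        s = s / scale
        if a == b:
            continue
        if node_subset is not None and (a not in node_subset or b not in node_subset):
            continue
        if s > score_threshold:
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], s)
            else:
                g.add_edge(a, b, score=s)
    return g


def connected_components(g: nx.Graph) -> list[set[str]]:
    """Maximal connected vertex sets, largest first (ties: smallest member)."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def find_hubs(g: nx.Graph) -> set[str]:
    """Nodes with degree strictly greater than 5."""
    return {n for n, d in g.degree() if d > HUB_DEGREE}


def select_network_genes(
    folds: pd.DataFrame,
    mode: str = "fold",
    fold_min: float = 8.0,
    quantile: float = 0.25,
) -> tuple[set[str], set[str]]:
    """Pick the most-changed genes for network construction.

    ``mode="fold"``: genes changed by strictly more than `fold_min`-fold
    (|log2fold| > log2(fold_min)), split into up/down.  ``mode="quantile"``:
    the top `quantile` fraction of genes by |log2fold|, split by sign.  The
    two selectors agree only when the fold cutoff happens to sit at that
    quantile of the data.
    """
    lf = folds["log2fold"]
    if mode == "fold":
        cut = np.log2(fold_min)
    elif mode == "quantile":
        cut = float(np.quantile(np.abs(lf.to_numpy()), 1.0 - quantile))
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return set(lf.index[lf > cut]), set(lf.index[lf < -cut])


def kmeans_cluster(g: nx.Graph, k: int, seed: int = 0) -> NetworkClustering:
    """Spectral k-means clustering of the interaction graph.

    Nodes are embedded by the first k eigenvectors (smallest eigenvalues)
    of the symmetric-normalized graph Laplacian built from the confidence-
    weighted adjacency; embedding rows are unit-normalized and clustered
    with k-means (k-means++ initialization, 20 restarts, fixed seed).
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        return NetworkClustering(assignment={v: 0 for v in nodes}, k=1, inertia=0.0)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="score")
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    lap = np.eye(n) - (d_inv_sqrt[:, None] * a) * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(lap)
    emb = eigvecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = np.where(norms > 0, emb / np.where(norms == 0, 1.0, norms), 0.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=20, random_state=int(seed) % (2**32))
    labels = km.fit_predict(emb)
    logger.info("k-means (k=%d) within-cluster sum of squares: %.4g", k, km.inertia_)
    return NetworkClustering(
        assignment={v: int(c) for v, c in zip(nodes, labels)},
        k=k,
        inertia=float(km.inertia_),
    )


def default_k(g: nx.Graph) -> int:
    """Heuristic cluster count: number of connected components of size >= 3."""
    k = sum(1 for c in nx.connected_components(g) if len(c) >= 3)
    k = max(1, min(k, g.number_of_nodes()))
    logger.info("default k heuristic chose k=%d", k)
    return k


def annotate_clusters(
    clustering: NetworkClustering,
    modules: dict[str, frozenset[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> NetworkClustering:
    """Annotate every cluster by module over-representation.

    For each cluster, each catalog module is tested with the hypergeometric
    test against `universe`; p-values are Benjamini–Hochberg adjusted
    within the cluster and modules with adjusted p < `alpha` are reported,
    most significant first.
    """
    universe = set(universe)
    for cluster in sorted(set(clustering.assignment.values())):
        members = clustering.members(cluster) & universe
        rows = []
        for mid in sorted(modules):
            genes = set(modules[mid]) & universe
            if not genes:
                continue
            n_overlap, expected, p = hypergeom_test(genes, members, universe)
            rows.append((mid, len(genes), n_overlap, expected, p))
        df = pd.DataFrame(
            rows, columns=["module_id", "n_module", "n_overlap", "expected", "p"]
        )
        if len(df):
            df["p_adj"] = bh_adjust(df["p"].to_numpy())
            df = df[df["p_adj"] < alpha].sort_values(["p_adj", "p", "module_id"])
        else:
            df["p_adj"] = []
        clustering.annotations[cluster] = df.reset_index(drop=True)
    return clustering


# ---------------------------------------------------------------------------
# plain-text writers


def write_components_tsv(components: list[set[str]], path) -> None:
    rows = [(i, n) for i, comp in enumerate(components) for n in sorted(comp)]
    pd.DataFrame(rows, columns=["component", "node"]).to_csv(path, sep="\t", index=False)


def write_hubs_tsv(g: nx.Graph, path) -> None:
    hubs = find_hubs(g)
    rows = [(n, d, n in hubs) for n, d in sorted(g.degree())]
    pd.DataFrame(rows, columns=["node", "degree", "is_hub"]).to_csv(
        path, sep="\t", index=False
    )


def write_clusters_tsv(clustering: NetworkClustering, path) -> None:
    rows = sorted(clustering.assignment.items())
    pd.DataFrame(rows, columns=["node", "cluster"]).to_csv(path, sep="\t", index=False)


def write_cluster_annotations_tsv(clustering: NetworkClustering, path) -> None:
    frames = []
    for cluster, df in sorted(clustering.annotations.items()):
        if len(df):
            out = df.copy()
            out.insert(0, "cluster", cluster)
            frames.append(out)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["cluster", "module_id", "n_module", "n_overlap", "expected", "p", "p_adj"]
        ).to_csv(path, sep="\t", index=False)
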