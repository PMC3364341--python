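"""Comprehensive screening, top-N bipartite networks and ligand clustering.

``comprehensive_screen`` scores every drug x target candidate pair with the
fitted classifier's binding score and annotates each pair, drug and target as
*known* (present among the catalog positives) or *new*. The top-N pairs form
a bipartite interaction network whose degree-sequence statistics
(centralization, heterogeneity, degree histogram) quantify how strongly the
predicted interaction space is dominated by hubs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import DescriptorMatrix, InteractionCatalog
from .exceptions import DtiforgeError


class ScoreTable:
    """Ranked candidate interactions.

    Wraps a DataFrame with columns drug_id, target_id, score, known, sorted by
    (score desc, drug_id, target_id) — the documented deterministic tie rule.
    """

    COLUMNS = ["drug_id", "target_id", "score", "known"]

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns) != self.COLUMNS:
            raise DtiforgeError(f"score table needs columns {self.COLUMNS}")
        if len(frame) and (frame["score"].min() < 0 or frame["score"].max() > 1):
            raise DtiforgeError("scores must lie in [0, 1]")
        self.frame = (
            frame.sort_values(
                ["score", "drug_id", "target_id"],
                ascending=[False, True, True],
                kind="mergesort",
            ).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    def top(self, n: int) -> pd.DataFrame:
        if n > len(self.frame):
            raise DtiforgeError(f"requested top {n} of a {len(self.frame)}-row table")
        return self.frame.head(n)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["score"] = out["score"].map(lambda v: f"{v:.3f}")  # presentation rounding only
        out.to_csv(path, sep="\t", index=False)


def comprehensive_screen(
    results,
    drugs: DescriptorMatrix,
    targets: DescriptorMatrix,
    catalog: InteractionCatalog,
    block_size: int = 4096,
) -> ScoreTable:
    """Score every drug x target pair and rank descending.

    Pairs are streamed in blocks of ``block_size`` drug-target combinations to
    bound memory; the output is independent of the block size. If the results
    carry a feature scaler, raw descriptor rows are scaled with the training
    ranges before scoring.
    """
    d_ids = drugs.row_ids
    t_ids = targets.row_ids
    D = drugs.values
    T = targets.values
    if D.shape[1] + T.shape[1] != results.n_features:
        raise DtiforgeError(
            f"pair dimension {D.shape[1] + T.shape[1]} does not match the "
            f"model's {results.n_features}"
        )
    rows_d, rows_t, scores = [], [], []
    pending: list[tuple[int, int]] = []

    def flush():
        if not pending:
            return
        X = np.hstack([D[[i for i, _ in pending]], T[[j for _, j in pending]]])
        if results.scaling is not None:
            X = results.scaling.transform(X)
        s = results.binding_score(X)
        for (i, j), v in zip(pending, s):
            rows_d.append(d_ids[i])
            rows_t.append(t_ids[j])
            scores.append(float(v))
        pending.clear()

    for i in range(len(d_ids)):
        for j in range(len(t_ids)):
            pending.append((i, j))
            if len(pending) >= block_size:
                flush()
    flush()
    frame = pd.DataFrame({
        "drug_id": rows_d,
        "target_id": rows_t,
        "score": scores,
    })
    frame["known"] = [
        (d, t) in catalog.positives for d, t in zip(frame["drug_id"], frame["target_id"])
    ]
    return ScoreTable(frame)


def top_n_network(table: ScoreTable, n: int) -> nx.Graph:
    """Bipartite network over the top-n scored pairs.

    Node attributes: ``kind`` (drug/target) and ``status`` (known/new — new iff
    the entity appears in no known positive of the screened table). Edge
    attributes: ``score`` and ``status`` (known/new pair).
    """
    top = table.top(n)
    known_drugs = set(table.frame.loc[table.frame["known"], "drug_id"])
    known_targets = set(table.frame.loc[table.frame["known"], "target_id"])
    g = nx.Graph()
    for row in top.itertuples(index=False):
        d = f"drug:{row.drug_id}"
        t = f"target:{row.target_id}"
        g.add_node(d, kind="drug", entity=row.drug_id,
                   status="known" if row.drug_id in known_drugs else "new")
        g.add_node(t, kind="target", entity=row.target_id,
                   status="known" if row.target_id in known_targets else "new")
        g.add_edge(d, t, score=float(row.score),
                   status="known" if row.known else "new")
    return g


def network_topology(net: nx.Graph) -> dict:
    """Degree centralization, heterogeneity and the degree histogram.

    centralization = (n/(n-2)) * (k_max/(n-1) - density)
    heterogeneity  = sqrt(variance(k)) / mean(k)   (population variance)

    Centralization is NaN for networks with fewer than 3 nodes; heterogeneity
    is 0 for any regular graph.
    """
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    n = len(degrees)
    hist: dict[int, int] = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    if n == 0:
        return {"centralization": float("nan"), "heterogeneity": float("nan"),
                "degree_histogram": hist}
    mean = degrees.mean()
    heterogeneity = float(np.sqrt(degrees.var()) / mean) if mean > 0 else float("nan")
    if n < 3:
        centralization = float("nan")
    else:
        density = nx.density(net)
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    return {
        "centralization": float(centralization),
        "heterogeneity": heterogeneity,
        "degree_histogram": dict(sorted(hist.items())),
    }


def write_network(net: nx.Graph, edge_tsv=None, graphml=None) -> None:
    if edge_tsv is not None:
        rows = [
            {
                "drug_id": net.nodes[u]["entity"] if net.nodes[u]["kind"] == "drug" else net.nodes[v]["entity"],
                "target_id": net.nodes[v]["entity"] if net.nodes[v]["kind"] == "target" else net.nodes[u]["entity"],
                "score": data["score"],
                "status": data["status"],
            }
            for u, v, data in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["drug_id", "target_id", "score", "status"]).to_csv(
            edge_tsv, sep="\t", index=False
        )
    if graphml is not None:
        nx.write_graphml(net, graphml)


# ---------------------------------------------------------------------------
# ligand clustering
# ---------------------------------------------------------------------------

def cluster_ligands(
    chem: DescriptorMatrix,
    linkage: str = "ward",
    k: int | None = 4,
    height: float | None = None,
) -> tuple[pd.Series, np.ndarray, list[str]]:
    """Agglomerative clustering of molecules on standardized descriptors.

    Default: Euclidean distance, Ward linkage, cut into k = 4 clusters (cut by
    ``height`` instead when given). Rows are ordered by id before linkage and
    cluster labels are canonicalized by the smallest row id they contain, so
    assignments are stable under row permutation. Returns (assignments indexed
    by row id, scipy linkage matrix, leaf labels in linkage order).
    """
    X = chem.values
    n = X.shape[0]
    if n < 2:
        raise DtiforgeError("clustering needs at least 2 rows")
    if k is not None and k > n:
        raise DtiforgeError(f"k = {k} exceeds number of rows {n}")
    # standardize non-constant columns
    sd = X.std(axis=0)
    mu = X.mean(axis=0)
    Z = (X - mu)
    nz = sd > 0
    Z[:, nz] = Z[:, nz] / sd[nz]
    # sort rows by id so the dendrogram (and hence the cut) is order-invariant
    order = np.argsort(np.array(chem.row_ids))
    ids_sorted = [chem.row_ids[i] for i in order]
    link = hierarchy.linkage(pdist(Z[order]), method=linkage)
    if height is not None:
        raw = hierarchy.fcluster(link, t=height, criterion="distance")
    else:
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # canonical labels: clusters numbered by their smallest member id
    groups: dict[int, list[str]] = {}
    for rid, lab in zip(ids_sorted, raw):
        groups.setdefault(int(lab), []).append(rid)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    mapping = {rid: ci + 1 for ci, members in enumerate(ordered) for rid in members}
    assignments = pd.Series({rid: mapping[rid] for rid in chem.row_ids}, name="cluster")
    assignments = assignments.loc[chem.row_ids]
    return assignments, link, ids_sorted


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Export a scipy linkage as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
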