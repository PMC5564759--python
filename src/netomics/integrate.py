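"""Module-metabolite integration: correlation, meta-clustering, key
metabolites and the bipartite network export.

The integration statistic is the Pearson correlation between module
eigengenes and normalized metabolite intensities over the samples shared by
both assays, with exact t-based two-sided p-values and Benjamini-Hochberg
adjustment across the whole matrix. On top of it sit:

* Cluster of Clusters: modules and metabolites are embedded by their
  correlation profiles (a module by its row across metabolites, a metabolite
  by its column across modules) and jointly clustered by average linkage on
  1 - |profile similarity|, cutting to k meta-clusters. Absolute similarity
  makes the assignment invariant to the arbitrary sign of any eigengene.
* Key metabolites: within each meta-cluster, the metabolite with the highest
  summed |correlation| to the cluster's modules.
* Bipartite network: thresholded module-metabolite (and optionally
  gene-metabolite) edges with weighted-degree node scores and hub flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModuleMetaboliteCorrelation",
    "MetaClustering",
    "BipartiteNetwork",
    "correlate_modules_metabolites",
    "cluster_of_clusters",
    "key_metabolites",
    "export_network",
]


class InsufficientOverlapError(ValueError):
    pass


@dataclass
class ModuleMetaboliteCorrelation:
    r: pd.DataFrame  # module x metabolite
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_overlap: int


@dataclass
class MetaClustering:
    entity_labels: pd.DataFrame  # columns: entity_id, entity_type, cluster
    n_clusters: int
    linkage_record: np.ndarray


@dataclass
class BipartiteNetwork:
    edges: pd.DataFrame  # source, target, weight
    node_scores: pd.Series
    hubs: list[str]


def correlation_pvalue(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for a Pearson correlation via the exact t transform,
    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def correlate_modules_metabolites(
    eigengenes: pd.DataFrame, metabolites: pd.DataFrame
) -> ModuleMetaboliteCorrelation:
    """Eigengene-metabolite Pearson correlation with BH-adjusted p-values."""
    shared = eigengenes.columns.intersection(metabolites.columns)
    n = len(shared)
    if n < 3:
        raise InsufficientOverlapError(f"only {n} shared samples; need >= 3")
    e = eigengenes[shared].to_numpy(dtype=float)
    m = metabolites[shared].to_numpy(dtype=float)
    es = e - e.mean(axis=1, keepdims=True)
    ms = m - m.mean(axis=1, keepdims=True)
    en = np.sqrt((es**2).sum(axis=1, keepdims=True))
    mn = np.sqrt((ms**2).sum(axis=1, keepdims=True))
    en[en == 0] = 1.0
    mn[mn == 0] = 1.0
    r = np.clip((es / en) @ (ms / mn).T, -1.0, 1.0)
    p = correlation_pvalue(r, n)
    p_adj = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    idx, cols = eigengenes.index, metabolites.index
    return ModuleMetaboliteCorrelation(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=cols),
        n_overlap=n,
    )


def _profile_similarity(r: np.ndarray) -> np.ndarray:
    """Joint similarity among modules (rows) and metabolites (columns).

    Works on the magnitude matrix A = |r|, making the result exactly
    invariant to the arbitrary sign of any eigengene (which negates a row
    of r but leaves A unchanged). Module-module and metabolite-metabolite
    similarity is the Pearson correlation of their A-profiles over the
    shared axis; module-metabolite similarity is A_ij directly.
    """
    a = np.abs(r)

    def profile_corr(profiles: np.ndarray) -> np.ndarray:
        if profiles.shape[1] < 2:
            # degenerate 1-long profiles carry no shape information
            return np.ones((profiles.shape[0], profiles.shape[0]))
        c = np.corrcoef(profiles)
        c = np.nan_to_num(c, nan=0.0)
        return np.clip(c, -1.0, 1.0)

    n_mod, n_met = a.shape
    n = n_mod + n_met
    s = np.zeros((n, n))
    s[:n_mod, :n_mod] = profile_corr(a)
    s[n_mod:, n_mod:] = profile_corr(a.T)
    s[:n_mod, n_mod:] = a
    s[n_mod:, :n_mod] = a.T
    np.fill_diagonal(s, 1.0)
    return s


def cluster_of_clusters(
    cm: ModuleMetaboliteCorrelation, k: int | None = 4
) -> MetaClustering:
    """Jointly cluster modules and metabolites by their correlation profiles.

    Average-linkage hierarchical clustering on 1 - |profile similarity|,
    cut to ``k`` clusters (default 4). ``k=None`` selects k in 2..8 by the
    largest silhouette on the dissimilarity.
    """
    r = cm.r.to_numpy()
    entities = list(cm.r.index) + list(cm.r.columns)
    types = ["module"] * len(cm.r.index) + ["metabolite"] * len(cm.r.columns)
    n = len(entities)
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds entity count {n}")
    sim = _profile_similarity(r)
    diss = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    link = average(squareform((diss + diss.T) / 2.0, checks=False))
    if k is None:
        best_k, best_score = 2, -np.inf
        for cand in range(2, min(8, n - 1) + 1):
            lab = fcluster(link, t=cand, criterion="maxclust")
            if len(set(lab)) < 2:
                continue
            score = silhouette_score(diss, lab, metric="precomputed")
            if score > best_score:
                best_k, best_score = cand, score
        k = best_k
    labels = fcluster(link, t=k, criterion="maxclust")
    table = pd.DataFrame(
        {"entity_id": entities, "entity_type": types, "cluster": labels}
    )
    return MetaClustering(
        entity_labels=table, n_clusters=int(len(set(labels))), linkage_record=link
    )


def key_metabolites(
    mc: MetaClustering, cm: ModuleMetaboliteCorrelation
) -> dict[int, str | None]:
    """Per meta-cluster, the metabolite with the highest summed |r| to the
    cluster's modules; metabolite-free clusters map to None, module-free
    clusters score metabolites 0 and fall back to lexicographic choice."""
    table = mc.entity_labels
    out: dict[int, str | None] = {}
    for cluster in sorted(table["cluster"].unique()):
        members = table[table["cluster"] == cluster]
        mets = sorted(members.loc[members["entity_type"] == "metabolite", "entity_id"])
        mods = list(members.loc[members["entity_type"] == "module", "entity_id"])
        if not mets:
            out[int(cluster)] = None
            continue
        scores = {
            met: float(cm.r.loc[mods, met].abs().sum()) if mods else 0.0
            for met in mets
        }
        best = max(scores, key=lambda m: (scores[m], ))
        ties = [m for m in mets if scores[m] == scores[best]]
        if len(ties) > 1:
            if mods:  # module-free clusters tie at zero by construction
                warnings.warn(
                    f"cluster {cluster}: key-metabolite tie {ties}; "
                    "breaking lexicographically"
                )
            best = sorted(ties)[0]
        out[int(cluster)] = best
    return out


def export_network(
    cm: ModuleMetaboliteCorrelation,
    kme: pd.DataFrame | None = None,
    gs: pd.DataFrame | None = None,
    threshold: float = 0.5,
    hub_quantile: float = 0.9,
) -> BipartiteNetwork:
    """Thresholded bipartite edge list with weighted-degree hub flags.

    Edges are all module-metabolite pairs with |r| >= threshold; when a GS
    table is supplied, gene-metabolite edges with |GS| >= threshold are
    appended. A node's score is the sum of |weight| over incident edges;
    hubs are the nodes at or above the ``hub_quantile`` quantile of scores.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rows = [
        {"source": mod, "target": met, "weight": float(cm.r.loc[mod, met])}
        for mod in cm.r.index
        for met in cm.r.columns
        if abs(cm.r.loc[mod, met]) >= threshold
    ]
    if gs is not None:
        strong = gs[gs.abs() >= threshold]
        for gene in strong.index:
            for met in strong.columns:
                w = strong.loc[gene, met]
                if pd.notna(w):
                    rows.append({"source": gene, "target": met, "weight": float(w)})
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    if edges.empty:
        warnings.warn("threshold produced an empty network")
        return BipartiteNetwork(
            edges=edges, node_scores=pd.Series(dtype=float), hubs=[]
        )
    scores = (
        pd.concat(
            [
                edges.assign(node=edges["source"]),
                edges.assign(node=edges["target"]),
            ]
        )
        .assign(absw=lambda d: d["weight"].abs())
        .groupby("node")["absw"]
        .sum()
        .sort_values(ascending=False)
    )
    cutoff = scores.quantile(hub_quantile)
    hubs = sorted(scores.index[scores >= cutoff])
    return BipartiteNetwork(edges=edges, node_scores=scores, hubs=hubs)
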