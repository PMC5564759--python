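"""Weighted co-expression network construction and gene-level statistics.

The network pipeline follows the standard weighted co-expression recipe:
pairwise Pearson correlation of genes, soft thresholding with a power chosen
by approximate scale-free topology fit, the topological overlap measure
(TOM), average-linkage clustering of 1 - TOM with a static dendrogram cut to
define modules, module eigengenes (first principal component of each module),
and the gene-level statistics the integration stage consumes:

* GS (gene significance): correlation of a gene with an external trait,
  here a metabolite intensity, over the samples shared by both assays.
* MM / kME (module membership, eigengene-based connectivity): correlation of
  a gene with a module eigengene, computed for every gene-module pair.

The topological overlap of genes i != j with adjacency ``a`` is

    TOM_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu``, and TOM_ii = 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "gene_significance",
    "module_membership",
    "build_network",
]


class DegenerateNetworkError(ValueError):
    pass


class InsufficientOverlapError(ValueError):
    pass


@dataclass
class NetworkConfig:
    power_candidates: list[float] = field(
        default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16]
    )
    target_r2: float = 0.8
    network_sign: str = "unsigned"  # or "signed"
    min_module_size: int = 20
    cut_height: float = 0.95
    n_kbins: int = 10


@dataclass
class NetworkState:
    """Everything downstream stages need from the network step."""

    beta: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_labels: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # module x sample
    kme: pd.DataFrame  # gene x module
    gs: pd.DataFrame | None = None  # gene x metabolite
    fit_table: pd.DataFrame | None = None


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation; constant genes dropped with a warning."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = expr.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("dropping %d constant gene(s): %s", len(constant),
                       list(constant[:5]))
        warnings.warn(f"dropping {len(constant)} constant gene(s)")
        expr = expr.drop(index=constant)
    x = expr.to_numpy()
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    cor = (x @ x.T) / (x.shape[1] - 1)
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: float,
              network_sign: str = "unsigned") -> pd.DataFrame | np.ndarray:
    """Soft-threshold correlations into a weighted adjacency in [0, 1]."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    c = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if network_sign == "unsigned":
        a = np.abs(c) ** beta
    elif network_sign == "signed":
        a = ((1.0 + c) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_sign {network_sign!r}")
    np.fill_diagonal(a, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(a, index=cor.index, columns=cor.columns)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """R^2 (signed negative when slope > 0) of log10 p(k) vs log10 k."""
    k = k[k > 0]
    if k.size == 0:
        raise DegenerateNetworkError("all-zero connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    log_k, log_p = np.array(log_k), np.array(log_p)
    if log_k.size < 3 or np.ptp(log_k) == 0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(log_k, log_p, 1)
    pred = slope * log_k + intercept
    ss_res = float(((log_p - pred) ** 2).sum())
    ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = -r2
    return float(r2), float(slope)


def pick_soft_threshold(
    cor: pd.DataFrame, config: NetworkConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Choose the soft power by approximate scale-free topology fit.

    Returns the smallest candidate whose signed fit index reaches
    ``target_r2``; if none does, the candidate with the best fit is
    returned with a warning. A single candidate is accepted as a forced
    choice (with a warning).
    """
    config = config or NetworkConfig()
    candidates = sorted(config.power_candidates)
    if not candidates:
        raise ValueError("power_candidates must be non-empty")
    rows = []
    for beta in candidates:
        a = adjacency(cor, beta, config.network_sign)
        a_np = a.to_numpy()
        k = a_np.sum(axis=1) - 1.0  # exclude the unit diagonal
        if np.allclose(k, 0.0):
            raise DegenerateNetworkError("all-zero connectivity (identity network)")
        r2, slope = _scale_free_fit(k, config.n_kbins)
        rows.append({"power": beta, "fit_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    if len(candidates) == 1:
        warnings.warn("single power candidate: forced choice")
        return float(candidates[0]), table
    ok = table[table["fit_r2"] >= config.target_r2]
    if len(ok):
        beta = float(ok.iloc[0]["power"])
    else:
        warnings.warn(
            f"no candidate reached target fit {config.target_r2}; "
            "returning the best-fitting power"
        )
        beta = float(table.loc[table["fit_r2"].idxmax(), "power"])
    return beta, table


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal."""
    a = adj.to_numpy() if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    # (off @ off)_ij = sum_u a_iu a_uj over u != i and u != j is obtained by
    # subtracting nothing: off has zero diagonal, so u = i, j terms vanish
    # except u = j (a_ij * a_jj-term absent) -- but u = j contributes
    # a_ij * 0 = 0 and likewise u = i; hence the product is already the
    # shared-neighbor sum.
    shared = off @ off
    num = shared + off
    den = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    tom: pd.DataFrame, config: NetworkConfig | None = None
) -> pd.Series:
    """Modules from average-linkage clustering of 1 - TOM, static cut.

    Clusters below ``min_module_size`` are relabelled 0 (unassigned);
    surviving modules are renumbered 1, 2, ... by decreasing size.
    """
    config = config or NetworkConfig()
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=config.cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= config.min_module_size]
    if keep.empty:
        warnings.warn("no cluster reached min_module_size: empty partition")
        return pd.Series(0, index=tom.index, name="module")
    mapping = {old: new for new, old in enumerate(keep.index, start=1)}
    return labels.map(lambda c: mapping.get(c, 0)).rename("module")


def module_eigengene(
    expr: pd.DataFrame, module_labels: pd.Series
) -> pd.DataFrame:
    """First-principal-component summary profile of each module.

    Eigengenes are scaled to unit standard deviation across samples and
    sign-oriented so the mean correlation with the module's genes is
    positive. Unassigned genes (label 0) are ignored.
    """
    out = {}
    for module in sorted(set(module_labels) - {0}):
        genes = module_labels.index[module_labels == module]
        if len(genes) == 0:
            raise ValueError(f"module {module} is empty")
        x = expr.loc[genes].to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        xs = (x - mu) / sd
        # first right singular vector = per-sample scores of PC1
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
        e = e / e.std(ddof=1)
        if np.corrcoef(np.vstack([e, xs]))[0, 1:].mean() < 0:
            e = -e
        out[f"ME{module}"] = e
    return pd.DataFrame(out, index=expr.columns).T


def _pairwise_correlation(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Rows of ``a`` vs rows of ``b`` over their shared sample columns."""
    shared = a.columns.intersection(b.columns)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared samples; need >= 3"
        )
    x = a[shared].to_numpy(dtype=float)
    y = b[shared].to_numpy(dtype=float)
    xs = (x - x.mean(axis=1, keepdims=True))
    ys = (y - y.mean(axis=1, keepdims=True))
    xn = np.sqrt((xs**2).sum(axis=1, keepdims=True))
    yn = np.sqrt((ys**2).sum(axis=1, keepdims=True))
    xn[xn == 0] = 1.0
    yn[yn == 0] = 1.0
    r = (xs / xn) @ (ys / yn).T
    np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=a.index, columns=b.index), len(shared)


def gene_significance(
    expr: pd.DataFrame, metabolite_values: pd.DataFrame
) -> pd.DataFrame:
    """GS: gene x metabolite Pearson correlation over shared samples."""
    gs, n = _pairwise_correlation(expr, metabolite_values)
    gs.attrs["n_overlap"] = n
    return gs


def module_membership(
    expr: pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """kME: gene x module correlation with every module eigengene."""
    kme, n = _pairwise_correlation(expr, eigengenes)
    kme.attrs["n_overlap"] = n
    return kme


def build_network(
    expr: pd.DataFrame,
    config: NetworkConfig | None = None,
    metabolites: pd.DataFrame | None = None,
) -> NetworkState:
    """Run the full network stage: power choice through kME (and GS)."""
    config = config or NetworkConfig()
    cor = correlation_matrix(expr)
    beta, fit_table = pick_soft_threshold(cor, config)
    adj = adjacency(cor, beta, config.network_sign)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, config)
    if (labels == 0).all():
        raise DegenerateNetworkError("no modules detected")
    eig = module_eigengene(expr.loc[cor.index], labels)
    kme = module_membership(expr.loc[cor.index], eig)
    gs = None
    if metabolites is not None:
        gs = gene_significance(expr.loc[cor.index], metabolites)
    return NetworkState(
        beta=beta, adjacency=adj, tom=tom, module_labels=labels,
        eigengenes=eig, kme=kme, gs=gs, fit_table=fit_table,
    )
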