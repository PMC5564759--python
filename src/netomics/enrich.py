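"""Connectivity-ranked gene set enrichment.

Two engines:

* :func:`preranked_gsea` — the classic weighted Kolmogorov-Smirnov running
  sum over a ranked gene list. Genes are sorted by decreasing statistic
  (here kME, normalized within a module); hits advance the running sum by
  |stat|^p / sum_set |stat|^p, misses retreat by 1 / (N - |S|); ES is the
  extremum of largest magnitude. Because the input is a pre-ranked list
  (no phenotype labels to permute), the null is random same-size gene sets;
  the empirical two-sided p uses the (count + 1)/(n_perm + 1) estimator and
  NES divides ES by the mean |permuted ES| of the same sign.
* :func:`per_sample_enrichment` — a single-sample rank statistic (ssGSEA
  style): within each sample, genes are ranked by expression and the score
  is the weighted difference between the in-set and out-of-set ECDFs of
  those ranks, giving a set-by-sample matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "preranked_gsea",
    "rank_by_connectivity",
    "gsea_table",
    "per_sample_enrichment",
]


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    n_perm: int
    leading_edge: list[str]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a set are dropped (order preserved) with a
    warning; a line with fewer than three fields is a parse error naming
    its line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[2].strip():
                raise GMTParseError(f"{path}: line {lineno} has < 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(f"set {name!r}: duplicated gene(s) dropped")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _enrichment_score(
    stats: np.ndarray, member: np.ndarray, weight_p: float
) -> tuple[float, int]:
    """ES and extremum position for a membership mask over a sorted list."""
    n = member.size
    n_hit = int(member.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper non-empty subset of the universe")
    w = np.abs(stats) ** weight_p if weight_p != 0 else np.ones(n)
    hit_w = np.where(member, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = member.astype(float)
        total = float(n_hit)
    steps = hit_w / total - (~member) / (n - n_hit)
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def preranked_gsea(
    ranked: pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "",
) -> EnrichmentResult:
    """Weighted KS enrichment of a gene set in a ranked list.

    ``ranked`` maps gene -> statistic; genes are sorted by decreasing
    statistic with ties broken by gene id. The permutation null resamples
    random gene sets of the same effective size.
    """
    ranked = ranked.sort_index().sort_values(ascending=False, kind="stable")
    genes = ranked.index.to_numpy()
    stats = ranked.to_numpy(dtype=float)
    member = np.isin(genes, list(gene_set))
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError("no gene of the set appears in the ranking")
    if n_hit == len(genes):
        raise ValueError("set covers the whole ranked universe: misses undefined")

    es, pos = _enrichment_score(stats, member, weight_p)
    if es >= 0:
        leading = [g for g, m in zip(genes[: pos + 1], member[: pos + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[pos:], member[pos:]) if m]

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    idx = np.arange(len(genes))
    for b in range(n_perm):
        pick = rng.choice(idx, size=n_hit, replace=False)
        mask = np.zeros(len(genes), dtype=bool)
        mask[pick] = True
        perm_es[b], _ = _enrichment_score(stats, mask, weight_p)
    p = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
    same_sign = perm_es[perm_es >= 0] if es >= 0 else perm_es[perm_es < 0]
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(
        set_name=set_name, es=es, nes=float(nes), p=float(p), fdr=float(p),
        n_perm=n_perm, leading_edge=leading,
    )


def rank_by_connectivity(kme: pd.DataFrame, module: str) -> pd.Series:
    """Ranking statistic: kME to a module, normalized by the module's max |kME|.

    Descending order with ties broken by gene id; the top gene scores 1.0.
    """
    if module not in kme.columns:
        raise ValueError(f"unknown module {module!r}")
    col = kme[module].dropna()
    if col.empty:
        raise ValueError(f"module {module!r} has no genes")
    max_abs = col.abs().max()
    if max_abs == 0:
        raise ValueError(f"module {module!r} has all-zero kME")
    stat = col / max_abs
    return stat.sort_index().sort_values(ascending=False, kind="stable")


def gsea_table(
    ranked: pd.Series,
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked GSEA for every set and BH-adjust p into FDR."""
    results = []
    for i, name in enumerate(collection):
        present = [g for g in collection[name] if g in ranked.index]
        if not present or len(present) >= len(ranked):
            warnings.warn(f"set {name!r} skipped: empty or universe-covering")
            continue
        results.append(
            preranked_gsea(
                ranked, present, weight_p=weight_p, n_perm=n_perm,
                seed=seed + i, set_name=name,
            )
        )
    if not results:
        return pd.DataFrame(columns=["set", "es", "nes", "p", "fdr", "size"])
    table = pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "size": [len(r.leading_edge) for r in results],
        }
    )
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table[["set", "es", "nes", "p", "fdr", "size"]]


def per_sample_enrichment(
    expr: pd.DataFrame, collection: GeneSetCollection, alpha: float = 0.25
) -> pd.DataFrame:
    """Single-sample enrichment: sets x samples score matrix.

    Within each sample, genes are ranked by expression (1 = lowest);
    the score is the sum over the ranked list of the difference between the
    rank-weighted in-set ECDF and the unweighted out-of-set ECDF, scaled by
    the list length. Depends on expression only through within-sample ranks.
    Sets with no gene in the matrix yield a zero row with a warning.
    """
    n_genes = expr.shape[0]
    ranks = expr.rank(axis=0, method="average").to_numpy()
    genes = expr.index
    scores = np.zeros((len(collection), expr.shape[1]))
    for i, name in enumerate(collection):
        member = np.asarray(genes.isin(collection[name]))
        if not member.any():
            warnings.warn(f"set {name!r} disjoint from the expression matrix")
            continue
        if member.all():
            continue
        for j in range(expr.shape[1]):
            order = np.argsort(-ranks[:, j], kind="stable")
            m = member[order]
            w = np.abs(ranks[order, j]) ** alpha
            hit_w = np.where(m, w, 0.0)
            p_in = np.cumsum(hit_w) / hit_w.sum()
            p_out = np.cumsum(~m) / (n_genes - m.sum())
            scores[i, j] = (p_in - p_out).sum() / n_genes
    return pd.DataFrame(scores, index=list(collection), columns=expr.columns)
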