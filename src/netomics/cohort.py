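"""Sample-level cohort analyses: consensus clustering, subtype
classification and survival statistics.

Consensus clustering follows the Monti resampling scheme: for each candidate
k, samples are repeatedly subsampled, clustered (average-linkage hierarchical
on Euclidean distance), and pairwise co-membership counts are normalized by
co-sampling counts. The consensus CDF area and its relative increase
(delta area) over k guide the choice of k.

Kaplan-Meier and the log-rank test are implemented directly from their
closed forms so they are testable by hand; the Cox proportional-hazards fit
is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "hierarchical_cluster",
    "train_subtype_classifier",
    "predict_subtypes",
    "evaluate_classifier",
    "km_estimate",
    "logrank_test",
    "cox_hr",
]


class CoverageError(ValueError):
    pass


class DegenerateSurvivalError(ValueError):
    pass


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> sample x sample matrix
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    best_k: int
    labels: dict[int, pd.Series]  # k -> sample labels


def hierarchical_cluster(
    matrix: pd.DataFrame,
    k: int,
    linkage_method: str = "average",
    distance: str = "euclidean",
) -> pd.Series:
    """Agglomerative clustering of samples (rows); deterministic."""
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds sample count {matrix.shape[0]}")
    if linkage_method not in ("average", "complete", "single", "ward"):
        raise ValueError(f"invalid linkage {linkage_method!r}")
    link = linkage(matrix.to_numpy(), method=linkage_method, metric=distance)
    return pd.Series(
        fcluster(link, t=k, criterion="maxclust"), index=matrix.index, name="cluster"
    )


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries on [0, 1]."""
    xs = np.sort(values)
    xs = np.concatenate([[0.0], xs, [1.0]])
    cdf = np.concatenate([[0.0], np.arange(1, values.size + 1) / values.size, [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cluster(
    matrix: pd.DataFrame,
    kmax: int = 10,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage_method: str = "average",
) -> ConsensusResult:
    """Monti consensus clustering of samples (rows of ``matrix``).

    best_k is the k >= 3 with the largest relative delta area, or 2 when
    kmax = 2. Final per-k labels come from average-linkage clustering of
    1 - consensus.
    """
    if reps < 10:
        raise ValueError("reps must be >= 10")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    samples = matrix.index
    n = len(samples)
    m = max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    subsets = [
        np.sort(rng.choice(n, size=m, replace=False)) for _ in range(reps)
    ]
    co_sampled = np.zeros((n, n))
    for idx in subsets:
        co_sampled[np.ix_(idx, idx)] += 1.0
    if (co_sampled == 0).any():
        raise CoverageError(
            "some sample pairs were never co-subsampled; increase reps or fraction"
        )

    x = matrix.to_numpy()
    consensus: dict[int, pd.DataFrame] = {}
    labels: dict[int, pd.Series] = {}
    cdf_area: dict[int, float] = {}
    for k in range(2, kmax + 1):
        co_cluster = np.zeros((n, n))
        for idx in subsets:
            sub_link = linkage(x[idx], method=linkage_method, metric="euclidean")
            lab = fcluster(sub_link, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        cons = co_cluster / co_sampled
        np.fill_diagonal(cons, 1.0)
        cons_df = pd.DataFrame(cons, index=samples, columns=samples)
        consensus[k] = cons_df
        tri = cons[np.triu_indices(n, k=1)]
        cdf_area[k] = _cdf_area(tri)
        final_link = linkage(
            squareform(np.clip(1.0 - cons, 0.0, None), checks=False),
            method="average",
        )
        labels[k] = pd.Series(
            fcluster(final_link, t=k, criterion="maxclust"),
            index=samples,
            name=f"k{k}",
        )

    delta_area: dict[int, float] = {2: cdf_area[2]}
    for k in range(3, kmax + 1):
        prev = cdf_area[k - 1]
        delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    if kmax >= 3:
        best_k = max(range(3, kmax + 1), key=lambda k: delta_area[k])
    else:
        best_k = 2
    return ConsensusResult(
        consensus=consensus,
        cdf_area=cdf_area,
        delta_area=delta_area,
        best_k=best_k,
        labels=labels,
    )


def train_subtype_classifier(
    train_expr: pd.DataFrame,
    train_labels: pd.Series,
    seed: int = 0,
    n_estimators: int = 500,
) -> RandomForestClassifier:
    """Random-forest subtype classifier on genes x samples expression."""
    counts = train_labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 classes in training data")
    if (counts < 5).any():
        small = list(counts.index[counts < 5])
        raise ValueError(f"classes with < 5 training samples: {small}")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(train_expr.T.to_numpy(), train_labels.loc[train_expr.columns].to_numpy())
    clf.feature_names_ = list(train_expr.index)
    return clf


def predict_subtypes(
    classifier: RandomForestClassifier, expr: pd.DataFrame
) -> pd.Series:
    """Predict subtype labels for new samples (columns of ``expr``)."""
    aligned = expr.reindex(classifier.feature_names_).fillna(0.0)
    return pd.Series(
        classifier.predict(aligned.T.to_numpy()), index=expr.columns, name="subtype"
    )


def evaluate_classifier(
    predicted: pd.Series, truth: pd.Series
) -> pd.DataFrame:
    """Per-class and macro sensitivity/specificity from the confusion matrix."""
    classes = sorted(set(truth) | set(predicted))
    rows = []
    for c in classes:
        tp = int(((predicted == c) & (truth == c)).sum())
        fn = int(((predicted != c) & (truth == c)).sum())
        fp = int(((predicted == c) & (truth != c)).sum())
        tn = int(((predicted != c) & (truth != c)).sum())
        rows.append(
            {
                "class": c,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    table.loc["macro"] = table.mean()
    return table


def km_estimate(table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator for one pooled sample.

    Returns a step table (time, n_at_risk, n_events, survival) with one row
    per distinct event time; survival after time t_i is
    prod_{j <= i} (1 - d_j / n_j).
    """
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    if e.sum() == 0:
        raise DegenerateSurvivalError("no events observed")
    rows = []
    s = 1.0
    for ti in np.unique(t[e == 1]):
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        rows.append(
            {"time": float(ti), "n_at_risk": n_risk, "n_events": d, "survival": s}
        )
    return pd.DataFrame(rows)


def logrank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Log-rank test across the ``group`` column.

    Observed-minus-expected statistic with hypergeometric variance at each
    event time; chi-square with (groups - 1) degrees of freedom. With two
    groups the statistic reduces to (O1 - E1)^2 / V1.
    """
    groups = sorted(table["group"].unique())
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    gl = table["group"].to_numpy()
    if e.sum() == 0:
        raise DegenerateSurvivalError("no events observed")
    o_minus_e = np.zeros(g)
    # covariance of the observed counts, summed over event times
    cov = np.zeros((g, g))
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        d = int(((t == ti) & (e == 1)).sum())
        n_g = np.array([int((at_risk & (gl == grp)).sum()) for grp in groups])
        d_g = np.array(
            [int(((t == ti) & (e == 1) & (gl == grp)).sum()) for grp in groups]
        )
        expected = d * n_g / n
        o_minus_e += d_g - expected
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p_g = n_g / n
            cov += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    sub = cov[:-1, :-1]
    v = o_minus_e[:-1]
    if np.allclose(v, 0.0):
        return 0.0, 1.0
    chi2_stat = float(v @ np.linalg.pinv(sub) @ v)
    p = float(chi2.sf(chi2_stat, df=g - 1))
    return chi2_stat, p


def cox_hr(table: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Cox proportional-hazards HR (second group vs first) with 95% CI."""
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("cox_hr expects exactly 2 groups")
    if table["event"].sum() == 0:
        raise DegenerateSurvivalError("no events observed")
    df = table.assign(x=(table["group"] == groups[1]).astype(int))[
        ["time", "event", "x"]
    ]
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(fitter.params_["x"]))
    lo, hi = fitter.confidence_intervals_.loc["x"]
    return hr, (float(np.exp(lo)), float(np.exp(hi)))
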