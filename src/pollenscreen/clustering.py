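"""Expression-pattern clustering with χ²-based cluster-number selection.

Per-gene 5-stage profiles (tissue medians over UNM → GPG) are standardized to
mean 0 and variance 1, clustered by k-means for each k in a range (default
3–7), and the number of clusters is chosen as the k whose cluster ×
functional-category contingency table shows the most significant Pearson χ²
association (smallest p; ties favour the smaller k).  Cluster labels are
canonicalized by the stage at which each centroid peaks, so "c0…c(k−1)" names
are stable across seeds for well-separated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .expr_model import POLLEN_STAGES, ExpressionDataset, ProbeAnnotation


@dataclass
class StandardizedProfiles:
    """Gene × 5-stage standardized profile matrix.

    Every row has mean 0 and variance 1; genes with a constant profile cannot
    be standardized and are listed in ``dropped``.
    """

    profiles: pd.DataFrame
    dropped: list[str]


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame          # k × 5, canonical order
    assignments: pd.Series           # gene -> "c0".."c(k-1)"
    seed: int
    inertia: float


@dataclass
class ClusterSelectionTrace:
    """Per-k χ² association between cluster assignment and category."""

    records: pd.DataFrame            # columns k, chi2, df, p
    tables: dict[int, pd.DataFrame]  # k -> cluster × category contingency
    models: dict[int, ClusterModel]


def standardize_profiles(
    dataset: ExpressionDataset,
    genes: list[str] | None = None,
    stages: tuple[str, ...] = POLLEN_STAGES,
) -> StandardizedProfiles:
    """Row-standardize per-gene stage-median profiles to mean 0, variance 1.

    Variance uses the population convention (denominator n), matching the
    usual profile-shape normalisation before pattern clustering.  Constant
    rows are dropped and reported.
    """
    med = dataset.tissue_medians(list(stages))
    if genes is not None:
        med = med.loc[genes]
    values = med.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    out = (values - mean) / np.where(sd == 0, 1.0, sd)
    profiles = pd.DataFrame(out[~constant], index=med.index[~constant], columns=list(stages))
    return StandardizedProfiles(profiles=profiles, dropped=list(med.index[constant]))


def _canonical_order(centroids: np.ndarray) -> np.ndarray:
    """Order clusters by peak stage, then lexicographically by centroid."""
    keys = [(int(np.argmax(c)), tuple(np.round(c, 9))) for c in centroids]
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))


def cluster_patterns(
    profiles: StandardizedProfiles,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterModel:
    """Seeded k-means on standardized profiles with canonical cluster labels."""
    if k < 2:
        raise ValueError("k must be >= 2")
    data = profiles.profiles.to_numpy(dtype=float)
    n_distinct = len(np.unique(data, axis=0))
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct profiles for k={k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(data)
    order = _canonical_order(km.cluster_centers_)
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = pd.Series(
        [f"c{relabel[int(r)]}" for r in raw],
        index=profiles.profiles.index, name="cluster",
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=[f"c{i}" for i in range(k)],
        columns=profiles.profiles.columns,
    )
    return ClusterModel(k=k, centroids=centroids, assignments=labels,
                        seed=seed, inertia=float(km.inertia_))


def chi_square_cluster_category(
    assignments: pd.Series,
    categories: pd.Series,
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson χ² on the cluster × category contingency table.

    All-zero rows/columns are dropped with a warning before testing; no
    continuity correction is applied.  Returns (statistic, df, p, table).
    """
    common = assignments.index.intersection(categories.index)
    table = pd.crosstab(assignments.loc[common], categories.loc[common])
    empty_rows = table.index[(table.sum(axis=1) == 0)]
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(
            f"dropping empty rows {list(empty_rows)} / columns {list(empty_cols)}"
        )
        table = table.drop(index=empty_rows, columns=empty_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >=2 clusters and >=2 categories with counts")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(df), float(p), table


def _chi2_log_sf(chi2: float, df: int) -> float:
    """log of the χ² upper tail, finite even far beyond double underflow.

    Falls back to the leading terms of the upper-incomplete-gamma asymptotic
    Q(a, z) ≈ z^(a-1) e^(-z) / Γ(a) · (1 + (a-1)/z) when scipy's logsf
    underflows; only the ranking across k matters at that magnitude.
    """
    lp = float(stats.chi2.logsf(chi2, df))
    if np.isfinite(lp):
        return lp
    from scipy.special import gammaln

    a, z = df / 2.0, chi2 / 2.0
    return float(-z + (a - 1.0) * np.log(z) - gammaln(a) + np.log1p(max(a - 1.0, 0.0) / z))


def select_cluster_number(
    profiles: StandardizedProfiles,
    categories: pd.Series,
    k_range: tuple[int, int] = (3, 7),
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[int, ClusterSelectionTrace]:
    """Choose k in ``k_range`` by the most significant cluster-category χ².

    Clusters the profiles for every k, tests the association between cluster
    assignment and functional category, and returns the k with the smallest
    p-value (ties → smaller k) together with the full selection trace.
    """
    lo, hi = k_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid k range {k_range}")
    rows = []
    tables: dict[int, pd.DataFrame] = {}
    models: dict[int, ClusterModel] = {}
    for k in range(lo, hi + 1):
        model = cluster_patterns(profiles, k, seed=seed, n_restarts=n_restarts)
        chi2, df, p, table = chi_square_cluster_category(model.assignments, categories)
        # log-scale p so strong associations do not underflow into spurious ties
        log_p = _chi2_log_sf(chi2, df)
        rows.append({"k": k, "chi2": chi2, "df": df, "p": p, "log_p": log_p})
        tables[k] = table
        models[k] = model
    records = pd.DataFrame(rows)
    best_k = int(records.sort_values(["log_p", "k"]).iloc[0]["k"])
    return best_k, ClusterSelectionTrace(records=records, tables=tables, models=models)


def summarize_cluster_table(
    assignments: pd.Series,
    annotation: ProbeAnnotation | pd.Series,
) -> pd.DataFrame:
    """Category × cluster count table with a Total column.

    ``annotation`` may be a :class:`ProbeAnnotation` (its functional groups
    are used) or a plain gene → category Series covering the same genes.
    """
    if isinstance(annotation, ProbeAnnotation):
        categories = annotation.functional_groups()
    else:
        categories = annotation
    common = assignments.index.intersection(categories.index)
    table = pd.crosstab(categories.loc[common], assignments.loc[common])
    table["Total"] = table.sum(axis=1)
    return table


def cluster_subset_share(
    row: pd.Series | dict[str, float] | list[float],
    clusters: list[str] | list[int],
    all_clusters: list[str] | None = None,
) -> float:
    """Share (%) of one category's genes falling in a subset of clusters.

    ``row`` may be a per-cluster count Series/dict keyed "c0".., or a plain
    count list in cluster order (then ``clusters`` holds integer positions).
    Used e.g. for the late-accumulation share, clusters c0–c2.
    """
    if isinstance(row, (list, tuple, np.ndarray)):
        counts = {i: float(v) for i, v in enumerate(row)}
    elif isinstance(row, pd.Series):
        counts = {k: float(v) for k, v in row.items() if k != "Total"}
    else:
        counts = {k: float(v) for k, v in row.items()}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    subset = sum(counts[c] for c in clusters)
    return 100.0 * subset / total
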