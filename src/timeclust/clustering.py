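"""K-means clustering of fitted temporal profiles with data-driven choice of k.

Surviving probes (significant + R^2 stringency) are represented by their
standardized treated-minus-control fitted difference over the day grid and
clustered by k-means.  The number of clusters is selected by sweeping k and
maximizing the mean silhouette width, with a gap-statistic check deciding
whether a single cluster explains the data better than any partition.  When
too few probes survive filtering the analysis reports zero clusters — the
degenerate outcome seen when a stringent R^2 tier removes nearly everything.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import InputError
from .regression import ContrastFit


@dataclasses.dataclass
class ClusterConfig:
    """Knobs of the profile-clustering stage.

    k_min/k_max : candidate range for the number of clusters.
    restarts : k-means restarts per candidate k (best inertia kept).
    min_cluster_size : smallest admissible cluster (1 permits singleton
        clusters, as extreme single-probe responses warrant).
    min_probes : fewer surviving probes than this reports zero clusters.
    feature_mode : 'fitted_difference' (default), 'fitted_both', or
        'coefficients'.
    """

    k_min: int = 1
    k_max: int = 15
    restarts: int = 25
    seed: int = 0
    min_cluster_size: int = 1
    min_probes: int = 5
    feature_mode: str = "fitted_difference"
    gap_refs: int = 20

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError(f"need 1 <= k_min <= k_max, got {self.k_min}..{self.k_max}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.feature_mode not in ("fitted_difference", "fitted_both", "coefficients"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


def _zscore_rows(mat: np.ndarray) -> np.ndarray:
    """Per-row standardization; zero-variance rows map to all-zeros."""
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def profile_vectors(fit: ContrastFit, probes: Iterable[str] | None = None,
                    feature_mode: str = "fitted_difference") -> pd.DataFrame:
    """Feature matrix (probe x feature) for clustering.

    fitted_difference: per-probe z-scored (treated - control) fitted values
    at the grid days — scale- and baseline-invariant, so clusters group
    probes by response *shape*.  fitted_both concatenates both z-scored
    curves; coefficients uses the reduced-model coefficient vector.
    """
    probes = fit.survivors() if probes is None else pd.Index(probes)
    treated, control = fit.profiles(probes)
    if feature_mode == "fitted_difference":
        diff = treated.to_numpy() - control.to_numpy()
        feats = _zscore_rows(diff)
        cols = [f"d{d:g}" for d in fit.day_grid]
    elif feature_mode == "fitted_both":
        feats = np.hstack([_zscore_rows(treated.to_numpy()), _zscore_rows(control.to_numpy())])
        cols = [f"treat_d{d:g}" for d in fit.day_grid] + [f"ctrl_d{d:g}" for d in fit.day_grid]
    elif feature_mode == "coefficients":
        sub = fit.table.loc[probes]
        coef_cols = [c for c in sub.columns if c.startswith("coef_")]
        if not coef_cols:  # reduced models: rebuild from fitted difference instead
            raise InputError("coefficient features unavailable on this fit table")
        feats = sub[coef_cols].to_numpy()
        cols = coef_cols
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    return pd.DataFrame(feats, index=probes, columns=cols)


def kmeans_cluster(vectors: pd.DataFrame | np.ndarray, k: int, restarts: int = 25,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Best-of-restarts k-means; labels are 1..k, every cluster non-empty.

    Raises when k exceeds the number of distinct vectors.
    """
    mat = vectors.to_numpy() if isinstance(vectors, pd.DataFrame) else np.asarray(vectors)
    n_distinct = np.unique(mat, axis=0).shape[0]
    if k > n_distinct:
        raise InputError(f"k={k} exceeds the {n_distinct} distinct vectors")
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        # near-duplicate points can collapse centroids for large k; such
        # candidates are discarded by the size check in select_optimal_k
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(mat)
    return km.labels_ + 1, float(km.inertia_)


def _log_wk(mat: np.ndarray, k: int, restarts: int, seed: int) -> float:
    if k == 1:
        centered = mat - mat.mean(axis=0, keepdims=True)
        w = float((centered ** 2).sum())
    else:
        _, w = kmeans_cluster(mat, k, restarts, seed)
    return np.log(max(w, 1e-300))


def gap_statistic(mat: np.ndarray, k: int, restarts: int, seed: int,
                  n_refs: int = 20) -> tuple[float, float]:
    """Tibshirani-style gap and its standard error at one k.

    References are sampled uniformly within the per-feature bounding box of
    the data, using a generator seeded independently of k-means restarts.
    """
    rng = np.random.default_rng(seed + 977)
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    ref_logs = []
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=mat.shape)
        ref_logs.append(_log_wk(ref, k, max(5, restarts // 5), seed))
    ref_logs = np.array(ref_logs)
    gap = float(ref_logs.mean() - _log_wk(mat, k, restarts, seed))
    se = float(ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs))
    return gap, se


@dataclasses.dataclass
class KSelection:
    k_star: int
    scores: dict  # candidate k -> selection score
    labels: pd.Series | None  # probe -> cluster id (1..k), None when k_star == 0


def select_optimal_k(vectors: pd.DataFrame, config: ClusterConfig) -> KSelection:
    """Choose the number of clusters.

    Fewer than min_probes vectors: k_star = 0 (degenerate outcome).
    Otherwise sweep k in [max(2, k_min), k_max], scoring each candidate by
    mean silhouette width (ties toward smaller k); candidates producing a
    cluster below min_cluster_size are discarded.  When k_min allows one
    cluster, a gap-statistic comparison decides whether the un-partitioned
    data beat the silhouette winner: k_star = 1 iff
    gap(1) >= gap(k_best) - se(k_best).
    """
    n = len(vectors)
    if n < config.min_probes:
        return KSelection(k_star=0, scores={}, labels=None)
    mat = vectors.to_numpy()
    n_distinct = np.unique(mat, axis=0).shape[0]
    if n_distinct == 1:
        labels = pd.Series(1, index=vectors.index)
        return KSelection(k_star=1, scores={1: 0.0}, labels=labels)

    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    k_lo = max(2, config.k_min)
    k_hi = min(config.k_max, n_distinct - 1, n - 1)
    for k in range(k_lo, k_hi + 1):
        labels, _ = kmeans_cluster(mat, k, config.restarts, config.seed)
        sizes = np.bincount(labels)[1:]
        if sizes.min() < config.min_cluster_size:
            continue
        scores[k] = float(silhouette_score(mat, labels))
        labels_by_k[k] = labels
    if not scores:
        # nothing admissible beyond a single cluster
        labels = pd.Series(1, index=vectors.index)
        return KSelection(k_star=1 if config.k_min <= 1 else 0,
                          scores={1: 0.0}, labels=labels if config.k_min <= 1 else None)

    k_best = max(scores, key=lambda k: (scores[k], -k))
    k_star = k_best
    if config.k_min <= 1:
        gap1, _ = gap_statistic(mat, 1, config.restarts, config.seed, config.gap_refs)
        gapb, seb = gap_statistic(mat, k_best, config.restarts, config.seed, config.gap_refs)
        scores[1] = gap1 - (gapb - seb)  # positive favours a single cluster
        if gap1 >= gapb - seb:
            k_star = 1
            labels_by_k[1] = np.ones(n, dtype=int)
    labels = pd.Series(labels_by_k[k_star], index=vectors.index)
    return KSelection(k_star=k_star, scores=scores, labels=labels)


@dataclasses.dataclass
class ClusterResult:
    """Clustering outcome for one treatment contrast."""

    contrast: str
    k: int
    labels: pd.Series | None  # probe -> cluster id 1..k
    cluster_profiles: pd.DataFrame  # cluster, day, mean_treated, mean_control
    selection_scores: dict

    def probe_ids(self) -> pd.Index:
        return self.labels.index if self.labels is not None else pd.Index([])


def cluster_contrast(fit: ContrastFit, config: ClusterConfig,
                     r2_threshold: float | None = None) -> ClusterResult:
    """Filter survivors, build feature vectors, pick k, summarize clusters."""
    survivors = fit.survivors(r2_threshold)
    if len(survivors) < config.min_probes:
        empty = pd.DataFrame(columns=["cluster", "day", "mean_treated", "mean_control"])
        return ClusterResult(contrast=fit.contrast, k=0, labels=None,
                             cluster_profiles=empty, selection_scores={})
    vectors = profile_vectors(fit, survivors, config.feature_mode)
    sel = select_optimal_k(vectors, config)
    treated, control = fit.profiles(survivors)
    rows = []
    for c in range(1, sel.k_star + 1):
        members = sel.labels.index[sel.labels == c]
        for j, d in enumerate(fit.day_grid):
            rows.append({
                "cluster": c, "day": d,
                "mean_treated": float(treated.loc[members].iloc[:, j].mean()),
                "mean_control": float(control.loc[members].iloc[:, j].mean()),
            })
    profiles = pd.DataFrame(rows, columns=["cluster", "day", "mean_treated", "mean_control"])
    return ClusterResult(contrast=fit.contrast, k=sel.k_star, labels=sel.labels,
                         cluster_profiles=profiles, selection_scores=sel.scores)


def cluster_report(result_a: ClusterResult, result_b: ClusterResult,
                   annotation: pd.Series) -> dict:
    """Combined cluster tables with shared-across-contrasts flags.

    For each contrast: rows (probe_id, gene, cluster, shared_flag), where
    shared_flag marks probes clustered in *both* contrasts — the grey-square
    annotation of the published cluster tables.
    """
    ids = {r.contrast: set(r.probe_ids()) for r in (result_a, result_b)}
    out = {}
    for res, other in ((result_a, result_b), (result_b, result_a)):
        if res.k == 0:
            out[res.contrast] = pd.DataFrame(
                columns=["probe_id", "gene", "cluster", "shared_flag"])
            continue
        shared = ids[other.contrast]
        tbl = pd.DataFrame({
            "probe_id": res.labels.index,
            "gene": annotation.reindex(res.labels.index).fillna("").to_numpy(),
            "cluster": res.labels.to_numpy(),
            "shared_flag": [p in shared for p in res.labels.index],
        }).sort_values(["cluster", "probe_id"]).reset_index(drop=True)
        out[res.contrast] = tbl
    return out
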