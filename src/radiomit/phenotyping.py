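"""Phenotype discovery: Ward clustering, consensus k-selection, SigClust.

Features are z-scored per column before clustering (documented pre-step;
Ward/Euclidean is scale-sensitive). The consensus procedure subsamples
patients only. The SigClust null is a single Gaussian with diagonal
covariance equal to the eigenvalues of the sample covariance (principal-axis
formulation, with Ledoit-Wolf eigenvalue shrinkage for finite-sample
calibration); its test statistic is the cluster index (CI): within-cluster
sum of squares about cluster means divided by total sum of squares about the
overall mean, minimized over 2-means restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.covariance import LedoitWolf

from radiomit.types import FeatureTable

__all__ = [
    "standardize",
    "ward_cluster",
    "cluster_index",
    "consensus_cluster",
    "ConsensusResult",
    "sigclust",
    "SigClustResult",
    "split_significance",
    "SplitSignificance",
    "identify_phenotypes",
    "PhenotypeResult",
]


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureTable):
        return features.values.to_numpy(dtype=float)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score columns; constant columns map to 0."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def ward_cluster(
    features, k: int, standardize_input: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Ward/Euclidean hierarchical clustering cut at k clusters.

    Returns (labels in 0..k-1, scipy linkage matrix).
    """
    x = _as_array(features)
    n = x.shape[0]
    if n < 3:
        raise ValueError("ward_cluster needs at least 3 observations")
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    if standardize_input:
        x = standardize(x)
    merge = linkage(x, method="ward")
    labels = fcluster(merge, t=k, criterion="maxclust") - 1
    return labels, merge


def cluster_index(features, labels) -> float:
    """Within-cluster SS about cluster means / total SS about the overall mean."""
    x = _as_array(features)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("cluster_index needs >= 2 clusters")
    total = float(((x - x.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 0.0
    within = 0.0
    for lab in uniq:
        rows = x[labels == lab]
        if rows.shape[0] == 0:
            raise ValueError(f"empty cluster {lab}")
        within += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return within / total


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus: dict[int, np.ndarray]  # k -> patients x patients matrix
    cdf_areas: dict[int, float]
    pac: dict[int, float]  # proportion of ambiguous consensus entries
    chosen_k: int
    labels: np.ndarray  # full-data Ward labels at chosen_k


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus entries over [0, 1]."""
    v = np.sort(values)
    # grid of unique consensus values plus the endpoint 1
    xs = np.unique(np.concatenate([v, [1.0]]))
    cdf = np.searchsorted(v, xs, side="right") / len(v)
    widths = np.diff(np.concatenate([[0.0], xs]))
    return float(np.sum(widths * cdf))


def consensus_cluster(
    features,
    k_range=range(2, 7),
    n_subsamples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    k_rule: str = "pac",
    area_increase_threshold: float = 0.05,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    standardize_input: bool = True,
) -> ConsensusResult:
    """Subsample-based consensus clustering with stability-based k selection.

    For each candidate k, ``n_subsamples`` patient subsamples (without
    replacement, fraction ``subsample_fraction``) are Ward-clustered; the
    consensus entry for a patient pair is the proportion of co-clusterings
    among their co-appearances. The CDF of the off-diagonal consensus
    entries (pairs that never co-appeared are skipped with a warning) and its
    area summarize stability per k.

    k selection (``k_rule``):

    * ``"pac"`` (default): minimize the proportion of ambiguous consensus
      entries, i.e. the CDF mass strictly inside ``pac_bounds`` (ties go to
      the smaller k). A perfectly stable clustering has all entries at 0 or
      1 and PAC 0.
    * ``"area-increase"``: largest k whose relative CDF-area increase over
      the previous k exceeds ``area_increase_threshold`` (k=2 if none does).
      Note the CDF area grows substantially with k even on clean 2-cluster
      data (forced extra splits move consensus mass off 1), so this rule
      over-selects k; it is kept for comparison only.
    """
    if not 0.5 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0.5, 1)")
    x = _as_array(features)
    if standardize_input:
        x = standardize(x)
    n = x.shape[0]
    m = int(round(subsample_fraction * n))
    ks = sorted(k_range)
    rng = np.random.default_rng(seed)

    if k_rule not in {"pac", "area-increase"}:
        raise ValueError("k_rule must be 'pac' or 'area-increase'")
    consensus: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    pac: dict[int, float] = {}
    for k in ks:
        together = np.zeros((n, n))
        appeared = np.zeros((n, n))
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            labels, _ = ward_cluster(x[idx], k, standardize_input=False)
            co = (labels[:, None] == labels[None, :]).astype(float)
            appeared[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += co
        defined = appeared > 0
        if not defined[np.triu_indices(n, k=1)].all():
            warnings.warn(
                "some patient pairs never co-appeared in a subsample; "
                "they are skipped in the consensus CDF",
                stacklevel=2,
            )
        mat = np.full((n, n), np.nan)
        mat[defined] = together[defined] / appeared[defined]
        np.fill_diagonal(mat, 1.0)
        consensus[k] = mat
        tri = mat[np.triu_indices(n, k=1)]
        tri = tri[~np.isnan(tri)]
        areas[k] = _cdf_area(tri)
        lo, hi = pac_bounds
        pac[k] = float(np.mean((tri > lo) & (tri < hi)))

    if k_rule == "pac":
        chosen = min(ks, key=lambda k: (pac[k], k))
    else:
        chosen = ks[0]
        for prev, k in zip(ks, ks[1:]):
            if areas[prev] > 0:
                rel = (areas[k] - areas[prev]) / areas[prev]
                if rel > area_increase_threshold:
                    chosen = k

    # Final labels: cluster the consensus matrix itself (average linkage on
    # 1 - consensus), then polish with k-means on the data starting from the
    # consensus partition; this denoises single-run Ward misassignments.
    mat = consensus[chosen].copy()
    mat[np.isnan(mat)] = 0.5
    np.fill_diagonal(mat, 1.0)
    merge = linkage(squareform(1.0 - mat, checks=False), method="average")
    labels = fcluster(merge, t=chosen, criterion="maxclust") - 1
    labels = _kmeans_polish(x, labels, chosen)
    return ConsensusResult(ks, consensus, areas, pac, chosen, labels)


def _kmeans_polish(x: np.ndarray, labels: np.ndarray, k: int, max_iter: int = 50) -> np.ndarray:
    """Lloyd iterations from an initial partition; keeps all k clusters."""
    lab = np.asarray(labels).copy()
    for _ in range(max_iter):
        centroids = np.stack([x[lab == c].mean(axis=0) for c in range(k)])
        d = ((x[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if (new == lab).all():
            break
        if len(np.unique(new)) < k:  # refuse to empty a cluster
            break
        lab = new
    return lab


@dataclass
class SigClustResult:
    observed_ci: float
    null_ci: np.ndarray
    pvalue: float


def _batched_two_means_ci(
    data: np.ndarray, restarts: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """Best-of-restarts 2-means cluster index for a batch of datasets.

    ``data`` has shape (S, n, p); returns (S,) minimal CI values. Lloyd's
    algorithm is vectorized across all S * restarts problems at once.
    """
    S, n, p = data.shape
    total_ss = ((data - data.mean(axis=1, keepdims=True)) ** 2).sum(axis=(1, 2))
    total_ss = np.where(total_ss == 0, 1.0, total_ss)

    # expand restarts into the batch dimension; float32 for compute speed
    rep = np.repeat(data.astype(np.float32), restarts, axis=0)  # (S*r, n, p)
    B = S * restarts
    # distinct random initial centroid pairs
    i1 = rng.integers(0, n, size=B)
    off = rng.integers(1, n, size=B)
    i2 = (i1 + off) % n
    centroids = np.stack(
        [rep[np.arange(B), i1], rep[np.arange(B), i2]], axis=1
    )  # (B, 2, p)

    # Lloyd iterations with an active set. Distances drop the ||x||^2 term
    # (assignment-invariant): argmin_c ||x-c||^2 = argmax_c (2 x.c - ||c||^2).
    # Converged problems are compressed out lazily (copies are costly).
    within = np.full(B, -1.0)
    active = np.arange(B)
    act_data = rep
    act_cent = centroids
    act_assign = np.full((B, n), -1, dtype=np.int8)

    def _score(data_b, assign_b):
        # exact within-SS from assignments, in float64
        x = data_b.astype(np.float64)
        w1 = assign_b.astype(np.float64)
        cnt1 = w1.sum(axis=1)
        cnt0 = n - cnt1
        s_all = x.sum(axis=1)
        s1 = np.einsum("bn,bnp->bp", w1, x)
        x2 = (x**2).sum(axis=(1, 2))
        ss1 = (s1**2).sum(axis=1) / np.where(cnt1 == 0, 1.0, cnt1)
        s0 = s_all - s1
        ss0 = (s0**2).sum(axis=1) / np.where(cnt0 == 0, 1.0, cnt0)
        return x2 - ss0 - ss1

    sum_all = act_data.sum(axis=1)  # (b, p); recomputed only on compression
    for _ in range(max_iter):
        cross = np.matmul(act_data, act_cent.transpose(0, 2, 1))  # (b, n, 2)
        c2 = (act_cent**2).sum(axis=2)
        new_assign = (
            2.0 * cross[:, :, 1] - c2[:, 1:2] > 2.0 * cross[:, :, 0] - c2[:, 0:1]
        ).astype(np.int8)
        done = (new_assign == act_assign).all(axis=1)
        n_done = int(done.sum())
        if n_done:
            idx = active[done]
            fresh = within[idx] < 0  # idle problems are already scored
            if fresh.any():
                sel = np.flatnonzero(done)[fresh]
                within[idx[fresh]] = _score(act_data[sel], new_assign[sel])
            if n_done > 0.25 * len(active) or n_done == len(active):
                keep = ~done
                active = active[keep]
                act_data = act_data[keep]
                act_cent = act_cent[keep]
                new_assign = new_assign[keep]
                sum_all = act_data.sum(axis=1)
                if len(active) == 0:
                    break
        act_assign = new_assign
        w1 = act_assign.astype(np.float32)
        cnt1 = w1.sum(axis=1)
        cnt0 = n - cnt1
        sum1 = np.matmul(w1[:, None, :], act_data)[:, 0, :]
        act_cent[:, 1] = sum1 / np.where(cnt1 == 0, 1.0, cnt1)[:, None]
        act_cent[:, 0] = (sum_all - sum1) / np.where(cnt0 == 0, 1.0, cnt0)[:, None]
    if len(active):  # hit max_iter or idling problems: score as-is
        todo = within[active] < 0
        if todo.any():
            within[active[todo]] = _score(act_data[todo], act_assign[todo])

    ci = within.reshape(S, restarts) / total_ss[:, None]
    return ci.min(axis=1)


def sigclust(
    features,
    n_sim: int = 1000,
    seed: int = 0,
    restarts: int = 10,
) -> SigClustResult:
    """Significance of 2-cluster structure against a single-Gaussian null.

    The null simulates ``n_sim`` datasets of the same size from a Gaussian
    with independent coordinates whose variances are the eigenvalues of the
    Ledoit-Wolf-shrunk sample covariance; the p-value is the add-one-corrected
    fraction of null cluster indices at or below the observed one.

    Raw sample-covariance eigenvalues are overdispersed at moderate n/p
    (Marchenko-Pastur spreading), which makes the simulated null genuinely
    anisotropic and hence easier to split than the data - the test then loses
    essentially all its power to reject and, worse, its type-I rate collapses
    to 0. Ledoit-Wolf shrinkage pulls the eigenvalues toward their mean by
    exactly the amount the data support, restoring calibration for
    near-spherical nulls while retaining real elongation.
    """
    x = _as_array(features)
    n, p = x.shape
    if n < 10:
        raise ValueError("sigclust needs at least 10 observations")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives coarse p-value resolution", stacklevel=2)
    rng = np.random.default_rng(seed)

    observed = float(
        _batched_two_means_ci(x[None, :, :], restarts=restarts, rng=rng)[0]
    )

    if p == 1:
        eigvals = np.atleast_1d(np.var(x, ddof=1))
    else:
        cov = LedoitWolf().fit(x).covariance_
        eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    sds = np.sqrt(eigvals)

    null = rng.standard_normal((n_sim, n, p)) * sds  # broadcast over coordinates
    null_ci = _batched_two_means_ci(null, restarts=restarts, rng=rng)
    pvalue = (1.0 + float((null_ci <= observed).sum())) / (n_sim + 1.0)
    return SigClustResult(observed, null_ci, pvalue)


@dataclass
class SplitSignificance:
    top_pvalue: float
    child_pvalues: dict[int, float] = field(default_factory=dict)  # cluster label -> p


def split_significance(
    features,
    merge: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    min_subset: int = 10,
    standardize_input: bool = True,
) -> SplitSignificance:
    """SigClust p-value at the top dendrogram split and its child subsets.

    The top-split test applies sigclust to all patients; each child of the
    2-cluster cut is then tested on its own subset when it has at least
    ``min_subset`` patients (smaller subsets are skipped with a warning).
    """
    x = _as_array(features)
    if standardize_input:
        x = standardize(x)
    labels, _ = ward_cluster(x, 2, standardize_input=False) if merge is None else (
        fcluster(merge, t=2, criterion="maxclust") - 1,
        merge,
    )
    top = sigclust(x, n_sim=n_sim, seed=seed)
    children: dict[int, float] = {}
    for lab in np.unique(labels):
        subset = x[labels == lab]
        if subset.shape[0] < min_subset:
            warnings.warn(
                f"split for cluster {lab} skipped ({subset.shape[0]} < {min_subset} patients)",
                stacklevel=2,
            )
            continue
        children[int(lab)] = sigclust(subset, n_sim=n_sim, seed=seed + 1 + int(lab)).pvalue
    return SplitSignificance(top.pvalue, children)


@dataclass
class PhenotypeResult:
    consensus: ConsensusResult
    chosen_k: int
    labels: np.ndarray
    sigclust_pvalue: float
    significant: bool


def identify_phenotypes(
    features,
    k_range=range(2, 7),
    n_subsamples: int = 100,
    subsample_fraction: float = 0.8,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PhenotypeResult:
    """Consensus k-selection gated by SigClust split significance."""
    cons = consensus_cluster(
        features,
        k_range=k_range,
        n_subsamples=n_subsamples,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )
    x = standardize(_as_array(features))
    top_p = sigclust(x, n_sim=n_sim, seed=seed).pvalue
    return PhenotypeResult(
        consensus=cons,
        chosen_k=cons.chosen_k,
        labels=cons.labels,
        sigclust_pvalue=top_p,
        significant=bool(top_p < alpha),
    )
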