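"""Per-strain co-expression clustering and DCp differential co-expression.

Clustering follows a tight-clustering contract: k-means over z-scored
replicate-mean time profiles with k chosen by mean silhouette, then
members correlating poorly with their centroid are moved to an
unassigned pool and undersized clusters are dissolved, so genes may
legitimately remain unclustered.

Differential co-expression uses the dCp statistic: for each protein, the
root-mean-square difference between its correlations to its linked
neighbours in condition A and in condition B,

    dCp_i = sqrt( sum_j (r_A(i,j) - r_B(i,j))^2 / n_i ),

where the link set contains neighbours strongly correlated (|r| above a
threshold) in either condition.  Significance comes from permuting the
condition labels of samples with the link sets held fixed, with the
add-one correction so permutation p-values are never exactly zero, and
BH adjustment across tested proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .proteoquant import AbundanceStudy

__all__ = [
    "DcpConfig",
    "ProfileMatrix",
    "ClusterSet",
    "LinkSet",
    "build_profiles",
    "cluster_profiles",
    "compute_links",
    "dcp_statistic",
    "dcp_permutation",
]


@dataclass
class DcpConfig:
    r_threshold: float = 0.8
    min_links: int = 5
    n_perm: int = 1000
    seed: int = 0
    q_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.r_threshold < 1):
            raise ValueError("r_threshold must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


@dataclass
class ProfileMatrix:
    """One strain's time profiles after missingness/variation filtering.

    ``means`` holds replicate-mean, z-scored profiles (protein x
    timepoint); ``replicates`` the per-sample values of the retained
    proteins, for correlation-based analyses.
    """

    strain: str
    means: pd.DataFrame
    replicates: pd.DataFrame
    dropped_missing: list[str] = field(default_factory=list)
    dropped_flat: list[str] = field(default_factory=list)


def build_profiles(study: AbundanceStudy, strain: str,
                   missingness_max: float = 0.5,
                   variation_min: float = 0.5) -> ProfileMatrix:
    """Replicate-mean, z-scored profiles for one strain.

    Proteins missing (pre-imputation) in more than ``missingness_max``
    of the strain's measurements are dropped, as are proteins whose
    replicate-mean profile spans less than ``variation_min`` log2 units
    across timepoints.
    """
    if study.scale != "imputed":
        raise ValueError("profiles are built from the imputed study")
    sel = study.samples["strain"] == strain
    if not sel.any():
        raise ValueError(f"strain {strain!r} not present in the study")
    sids = list(study.samples.index[sel])
    sub = study.matrix[sids]
    if study.imputed_mask is not None:
        frac_missing = study.imputed_mask[sids].mean(axis=1)
    else:
        frac_missing = pd.Series(0.0, index=sub.index)
    keep_missing = frac_missing <= missingness_max
    dropped_missing = list(sub.index[~keep_missing])
    sub = sub.loc[keep_missing]

    tps = study.samples.loc[sids, "timepoint"]
    order = list(dict.fromkeys(tps))
    means = pd.DataFrame({tp: sub[[s for s in sids if tps[s] == tp]].mean(axis=1)
                          for tp in order})
    spans = means.max(axis=1) - means.min(axis=1)
    keep_var = spans >= variation_min
    dropped_flat = list(means.index[~keep_var])
    means = means.loc[keep_var]
    sub = sub.loc[keep_var]

    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd, axis=0)
    return ProfileMatrix(strain=strain, means=z, replicates=sub,
                         dropped_missing=dropped_missing,
                         dropped_flat=dropped_flat)


@dataclass
class ClusterSet:
    strain: str
    clusters: dict[int, list[str]]
    centroids: dict[int, np.ndarray]
    unassigned: set[str]
    params: dict


def _pearson_to_centroid(row: np.ndarray, centroid: np.ndarray) -> float:
    a = row - row.mean()
    b = centroid - centroid.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def cluster_profiles(profiles: ProfileMatrix, k_range=(2, 10), tau: float = 0.7,
                     min_size: int = 5, restarts: int = 20,
                     seed: int = 0) -> ClusterSet:
    """Tight k-means clustering with silhouette model selection.

    After choosing k by maximum mean silhouette over ``k_range``,
    members whose Pearson correlation to their centroid falls below
    ``tau`` are unassigned, and clusters smaller than ``min_size``
    dissolve into the unassigned pool.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    means = profiles.means.sort_index()  # canonical order: row-order invariance
    X = means.to_numpy(dtype=float)
    names = list(means.index)
    n = len(names)
    if n < min_size:
        raise ValueError("fewer retained proteins than min_size")
    k_lo, k_hi = k_range
    if k_hi >= n:
        raise ValueError("k_range upper bound must be below the protein count")
    best = None
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if best is None or score > best[0]:
            best = (score, k, labels, km.cluster_centers_)
    if best is None:
        raise ValueError("clustering degenerate for every k in range")
    _, k, labels, centers = best

    clusters: dict[int, list[str]] = {}
    unassigned: set[str] = set()
    for i, name in enumerate(names):
        c = int(labels[i])
        if _pearson_to_centroid(X[i], centers[c]) >= tau:
            clusters.setdefault(c, []).append(name)
        else:
            unassigned.add(name)
    for c in list(clusters):
        if len(clusters[c]) < min_size:
            unassigned.update(clusters.pop(c))
    # renumber compactly, keeping deterministic order
    renumbered = {}
    centroids = {}
    for new_id, c in enumerate(sorted(clusters)):
        renumbered[new_id] = clusters[c]
        centroids[new_id] = centers[c]
    return ClusterSet(strain=profiles.strain, clusters=renumbered,
                      centroids=centroids, unassigned=unassigned,
                      params={"k": k, "tau": tau, "min_size": min_size,
                              "restarts": restarts, "seed": seed})


def _corr(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with constant rows mapped to r = 0."""
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[~np.isfinite(R)] = 0.0
    R[sd == 0, :] = 0.0
    R[:, sd == 0] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class LinkSet:
    proteins: list[str]
    neighbors: dict[int, np.ndarray]     # protein index -> neighbor indices
    r_a: np.ndarray
    r_b: np.ndarray
    excluded: dict[str, str]             # protein -> reason


def compute_links(mat_a: pd.DataFrame, mat_b: pd.DataFrame,
                  config: DcpConfig | None = None) -> LinkSet:
    """Link sets over both conditions for shared proteins.

    ``j`` is a neighbour of ``i`` when ``|r_A(i,j)|`` or ``|r_B(i,j)|``
    reaches the threshold; proteins with fewer than ``min_links``
    neighbours are excluded from testing (with the reason recorded).
    """
    config = config or DcpConfig()
    if list(mat_a.index) != list(mat_b.index):
        raise ValueError("conditions must share an identical protein list")
    if mat_a.shape[1] < 4 or mat_b.shape[1] < 4:
        raise ValueError("need >= 4 samples per condition for stable correlations")
    A = mat_a.to_numpy(dtype=float)
    B = mat_b.to_numpy(dtype=float)
    r_a, r_b = _corr(A), _corr(B)
    hit = (np.abs(r_a) >= config.r_threshold) | (np.abs(r_b) >= config.r_threshold)
    np.fill_diagonal(hit, False)
    neighbors = {}
    excluded = {}
    for i, name in enumerate(mat_a.index):
        nb = np.flatnonzero(hit[i])
        if nb.size >= config.min_links:
            neighbors[i] = nb
        else:
            excluded[name] = f"only {nb.size} links (< {config.min_links})"
    return LinkSet(proteins=list(mat_a.index), neighbors=neighbors,
                   r_a=r_a, r_b=r_b, excluded=excluded)


def dcp_statistic(r_a_links: np.ndarray, r_b_links: np.ndarray) -> float:
    """Root-mean-square correlation change over a protein's links."""
    r_a_links = np.asarray(r_a_links, dtype=float)
    if r_a_links.size == 0:
        raise ValueError("empty link set; dCp undefined")
    return float(np.sqrt(np.mean((r_a_links - np.asarray(r_b_links)) ** 2)))


def dcp_permutation(mat_a: pd.DataFrame, mat_b: pd.DataFrame,
                    config: DcpConfig | None = None) -> pd.DataFrame:
    """dCp with a condition-label permutation null.

    Sample labels are permuted between the two conditions ``n_perm``
    times with link sets held fixed; ``p = (1 + #{perm >= obs}) /
    (n_perm + 1)`` and q is BH across tested proteins.
    """
    config = config or DcpConfig()
    links = compute_links(mat_a, mat_b, config)
    tested = sorted(links.neighbors)
    names = links.proteins
    if not tested:
        return pd.DataFrame(columns=["protein", "n_links", "dcp", "p", "q", "flagged"])
    obs = np.array([
        dcp_statistic(links.r_a[i, links.neighbors[i]],
                      links.r_b[i, links.neighbors[i]])
        for i in tested
    ])
    pooled = np.hstack([mat_a.to_numpy(dtype=float), mat_b.to_numpy(dtype=float)])
    n_a = mat_a.shape[1]
    n_total = pooled.shape[1]
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros(len(tested))
    for _ in range(config.n_perm):
        perm = rng.permutation(n_total)
        Ra = _corr(pooled[:, perm[:n_a]])
        Rb = _corr(pooled[:, perm[n_a:]])
        null = np.array([
            dcp_statistic(Ra[i, links.neighbors[i]], Rb[i, links.neighbors[i]])
            for i in tested
        ])
        exceed += null >= obs
    p = (1.0 + exceed) / (config.n_perm + 1.0)
    q = bh_adjust(p)
    return pd.DataFrame({
        "protein": [names[i] for i in tested],
        "n_links": [links.neighbors[i].size for i in tested],
        "dcp": obs, "p": p, "q": q, "flagged": q < config.q_alpha,
    })
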