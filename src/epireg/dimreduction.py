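"""Two-step dimensionality reduction of genome-wide methylation data.

Step one groups CpG sites by genomic proximity: within a chromosome,
successive sites at most ``gap`` base pairs apart (2,000 by default) are
aggregated into one region.  Step two clusters each region's methylation
profiles by similarity using K-Spectral Clustering (KSC): a Gaussian
affinity matrix A with zero diagonal, the symmetrically normalized matrix
L = D^(-1/2) A D^(-1/2), the row-normalized matrix Y of L's top-k
eigenvectors, and k-means on the rows of Y.  The affinity bandwidth sigma
and the cluster count k are selected automatically by minimizing cluster
compactness W/B over a grid, where W is the largest distance from a point
to its own center and B the smallest distance between two centers.

Profiles are compressed by a single panel-wide PCA (99% of variance
retained by default) before clustering; each final cluster is summarized
by the mean of its members' original methylation percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .datatypes import ClusterModel, MethylationSite, Panel, PCAModel, Region

logger = logging.getLogger(__name__)

DEFAULT_GAP_BP = 2000
DEFAULT_VARIANCE_TARGET = 0.99
MIN_CLUSTERABLE_SIZE = 3  # regions of 1-2 sites bypass KSC as one cluster
KMEANS_RESTARTS = 10


def group_by_proximity(
    sites: list[MethylationSite], gap: int = DEFAULT_GAP_BP
) -> list[Region]:
    """Aggregate sites adjoining within `gap` base pairs into regions.

    Input must be sorted by (chromosome, position).  A new region starts
    exactly when the distance to the previous site exceeds ``gap``
    (distance equal to ``gap`` still merges).  Every site lands in exactly
    one region.
    """
    regions: list[Region] = []
    cur: list[MethylationSite] = []

    def flush() -> None:
        if cur:
            regions.append(
                Region(
                    region_id=f"R{len(regions):05d}",
                    chromosome=cur[0].chromosome,
                    member_sites=[s.site_id for s in cur],
                    span=(cur[0].position, cur[-1].position),
                )
            )

    for s in sites:
        if cur and (s.chromosome != cur[-1].chromosome or s.position - cur[-1].position > gap):
            flush()
            cur = []
        cur.append(s)
    flush()
    return regions


def fit_pca(
    all_profiles: np.ndarray, variance_target: float = DEFAULT_VARIANCE_TARGET
) -> PCAModel:
    """PCA of the full site-by-cell-line matrix, keeping `variance_target` variance.

    Fitted once, globally: columns (cell lines) are mean-centered and the
    smallest number of components whose cumulative explained-variance
    fraction reaches the target is retained.
    """
    X = np.asarray(all_profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 sites and 2 cell lines")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD is exact and deterministic at these panel widths (~tens of lines)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("methylation matrix has zero variance (rank 0 after centering)")
    evr = var / total
    cum = np.cumsum(evr)
    rank = int((s > s[0] * 1e-12).sum())
    n_kept = int(np.searchsorted(cum, variance_target - 1e-9) + 1)
    n_kept = min(n_kept, rank)
    # deterministic sign: largest-magnitude loading of each component positive
    comp = Vt[:n_kept].copy()
    for i in range(n_kept):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return PCAModel(
        components=comp,
        mean=mean,
        n_kept=n_kept,
        variance_fraction=float(cum[n_kept - 1]),
        explained_variance_ratio=evr,
    )


def affinity_matrix(points: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian affinity A_ij = exp(-||s_i - s_j||^2 / (2 sigma^2)), A_ii = 0."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("affinity matrix needs at least 2 points")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        A = np.exp(-d2 / (2.0 * sigma**2))
    np.nan_to_num(A, copy=False, nan=1.0)  # 0/0 on the diagonal at tiny sigma
    np.fill_diagonal(A, 0.0)
    return (A + A.T) / 2.0


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetrically normalized matrix L = D^(-1/2) A D^(-1/2).

    D is diagonal with D_ii the sum of A's i-th row.  A zero row sum means
    an isolated point and raises, naming the point.
    """
    A = np.asarray(A, dtype=float)
    d = A.sum(axis=1)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValueError(f"isolated point(s) with zero affinity row sum: {bad.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def spectral_embed(L: np.ndarray, k: int) -> np.ndarray:
    """Rows of the top-k eigenvector matrix of L, scaled to unit norm.

    X holds eigenvectors for the k algebraically largest eigenvalues
    (deterministic sign: the largest-magnitude entry of each eigenvector is
    made positive); Y is X with each row normalized to unit Euclidean
    length.  Zero rows are left as zero with a warning.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    vals, vecs = eigh(L, subset_by_index=(n - k, n - 1))
    X = vecs[:, ::-1]  # descending eigenvalue order
    for i in range(k):
        j = int(np.argmax(np.abs(X[:, i])))
        if X[j, i] < 0:
            X[:, i] = -X[:, i]
    norms = np.linalg.norm(X, axis=1)
    zero = norms <= 1e-300
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero row(s) in spectral embedding left as zero")
        norms[zero] = 1.0
    return X / norms[:, None]


def _kmeans_restarts(
    Y: np.ndarray, k: int, seed: int, n_restarts: int = KMEANS_RESTARTS
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means with `n_restarts` seeded runs; best inertia wins, ties to the
    lowest restart index."""
    ss = np.random.SeedSequence(seed)
    best = None
    for i, child in enumerate(ss.spawn(n_restarts)):
        km = KMeans(
            n_clusters=k, n_init=1,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        ).fit(Y)
        if best is None or km.inertia_ < best[2]:
            best = (km.labels_.copy(), km.cluster_centers_.copy(), float(km.inertia_))
    return best


def ksc_cluster(
    points: np.ndarray, sigma: float, k: int, seed: int = 0
) -> np.ndarray:
    """K-Spectral Clustering: affinity -> L -> embedding Y -> k-means on Y.

    Returns the cluster assignment per input point; point i inherits the
    cluster of row Y_i.
    """
    labels, _, _ = _ksc_full(points, sigma, k, seed)
    return labels


def _ksc_full(points, sigma, k, seed):
    A = affinity_matrix(points, sigma)
    L = normalized_laplacian(A)
    Y = spectral_embed(L, k)
    labels, centers, _ = _kmeans_restarts(Y, k, seed)
    return labels, Y, centers


def compactness(
    points: np.ndarray, assignments: np.ndarray, centers: np.ndarray
) -> float:
    """W/B: worst point-to-own-center distance over best center separation.

    Smaller is more compact.  Coincident centers (B = 0) return +inf so the
    parameter pair is rejected during selection; fewer than 2 clusters is
    undefined and raises.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    assignments = np.asarray(assignments, dtype=int)
    k = centers.shape[0]
    if k < 2:
        raise ValueError("compactness needs at least 2 clusters")
    present = np.unique(assignments)
    if present.size < 2:
        raise ValueError("compactness needs at least 2 nonempty clusters")
    W = float(np.linalg.norm(points - centers[assignments], axis=1).max())
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    B = float(dist[np.triu_indices(k, 1)].min())
    if B <= 1e-300:
        return float("inf")
    return W / B


@dataclass
class GridSearchResult:
    """Outcome of the exhaustive (sigma, k) compactness search."""

    sigma: float
    k: int
    labels: np.ndarray
    score: float
    table: list[tuple[float, int, float]] = field(repr=False, default_factory=list)
    fallback: bool = False  # True when every pair was rejected


def default_sigma_grid(points: np.ndarray, n: int = 8) -> np.ndarray:
    """Log-spaced bandwidths between 0.1x and 10x the median pairwise distance."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    iu = np.triu_indices(X.shape[0], 1)
    d = np.linalg.norm(X[iu[0]] - X[iu[1]], axis=1)
    med = float(np.median(d))
    if med <= 0:
        med = float(d[d > 0].mean()) if (d > 0).any() else 1.0
    return np.geomspace(0.1 * med, 10.0 * med, n)


def default_k_grid(n_points: int, k_max: int = 8) -> list[int]:
    return list(range(2, min(k_max, n_points - 1) + 1))


def select_parameters(
    points: np.ndarray,
    sigma_grid: np.ndarray,
    k_grid: list[int],
    seed: int = 0,
) -> tuple[float | None, int, GridSearchResult]:
    """Exhaustive grid search: KSC at every (sigma, k), keep the compactness
    minimum.

    Ties keep the first pair in grid order (sigma outer, k inner).  If every
    pair is rejected (infinite or failed), a single-cluster fallback is
    returned with a warning.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0 or len(k_grid) == 0:
        raise ValueError("parameter grids must be nonempty")
    best: tuple[float, float, int, np.ndarray] | None = None
    table: list[tuple[float, int, float]] = []
    for sigma in sigma_grid:
        for k in k_grid:
            if k > n:
                continue
            try:
                labels, Y, centers = _ksc_full(points, sigma, k, seed)
                score = compactness(Y, labels, centers)
            except (ValueError, np.linalg.LinAlgError):
                score = float("inf")
                labels = None
            table.append((float(sigma), int(k), score))
            if labels is not None and np.isfinite(score):
                if best is None or score < best[0]:
                    best = (score, float(sigma), int(k), labels)
    if best is None:
        warnings.warn("all (sigma, k) pairs rejected; falling back to a single cluster")
        res = GridSearchResult(
            sigma=float("nan"), k=1, labels=np.zeros(n, dtype=int),
            score=float("inf"), table=table, fallback=True,
        )
        return None, 1, res
    score, sigma, k, labels = best
    res = GridSearchResult(sigma=sigma, k=k, labels=labels, score=score, table=table)
    return sigma, k, res


@dataclass
class ReduceConfig:
    gap_bp: int = DEFAULT_GAP_BP
    variance_target: float = DEFAULT_VARIANCE_TARGET
    sigma_grid_size: int = 8
    k_max: int = 8
    min_clusterable_size: int = MIN_CLUSTERABLE_SIZE
    seed: int = 0


def reduce(
    sites: list[MethylationSite],
    panel: Panel,
    config: ReduceConfig | None = None,
) -> tuple[list[ClusterModel], PCAModel | None, list[Region]]:
    """Full stage (i): proximity regions, global PCA, per-region KSC.

    Regions smaller than the minimum clusterable size (3 sites) become
    single-cluster models.  Every input site appears in exactly one
    cluster's membership; each cluster's representative profile is the
    nan-mean of its members' original methylation percentages, and its
    anchor is the member site nearest the cluster's positional centroid.
    """
    cfg = config or ReduceConfig()
    regions = group_by_proximity(sites, cfg.gap_bp)
    if not regions:
        return [], None, []
    by_id = {s.site_id: s for s in sites}
    X = np.vstack([s.profile for s in sites])
    # NaNs are imputed with per-line means for PCA/clustering only;
    # representatives below use the original values.
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        Xf = np.where(np.isnan(X), col_mean[None, :], X)
    else:
        Xf = X
    pca = fit_pca(Xf, cfg.variance_target) if len(sites) >= 2 and len(panel) >= 2 else None
    coords = pca.transform(Xf) if pca is not None else Xf
    row_of = {s.site_id: i for i, s in enumerate(sites)}

    models: list[ClusterModel] = []
    ss = np.random.SeedSequence(cfg.seed)
    region_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(regions))]
    for region, rseed in zip(regions, region_seeds):
        members = region.member_sites
        pts = coords[[row_of[m] for m in members]]
        n = len(members)
        if n < cfg.min_clusterable_size:
            sigma, k, labels, score = None, 1, np.zeros(n, dtype=int), None
        else:
            sgrid = default_sigma_grid(pts, cfg.sigma_grid_size)
            kgrid = default_k_grid(n, cfg.k_max)
            if not kgrid or not np.all(np.isfinite(sgrid)) or sgrid[0] <= 0:
                sigma, k, labels, score = None, 1, np.zeros(n, dtype=int), None
            else:
                sigma, k, res = select_parameters(pts, sgrid, kgrid, rseed)
                labels = res.labels
                score = None if res.fallback else res.score
        reps = np.empty((k, len(panel)))
        anchors: list[tuple[str, int]] = []
        for c in range(k):
            idx = [m for m, lab in zip(members, labels) if lab == c]
            prof = np.vstack([X[row_of[m]] for m in idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                reps[c] = np.nanmean(prof, axis=0)
            pos = np.array([by_id[m].position for m in idx], dtype=float)
            centroid = pos.mean()
            j = int(np.argmin(np.abs(pos - centroid)))
            anchors.append((idx[j], int(pos[j])))
        models.append(
            ClusterModel(
                region_id=region.region_id,
                chromosome=region.chromosome,
                sigma=sigma,
                k=k,
                assignments={m: int(lab) for m, lab in zip(members, labels)},
                compactness=score,
                representatives=reps,
                anchors=anchors,
            )
        )
    n_clusters = sum(m.k for m in models)
    logger.info(
        "reduce: %d sites -> %d regions -> %d clusters (%.1f%% compression)",
        len(sites), len(regions), n_clusters,
        100.0 * (1 - n_clusters / max(len(sites), 1)),
    )
    return models, pca, regions
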