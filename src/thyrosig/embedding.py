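"""Sample ordination and clustering on correlation distances.

Between-sample dissimilarity is 1 - Pearson correlation of the samples' log2
ratio profiles (range [0, 2]). Nonmetric multidimensional scaling minimizes
Kruskal stress-1,

    stress = sqrt( sum_{i<j} (dhat_ij - dist_ij)^2 / sum_{i<j} dist_ij^2 ),

where dist are configuration distances and dhat their monotone
(pool-adjacent-violators) regression on the rank order of the input
dissimilarities. The configuration is updated by the Guttman transform;
iterations that would increase stress are rejected, so the reported stress
sequence is non-increasing. Several restarts are run (the first initialized
from classical MDS, the rest from jittered copies) and the best kept.

Hierarchical clustering uses average linkage (UPGMA) on the same correlation
distances, for the signature heatmap ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, DataError

__all__ = [
    "DistanceMatrix",
    "correlation_distances",
    "classical_mds",
    "MdsEmbedding",
    "nonmetric_mds",
    "NonmetricMDS",
    "Dendrogram",
    "hierarchical_cluster",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with named items."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise DataError("distance matrix must be square and match its ids")
        if not np.all(np.isfinite(d)):
            raise DataError("distance matrix contains non-finite entries")
        if not np.allclose(d, d.T, atol=1e-10):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise DataError("distance matrix must have a zero diagonal")
        if d.min() < -1e-10:
            raise DataError("distances must be non-negative")
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def correlation_distances(
    ratios: pd.DataFrame, probe_subset=None
) -> DistanceMatrix:
    """1 - Pearson correlation between sample profiles.

    ``probe_subset`` restricts the profiles to the given probes (default:
    all). Samples with zero profile variance have undefined correlation and
    are rejected by name.
    """
    sub = ratios if probe_subset is None else ratios.loc[list(probe_subset)]
    if sub.shape[1] < 2:
        raise DataError("need at least two samples for distances")
    X = sub.to_numpy().T  # samples x probes
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DataError(
            f"zero-variance profile(s): {[sub.columns[i] for i in bad]}"
        )
    corr = np.corrcoef(X)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(sub.columns), values=np.clip(d, 0.0, 2.0))


def classical_mds(D: DistanceMatrix, k: int) -> np.ndarray:
    """Classical (Torgerson) MDS: spectral coordinates of -1/2 J D^2 J.

    Returns an (n, k) coordinate array (centered at the origin). Used as the
    starting configuration for nonmetric MDS; exact for Euclidean-embeddable
    inputs.
    """
    n = D.n
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= n:
        raise ConfigurationError(f"k must be < number of items ({n})")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


@dataclass
class MdsEmbedding:
    """Nonmetric MDS result: coordinates (centroid at origin) + stress."""

    ids: list[str]
    coords: np.ndarray = field(repr=False)
    stress: float
    n_iter: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


def _stress_and_disparities(
    dist_flat: np.ndarray, order: np.ndarray, denom_from_dist: bool = True
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the monotone-fitted disparities.

    ``order`` is the rank order (argsort) of the input dissimilarities;
    disparities are the isotonic regression of configuration distances taken
    in that order.
    """
    dhat = np.empty_like(dist_flat)
    dhat[order] = isotonic_regression(dist_flat[order]).x
    denom = float(np.sum(dist_flat**2))
    if denom == 0:
        return 0.0, dhat
    return float(np.sqrt(np.sum((dhat - dist_flat) ** 2) / denom)), dhat


def _guttman_update(X: np.ndarray, dhat_flat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    dist = squareform(pdist(X), checks=False)
    dhat = squareform(dhat_flat, checks=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, dhat / np.where(dist > 0, dist, 1.0), 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def _run_single(
    D_flat: np.ndarray,
    order: np.ndarray,
    X0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, int, bool]:
    X = X0 - X0.mean(axis=0)
    dist = pdist(X)
    stress, dhat = _stress_and_disparities(dist, order)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        X_new = _guttman_update(X, dhat)
        X_new -= X_new.mean(axis=0)
        dist_new = pdist(X_new)
        stress_new, dhat_new = _stress_and_disparities(dist_new, order)
        if stress_new > stress + 1e-12:  # reject non-improving step
            break
        delta = stress - stress_new
        X, dhat, stress = X_new, dhat_new, stress_new
        if delta < tol * max(stress, 1e-12):
            converged = True
            break
    return X, stress, it, converged


def nonmetric_mds(
    D: DistanceMatrix,
    k: int = 2,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 4,
    seed: int | None = 0,
) -> MdsEmbedding:
    """Kruskal nonmetric MDS of a dissimilarity matrix into k dimensions.

    Restart 0 starts from the classical-MDS configuration; the remaining
    restarts jitter it with Gaussian noise. The embedding with the lowest
    final stress-1 is returned. Coordinates are meaningful up to isometry
    only; compare distance structure, not raw coordinates.
    """
    if not np.all(np.isfinite(D.values)):
        raise DataError("dissimilarities must be finite")
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")
    D_flat = D.condensed()
    order = np.argsort(D_flat, kind="stable")
    X_init = classical_mds(D, k)
    scale = max(float(np.sqrt((X_init**2).sum(axis=1).mean())), 1e-3)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        X0 = X_init if r == 0 else X_init + rng.normal(
            0.0, 0.3 * scale, size=X_init.shape
        )
        X, stress, n_iter, conv = _run_single(D_flat, order, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, n_iter, conv)
    X, stress, n_iter, conv = best
    return MdsEmbedding(
        ids=list(D.ids), coords=X, stress=stress, n_iter=n_iter, converged=conv
    )


class NonmetricMDS:
    """sklearn-style estimator wrapper around :func:`nonmetric_mds`.

    Parameters mirror the function; ``dissimilarity`` is either
    ``'correlation'`` (X is samples x features, correlation distances are
    computed) or ``'precomputed'`` (X is a square dissimilarity matrix).

    Fitted attributes: ``embedding_``, ``stress_``, ``n_iter_``,
    ``converged_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        dissimilarity: str = "correlation",
        max_iter: int = 300,
        tol: float = 1e-6,
        n_restarts: int = 4,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.dissimilarity = dissimilarity
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "dissimilarity": self.dissimilarity,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        ids = [str(i) for i in range(n)]
        if self.dissimilarity == "precomputed":
            D = DistanceMatrix(ids=ids, values=X)
        elif self.dissimilarity == "correlation":
            frame = pd.DataFrame(X.T, columns=ids)
            D = correlation_distances(frame)
        else:
            raise ConfigurationError(
                f"unknown dissimilarity: {self.dissimilarity!r}"
            )
        emb = nonmetric_mds(
            D,
            k=self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        self.embedding_ = emb.coords
        self.stress_ = emb.stress
        self.n_iter_ = emb.n_iter
        self.converged_ = emb.converged
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples or probes.

    ``linkage`` is the scipy (n-1) x 4 linkage matrix; ``heights`` its merge
    heights (non-decreasing for average linkage); ``leaf_order`` the ids in
    standard dendrogram order.
    """

    ids: list[str]
    linkage: np.ndarray = field(repr=False)
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..n_clusters) per item."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.ids[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(
    ratios: pd.DataFrame,
    probe_subset=None,
    linkage: str = "average",
    axis: str = "samples",
) -> Dendrogram:
    """UPGMA clustering on correlation distances.

    ``axis='samples'`` clusters samples by their profiles over
    ``probe_subset`` (default all probes); ``axis='probes'`` clusters the
    subset's probes by their profiles over samples.
    """
    if probe_subset is not None and len(list(probe_subset)) == 0:
        raise ConfigurationError("probe_subset must not be empty")
    if axis == "samples":
        D = correlation_distances(ratios, probe_subset)
    elif axis == "probes":
        sub = ratios if probe_subset is None else ratios.loc[list(probe_subset)]
        D = correlation_distances(sub.T)
    else:
        raise ConfigurationError(f"axis must be 'samples' or 'probes', got {axis!r}")
    if D.n < 2:
        raise DataError("need at least two items to cluster")
    Z = hierarchy.linkage(D.condensed(), method=linkage)
    order = [D.ids[i] for i in hierarchy.leaves_list(Z)]
    return Dendrogram(ids=D.ids, linkage=Z, leaf_order=order)
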