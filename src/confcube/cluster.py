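"""K-means clustering of the tuple cube, elbow k-selection, cluster free
energies, and KDE-based representative conformations.

Clusters are interpreted as conformational states; treating the tuple count
of each cluster as an occupancy, the standard free-energy difference between
states i and j is the Boltzmann population ratio

    dG0_ij = -R T ln(P_i / P_j),    R = 8.314 J mol^-1 K^-1.

K-means is Lloyd's algorithm with centroids initialized at randomly chosen
data points, a centroid-displacement stopping tolerance, and empty clusters
re-seeded at the point farthest from its assigned centroid; the per-restart
objective trace is retained so monotonic descent can be verified. Clusters
are always numbered in descending order of size. The number of clusters is
chosen with the elbow method: the explained-variance fraction
``1 - inertia_k / inertia_1`` is computed per k and the elbow is the k at
the "angle" of the curve, i.e. where its concavity (the second difference
of the inertia curve) is largest.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClusterMixin

from .core import Frame
from .errors import ValidationError
from .metrics import helix_content, radius_of_gyration, residue_distance, sasa

__all__ = [
    "GAS_CONSTANT",
    "THERMAL_NOISE_J_PER_MOL",
    "ClusterModel",
    "FreeEnergyTable",
    "TupleKMeans",
    "ElbowKMeans",
    "kmeans",
    "elbow_select_k",
    "cluster_free_energy",
    "free_energy_table",
    "kde_representative",
    "CharacterizationRecord",
    "characterize_frame",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
# conventional thermal-noise bound quoted for these systems; note RT at the
# simulation temperature 310 K is 8.314 * 310 = 2577.3 J/mol — both are
# reported by FreeEnergyTable.
THERMAL_NOISE_J_PER_MOL = 2470.0


# ---------------------------------------------------------------------------
# Lloyd's algorithm


def _init_centroids(
    X: np.ndarray, k: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    n = X.shape[0]
    if method == "random":
        return X[rng.choice(n, size=k, replace=False)].copy()
    if method == "kmeans++":
        # D^2 sampling: each next centroid drawn with probability proportional
        # to squared distance from the nearest centroid chosen so far
        centroids = np.empty((k, X.shape[1]))
        centroids[0] = X[rng.integers(n)]
        d2 = ((X - centroids[0]) ** 2).sum(-1)
        for c in range(1, k):
            total = d2.sum()
            if total <= 0:
                centroids[c:] = centroids[0]
                break
            centroids[c] = X[rng.choice(n, p=d2 / total)]
            d2 = np.minimum(d2, ((X - centroids[c]) ** 2).sum(-1))
        return centroids
    raise ValidationError(f"unknown init method {method!r}")


def _lloyd(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: str = "random",
):
    n = X.shape[0]
    centroids = _init_centroids(X, k, rng, init)
    labels = np.zeros(n, dtype=np.intp)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(n), labels].sum()))
        new_centroids = centroids.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centroids[c] = X[mask].mean(axis=0)
            else:
                # empty cluster: re-seed at the point farthest from its centroid
                farthest = int(d2[np.arange(n), labels].argmax())
                new_centroids[c] = X[farthest]
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    trace.append(inertia)
    return centroids, labels, inertia, np.array(trace)


def _relabel_by_size(centroids: np.ndarray, labels: np.ndarray, k: int):
    """Renumber clusters so counts are non-increasing in cluster id."""
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.intp)
    remap[order] = np.arange(k)
    return centroids[order], remap[labels], counts[order]


class TupleKMeans(ClusterMixin, BaseEstimator):
    """K-means over tuple-cube points, sklearn-style.

    Parameters
    ----------
    k : number of clusters.
    n_restarts : independent random initializations; the best (lowest
        inertia) run is kept.
    max_iter, tol : Lloyd iteration cap and centroid-displacement tolerance.
    random_state : mandatory seed for the data-point initialization.
    standardize : when True, cluster on z-scored axes (the RMSD axis carries
        nm while the two FNC axes are unitless); default False clusters raw
        values.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, d) centroids, size-descending order, original scale.
    labels_ : 0-based cluster id per point (0 = largest cluster).
    counts_ : points per cluster, non-increasing.
    inertia_ : sum of squared distances to assigned centroids (fit scale).
    objective_trace_ : per-iteration objective of the winning restart.
    """

    def __init__(
        self,
        k: int = 4,
        n_restarts: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int = 0,
        standardize: bool = False,
        init: str = "random",
    ):
        self.k = k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.standardize = standardize
        self.init = init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_points, n_features)")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if X.shape[0] < self.k:
            raise ValidationError(
                f"k={self.k} exceeds the number of points ({X.shape[0]})"
            )
        Xf = X
        scale = None
        if self.standardize:
            mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Xf = (X - mean) / sd
            scale = (mean, sd)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            result = _lloyd(Xf, self.k, rng, self.max_iter, self.tol, self.init)
            if best is None or result[2] < best[2]:
                best = result
        centroids, labels, inertia, trace = best
        centroids, labels, counts = _relabel_by_size(centroids, labels, self.k)
        if scale is not None:
            centroids = centroids * scale[1] + scale[0]
        self.cluster_centers_ = centroids
        self.labels_ = labels
        self.counts_ = counts
        self.inertia_ = inertia
        self.objective_trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


class ElbowKMeans(ClusterMixin, BaseEstimator):
    """K-means with the number of clusters selected by the elbow method.

    Fits ``TupleKMeans`` for every k in ``k_range`` (inclusive), computes
    the explained-variance fraction ``1 - inertia_k / inertia_1`` and picks
    the k where that curve bends most sharply (largest second difference of
    the inertia curve). A flat or degenerate curve falls back to the
    smallest k and sets ``degenerate_`` = True.

    After ``fit``: ``k_``, ``explained_variance_``, ``degenerate_``, plus
    the winning model's ``cluster_centers_``, ``labels_``, ``counts_``,
    ``inertia_``.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (1, 10),
        n_restarts: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int = 0,
        standardize: bool = False,
        init: str = "random",
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.standardize = standardize
        self.init = init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k_min, k_max = self.k_range
        if k_min < 1 or k_max < k_min:
            raise ValidationError("k_range must satisfy 1 <= k_min <= k_max")
        k_max = min(k_max, max(X.shape[0] - 1, 1))
        ks = np.arange(k_min, k_max + 1)
        models = {}
        inertias = []
        for k in ks:
            model = TupleKMeans(
                k=int(k),
                n_restarts=self.n_restarts,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
                standardize=self.standardize,
                init=self.init,
            ).fit(X)
            models[int(k)] = model
            inertias.append(model.inertia_)
        inertias = np.array(inertias)
        # total sum of squares = inertia at k=1 (computed even if k_min > 1)
        total_ss = (
            inertias[0]
            if k_min == 1
            else float(((X - X.mean(axis=0)) ** 2).sum())
        )
        self.degenerate_ = False
        if total_ss <= 0:
            explained = np.ones_like(inertias)
        else:
            explained = 1.0 - inertias / total_ss
        if len(ks) >= 3 and total_ss > 0 and np.ptp(explained) > 1e-12:
            # elbow = sharpest drop in marginal gain: maximum concavity of the
            # explained-variance curve (= maximum second difference of inertia)
            curvature = 2 * explained[1:-1] - explained[:-2] - explained[2:]
            k_sel = int(ks[1:-1][np.argmax(curvature)])
        else:
            self.degenerate_ = True
            k_sel = int(ks[0])
        self.k_ = k_sel
        self.ks_ = ks
        self.explained_variance_ = explained
        best = models[k_sel]
        self.cluster_centers_ = best.cluster_centers_
        self.labels_ = best.labels_
        self.counts_ = best.counts_
        self.inertia_ = best.inertia_
        self.objective_trace_ = best.objective_trace_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


# ---------------------------------------------------------------------------
# functional surface


@dataclass
class ClusterModel:
    """K-means result with 1-based, size-descending cluster ids."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray  # 1-based, in [1..k]
    counts: np.ndarray  # non-increasing
    inertia: float
    seed: int
    objective_trace: np.ndarray


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 10,
    standardize: bool = False,
    init: str = "random",
) -> ClusterModel:
    """Cluster tuple points; thin wrapper over :class:`TupleKMeans`."""
    est = TupleKMeans(
        k=k,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        standardize=standardize,
        init=init,
    ).fit(points)
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        labels=est.labels_ + 1,
        counts=est.counts_,
        inertia=est.inertia_,
        seed=seed,
        objective_trace=est.objective_trace_,
    )


def elbow_select_k(
    points: np.ndarray,
    k_range: tuple[int, int] = (1, 10),
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = False,
):
    """Elbow-method k selection; returns ``(k, explained_curve, degenerate)``."""
    est = ElbowKMeans(
        k_range=k_range,
        n_restarts=n_restarts,
        random_state=seed,
        standardize=standardize,
    ).fit(points)
    return est.k_, est.explained_variance_, est.degenerate_


# ---------------------------------------------------------------------------
# free energies


def cluster_free_energy(P1: float, P2: float, T: float) -> float:
    """dG0 = -R T ln(P1 / P2) in J/mol from two cluster populations."""
    if T <= 0:
        raise ValidationError("temperature must be positive")
    if P1 <= 0 or P2 <= 0:
        raise ValidationError(
            "free energy is infinite for a zero cluster population "
            f"(P1={P1}, P2={P2})"
        )
    return float(-GAS_CONSTANT * T * np.log(P1 / P2))


@dataclass
class FreeEnergyTable:
    """Pairwise dG0 (J/mol) between clusters at temperature T.

    ``dG[i, j] = -R T ln(P_{i+1} / P_{j+1})`` is antisymmetric and
    path-additive by construction. ``below_thermal_noise`` flags whether the
    largest |dG0| stays under the supplied thermal-noise threshold; the
    thermodynamic RT at T is reported alongside.
    """

    T: float
    populations: np.ndarray
    dG: np.ndarray
    R: float = GAS_CONSTANT
    thermal_threshold_J: float = THERMAL_NOISE_J_PER_MOL

    @property
    def max_abs_dG(self) -> float:
        return float(np.abs(self.dG).max())

    @property
    def below_thermal_noise(self) -> bool:
        return self.max_abs_dG <= self.thermal_threshold_J

    @property
    def RT(self) -> float:
        return self.R * self.T

    def pair(self, i: int, j: int) -> float:
        """dG0 between clusters ``i`` and ``j`` (1-based ids)."""
        return float(self.dG[i - 1, j - 1])


def free_energy_table(
    counts: np.ndarray,
    T: float,
    thermal_threshold_J: float = THERMAL_NOISE_J_PER_MOL,
) -> FreeEnergyTable:
    """All-pairs cluster free energies from population counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValidationError("all cluster populations must be positive")
    log_p = np.log(counts)
    dG = -GAS_CONSTANT * T * (log_p[:, None] - log_p[None, :])
    return FreeEnergyTable(
        T=T, populations=counts, dG=dG, thermal_threshold_J=thermal_threshold_J
    )


# ---------------------------------------------------------------------------
# representatives & characterization


def kde_representative(cluster_points: np.ndarray, provenance=None):
    """Tuple closest to the cluster's kernel-density maximum.

    A Gaussian KDE (Scott bandwidth) is fitted to the cluster's tuples and
    evaluated *on the tuples themselves*; the maximizer (ties -> lowest
    index) is the density mode, and the representative is the tuple
    minimizing squared distance to it. Returns ``(index, tuple)`` where
    ``index`` is into ``provenance`` when given, else into
    ``cluster_points``.
    """
    pts = np.asarray(cluster_points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValidationError("cluster_points must be a non-empty 2-D array")
    if len(pts) == 1 or np.allclose(pts, pts[0]):
        mode_idx = 0
    else:
        try:
            kde = gaussian_kde(pts.T)
            density = kde(pts.T)
            mode_idx = int(np.argmax(density))
        except (np.linalg.LinAlgError, ValueError):
            # singular covariance (degenerate cloud, or fewer points than
            # dimensions): fall back to the point closest to the cluster mean
            mode_idx = int(np.argmin(((pts - pts.mean(axis=0)) ** 2).sum(-1)))
    d2 = ((pts - pts[mode_idx]) ** 2).sum(-1)
    rep_idx = int(np.argmin(d2))  # argmin ties -> lowest index
    if provenance is not None:
        return provenance[rep_idx], pts[rep_idx]
    return rep_idx, pts[rep_idx]


@dataclass
class CharacterizationRecord:
    """Per-conformation descriptors: the summary-table row format."""

    rgyr_nm: float
    sasa_A2: float
    helix_percent: float
    distances_A: dict[str, float]


def characterize_frame(
    frame: Frame,
    distance_specs: list[tuple[int, int]] | None = None,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> CharacterizationRecord:
    """RGyr (nm), SASA (A^2), helix content (%), named residue distances (A)."""
    distances = {}
    for res_a, res_b in distance_specs or []:
        distances[f"{res_a}-{res_b}"] = residue_distance(frame, res_a, res_b)
    return CharacterizationRecord(
        rgyr_nm=radius_of_gyration(frame),
        sasa_A2=sasa(frame, probe_radius=probe_radius, n_points=n_points),
        helix_percent=helix_content(frame),
        distances_A=distances,
    )
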