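"""Conformational selection: K-means in PC space.

Frames are clustered with K-means (squared Euclidean, k-means++ seeding,
best of several restarts).  Cluster labels are renumbered by descending
population so that cluster 0 is always the most-populated state.  Cluster
occupancies give relative conformational free energies
ΔG_conf(1,i) = −ln(Pᵢ/P₁) in kT, and the trajectory frame closest to each
cluster centre is exported as that state's docking representative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .decomposition import EssentialDynamics, ProjectedTrajectory
from .exceptions import ClusterCountError, EmptyClusterError, ZeroPopulationError


def _scores_of(X) -> np.ndarray:
    if isinstance(X, ProjectedTrajectory):
        return X.scores
    return np.atleast_2d(np.asarray(X, dtype=float))


@dataclass
class ClusterEnsemble:
    """Cluster assignments, populations, free energies and representatives."""

    k: int
    assignments: np.ndarray          # (F,) int labels, 0 = most populated
    centers: np.ndarray              # (k, d) PC-space centres
    populations: np.ndarray          # (k,) fractions, descending
    dg_conf: np.ndarray              # (k,) kT, 0 for cluster 0
    representative_frames: np.ndarray | None = None  # (k,) frame indices
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.populations.sum(), 1.0, atol=1e-12):
            raise ValueError("populations must sum to 1")
        if self.dg_conf[int(np.argmax(self.populations))] != 0.0:
            raise ValueError("dg_conf of the most-populated cluster must be 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(self.k),
            "population": self.populations,
            "dg_conf_kT": self.dg_conf,
            "representative_frame": (
                self.representative_frames
                if self.representative_frames is not None
                else [-1] * self.k
            ),
        })

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def conf_free_energies(populations: np.ndarray,
                       temperature_mode: str = "populations") -> np.ndarray:
    """Relative conformational free energies from cluster occupancies.

    ``"populations"``: ΔG_conf(1,i) = −ln(Pᵢ/P₁) in kT with P₁ the largest
    population.  ``"equal"``: all zeros (every conformation equally likely).
    """
    populations = np.asarray(populations, dtype=float)
    if temperature_mode == "equal":
        return np.zeros_like(populations)
    if temperature_mode != "populations":
        raise ValueError(f"unknown temperature_mode {temperature_mode!r}")
    if np.any(populations <= 0):
        raise ZeroPopulationError("all cluster populations must be positive")
    if not np.isclose(populations.sum(), 1.0, atol=1e-9):
        raise ValueError("populations must sum to 1")
    out = -np.log(populations / populations.max())
    return np.where(out == 0.0, 0.0, out)  # avoid -0.0 in serialised output


class KMeansConformations(BaseEstimator, ClusterMixin):
    """K-means clustering of PC-space frames with population bookkeeping.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of conformational states to extract.
    random_state : int, default 0
        Seed for k-means++ initialisation.
    n_init : int, default 10
        Number of restarts; the run with the lowest inertia wins.
    energy_mode : {"populations", "equal"}, default "populations"
        How ΔG_conf is assigned (occupancy-based, or the equal-weighting
        limit where every state costs 0 kT).
    dg_conf_override : array or None
        User-supplied ΔG_conf vector (kT, reference state 0) replacing the
        occupancy estimate.

    Attributes
    ----------
    labels_, cluster_centers_, inertia_ : as in scikit-learn, but with
        labels renumbered by descending population.
    populations_ : (k,) cluster occupancy fractions, descending.
    dg_conf_ : (k,) relative free energies, kT.
    representative_frames_ : (k,) index of the member frame nearest each
        centre (Euclidean in retained-PC space; ties -> lowest index).
    """

    def __init__(self, n_clusters: int = 4, random_state: int = 0,
                 n_init: int = 10, energy_mode: str = "populations",
                 dg_conf_override=None):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_init = n_init
        self.energy_mode = energy_mode
        self.dg_conf_override = dg_conf_override

    def fit(self, X, y=None) -> "KMeansConformations":
        scores = _scores_of(X)
        F = scores.shape[0]
        if not 1 <= self.n_clusters <= F:
            raise ClusterCountError(
                f"n_clusters={self.n_clusters} invalid for {F} frames"
            )
        km = KMeans(n_clusters=self.n_clusters, init="k-means++",
                    n_init=self.n_init, random_state=self.random_state).fit(scores)
        counts = np.bincount(km.labels_, minlength=self.n_clusters)
        if np.any(counts == 0):
            raise EmptyClusterError("k-means converged with an empty cluster")

        # renumber: cluster 0 = most populated (stable for ties)
        order = np.lexsort((np.arange(self.n_clusters), -counts))
        relabel = np.empty(self.n_clusters, dtype=int)
        relabel[order] = np.arange(self.n_clusters)
        self.labels_ = relabel[km.labels_]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.inertia_ = float(km.inertia_)
        self.populations_ = counts[order] / F
        if self.dg_conf_override is not None:
            self.dg_conf_ = np.asarray(self.dg_conf_override, dtype=float)
            if self.dg_conf_.shape != (self.n_clusters,):
                raise ValueError("dg_conf_override has wrong length")
        else:
            self.dg_conf_ = conf_free_energies(self.populations_,
                                               self.energy_mode)
        self.representative_frames_ = _nearest_members(
            scores, self.labels_, self.cluster_centers_
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        scores = _scores_of(X)
        d = ((scores[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return d.argmin(axis=1)

    def to_ensemble(self, seed: int | None = None) -> ClusterEnsemble:
        check_is_fitted(self, "cluster_centers_")
        return ClusterEnsemble(
            k=self.n_clusters, assignments=self.labels_.copy(),
            centers=self.cluster_centers_.copy(),
            populations=self.populations_.copy(), dg_conf=self.dg_conf_.copy(),
            representative_frames=self.representative_frames_.copy(),
            seed=self.random_state if seed is None else seed,
        )


def _nearest_members(scores: np.ndarray, labels: np.ndarray,
                     centers: np.ndarray) -> np.ndarray:
    """Per cluster, the member frame nearest the centre; ties -> lowest index."""
    reps = np.empty(len(centers), dtype=int)
    for c in range(len(centers)):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise EmptyClusterError(f"cluster {c} has no members")
        d2 = ((scores[members] - centers[c]) ** 2).sum(axis=1)
        reps[c] = members[int(np.argmin(d2))]  # argmin returns first minimum
    return reps


# -- thin functional wrappers -------------------------------------------------

def kmeans_cluster(proj, k: int, seed: int = 0,
                   restarts: int = 10) -> ClusterEnsemble:
    """Cluster PC-space frames; returns the ensemble without representatives."""
    model = KMeansConformations(n_clusters=k, random_state=seed,
                                n_init=restarts).fit(proj)
    ens = model.to_ensemble()
    return replace(ens, representative_frames=None)


def select_representatives(
    proj,
    ensemble: ClusterEnsemble,
    metric: str = "pc",
    features: np.ndarray | None = None,
    model: EssentialDynamics | None = None,
) -> np.ndarray:
    """One representative frame index per cluster.

    ``metric="pc"`` (default): Euclidean distance in retained-PC space.
    ``metric="cartesian"``: RMS distance between each member frame's feature
    vector and the back-projected (reconstructed) cluster centre; requires
    ``features`` and the fitted ``model``.
    """
    scores = _scores_of(proj)
    if metric == "pc":
        return _nearest_members(scores, ensemble.assignments, ensemble.centers)
    if metric != "cartesian":
        raise ValueError(f"unknown metric {metric!r}")
    if features is None or model is None:
        raise ValueError("cartesian metric needs features and the PCA model")
    feats = np.asarray(features, dtype=float)
    recon = model.inverse_transform(ensemble.centers)
    reps = np.empty(ensemble.k, dtype=int)
    for c in range(ensemble.k):
        members = np.flatnonzero(ensemble.assignments == c)
        d2 = ((feats[members] - recon[c]) ** 2).sum(axis=1)
        reps[c] = members[int(np.argmin(d2))]
    return reps


def inertia_report(proj, k_values, seed: int = 0,
                   restarts: int = 10) -> pd.DataFrame:
    """Inertia vs k (elbow curve) to support manual choice of k."""
    scores = _scores_of(proj)
    rows = []
    for k in k_values:
        km = KMeans(n_clusters=int(k), init="k-means++", n_init=restarts,
                    random_state=seed).fit(scores)
        rows.append({"k": int(k), "inertia": float(km.inertia_)})
    return pd.DataFrame(rows)
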