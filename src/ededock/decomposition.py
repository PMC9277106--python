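"""Essential dynamics: PCA of the pocket feature matrix.

The dominant collective motions of the pocket are the leading eigenvectors
of the covariance of the mean-centred feature matrix (unbiased F−1
denominator, no variance scaling — all columns are in Å).  Components are
retained up to a cumulative-variance threshold (default 90%) and capped at
``max_pcs`` (default 15).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .exceptions import DimensionMismatchError, ZeroVarianceError
from .pocket import FeatureMatrix


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


class EssentialDynamics(BaseEstimator, TransformerMixin):
    """PCA with cumulative-variance component retention.

    Parameters
    ----------
    variance_threshold : float, default 0.90
        Retain the smallest number of leading components whose cumulative
        variance fraction reaches this value.
    max_pcs : int or None, default 15
        Hard cap on the retained component count, applied after the
        threshold rule.

    Attributes
    ----------
    mean_ : (3m,) array — feature mean, Å.
    components_ : (r, 3m) array — full orthonormal basis, eigenvalue-sorted;
        each row's largest-magnitude entry is positive (deterministic sign).
    eigenvalues_ : (r,) array — variances along each component, Å².
    variance_fraction_, cumulative_fraction_ : (r,) arrays.
    n_retained_ : int — retained component count.
    """

    def __init__(self, variance_threshold: float = 0.90, max_pcs: int | None = 15):
        self.variance_threshold = variance_threshold
        self.max_pcs = max_pcs

    def fit(self, X, y=None) -> "EssentialDynamics":
        X = _as_array(X)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with >= 1 column")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 frames to estimate covariance")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if np.allclose(X, X[0], atol=1e-12):
            raise ZeroVarianceError("all frames identical; covariance is zero")

        pca = PCA(n_components=None, svd_solver="full").fit(X)
        comps = pca.components_.copy()
        # deterministic sign: largest-magnitude entry of each component > 0
        flip = comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)] < 0
        comps[flip] *= -1.0

        self.mean_ = pca.mean_
        self.components_ = comps
        self.eigenvalues_ = pca.explained_variance_
        self.variance_fraction_ = pca.explained_variance_ratio_
        self.cumulative_fraction_ = np.cumsum(self.variance_fraction_)
        k = int(np.searchsorted(self.cumulative_fraction_,
                                self.variance_threshold - 1e-12) + 1)
        k = min(k, len(self.eigenvalues_))
        if self.max_pcs is not None:
            k = min(k, int(self.max_pcs))
        self.n_retained_ = k
        self.n_features_in_ = X.shape[1]
        return self

    def _check_dim(self, X: np.ndarray) -> None:
        if X.shape[-1] != self.n_features_in_:
            raise DimensionMismatchError(
                f"expected {self.n_features_in_} features, got {X.shape[-1]}"
            )

    def transform(self, X) -> np.ndarray:
        """Project onto the retained components: (X − mean) · Wᵀ."""
        check_is_fitted(self, "components_")
        X = _as_array(X)
        self._check_dim(X)
        return (X - self.mean_) @ self.components_[: self.n_retained_].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Approximate Cartesian image of PC-space points: mean + Σ sₖ·wₖ."""
        check_is_fitted(self, "components_")
        scores = np.asarray(scores, dtype=float)
        squeeze = scores.ndim == 1
        scores = np.atleast_2d(scores)
        if scores.shape[1] > len(self.components_):
            raise DimensionMismatchError(
                f"got {scores.shape[1]} score dimensions but only "
                f"{len(self.components_)} components exist"
            )
        out = self.mean_ + scores @ self.components_[: scores.shape[1]]
        return out[0] if squeeze else out

    # -- persistence --------------------------------------------------------
    def to_dir(self, out_dir: str | Path) -> Path:
        check_is_fitted(self, "components_")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(out_dir / "mean.csv", self.mean_[None, :], delimiter=",")
        np.savetxt(out_dir / "components.csv", self.components_, delimiter=",")
        np.savetxt(out_dir / "eigenvalues.csv", self.eigenvalues_, delimiter=",")
        meta = pd.Series({
            "variance_threshold": self.variance_threshold,
            "max_pcs": -1 if self.max_pcs is None else self.max_pcs,
            "n_retained": self.n_retained_,
        })
        meta.to_csv(out_dir / "metadata.csv", header=False)
        return out_dir

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "EssentialDynamics":
        in_dir = Path(in_dir)
        meta = pd.read_csv(in_dir / "metadata.csv", header=None, index_col=0)[1]
        max_pcs = int(meta["max_pcs"])
        model = cls(variance_threshold=float(meta["variance_threshold"]),
                    max_pcs=None if max_pcs < 0 else max_pcs)
        model.mean_ = np.loadtxt(in_dir / "mean.csv", delimiter=",", ndmin=1)
        model.components_ = np.loadtxt(in_dir / "components.csv",
                                       delimiter=",", ndmin=2)
        model.eigenvalues_ = np.loadtxt(in_dir / "eigenvalues.csv",
                                        delimiter=",", ndmin=1)
        total = model.eigenvalues_.sum()
        model.variance_fraction_ = model.eigenvalues_ / total
        model.cumulative_fraction_ = np.cumsum(model.variance_fraction_)
        model.n_retained_ = int(meta["n_retained"])
        model.n_features_in_ = model.components_.shape[1]
        return model


@dataclass
class ProjectedTrajectory:
    """Per-frame PC coordinates over the retained components."""

    scores: np.ndarray  # (F, n_retained)
    model: EssentialDynamics

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


# -- thin functional wrappers -------------------------------------------------

def fit_pca(features, variance_threshold: float = 0.90,
            max_pcs: int | None = 15) -> EssentialDynamics:
    """Fit the essential-dynamics model on a feature matrix."""
    return EssentialDynamics(variance_threshold=variance_threshold,
                             max_pcs=max_pcs).fit(features)


def project(features, model: EssentialDynamics) -> ProjectedTrajectory:
    return ProjectedTrajectory(scores=model.transform(features), model=model)


def reconstruct(scores: np.ndarray, model: EssentialDynamics) -> np.ndarray:
    return model.inverse_transform(scores)


def pc_histogram(proj: ProjectedTrajectory, bins: int = 50) -> pd.DataFrame:
    """2-D histogram of the first two PCs, as a tidy frame for plotting."""
    if proj.scores.shape[1] < 2:
        raise DimensionMismatchError("need at least two retained PCs")
    h, xe, ye = np.histogram2d(proj.scores[:, 0], proj.scores[:, 1], bins=bins)
    xc, yc = 0.5 * (xe[:-1] + xe[1:]), 0.5 * (ye[:-1] + ye[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame({"pc1": xx.ravel(), "pc2": yy.ravel(),
                         "count": h.ravel().astype(int)})
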