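"""PCA + canonical discriminant analysis of breath prints.

The recognition model used throughout this package is the classical
chemometrics pipeline for sensor arrays:

1. autoscale each active sensor (zero mean, unit SD on the training data);
2. reduce to ``n_pc`` principal components;
3. fit the two-class Fisher canonical axis ``w ∝ S_pooled⁻¹ (m̄₁ − m̄₂)`` in
   PC space (two groups admit exactly one canonical variate);
4. classify by nearest group centroid along the canonical axis (equal
   priors), and report the Mahalanobis (M-)distance between the group
   centroids, ``M = sqrt((m̄₁−m̄₂)ᵀ S_pooled⁻¹ (m̄₁−m̄₂))``.

An M-distance above 3 is conventionally read as a high probability of group
discrimination.  The pooled within-class covariance uses denominator
``n − 2`` and is ridge-regularized by ``eps · trace(S)/k`` only when its
condition number exceeds 1e10, so tiny cohorts (n ≈ 11) remain workable.

:class:`PCACanonicalDiscriminant` is a scikit-learn compatible estimator;
:func:`fit_model` / :func:`classify` / :func:`m_distance` wrap it for
:class:`~breathprint.containers.BreathPrintSet` inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .containers import N_SENSORS, BreathPrint, BreathPrintSet

__all__ = [
    "PCACanonicalDiscriminant",
    "DiscriminationModel",
    "fit_model",
    "classify",
    "m_distance",
    "M_DISTANCE_THRESHOLD",
]

#: conventional cut-off above which group discrimination is called "high probability"
M_DISTANCE_THRESHOLD = 3.0


class PCACanonicalDiscriminant(BaseEstimator, ClassifierMixin):
    """Two-class canonical discriminant on a principal-component reduction.

    Parameters
    ----------
    n_pc : int
        Number of principal components retained before the discriminant.
    autoscale : bool
        If True (default), divide each feature by its training SD after
        centering (correlation-matrix PCA); if False, center only.
    ridge : float
        Relative ridge ``ridge * trace(S)/k`` added to the pooled covariance
        when it is near-singular.
    cond_threshold : float
        Condition-number threshold triggering the ridge.

    Attributes (after ``fit``)
    --------------------------
    classes_ : (2,) array of class labels, sorted; ties and the canonical
        sign convention resolve toward ``classes_[0]``.
    mean_, scale_ : per-feature training mean and scale.
    pc_loadings_ : (p, n_pc) orthonormal principal axes.
    canonical_axis_ : (n_pc,) Fisher discriminant direction in PC space.
    centroids_ : (2,) canonical-score class means (classes_[0] first, lower).
    pooled_within_cov_ : (n_pc, n_pc) pooled within-class covariance (n-2).
    m_distance_ : Mahalanobis distance between the class centroids.
    discriminative_ : bool, ``m_distance_ > 3``.
    regularization_ : ridge actually applied (0.0 if none).
    """

    def __init__(
        self,
        n_pc: int = 4,
        autoscale: bool = True,
        ridge: float = 1e-8,
        cond_threshold: float = 1e10,
    ):
        self.n_pc = n_pc
        self.autoscale = autoscale
        self.ridge = ridge
        self.cond_threshold = cond_threshold

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(f"exactly 2 classes required; got {classes.tolist()}")
        if np.any(counts < 2):
            small = classes[counts < 2]
            raise ValueError(f"each class needs >= 2 samples; class {small[0]!r} has fewer")
        if self.n_pc < 1:
            raise ValueError("n_pc must be >= 1")

        n, p = X.shape
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not np.all(keep):
            dropped = np.flatnonzero(~keep).tolist()
            warnings.warn(
                f"dropping constant feature(s) at column(s) {dropped} (zero variance)",
                UserWarning,
                stacklevel=2,
            )
        if int(keep.sum()) < 1:
            raise ValueError("no non-constant features left to fit on")
        k = int(self.n_pc)
        if k > min(int(keep.sum()), n - 1):
            raise ValueError(
                f"n_pc={k} exceeds min(n_features={int(keep.sum())}, n_samples-1={n - 1})"
            )

        Z = X[:, keep] - mean[keep]
        scale = sd[keep] if self.autoscale else np.ones(int(keep.sum()))
        Z = Z / scale

        # principal axes of the (auto)scaled data
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        loadings = Vt[:k].T
        # deterministic sign: largest-magnitude element of each axis positive
        for j in range(k):
            i_max = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i_max, j] < 0:
                loadings[:, j] = -loadings[:, j]
        T = Z @ loadings

        m0 = T[y == classes[0]].mean(axis=0)
        m1 = T[y == classes[1]].mean(axis=0)
        S = np.zeros((k, k))
        for c, m in ((classes[0], m0), (classes[1], m1)):
            D = T[y == c] - m
            S += D.T @ D
        S /= n - 2

        reg = 0.0
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > self.cond_threshold:
            reg = self.ridge * np.trace(S) / k
            if reg <= 0:
                reg = self.ridge
            S = S + reg * np.eye(k)
        try:
            w = np.linalg.solve(S, m0 - m1)
            md2 = float((m0 - m1) @ np.linalg.solve(S, m0 - m1))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular even after regularization"
            ) from exc

        # orient the axis so classes_[0] has the lower mean canonical score
        if float(w @ m0) > float(w @ m1):
            w = -w
        c0, c1 = float(w @ m0), float(w @ m1)

        self.classes_ = classes
        self.feature_keep_ = keep
        self.mean_ = mean[keep]
        self.scale_ = scale
        self.pc_loadings_ = loadings
        self.canonical_axis_ = w
        self.centroids_ = np.array([c0, c1])
        self.pooled_within_cov_ = S
        self.m_distance_ = math.sqrt(max(md2, 0.0))
        self.discriminative_ = bool(self.m_distance_ > M_DISTANCE_THRESHOLD)
        self.regularization_ = reg
        self.n_features_in_ = p
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "canonical_axis_"):
            raise RuntimeError("estimator is not fitted")

    def transform(self, X) -> np.ndarray:
        """PC scores of new samples."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.feature_keep_] - self.mean_) / self.scale_
        return Z @ self.pc_loadings_

    def canonical_scores(self, X) -> np.ndarray:
        return self.transform(X) @ self.canonical_axis_

    def decision_function(self, X) -> np.ndarray:
        """Signed distance from the midpoint; positive favours classes_[1]."""
        mid = float(self.centroids_.mean())
        return self.canonical_scores(X) - mid

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid assignment; exact midpoint goes to classes_[0]."""
        d = self.decision_function(np.asarray(X, dtype=float))
        return np.where(d <= 0, self.classes_[0], self.classes_[1])


# -- BreathPrintSet-facing wrappers ---------------------------------------


@dataclass
class DiscriminationModel:
    """Frozen, serializable recognition model for 32-sensor breath prints."""

    sensor_mask: np.ndarray  # (32,) bool: sensors the model actually uses
    class_labels: tuple[str, str]
    scaling_mean: np.ndarray
    scaling_sd: np.ndarray
    pc_loadings: np.ndarray
    n_pc: int
    canonical_axis: np.ndarray
    centroids: np.ndarray
    pooled_within_cov: np.ndarray
    m_distance: float
    regularization: float
    autoscale: bool = True

    @property
    def discriminative(self) -> bool:
        return self.m_distance > M_DISTANCE_THRESHOLD

    def canonical_score(self, bp: BreathPrint) -> float:
        self._check_mask(bp)
        x = bp.response[self.sensor_mask]
        scale = self.scaling_sd if self.autoscale else np.ones_like(self.scaling_sd)
        z = (x - self.scaling_mean) / scale
        return float(z @ self.pc_loadings @ self.canonical_axis)

    def _check_mask(self, bp: BreathPrint) -> None:
        missing = np.flatnonzero(self.sensor_mask & ~bp.mask) + 1
        if missing.size:
            raise ValueError(
                f"print {bp.sample_id!r} is missing sensors the model was trained on: "
                f"{missing.tolist()}"
            )


def fit_model(
    prints: BreathPrintSet, n_pc: int = 4, autoscale: bool = True
) -> DiscriminationModel:
    """Train the recognition model on a labelled breath-print set."""
    mask = prints.common_mask
    X = prints.X[:, mask]
    y = prints.y
    if "unknown" in set(y):
        raise ValueError("training prints must all be labelled asthma/control")
    est = PCACanonicalDiscriminant(n_pc=n_pc, autoscale=autoscale).fit(X, y)
    sensor_mask = mask.copy()
    sensor_mask[np.flatnonzero(mask)[~est.feature_keep_]] = False
    return DiscriminationModel(
        sensor_mask=sensor_mask,
        class_labels=(str(est.classes_[0]), str(est.classes_[1])),
        scaling_mean=est.mean_,
        scaling_sd=est.scale_ if autoscale else np.ones_like(est.mean_),
        pc_loadings=est.pc_loadings_,
        n_pc=int(n_pc),
        canonical_axis=est.canonical_axis_,
        centroids=est.centroids_,
        pooled_within_cov=est.pooled_within_cov_,
        m_distance=float(est.m_distance_),
        regularization=float(est.regularization_),
        autoscale=autoscale,
    )


def classify(model: DiscriminationModel, bp: BreathPrint) -> tuple[str, float]:
    """Assign a print to the class with the nearer canonical centroid.

    An exact midpoint score is broken deterministically toward the first
    class in ``model.class_labels``.
    """
    score = model.canonical_score(bp)
    mid = float(np.mean(model.centroids))
    label = model.class_labels[0] if score <= mid else model.class_labels[1]
    return label, score


def m_distance(model: DiscriminationModel | PCACanonicalDiscriminant) -> float:
    """Mahalanobis distance between the fitted group centroids in PC space."""
    if isinstance(model, PCACanonicalDiscriminant):
        model._check_fitted()
        return float(model.m_distance_)
    return float(model.m_distance)
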