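"""Comparison arm: GLCM Haralick features with a neural-net classifier.

The gray-level cooccurrence matrix (GLCM) records how often a pixel
pair at displacement (d, theta) takes gray levels (i, j); the 14
classical Haralick texture features are derived from the normalized
matrix.  A small one-hidden-layer feed-forward network classifies the
14-dimensional feature vectors, evaluated by stratified tenfold cross
validation.  This baseline carries the strong assumptions the random-
feature pipeline avoids — a specific displacement, direction, and
quantization — which are therefore all exposed in :class:`GlcmConfig`.

Conventions for degenerate inputs (documented, not silent):
logarithms are base 2; zero-probability terms contribute 0 to
entropy-type features; the information measures of correlation and the
maximal correlation coefficient use an epsilon floor of 1e-12 inside
logs and divisions; correlation on a zero-variance marginal is defined
as 0 (with a logged note).  Gray levels are indexed from 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

EPS = 1e-12

#: The 14 Haralick features in their fixed output order.
HARALICK_NAMES: tuple[str, ...] = (
    "angular_second_moment", "contrast", "correlation", "variance",
    "inverse_difference_moment", "sum_average", "sum_variance",
    "sum_entropy", "entropy", "difference_variance", "difference_entropy",
    "info_measure_correlation_1", "info_measure_correlation_2",
    "maximal_correlation_coefficient",
)

_ANGLES = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass(frozen=True)
class GlcmConfig:
    """Displacement, direction, quantization, and symmetry of the GLCM."""

    distance: int = 1
    direction: Literal[0, 45, 90, 135, "average"] = "average"
    gray_levels: int = 32
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.direction != "average" and self.direction not in _ANGLES:
            raise ValueError("direction must be 0, 45, 90, 135 or 'average'")


def quantize(image: np.ndarray, gray_levels: int) -> np.ndarray:
    """Map an image onto integer gray levels 0 .. gray_levels-1 by
    equal-width binning over the observed intensity range (a constant
    image maps to level 0)."""
    img = np.asarray(image).astype(float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * gray_levels).astype(int)
    return np.clip(q, 0, gray_levels - 1).astype(np.uint8)


def compute_glcm(image: np.ndarray, config: GlcmConfig = GlcmConfig()) -> np.ndarray:
    """Normalized (sum-1) cooccurrence matrix at the configured offset.

    ``direction='average'`` averages the four directional normalized
    matrices; ``symmetric`` counts each pair in both orders.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if config.distance >= max(img.shape):
        raise ValueError(
            f"distance {config.distance} too large for image {img.shape}")
    q = quantize(img, config.gray_levels)
    if config.direction == "average":
        angles = list(_ANGLES.values())
    else:
        angles = [_ANGLES[config.direction]]
    P = graycomatrix(q, distances=[config.distance], angles=angles,
                     levels=config.gray_levels, symmetric=config.symmetric,
                     normed=True)
    # (levels, levels, n_dist, n_angle) -> average over angles
    glcm = P[:, :, 0, :].mean(axis=2)
    total = glcm.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at the configured offset")
    return glcm / total


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 14 classical texture features of a normalized GLCM.

    Returned in the order of :data:`HARALICK_NAMES`.  The maximal
    correlation coefficient is the square root of the second-largest
    eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k)).
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be nonnegative and sum to 1")
    L = p.shape[0]
    i = np.arange(L)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0 .. 2L-2 and p_{x-y}(k), k = 0 .. L-1
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(),
                        minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(),
                         minlength=L)
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    def entropy(q: np.ndarray) -> float:
        nz = q > 0
        return float(-np.sum(q[nz] * np.log2(q[nz])))

    f1 = float(np.sum(p ** 2))
    f2 = float((k_diff ** 2) @ p_diff)
    if sd_x > 0 and sd_y > 0:
        f3 = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        logger.info("zero-variance GLCM marginal: correlation set to 0")
        f3 = 0.0
    f4 = float(np.sum((ii - mu_x) ** 2 * p))
    f5 = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    f6 = float(k_sum @ p_sum)
    f7 = float(((k_sum - f6) ** 2) @ p_sum)
    f8 = entropy(p_sum)
    f9 = entropy(p.ravel())
    mu_diff = float(k_diff @ p_diff)
    f10 = float(((k_diff - mu_diff) ** 2) @ p_diff)
    f11 = entropy(p_diff)

    hx = entropy(px)
    hy = entropy(py)
    outer = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(outer + EPS)))
    hxy2 = float(-np.sum(outer * np.log2(outer + EPS)))
    denom = max(hx, hy)
    f12 = (f9 - hxy1) / denom if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - f9)))))

    Q = (p / (px[:, None] + EPS)) @ (p / (py[None, :] + EPS)).T
    eig = np.sort(np.abs(np.linalg.eigvals(Q)))
    f14 = float(np.sqrt(max(0.0, min(1.0, eig[-2])))) if L > 1 else 0.0

    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11,
                     f12, f13, f14])


def roi_haralick(image: np.ndarray,
                 config: GlcmConfig = GlcmConfig()) -> np.ndarray:
    """Convenience: GLCM then the 14 features for one ROI."""
    return haralick_features(compute_glcm(image, config))


def nn_train(features: np.ndarray, labels: Sequence[str],
             hidden_size: int = 10, epochs: int = 500,
             seed: int = 0) -> Pipeline:
    """Fit the baseline classifier on z-scored Haralick vectors.

    One hidden layer of logistic units trained by gradient descent;
    ``hidden_size=0`` degenerates to a multinomial linear classifier.
    Deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if hidden_size == 0:
        clf = LogisticRegression(max_iter=max(epochs, 200), random_state=seed)
    else:
        # logistic units learn slowly at adam's stock 1e-3 step; 1e-2 on
        # z-scored inputs converges well within the default epoch budget
        clf = MLPClassifier(hidden_layer_sizes=(hidden_size,),
                            activation="logistic", solver="adam",
                            learning_rate_init=0.01,
                            max_iter=epochs, random_state=seed)
    model = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    model.fit(X, y)
    return model


def cv_splits(labels: Sequence[str], seed: int = 0
              ) -> list[tuple[np.ndarray, np.ndarray]]:
    """The (train, test) index folds used by :func:`tenfold_cv`.

    Stratified 10-fold when every class has at least 10 samples,
    otherwise leave-one-out with a logged warning.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        logger.warning(
            "class %s has %d < 10 samples; falling back to leave-one-out",
            classes[counts.argmin()], counts.min())
        return list(LeaveOneOut().split(np.zeros_like(y, dtype=float)))
    splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y, dtype=float), y))


def tenfold_cv(features: np.ndarray, labels: Sequence[str], seed: int = 0,
               hidden_size: int = 10, epochs: int = 500,
               stage_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Stratified 10-fold cross validation of the baseline classifier.

    Predictions are pooled over the test folds and per-stage accuracies
    (percent) reported.  A class with fewer than 10 samples cannot be
    stratified into ten folds; the split then falls back to
    leave-one-out with a logged warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    y_pred = np.empty_like(y)
    for fold, (tr, te) in enumerate(cv_splits(y, seed)):
        model = nn_train(X[tr], y[tr], hidden_size=hidden_size,
                         epochs=epochs, seed=seed + fold)
        y_pred[te] = model.predict(X[te])
    order = list(stage_order) if stage_order is not None else list(classes)
    rows = []
    for stage in order:
        sel = y == stage
        rows.append({"stage": stage,
                     "accuracy": 100.0 * float(np.mean(y_pred[sel] == stage))
                     if sel.any() else np.nan,
                     "n": int(sel.sum())})
    return pd.DataFrame(rows).set_index("stage")
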