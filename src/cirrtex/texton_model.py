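"""Compressed-texton dictionary learning and chi-square 1-NN staging.

The ROI classification system works in the compressed feature domain:

1. *Dictionary learning* — for each of the C stages, K textons are
   learned by K-means over that stage's pooled compressed patch
   vectors; the dictionary W concatenates the per-stage blocks in stage
   order, so its size is C*K and textons [c*K, (c+1)*K) always come
   from stage c's pool.
2. *Histogram of textons* — each ROI is represented by the normalized
   frequency, over its patches, of the nearest dictionary texton
   (Euclidean, ties to the lowest index).  Each stage c is represented
   by the set H_c of its training-ROI histograms.
3. *Classification* — a test histogram h_new is assigned the stage of
   the single training histogram nearest in the chi-square histogram
   distance

       chi2(h1, h2) = 1/2 * sum_k (h1(k) - h2(k))^2 / (h1(k) + h2(k)),

   with empty-vs-empty bins contributing zero.  On normalized
   histograms this distance lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .random_features import (CompressedFeatureSet, NormalizationMethod,
                              ProjectionMatrix, make_projection, roi_features)
from .roi_extraction import RoiImage
from .synthetic_textures import STAGES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TextonDictionary:
    """C*K compressed textons, K per stage, stage blocks concatenated."""

    textons: np.ndarray              # (C*K, output_dim)
    K: int
    stage_order: tuple[str, ...]

    @property
    def C(self) -> int:
        return len(self.stage_order)

    @property
    def size(self) -> int:
        return self.textons.shape[0]

    def stage_block(self, stage: str) -> np.ndarray:
        c = self.stage_order.index(stage)
        return self.textons[c * self.K:(c + 1) * self.K]


@dataclass(frozen=True)
class TextonHistogram:
    """Normalized texton-frequency histogram representing one ROI."""

    bins: np.ndarray
    stage_label: str | None = None   # known for training ROIs, None for test
    source: RoiImage | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.ndim != 1 or np.any(b < 0):
            raise ValueError("histogram bins must be a 1-D nonnegative vector")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("histogram bins must sum to 1")
        object.__setattr__(self, "bins", b)


@dataclass(frozen=True)
class StageModelSet:
    """For each stage c, the set H_c of training histograms."""

    models: Mapping[str, list[TextonHistogram]]
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        for stage in self.stage_order:
            if not self.models.get(stage):
                raise ValueError(f"stage {stage!r} has no model histograms")


def learn_textons(features_by_stage: Mapping[str, np.ndarray], K: int,
                  seed: int, stage_order: Sequence[str] | None = None,
                  ) -> TextonDictionary:
    """Per-stage K-means in the compressed domain; concatenate blocks.

    Each stage's K-means runs independently (seeded restarts), so the
    dictionary's block structure identifies the originating stage.
    """
    order = tuple(stage_order) if stage_order is not None \
        else tuple(s for s in STAGES if s in features_by_stage) or tuple(features_by_stage)
    blocks = []
    for c, stage in enumerate(order):
        pool = np.asarray(features_by_stage[stage], dtype=float)
        if pool.shape[0] < K:
            raise ValueError(
                f"stage {stage!r} has only {pool.shape[0]} features, "
                f"fewer than K={K}")
        km = KMeans(n_clusters=K, n_init=10, random_state=seed + c)
        km.fit(pool)
        blocks.append(km.cluster_centers_)
    return TextonDictionary(textons=np.vstack(blocks), K=K, stage_order=order)


def assign_textons(features: CompressedFeatureSet | np.ndarray,
                   dictionary: TextonDictionary) -> np.ndarray:
    """Label each feature with its nearest texton (lowest index on ties)."""
    X = features.features if isinstance(features, CompressedFeatureSet) \
        else np.asarray(features, dtype=float)
    if X.shape[1] != dictionary.textons.shape[1]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match texton dim "
            f"{dictionary.textons.shape[1]}")
    # np.argmin returns the first minimizer, i.e. the lowest texton index
    return np.argmin(cdist(X, dictionary.textons), axis=1)


def texton_histogram(indices: np.ndarray | Sequence[int], dict_size: int,
                     stage_label: str | None = None,
                     source: RoiImage | None = None) -> TextonHistogram:
    """Normalized bin frequencies of texton indices."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("cannot build a histogram from an empty index list")
    if idx.min() < 0 or idx.max() >= dict_size:
        raise ValueError("texton index out of range")
    counts = np.bincount(idx, minlength=dict_size)
    return TextonHistogram(bins=counts / counts.sum(),
                           stage_label=stage_label, source=source)


def chi2_distance(h1: TextonHistogram | np.ndarray,
                  h2: TextonHistogram | np.ndarray) -> float:
    """Chi-square statistic between two histograms.

    Symmetric, zero iff equal, and bounded by 1 when both histograms
    are normalized.  Bins empty in both histograms contribute nothing.
    """
    a = h1.bins if isinstance(h1, TextonHistogram) else np.asarray(h1, dtype=float)
    b = h2.bins if isinstance(h2, TextonHistogram) else np.asarray(h2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"histogram lengths differ: {a.shape} vs {b.shape}")
    denom = a + b
    num = (a - b) ** 2
    mask = denom > 0
    return 0.5 * float(np.sum(num[mask] / denom[mask]))


@dataclass(frozen=True)
class PipelineConfig:
    """Feature-pipeline settings shared by training and testing."""

    patch_side: int = 5
    compressed_dim: int = 15
    normalization: NormalizationMethod = "unit"
    K: int = 10
    projection_seed: int = 0
    kmeans_seed: int = 0
    classifier_mode: str = "nearest_histogram"   # or "stage_centroid"


def train_models(training_rois: Sequence[tuple[RoiImage, str]],
                 config: PipelineConfig = PipelineConfig(),
                 phi: ProjectionMatrix | None = None,
                 ) -> tuple[TextonDictionary, StageModelSet, ProjectionMatrix]:
    """Full histogram-of-textons learning from labelled training ROIs.

    Runs patches -> compression -> normalization, pools per-stage
    features for dictionary learning, then represents every training
    ROI by its texton histogram, grouped into the per-stage model sets.
    The projection Phi is sampled once and shared with the test side.
    """
    stages_present = tuple(s for s in STAGES
                           if any(lbl == s for _, lbl in training_rois))
    if len(stages_present) < len(STAGES):
        missing = set(STAGES) - set(stages_present)
        raise ValueError(f"training set lacks stage(s): {sorted(missing)}")
    if phi is None:
        phi = make_projection(config.patch_side ** 2, config.compressed_dim,
                              config.projection_seed)
    per_roi: list[tuple[np.ndarray, str, RoiImage]] = []
    for roi, stage in training_rois:
        feats = roi_features(roi, phi, config.patch_side, config.normalization)
        per_roi.append((feats.features, stage, roi))
    pooled = {s: np.vstack([f for f, lbl, _ in per_roi if lbl == s])
              for s in stages_present}
    dictionary = learn_textons(pooled, config.K, config.kmeans_seed,
                               stage_order=stages_present)
    models: dict[str, list[TextonHistogram]] = {s: [] for s in stages_present}
    for feats, stage, roi in per_roi:
        idx = assign_textons(feats, dictionary)
        models[stage].append(texton_histogram(idx, dictionary.size,
                                              stage_label=stage, source=roi))
    return dictionary, StageModelSet(models=models,
                                     stage_order=stages_present), phi


def classify_roi(h_new: TextonHistogram,
                 models: StageModelSet) -> tuple[str, float]:
    """1-NN stage assignment of a test histogram by chi-square distance.

    Returns (stage, nearest distance).  Exact distance ties are broken
    by stage-order precedence.  A ``stage_centroid`` variant (distance
    to each stage's mean histogram) is available via
    :func:`classify_roi_centroid`.
    """
    best_stage, best_d = None, np.inf
    for stage in models.stage_order:
        for h in models.models[stage]:
            d = chi2_distance(h_new, h)
            if d < best_d:        # strict: earlier stage wins exact ties
                best_stage, best_d = stage, d
    assert best_stage is not None
    return best_stage, best_d


def classify_roi_centroid(h_new: TextonHistogram,
                          models: StageModelSet) -> tuple[str, float]:
    """Alternative classifier: nearest per-stage mean histogram."""
    best_stage, best_d = None, np.inf
    for stage in models.stage_order:
        centroid = np.mean([h.bins for h in models.models[stage]], axis=0)
        d = chi2_distance(h_new.bins, centroid)
        if d < best_d:
            best_stage, best_d = stage, d
    assert best_stage is not None
    return best_stage, best_d
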