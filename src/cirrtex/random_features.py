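"""Random-projection texture features for ROI classification.

An ``n x n`` ROI is decomposed into all fully-interior ``s x s`` patches
(one per interior center, ``(n - s + 1)^2`` in total), each flattened
row-major into a vector ``p_l`` of length ``m = s^2``.  Patch vectors
are compressed by a random projection ``x_l = Phi p_l`` where ``Phi``
is a short-fat matrix of i.i.d. standard-normal entries.  Compressed
sensing guarantees that, for sparse signals, such nonadaptive random
measurements capture most of the salient information while cutting the
dimension — here typically 25 -> 15.

Two optional normalizations of the compressed vector are supported:

* ``unit``:  x <- x / ||x||_2
* ``weber``: x <- x * log(1 + ||x||_2 / 0.03) / ||x||_2   (natural log)

The Weber rescaling compresses large responses logarithmically, in the
spirit of Weber's law of perceptual contrast; the 0.03 constant is
scale-meaningful because ROI intensities live on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .roi_extraction import RoiImage

NormalizationMethod = Literal["none", "weber", "unit"]

#: Contrast constant of the Weber-law normalization, on the [0, 1]
#: intensity scale.
WEBER_CONSTANT: float = 0.03


class ZeroNormError(ValueError):
    """Raised when a zero-norm feature meets a norm-based normalization."""

    def __init__(self, patch_index: int):
        self.patch_index = patch_index
        super().__init__(
            f"feature of patch {patch_index} has zero norm; "
            "'weber' and 'unit' normalization are undefined for it")


@dataclass(frozen=True)
class PatchVectorSet:
    """All interior patch vectors of one ROI, row-major flattened."""

    vectors: np.ndarray          # (count, s^2)
    patch_side: int
    roi_ref: RoiImage | None = None

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class ProjectionMatrix:
    """The random projection Phi with its generating seed."""

    entries: np.ndarray          # (output_dim, input_dim)
    seed: int
    output_dim: int
    input_dim: int


@dataclass(frozen=True)
class CompressedFeatureSet:
    """Compressed (and possibly normalized) patch vectors of one ROI."""

    features: np.ndarray         # (count, output_dim)
    normalization: NormalizationMethod = "none"
    roi_ref: RoiImage | None = None

    def __len__(self) -> int:
        return self.features.shape[0]


def extract_patches(roi: RoiImage | np.ndarray, patch_side: int) -> PatchVectorSet:
    """Slide an ``s x s`` window over every interior center of the ROI.

    Boundary pixels whose patch would overhang the ROI are dropped, so
    the count is exactly ``(n - s + 1)^2``.  ``patch_side`` must be odd
    (a patch needs a center pixel) and at least 3 — except for the
    degenerate single-patch case ``s = n``.
    """
    ref = roi if isinstance(roi, RoiImage) else None
    px = roi.pixels if isinstance(roi, RoiImage) else np.asarray(roi, dtype=float)
    if px.ndim != 2 or px.shape[0] != px.shape[1]:
        raise ValueError("ROI must be a square 2-D array")
    n = px.shape[0]
    s = int(patch_side)
    if s > n:
        raise ValueError(f"patch_side {s} exceeds ROI side {n}")
    if s % 2 == 0:
        raise ValueError("patch_side must be odd")
    if s < 3 and s != n:
        raise ValueError("patch_side must be at least 3")
    windows = np.lib.stride_tricks.sliding_window_view(px, (s, s))
    vectors = windows.reshape(-1, s * s).astype(float, copy=True)
    return PatchVectorSet(vectors=vectors, patch_side=s, roi_ref=ref)


def make_projection(input_dim: int, output_dim: int, seed: int) -> ProjectionMatrix:
    """Sample Phi (output_dim x input_dim) with i.i.d. N(0, 1) entries.

    ``output_dim`` must be strictly smaller than ``input_dim`` — the
    projection is a compression by contract.
    """
    if output_dim < 1 or output_dim >= input_dim:
        raise ValueError(
            f"need 1 <= output_dim < input_dim, got {output_dim} >= {input_dim}")
    rng = np.random.default_rng(seed)
    entries = rng.standard_normal((output_dim, input_dim))
    return ProjectionMatrix(entries=entries, seed=seed,
                            output_dim=output_dim, input_dim=input_dim)


def compress(phi: ProjectionMatrix, patches: PatchVectorSet) -> CompressedFeatureSet:
    """Apply ``x_l = Phi p_l`` to every patch vector."""
    if phi.input_dim != patches.vectors.shape[1]:
        raise ValueError(
            f"projection input_dim {phi.input_dim} does not match patch "
            f"vector length {patches.vectors.shape[1]}")
    features = patches.vectors @ phi.entries.T
    return CompressedFeatureSet(features=features, normalization="none",
                                roi_ref=patches.roi_ref)


def normalize(features: CompressedFeatureSet,
              method: NormalizationMethod = "unit",
              weber_constant: float = WEBER_CONSTANT) -> CompressedFeatureSet:
    """Rescale compressed features by one of {none, weber, unit}."""
    if method == "none":
        return features
    X = features.features
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ZeroNormError(int(zero[0]))
    if method == "unit":
        scale = 1.0 / norms
    elif method == "weber":
        scale = np.log1p(norms / weber_constant) / norms
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return CompressedFeatureSet(features=X * scale[:, None],
                                normalization=method,
                                roi_ref=features.roi_ref)


def roi_features(roi: RoiImage | np.ndarray, phi: ProjectionMatrix,
                 patch_side: int = 5,
                 normalization: NormalizationMethod = "unit",
                 ) -> CompressedFeatureSet:
    """Convenience: patches -> compression -> normalization for one ROI."""
    return normalize(compress(phi, extract_patches(roi, patch_side)),
                     normalization)
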