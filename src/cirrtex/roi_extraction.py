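"""Square ROI extraction from liver images under an exclusion mask.

Diagnostic texture is read from the diffuse parenchyma, so regions that
do not carry it — large blood vessels in particular — must be excluded.
The caller supplies a binary admissibility mask (True = usable liver
tissue); every extracted ROI footprint lies entirely inside it.

ROI placement is a deterministic greedy row-major tiling: candidate
origins are scanned in row-major order, and an origin is accepted when
its full ``n x n`` footprint is admissible and (unless overlap is
allowed) disjoint from every previously accepted ROI.  Multiple ROIs
are taken from one image whenever it has enough admissible region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ROI side lengths used by the staging pipeline.
ALLOWED_ROI_SIZES: frozenset[int] = frozenset({30, 60})


@dataclass(frozen=True)
class RoiImage:
    """An ``n x n`` grayscale sub-image cut from a liver image.

    ``origin`` is the 0-based (row, col) of the top-left corner in the
    source image; the footprint is the half-open square
    ``[r, r+n) x [c, c+n)``.
    """

    pixels: np.ndarray
    source_case: str = ""
    source_sequence: str = ""
    origin: tuple[int, int] = (0, 0)
    enforce_size: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("ROI pixels must form a square 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("ROI pixels must be finite")
        if self.enforce_size and px.shape[0] not in ALLOWED_ROI_SIZES:
            raise ValueError(
                f"ROI side {px.shape[0]} not in allowed sizes "
                f"{sorted(ALLOWED_ROI_SIZES)}")
        object.__setattr__(self, "pixels", px)

    @property
    def n(self) -> int:
        return self.pixels.shape[0]


def extract_rois(image: np.ndarray, admissible_mask: np.ndarray,
                 roi_size: int = 30, max_rois: int | None = None,
                 allow_overlap: bool = False,
                 source_case: str = "", source_sequence: str = "",
                 ) -> list[RoiImage]:
    """Greedily tile admissible ``roi_size`` squares over the image.

    Returns all admissible (and, with ``allow_overlap`` off, pairwise
    disjoint) ROIs in deterministic row-major scan order, up to
    ``max_rois`` (None = unlimited).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(admissible_mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}")
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    n = int(roi_size)
    if n < 1 or n > min(image.shape):
        raise ValueError(
            f"roi_size {n} exceeds image dimensions {image.shape}")
    if max_rois is not None and max_rois < 0:
        raise ValueError("max_rois must be nonnegative")

    # integral image of the mask: footprint admissible iff its sum == n^2
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)

    def footprint_sum(grid: np.ndarray, r: int, c: int) -> int:
        return int(grid[r + n, c + n] - grid[r, c + n]
                   - grid[r + n, c] + grid[r, c])

    occupied = np.zeros_like(mask, dtype=bool)
    occ_ii = np.zeros_like(ii)
    rois: list[RoiImage] = []
    limit = np.inf if max_rois is None else max_rois
    for r in range(image.shape[0] - n + 1):
        if len(rois) >= limit:
            break
        for c in range(image.shape[1] - n + 1):
            if len(rois) >= limit:
                break
            if footprint_sum(ii, r, c) != n * n:
                continue
            if not allow_overlap and footprint_sum(occ_ii, r, c) != 0:
                continue
            rois.append(RoiImage(pixels=image[r:r + n, c:c + n].copy(),
                                 source_case=source_case,
                                 source_sequence=source_sequence,
                                 origin=(r, c), enforce_size=False))
            if not allow_overlap:
                occupied[r:r + n, c:c + n] = True
                occ_ii[1:, 1:] = np.cumsum(np.cumsum(occupied, axis=0), axis=1)
    return rois


def roi_inventory(rois: list[RoiImage]) -> "pandas.DataFrame":
    """Tabulate ROIs as (case_id, sequence, roi_index, origin, size)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.source_case, r.source_sequence, i, r.origin[0], r.origin[1], r.n)
         for i, r in enumerate(rois)],
        columns=["case_id", "sequence", "roi_index",
                 "origin_row", "origin_col", "size"])
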