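"""Synthetic liver-parenchyma textures for the three cirrhosis stages.

Patient MRI data of the kind this pipeline was designed for are not
publicly available, so this module generates grayscale textures that
carry the same qualitative signature radiologists describe: normal
parenchyma is a delicate, spatially smooth texture around a uniform
medium gray, while early and middle/advanced cirrhosis show coarse
particles — small nodular structures with saltatory (jumpy) gray
levels — of increasing density, size, and contrast.

The texture model is deliberately minimal: a band-limited correlated
background (Gaussian-smoothed white noise around a base gray level),
plus Poisson-scattered disc "nodules" whose interiors are shifted up or
down by a saltation amplitude, plus additive pixel noise.  The three
default presets are ordered so that high-frequency texture energy
(mean squared Laplacian, local intensity range) increases strictly from
normal through early to middle/advanced stage.

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence`` spawns keyed on (stage, case, sequence),
so any image is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

#: Canonical stage labels in increasing order of severity.
STAGES: tuple[str, str, str] = ("normal", "early", "mid_advanced")

#: The five MR contrasts acquired per patient.
DEFAULT_SEQUENCES: tuple[str, ...] = (
    "T1", "T2", "arterial", "portal_venous", "equilibrium",
)


@dataclass(frozen=True)
class TextureClassParams:
    """Generative parameters of one cirrhosis-stage texture class.

    Parameters
    ----------
    stage_label:
        One of :data:`STAGES`.
    base_gray:
        Mean intensity on the [0, 1] scale.
    smooth_scale:
        Spatial correlation length (Gaussian sigma, pixels) of the
        background field.  ``math.inf`` yields a perfectly flat field.
    field_sd:
        Standard deviation of the white noise *before* smoothing; the
        post-smoothing contrast of the background falls off as
        ``field_sd / (2 sqrt(pi) smooth_scale)``.
    nodule_density:
        Expected nodule count per 1000 px².
    nodule_radius_range:
        (min, max) nodule radius in pixels.
    gray_saltation:
        Amplitude of the intensity jump inside nodules, on [0, 1].
    noise_sd:
        Standard deviation of additive white pixel noise.
    """

    stage_label: str
    base_gray: float = 0.5
    smooth_scale: float = 4.0
    field_sd: float = 0.5
    nodule_density: float = 0.0
    nodule_radius_range: tuple[float, float] = (1.0, 2.0)
    gray_saltation: float = 0.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.smooth_scale > 0:
            raise ValueError("smooth_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nodule_density < 0:
            raise ValueError("nodule_density must be nonnegative")
        if not 0.0 <= self.gray_saltation <= 1.0:
            raise ValueError("gray_saltation must lie in [0, 1]")
        lo, hi = self.nodule_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nodule_radius_range must satisfy 0 < min <= max")


#: Default presets.  Chosen once so that nodule density, size, gray
#: saltation, and pixel noise all increase with stage severity, matching
#: the clinical description of progressively coarser, more nodular
#: parenchyma; normal tissue has no nodules and the longest correlation
#: length (smoothest background).
DEFAULT_PRESETS: dict[str, TextureClassParams] = {
    "normal": TextureClassParams(
        stage_label="normal",
        base_gray=0.50,
        smooth_scale=6.0,
        field_sd=0.5,
        nodule_density=0.0,
        nodule_radius_range=(1.0, 1.5),
        gray_saltation=0.0,
        noise_sd=0.015,
    ),
    "early": TextureClassParams(
        stage_label="early",
        base_gray=0.50,
        smooth_scale=3.0,
        field_sd=0.5,
        nodule_density=2.0,
        nodule_radius_range=(1.0, 2.5),
        gray_saltation=0.22,
        noise_sd=0.035,
    ),
    "mid_advanced": TextureClassParams(
        stage_label="mid_advanced",
        base_gray=0.50,
        smooth_scale=1.5,
        field_sd=0.5,
        nodule_density=5.0,
        nodule_radius_range=(1.5, 4.0),
        gray_saltation=0.40,
        noise_sd=0.055,
    ),
}


@dataclass(frozen=True)
class CohortImage:
    """One (case, sequence) image of a synthetic cohort."""

    case_id: str
    stage_label: str
    sequence_name: str
    image: np.ndarray
    exclusion_mask: np.ndarray
    max_rois: int


@dataclass(frozen=True)
class SyntheticCohort:
    """A reproducible multi-case, multi-sequence synthetic cohort."""

    cases: list[CohortImage]
    seed: int
    counts_per_stage: tuple[int, int, int]
    sequences: tuple[str, ...] = DEFAULT_SEQUENCES

    def case_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.cases:
            seen.setdefault(rec.case_id, None)
        return list(seen)

    def stage_of(self, case_id: str) -> str:
        for rec in self.cases:
            if rec.case_id == case_id:
                return rec.stage_label
        raise KeyError(case_id)

    def records_for(self, case_ids: Sequence[str],
                    sequence: str | None = None) -> list[CohortImage]:
        wanted = set(case_ids)
        return [r for r in self.cases
                if r.case_id in wanted
                and (sequence is None or r.sequence_name == sequence)]


def generate_texture(params: TextureClassParams, height: int, width: int,
                     seed: int | np.random.SeedSequence) -> np.ndarray:
    """Draw one stage-conditioned texture image with values in [0, 1].

    The image is the sum of the base gray, a smoothed-noise background,
    nodular saltation discs, and white pixel noise, clipped to [0, 1].
    Deterministic given (params, seed).
    """
    if height < 8 or width < 8:
        raise ValueError("height and width must be at least 8 pixels")
    rng = np.random.default_rng(seed)

    img = np.full((height, width), params.base_gray, dtype=float)
    if math.isfinite(params.smooth_scale):
        white = rng.normal(0.0, params.field_sd, size=(height, width))
        img += ndimage.gaussian_filter(white, params.smooth_scale, mode="reflect")
    # nodules: Poisson count over the image area, discs of random radius
    # whose interior gray jumps by +/- the saltation amplitude
    if params.nodule_density > 0:
        lam = params.nodule_density * height * width / 1000.0
        n_nodules = rng.poisson(lam)
        lo, hi = params.nodule_radius_range
        yy, xx = np.mgrid[0:height, 0:width]
        for _ in range(n_nodules):
            r = rng.uniform(lo, hi)
            cy = rng.uniform(0, height)
            cx = rng.uniform(0, width)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            img[disc] += sign * params.gray_saltation
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=(height, width))
    # magnitude reconstruction: negative excursions fold back, as in MR
    # magnitude images, so tissue intensity is never exactly zero
    return np.clip(np.abs(img), 0.0, 1.0)


def _vessel_mask(height: int, width: int,
                 rng: np.random.Generator,
                 n_vessels: tuple[int, int] = (2, 4),
                 radius_range: tuple[float, float] = (5.0, 12.0)) -> np.ndarray:
    """Admissibility mask: full frame minus a few random 'vessel' discs."""
    mask = np.ones((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(rng.integers(n_vessels[0], n_vessels[1] + 1)):
        r = rng.uniform(*radius_range)
        cy = rng.uniform(0.15 * height, 0.85 * height)
        cx = rng.uniform(0.15 * width, 0.85 * width)
        mask &= (yy - cy) ** 2 + (xx - cx) ** 2 > r ** 2
    return mask


def generate_cohort(counts_per_stage: tuple[int, int, int] = (26, 13, 16),
                    sequences: Sequence[str] = DEFAULT_SEQUENCES,
                    rois_per_case_range: tuple[int, int] = (2, 6),
                    seed: int = 0,
                    image_shape: tuple[int, int] = (256, 256),
                    presets: dict[str, TextureClassParams] | None = None,
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    One image and exclusion mask per (case, sequence); the per-case ROI
    budget is drawn uniformly in ``rois_per_case_range``.  Sequences of
    the same case share the stage texture class but differ in base gray
    (emulating MR contrast differences) and in realization.  The default
    stage counts (26, 13, 16) mirror a realistic three-stage cohort of
    55 patients.
    """
    if len(sequences) == 0:
        raise ValueError("sequences list must not be empty")
    if any(c < 0 for c in counts_per_stage):
        raise ValueError("stage counts must be nonnegative")
    if rois_per_case_range[0] < 1 or rois_per_case_range[1] < rois_per_case_range[0]:
        raise ValueError("rois_per_case_range must satisfy 1 <= min <= max")
    presets = dict(DEFAULT_PRESETS if presets is None else presets)
    height, width = image_shape

    # per-sequence base-gray offsets emulate contrast differences between
    # MR sequences; deterministic in the sequence position
    seq_offsets = np.linspace(-0.08, 0.08, num=len(sequences))

    records: list[CohortImage] = []
    case_counter = 0
    for stage_idx, stage in enumerate(STAGES):
        n_cases = counts_per_stage[stage_idx]
        for case_idx in range(n_cases):
            case_counter += 1
            case_id = f"case_{case_counter:04d}"
            case_ss = np.random.SeedSequence(
                entropy=seed, spawn_key=(stage_idx, case_idx))
            case_rng = np.random.default_rng(case_ss)
            roi_budget = int(case_rng.integers(rois_per_case_range[0],
                                               rois_per_case_range[1] + 1))
            base_jitter = float(case_rng.uniform(-0.02, 0.02))
            for seq_idx, seq in enumerate(sequences):
                img_ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(stage_idx, case_idx, seq_idx))
                params = replace(
                    presets[stage],
                    base_gray=float(np.clip(
                        presets[stage].base_gray
                        + seq_offsets[seq_idx] + base_jitter, 0.15, 0.85)),
                )
                image = generate_texture(params, height, width, img_ss)
                mask_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed,
                                           spawn_key=(stage_idx, case_idx,
                                                      seq_idx, 1)))
                mask = _vessel_mask(height, width, mask_rng)
                records.append(CohortImage(
                    case_id=case_id, stage_label=stage, sequence_name=str(seq),
                    image=image, exclusion_mask=mask, max_rois=roi_budget))
    return SyntheticCohort(cases=records, seed=seed,
                           counts_per_stage=tuple(counts_per_stage),
                           sequences=tuple(str(s) for s in sequences))


def write_cohort(cohort: SyntheticCohort, outdir) -> "Path":
    """Write a cohort to disk: 16-bit grayscale PNGs, 8-bit binary mask
    PNGs, and a manifest CSV (case_id,sequence,stage,image_path,mask_path).

    Returns the manifest path.
    """
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.cases:
        stem = f"{rec.case_id}_{rec.sequence_name}"
        img_path = outdir / "images" / f"{stem}.png"
        mask_path = outdir / "images" / f"{stem}_mask.png"
        img16 = np.round(rec.image * 65535.0).astype("<u2")
        Image.fromarray(img16).save(img_path)
        Image.fromarray(rec.exclusion_mask.astype(np.uint8) * 255,
                        mode="L").save(mask_path)
        rows.append((rec.case_id, rec.sequence_name, rec.stage_label,
                     str(img_path), str(mask_path)))
    manifest = outdir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("case_id,sequence,stage,image_path,mask_path\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    return manifest


def split_cases(cohort: SyntheticCohort, train_fraction: float = 0.5,
                seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified case-level train/test split.

    Whole cases go to one side only — a case's ROIs never straddle the
    split, so test cases are completely new relative to training.
    ``n_train`` per stage is ``floor(n * fraction + 0.5)`` (half rounds
    up: 13/26, 7/13, 8/16 at fraction 0.5).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(9999,)))
    by_stage: dict[str, list[str]] = {s: [] for s in STAGES}
    for cid in cohort.case_ids():
        by_stage[cohort.stage_of(cid)].append(cid)
    train: list[str] = []
    test: list[str] = []
    for stage in STAGES:
        ids = sorted(by_stage[stage])
        rng.shuffle(ids)
        n_train = int(math.floor(len(ids) * train_fraction + 0.5))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return sorted(train), sorted(test)
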