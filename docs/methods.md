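# Methods

## Problem and model

The package stages hepatic cirrhosis into three classes — normal,
early, middle/advanced — from the texture of square liver ROIs on five
MR sequences, each sequence evaluated independently. The texture
representation is a bag of compressed textons: dense interior patches,
a random Gaussian projection, optional norm-based rescaling, per-stage
K-means texton dictionaries, normalized texton histograms, chi-square
1-nearest-neighbor ROI classification, and a majority vote over a
case's ROIs. The assumptions are deliberately weak: only that liver
texture is sparse/compressible enough for random projections to
preserve patch geometry (the compressed-sensing rationale), and that
within-stage texture is more self-similar than between-stage texture.

## Pipeline parameters

| parameter | default | units | why |
|---|---|---|---|
| ROI side `n` | 30 (60 allowed) | px | the two ROI sizes the staging protocol uses |
| patch side `s` | 5 | px | 25-dim patch vectors; small enough to be local, large enough to capture nodule edges |
| compressed dim | 15 | — | the published operating point for 25-dim patches |
| normalization | `unit` | — | best-performing option for T1-weighted in the source protocol; `weber` (constant 0.03, natural log) and `none` available |
| K textons/stage | 10 | — | not published; 10 balances histogram resolution against the per-stage feature pool size, exposed in config |
| χ² tie-break | earlier stage block | — | deterministic; ties are measure-zero in practice |
| vote tie-break | smaller mean χ², then more severe stage | — | uses available confidence first, then errs toward the clinically conservative call |

ROI intensities are mapped to [0, 1] before patch extraction so the
Weber constant 0.03 is scale-meaningful. Φ is sampled once per
experiment and shared by train and test — features must live in one
space. Compression precedes normalization (the feature is `Φp`, then
rescaled). Histograms are frequency- (not count-) normalized so ROIs
of different sizes are comparable and χ² is bounded by 1. Empty-vs-
empty histogram bins contribute zero to χ² (no evidence). The 1-NN
classifier compares against individual training histograms; a
stage-centroid variant (`classify_roi_centroid`) is provided.

ROI placement is a greedy row-major tiling of admissible origins:
deterministic and mask-compliant by construction (integral-image
footprint test), non-overlapping by default to avoid double-counting
texture in the vote. Manual radiologist placement is out of scope; the
admissibility mask (vessels excluded) is an input.

## Baseline

GLCM at displacement d=1, averaged over the four directions, 32 gray
levels (equal-width binning over the observed ROI range; a constant
ROI quantizes to level 0), symmetric counts — none of these were
published for the comparison arm, so all are config-exposed. The 14
Haralick features use base-2 logarithms, 0-based gray-level indices,
zero-probability terms dropped from entropies, an ε=1e-12 floor inside
the information measures and the Q matrix, correlation defined as 0 on
zero-variance marginals, sum variance centered on sum average, and the
maximal correlation coefficient as the square root of the
second-largest eigenvalue magnitude of Q (clamped to [0, 1]). The
classifier is one hidden layer of logistic units (default 10) trained
by adam (learning rate 0.01 on z-scored features, 500 epochs,
seeded); `hidden_size=0` degenerates to multinomial logistic
regression. Tenfold CV is stratified; classes under 10 samples fall
back to leave-one-out with a logged warning.

## Synthetic cohort

No patient images ship with the package; the generator emulates the
qualitative radiology: normal parenchyma is delicate texture at a
uniform medium gray; cirrhotic parenchyma shows coarse particles /
small nodules with saltatory gray, worsening with stage. The model is

    image = base_gray + smooth(white noise, σ = smooth_scale)
            + nodule discs (Poisson count, radius U(r_min, r_max),
              interior shifted ± gray_saltation)
            + N(0, noise_sd),   then magnitude-folded and clipped to [0, 1].

The magnitude fold (|·|) mirrors MR magnitude reconstruction and keeps
tissue intensity away from exact zero, where norm-based normalization
is undefined. The pre-smoothing amplitude of the background field
(`field_sd`, default 0.5) is a package addition: without it the
correlated background has no contrast control; post-smoothing contrast
falls off as `field_sd/(2√π·smooth_scale)`.

Default presets (chosen once, as the package's study conditions):
normal — no nodules, smooth_scale 6 px, noise 0.015; early — 2
nodules/1000 px², radii 1–2.5 px, saltation 0.22, noise 0.035;
mid_advanced — 5 nodules/1000 px², radii 1.5–4 px, saltation 0.40,
noise 0.055. These give strictly increasing high-frequency energy and
local intensity range across stages (verified in aggregate over 50
seeds). The default cohort is 26/13/16 cases over five sequences,
256×256 images, 2–6 ROIs per case, vessel-disc exclusion masks; the
case-level split (half rounds up: 13/7/8 training cases) never places
one case's ROIs on both sides. All randomness flows from one cohort
seed via `SeedSequence` spawn keys on (stage, case, sequence), so any
image is reproducible in isolation.

What the generator does *not* emulate: organ anatomy, bias fields,
k-space artifacts, partial-volume effects, inter-scanner variation, or
the irregular morphology that makes real middle/advanced ROIs hard to
place. The synthetic stages are cleanly separable by construction, so
passing end-to-end tests demonstrates the pipeline's correctness and
the vote's error-absorbing behavior — not clinical performance. The
per-stage accuracies on real hospital cohorts cannot be reproduced
here and are not claimed.

## Numerical and design notes

- Texton assignment is Euclidean (inherited from K-means geometry);
  argmin ties go to the lowest texton index.
- K-means uses 10 seeded restarts per stage; each stage's run is
  seeded independently so dictionary blocks are stable.
- The distance-preservation regression test pre-registers the band
  [0.92, 1.03] for the median of `‖Φ(u−v)‖/‖u−v‖/√15` over 200 sparse
  25-dim pairs at a fixed seed; the theoretical center is
  `√(median χ²₁₅/15) ≈ 0.978`, and per-Φ medians scatter with
  σ ≈ 0.04, so the band covers the fixed-seed value with margin while
  still catching scaling errors.
- Zero-norm compressed features raise a typed error naming the
  offending patch; they cannot arise from the generator (magnitude
  fold) but can from degenerate user input.
- Experiment sizes in tests and the acceptance script use the default
  cohort (55 cases, five sequences) or smaller; these sizes were
  chosen as the package's standard demonstration scale.

## Known limitations

- Greedy row-major tiling extracts fewer ROIs than optimal packing on
  fragmented masks.
- The per-sequence parameter adjustments the source protocol alludes
  to (other than unit norm for T1) are unpublished; all sequences here
  share one operating point.
- `hidden_size=0` changes optimizer (lbfgs logistic regression), so it
  is a semantic, not merely architectural, boundary case.
- Cross-sequence fusion (`decide_patient`) is provided but off the
  main path; per-sequence evaluation is the default protocol.
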