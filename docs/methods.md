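# Methods

## The pipeline

`panfat` automates the manual MR-opsy protocol for pancreas morphometry on
paired water/fat abdominal MR slices (nominal 512×512 px, 3 mm slice
thickness). The chain is: grayscale-LSC superpixel preprocessing → U-net
segmentation of the water phase → phantom-calibrated, erosion- and
band-filtered fat accumulation on the fat phase → Cavalieri volume.

### Grayscale LSC superpixels

Pixels are embedded as
`f(p) = (c_s cos(π/2 x), c_s sin(π/2 x), c_s cos(π/2 y), c_s sin(π/2 y),
c_c cos(π/2 g), c_c sin(π/2 g))`
with x, y normalized by the image extent and g min-max normalized per slice,
so that the inner product `f(p)·f(q)` reproduces the similarity kernel
`c_s²(cos(π/2 Δx)+cos(π/2 Δy)) + c_c² cos(π/2 Δg)` exactly (this identity is
asserted to 1e-12 in the tests). Although historically written as a
"distance", the kernel is maximal for identical pixels; clustering therefore
*maximizes* it, which the embedding turns into plain Euclidean k-means —
pixel feature norms are constant (`2c_s²+c_c²`), so nearest-centroid
assignment and similarity maximization coincide.

Implementation choices:

- **Seeding and search window.** Centers start on a regular ≈√K×√K grid,
  perturbed to the lowest-gradient pixel in a 3×3 window; assignment is
  restricted to a 2S×2S window per cluster (S = √(N/K)), the standard
  locality constraint. Pixel weights are uniform.
- **Only the ratio matters.** `c_c` is fixed at 1 and `c_s = r·c_c`; the
  single parameter `r` (default 0.25) trades compactness against boundary
  adherence.
- **Pre-smoothing.** The gray channel is smoothed with a Gaussian
  (`smooth_sigma`, default 1 px) before embedding — the same convention as
  common superpixel implementations — so that at small r the intensity term
  follows tissue edges rather than pixel noise.
- **Connectivity.** After k-means, each label keeps its largest 4-connected
  component; stray fragments, and labels whose largest component is smaller
  than `min_region_fraction × N/K` (default 0.05), are absorbed into the
  adjacent component with the closest mean gray value. Merging by gray
  similarity rather than by size preserves boundary adherence: size-based
  merging was observed to leak fragments across the organ boundary at low r,
  inverting the expected BR trend. The 0.05 floor keeps the final superpixel
  count stable across the whole r range (a prerequisite for comparing
  quality metrics at different r), where 0.25 collapsed K several-fold at
  low r.
- **Superpixel count.** The default K = 2500 refers to the nominal 512×512
  frame; on smaller frames the pipeline keeps the same superpixel *density*.
  For benchmarks that shrink the frame but must preserve the clinical
  granularity of ~20–80 superpixels across the organ, the count is instead
  matched organ-relative (e.g. K = 157 on 64×64 frames).

### Quality metrics and the choice of r

UE (undersegmentation error) uses the majority-overlap object rule: a
superpixel belongs to the object when >50% of its pixels overlap the
reference mask. BR (boundary recall) counts reference boundary pixels within
Chebyshev distance d (default 2 px) of a superpixel boundary; a boundary
pixel is one with a 4-neighbor of different value. ASA is the area-agreement
percentage `(1 − |R−T|/R)·100`, floored at 0. CP is the size-weighted
isoperimetric quotient `Σ (|S_k|/N)(4π A_k/P_k²)` with exposed pixel edges
(image border included) as the perimeter, clipped to 1.

The balance index `I = 1 − BR/CP` is minimized over r ∈ [0.05, 1] by
simulated annealing (Gaussian proposals, σ = 10% of the range, T₀ = 0.1,
geometric cooling 0.95, 60 steps, seeded). The protocol seeks the minimum
*positive* I; the annealer therefore ranks any positive I before all
negative values, then by magnitude (score = I for I ≥ 0, else 2 + |I|). On
the synthetic benchmark BR saturates near 1 at the default tolerance while
CP stays well below 1, so I is negative throughout and the search
effectively maximizes CP at preserved BR; the ranking rule is what makes
this the correct limit of the positive-I criterion.

### Segmentation network

A conventional 2-D U-net: `depth` (default 2) encoder levels of two 3×3
convolutions + ReLU and 2×2 max pooling, a two-convolution bottleneck, and
mirrored decoder levels (nearest-neighbor ×2 upsampling, a 3×3 up-conv, skip
concatenation, two 3×3 convolutions), closed by a 1×1 convolution to a
2-class score map. Width doubles per level from `base_channels` (default 8).
The network, its backpropagation and the Adam optimizer are implemented
directly in numpy (im2col convolutions, float32), sized for CPU training.

Defaults: soft-Dice loss (it directly optimizes the reported metric;
cross-entropy and an equal-weight combination are options), Adam at 1e-3,
batch size 4 (benchmarks use 8), 20 epochs, per-slice min-max input
normalization. Training/validation and train/test splits are always made by
stack (subject), never by slice, to avoid leakage. `encoder_init =
"transferred"` is accepted but falls back to scratch initialization with a
warning when no pretrained encoder weights are available. Inference is dense
by default; *centered* mode reads the class only at each superpixel's center
pixel — the member pixel closest to the centroid, which is guaranteed to lie
inside the superpixel even for non-convex shapes — and broadcasts it,
producing masks that are exact unions of superpixels. Centered
classification is applied at inference only; training remains dense (the
alternative, centered training, is noted as an open variant).

### Quantification

- **Calibration**: ordinary least squares of phantom fat fraction (%) on
  observed mean intensity; predictions are clipped to [0, 100]% and
  intensities outside the fitted range are counted and logged. The phantom
  series spans 0–100% in 10% steps by default.
- **Erosion**: `X⊖B` with a square structuring element (default 5×5, odd
  sizes only; pixels beyond the image count as background), applied to the
  predicted mask before fat is read, to discard the ambiguous rim.
- **MR-opsy band**: kept pixels satisfy 1% ≤ fraction ≤ 20% inclusive —
  the text excludes "<1% and >20%", so the endpoints stay in; both bounds
  are configurable.
- **Volumes**: slice area = pixel count × spacing²; pancreas volume =
  Σ areas × thickness (Cavalieri); fat volume = Σ kept (fraction/100) ×
  spacing² × thickness. The fat-fraction denominator is the full
  (un-eroded) pancreas volume by default — the protocol reports fat of the
  whole organ — with an `eroded` option; the run log prints both so the
  sensitivity to this choice is visible. Slices whose eroded mask is empty
  contribute no fat but their full area still counts toward volume.
- The per-pixel fraction source is calibrated fat-image brightness (the
  phantom route). A two-phase estimator `100·F/(F+W)` exists in PDFF
  practice but is not what this pipeline's calibration models; it is out of
  scope here.

## The synthetic data model

The generator emulates the *structure* of the clinical inputs, not MR
physics (no relaxometry, no Dixon reconstruction):

- **Organ**: union of 2–3 overlapping ellipses laid along a tilted major
  axis with a sinusoidal radial perturbation (7 lobes, 10% amplitude) —
  elongated, lobulated, soft-edged. Default size ~14% of the frame.
- **Water phase**: organ 125, background 40, confounder blobs 118 intensity
  units, partial-volume blur σ = 1.1 px, a smooth bias field (σ = frame/8,
  amplitude 4) and pixel noise σ = 6. The organ/confounder contrast (7
  units) is deliberately close to the noise level: the clinically hard part
  of the boundary is genuinely ambiguous, which is the condition superpixel
  preprocessing exists for.
- **Fat phase**: `intensity = 1.5 × fraction(%) + 5 + N(0, 1.5)`, shared
  with the phantom generator so calibration is consistent end to end. The
  fat-phase noise (σ/slope = 1%) is what keeps the calibrated per-pixel
  fraction error below one percentage point.
- **Fat speckle**: Gaussian blobs stamped at random intra-organ sites,
  blurred (σ = 1.2 px), cut below 1.5% and capped at 18%, then rescaled
  iteratively until the area-weighted mean matches the requested fraction
  (±0.2 points). Speckle values therefore lie strictly inside the MR-opsy
  band, so acquisition noise cannot silently move genuine fat across the
  exclusion thresholds.
- **Stacks**: 6–9 slices by default at 3 mm thickness; the per-slice organ
  scale follows an ellipsoid profile. Stored true volumes are recomputed
  from the generated masks, so they match a pixel-count recount exactly. A
  separate exact-ellipsoid stack with analytic volume 4/3·π·abc serves as
  the volume oracle.

What passing tests on this data do *not* show: robustness to textured
parenchyma, acquisition artifacts (motion, ghosting, inhomogeneity beyond a
smooth bias), annotation noise, anatomical variability of real pancreata, or
the MRS-vs-manual fat-fraction discrepancy seen in clinical readings (the
generator targets the manual/MR-opsy scale throughout).

## Benchmark sizes

The test suite runs the pipeline at reduced, fixed sizes chosen so the full
suite completes in minutes on one CPU while preserving the operating regime:

- Training benchmark: 15 stacks × 8 slices (120 slices) at 128×128 —
  superpixels at clinical density put ~22 superpixels across the organ,
  matching the clinical organ-relative granularity; 20 epochs.
- The schematic-vs-raw input comparison: 5 paired seeds, 5 stacks × 8 at
  64×64 with organ-relative superpixel count (157); 20 epochs.
- Quantification: the fat-recovery check runs at the full 512×512 frame,
  because the 5×5 erosion kernel is a fixed-pixel cost whose relative bias
  depends on organ size in pixels.
- The acceptance script mirrors these sizes with 10 training stacks.

## Numerical choices

- Schematic "exactness": the superpixel-mean image conserves the global
  mean and is idempotent only up to floating-point rounding (`n·(s/n) ≠ s`
  in IEEE arithmetic); tests assert 1e-9 relative agreement.
- Annealing objective values are cached on r rounded to 1e-4; the SA trace
  records every proposal and the best-so-far score is non-increasing by
  construction.
- k-means ties and the orphan pixels outside every search window resolve to
  the spatially nearest center; max pooling ties break toward the first
  maximum — all deterministic, so fixed seeds give bit-identical runs.
- Erosion uses kernel size 1 as the identity; even sizes are rejected rather
  than silently rounded.
- Empty masks: Dice of two empty masks is undefined and raises; training
  history uses the convention Dice = 1 when prediction and reference are
  both empty (a correctly empty prediction).

## Known limitations

- The segmenter is a reduced-width U-net trained from scratch; no pretrained
  encoder is bundled, and clinical-scale accuracy claims are out of scope.
- On this synthetic benchmark the benefit of schematic preprocessing over
  raw inputs is small and seed-sensitive (the paired comparison passes at
  the suite's fixed seeds, but the mean effect across wider seed sets is
  near zero). The generator's i.i.d. noise is learnable by the network
  itself; on real data with structured texture the preprocessing margin may
  differ in either direction.
- The balance index never turns positive on this benchmark (BR saturates at
  the default tolerance d = 2 while CP < 1), so r-selection operates in the
  negative-I regime described above; with finer tolerance or richer images
  the positive-I regime would re-emerge.
- Erosion bias: the recovered fat fraction is systematically below truth by
  the rim share of the fat (≈7% of fat at 512², more on smaller organs);
  this is inherent to the protocol's rim-exclusion step, not an estimator
  defect, and shrinks with organ size.
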