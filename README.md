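# panfat

Superpixel-assisted pancreas segmentation and intra-pancreatic fat
quantification from paired water/fat abdominal MR slices.

Pancreatic volume and fat fraction are prognostic markers for type 2
diabetes, but the pancreas is small, soft, and easily confused with the
tissue it abuts, so manual measurement takes an expert more than an hour per
subject. `panfat` implements an automated version of the manual protocol:

1. **Superpixel preprocessing** — grayscale linear spectral clustering (LSC).
   Pixel similarity is the kernel
   `D(p,q) = c_s² (cos(π/2 Δx) + cos(π/2 Δy)) + c_c² cos(π/2 Δg)`
   with coordinates and gray value normalized to [0, 1]. The kernel
   factorizes exactly through a 6-D cosine/sine embedding, so k-means in the
   embedded space maximizes within-cluster similarity. The spatial/intensity
   ratio `r = c_s / c_c` trades boundary recall (BR) against compactness
   (CP); the balance index `I = 1 − BR/CP` is minimized by simulated
   annealing to choose r. Each superpixel is then replaced by its mean gray
   value, producing a *schematic* image with enhanced tissue separability.
2. **Segmentation** — a U-net-style encoder-decoder (implemented in numpy,
   trained with soft-Dice loss and Adam) consumes the schematic water slices.
   At inference, classification can be read only at each superpixel's center
   pixel and broadcast to the whole superpixel (*centered* mode), since the
   schematic is constant per superpixel.
3. **Quantification** — a phantom series of known fat fractions calibrates
   an affine map from fat-image intensity to fat fraction (%); the predicted
   mask is eroded by a 5×5 structuring element to discard the ambiguous rim
   (X⊖B = {z : (B+z) ⊆ X}); pixels with calibrated fraction <1% or >20% are
   excluded as vessels, ducts or visceral fat (the MR-opsy rule); volume
   follows the Cavalieri principle, `V = Σ slice area × thickness`, and the
   fat volume accumulates `(fraction/100) × pixel area × thickness` over the
   kept pixels.

Segmentation quality is scored with the Dice similarity coefficient
`DSC = 2|X∩Y| / (|X|+|Y|)` and superpixel quality with undersegmentation
error (UE), boundary recall (BR), achievable segmentation accuracy (ASA) and
compactness (CP).

Because no clinical images ship with the package, a synthetic module
generates water/fat slice pairs with a lobulated low-contrast organ,
confounder tissue touching its boundary, intra-organ fat speckle at a known
area-weighted fraction, and phantom series on the same intensity convention
— every stage is testable against analytically known ground truth.

## Worked example

```python
import panfat as pf
from panfat.quantify import fat_volume, fit_calibration

# 1. calibrate intensity -> fat fraction on a phantom series
series = pf.generate_phantom_series(noise_sd=0.5, seed=1)
curve = fit_calibration(series)

# 2. generate a 7-slice water/fat stack with 8% intra-pancreatic fat
stack = pf.generate_stack(n_slices=7, shape=(256, 256), fat_fraction=8.0, seed=1)

# 3. superpixel-preprocess one water slice
spmap = pf.lsc_segment(stack.slices[3].water,
                       pf.LSCParams(n_superpixels=625, r=0.25))
quality = pf.evaluate_map(spmap, stack.slices[3].gt_mask)

# 4. quantify volume and fat with the ground-truth masks
result = fat_volume([p.fat for p in stack.slices],
                    [p.gt_mask for p in stack.slices],
                    curve, spacing=1.0, thickness=3.0)
```

printing the pieces gives:

```
calibration: fraction = 0.6669 * intensity -3.42   (R^2 = 0.99996)
stack: 7 slices, true volume 144.7 mL, true fat fraction 7.85%
superpixels: K = 621, UE = 0.019, BR = 1.000, CP = 0.181
quantified: volume 144.7 mL, fat 10.02 mL (6.92%)
```

The calibration inverts the generator's intensity convention (slope 1.5
intensity units per percent ⇒ 1/1.5 ≈ 0.667 %, intercept −5/1.5 ≈ −3.42),
the Cavalieri volume matches the constructed one, and the recovered fat
fraction sits just below the true 7.85% because erosion deliberately
discards the organ rim before fat is counted.

The same flow is available from the shell:

```bash
panfat run --out demo --seed 1          # simulate → … → quantify → evaluate
panfat quantify --out demo --kernel 5 --low 1 --high 20 --thickness 3
```

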