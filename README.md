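# emip — enhanced maximum intensity projection for dual-band RSOM

Raster-scan optoacoustic mesoscopy (RSOM) images the skin microvasculature
at tens-of-micrometre resolution. Each scan is reconstructed twice from
band-pass-filtered sinograms — a low-frequency reconstruction (LFR,
10–40 MHz, larger vessels) and a high-frequency reconstruction (HFR,
40–99 MHz, small vascular structures) — on a shared lattice with voxel
size 20 µm × 20 µm × 4 µm. The standard rendering, a per-axis maximum
intensity projection (MIP) with frequency-band-equalized red/green
fusion, degrades in two common situations:

* the skin is **tilted or curved** relative to the scan lattice, so
  lateral projections mix epidermis and dermis along each projection
  line; and
* a single **strong absorber** (hair, artifact) sets the global contrast
  reference, dimming the vasculature everywhere else.

This package implements the enhanced projection (**eMIP**) pipeline and
everything needed to evaluate it:

* **Surface detection** — iterative estimation of the skin surface
  `sfit(x, y) = Σ c_ik x^i y^k`: per-tile local thresholds on a fixed
  4×4 raster (`th_t = max((τ/s)·q_α(zMIP_ρ,t), 0.15·(τ/s)·q_α'(zMIP_ρ))`
  with relaxed quantile `α' = α − (1−α)/3`), first-crossing surface
  points per z-column and band, robust fitting (RANSAC planes, then
  penalized least squares with degree selection via
  `cost = 1.01^((n−1)²+(m−1)²) · SSE_test`, degrees ≤ 4), residual-band
  outlier exclusion (`h_top = min(max(σ_top σ, γ_top γ_t), h_abs)`),
  and per-column feasible-range narrowing; the final iteration picks the
  threshold quantile adaptively from the noise level just above the
  surface.
* **Surface correction** — rasterize the surface (`s_ij` = nearest depth
  index) and shift every z-column so the skin lands at a fixed zero
  level (default index 100 = 400 µm); cut/zero-pad at the volume limits.
* **Contrast** — the conventional baseline (least-squares band
  equalization `α* = ⟨im_LF, im_HF⟩/⟨im_HF, im_HF⟩`, joint [0, 1]
  scaling, 0.06–0.35 saturation window) and the dynamic per-band
  contrast (`th⁺ = 1.25·q_0.95(z-MIP)` per band; zero-clip, cap,
  divide).
* **Phantoms** — synthetic LFR/HFR pairs with a known polynomial
  surface, melanin sheet, vessels, hairs, noise and outliers, so every
  stage is testable against ground truth.
* **Agreement statistics** — mean opinion scores (MOS) with two-stage
  repeat averaging, MOS-difference analysis and histograms, t/Wilcoxon
  tests, and the generalized weighted Fleiss' κ (linear weights
  `w_ij = |i−j|/3`) with image-sampling and jackknife rater-sampling
  variances, group-of-3 aggregation and agreement-gain tests.

## Worked example

```python
import numpy as np
import emip

# a curved, tilted phantom with two hairs and 10% noise
spec = emip.PhantomSpec(
    surface_coefficients={(0, 0): 140.0, (1, 0): 0.25, (2, 0): -0.0008},
    n_hairs=2, noise_sd=10.0, seed=42,
)
pair, gt = emip.generate_phantom(spec)

sfit, report = emip.detect_surface(pair, emip.DetectionConfig(random_seed=0))
rmse = np.sqrt(np.mean((sfit.evaluate_grid(200, 100) - gt.true_surface) ** 2))
print(f"selected degree : {sfit.degree}")
print(f"offset (voxels) : {sfit.offset:.3f}")
print(f"surface RMSE    : {rmse:.3f} voxels ({4 * rmse:.1f} um)")

images = emip.render_emip(pair, sfit, axes=("y",))
row = images["y"].red.argmax(axis=1) + 1
print(f"skin line depth : {np.median(row):.0f} (zero level 100)")
```

prints

```
selected degree : (2, 1)
offset (voxels) : 3.321
surface RMSE    : 0.521 voxels (2.1 um)
skin line depth : 101 (zero level 100)
```

The detector recovered the quadratic-in-x surface to half a voxel
(2 µm) despite hairs and noise; after flattening, the bright skin line
sits at the zero level in the lateral projection. The `offset` is the
conservative above-skin margin (80th residual percentile + sd/5 + 3
voxels) stored with the surface.

The same pipeline is available from the shell:

```sh
emip phantom --out-dir scan --seed 42 --n-hairs 2 --noise-sd 10
emip emip scan/phantom_lfr.tif scan/phantom_hfr.tif --out-dir out --seed 0
emip mip  scan/phantom_lfr.tif scan/phantom_hfr.tif --out-dir out
emip agree ratings.csv --out-dir out        # scan_id,rater_id,method,session,rating
```

`emip emip` writes one PNG per axis, the surface sidecar
(`surface.json`), a detection report and a run manifest with input
hashes and the full configuration snapshot.

## Layout

```
src/emip/
  volume.py      3D containers, axis conventions
  io.py          TIFF/NIfTI volumes, PNG, surface sidecars
  config.py      detection configuration + iteration schedule
  tiling.py      4x4 raster, restricted z-MIPs, thresholds, adaptive alpha
  phantom.py     synthetic LFR/HFR generator with ground truth
  surface.py     iterative surface detection
  correction.py  rasterization and z-column flattening
  projection.py  MIPs, band fusion, MIP/eMIP pipelines
  agreement.py   MOS, histograms, tests, weighted Fleiss' kappa
  cli.py         command-line front end
docs/methods.md  model, parameters, numerical choices, limitations
```
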