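# Methods

This note documents the models and procedures implemented in `emip`, the
parameters that matter, the numerical choices made where conventions were
open, and what the synthetic phantoms do and do not establish.

## Coordinate and storage conventions

A reconstruction `V_ijk` lives on the 1-based lattice
`D_xyz = {1..n_x} × {1..n_y} × {1..n_z}`; `x` is the slow-scanning axis,
`y` the fast-scanning axis, and `k` the depth axis with `k = 1` nearest
the detector (depth increases with the index). Storage is 0-based NumPy
with the conversion made exactly once at the API boundary, so index
formulas (tile boundaries `a_j = ⌊d_j n_x + ½⌋`, first-crossing depths,
shift arithmetic) read literally. On disk, multi-page TIFF stores float32
depth slices in increasing-`k` page order; NIfTI-1 stores `(x, y, z)`
with the voxel pitch (mm) on the affine diagonal. Both round-trip
bit-exactly.

All quantiles in the package — tile thresholds, the adaptive-alpha
machinery, dynamic contrast caps, and the finalization percentile — go
through one shared routine implementing linear interpolation between
order statistics (the "type 7" convention). The convention is not
dictated by the method itself; fixing a single routine makes every
derived number reproducible.

## Surface detection

The skin surface is modeled as a bivariate polynomial
`sfit(x, y) = Σ_{(i,k)∈I} c_ik x^i y^k` with
`I = {(i, k): i ≤ n, k ≤ m, i + k ≤ max(n, m)}` and degree capped at 4
(higher degrees invite Runge-type instability on a 200 × 100 lateral
lattice). Coefficients are enumerated row-major in `(i, k)`; the same
ordering is used in fits, sidecars and evaluation.

Detection alternates four blocks over `n_outer_iterations` (default 4):

1. **Find surface points.** Per band and z-column, the first voxel
   inside the current feasible range whose intensity reaches the
   column's tile threshold. Thresholds are local to a fixed 4×4 raster
   (relative splits 0, 0.15, 0.5, 0.85, 1 per axis):
   `th_t = max((τ/s)·q_α(zMIP_ρ|t), 0.15·(τ/s)·q_α'(zMIP_ρ))` with the
   relaxed global floor quantile `α' = α − (1−α)/3`. Thresholds are
   computed separately for LFR and HFR from each band's own restricted
   z-MIP (the bands' intensity scales differ); the union of both bands'
   points forms the candidate set.
2. **Fit.** Early iterations use a RANSAC plane (sample size 10, inlier
   distance 30 voxels, 200 trials, consensus-maximal model refitted on
   its inliers) for robustness; later iterations use penalized least
   squares with data-driven degree selection: a seeded 95/5 train/test
   split, per-degree cost `1.01^((n−1)²+(m−1)²)·SSE_test`, minimal cost
   wins (ties, including numerical ties from exact interpolation, go to
   the earliest degree in row-major order), and the winning degree is
   refitted on all included points. Fitting is performed in lateral
   coordinates centered and scaled to [−1, 1] for conditioning; the
   coefficients reported are in raw lattice coordinates.
3. **Exclude outliers.** Residuals `r_j = sfit(x_j, y_j) − z_j`; global
   spread `σ` (sample sd, n−1) and per-tile second-moment roots
   `γ_t = sqrt(mean r²)` (tiles without residuals inherit σ). A point
   stays iff `−h_bot < r < h_top` with
   `h_top = min(max(σ_top σ, γ_top γ_t), h_abs)` and
   `h_bot = max(σ_bot σ, γ_bot γ_t)`. The absolute cap `h_abs` removes
   reflections and hairs regardless of how much they inflate the local
   spread. Inequalities are strict; a degenerate zero-width band (exact
   fit) retains exact-fit points. Fit → exclude repeats (≤ 5 inner
   iterations) until no point is removed.
4. **Feasible range.** The next iteration searches
   `[sfit − θ_top, sfit + θ_bot]` per column, clamped to the depth
   lattice; `θ` shrinks over iterations so the search concentrates
   around the current estimate.

In the final iteration the tile quantile α is chosen adaptively: a
41-voxel window centered on the shallow (detector-side) range bound
samples the local noise floor, its 95th percentile is clamped between
the `α_min`/`α_max` quantiles of the band's full z-MIP, and the quantile
matching the resulting target threshold is found by inverting the
empirical quantile function, then de-relaxed (`α = (3α' + 1)/4`). Where
the empirical quantile function is flat at the target (tied order
statistics, e.g. a noiseless phantom's melanin plateau), the smallest
quantile attaining the target is used: lower α means lower tile
thresholds and more surface points near the true surface, which is the
purpose of the adaptive choice; on continuous data the inversion is
unique anyway.

**Finalization.** After the last iteration the surface records an
offset `q_0.80(r) + sd(r)/5 + 3` voxels (population sd; residuals of the
final fit on the final included set). `sfit + offset` is a conservative
boundary bounding at least 80% of the included points on the deep side,
with the 3-voxel term guarding against residual outliers. The
polynomial itself — the skin-level estimate — is unchanged, and it is
the skin-level surface that drives flattening (below); the offset
travels with the surface sidecar for consumers that need the
conservative margin.

### Orientation conventions

With `k` increasing downward, the printed top/bottom labels of the
range bounds and the direction of the finalization offset admit two
readings. This package fixes: the feasible range is
`(sfit − θ_top, sfit + θ_bot)` — `θ_top` limits the detector side — the
noise window is centered on the detector-side bound (noise lies above
the skin), and the finalization offset extends the surface toward the
deep side as a bound under the point cloud. These choices make the
search direction (first crossing from the detector side), the noise
model and the ≥ 80% coverage contract mutually consistent.

### Hyperparameter schedule

The per-iteration values (fit method, α, τ, band multipliers, `h_abs`,
`θ`) are package defaults chosen to realize the documented qualitative
behavior — robust linear fits first, dynamic degree selection later,
adaptive α last, monotonically narrowing range — not calibrated
constants; the detection report labels them "non-canonical defaults"
and every value is overridable from a YAML config:

| iter | fit              | α        | τ   | σ/γ mult | h_abs | θ_top/θ_bot |
|------|------------------|----------|-----|----------|-------|-------------|
| 1    | RANSAC plane     | 0.99     | 1.0 | 4        | 200   | 150/150     |
| 2    | polyfit (1,1)    | 0.98     | 0.9 | 3        | 120   | 80/100      |
| 3    | polyfit dynamic  | 0.97     | 0.8 | 2.5      | 80    | 40/60       |
| 4    | polyfit dynamic  | adaptive | 0.7 | 2        | 60    | 40/60       |

A single `sensitivity` parameter (default 1) divides every threshold;
values > 1 admit weaker surface signal.

## Surface correction

`s_ij` is the nearest depth index to `sfit(i, j)` (exact halves round to
the smaller index; out-of-lattice values clamp to the nearest bound).
Each z-column of both bands shifts by `s_ij − zero_level` so the voxel
at the surface lands at the zero level (default index 100 = 400 µm at
the 4 µm depth pitch); voxels shifted out are cut, vacated entries are
zero-padded. Both bands share one shift map because one surface is
fitted from the union of both bands' points. Shifting is integer
(voxel-resolution); sub-voxel interpolation is out of scope.

## Contrast and rendering

**Conventional MIP.** Per axis, the HF projection is rescaled by the
least-squares equalization factor `α* = ⟨im_LF, im_HF⟩/⟨im_HF, im_HF⟩`
(the closed form of the L2 minimizer; verified against grid search),
both channels are scaled to [0, 1] between the joint minimum and
maximum, and a linear saturation window (defaults 0.06–0.35, applied to
the jointly scaled intensities: ≤ low → 0, ≥ high → 1, linear between)
boosts visibility. `α*` is computed independently per axis. Because the
joint maximum is the reference, one strong absorber compresses the rest
of the image — the failure mode the dynamic contrast removes.

**eMIP.** Both bands are flattened, then each band is normalized
independently by `th⁺ = 1.25·q_0.95` of its own full z-MIP — a
percentile, not the maximum, so isolated strong absorbers do not set
the scale — via zero-clip, cap at `th⁺`, divide. Thresholds are
computed on the corrected volumes; flattening only cuts/pads voxels, so
the z-MIP quantiles are nearly invariant to this choice. LF renders
red, HF green, blue stays zero. Lateral projections are displayed with
depth increasing downward.

## Phantoms

The generator emulates the structures that drive (and stress) surface
detection, on the default lattice 200 × 100 × 500 (a 4 mm × 2 mm field
at 0.020 mm steps):

* a melanin sheet of 2–4 voxel thickness starting at the true
  polynomial surface `z_true(x, y)` (degree ≤ 3), the brightest extended
  structure (default intensity 100, both bands) — in skin, the
  melanin-rich epidermis dominates the surface signal;
* capsule-shaped vessels below the surface: radius 3–6 voxels in LF,
  1–2 in HF, mirroring the large/small-structure split of the two
  bands;
* hair shafts at 1.5× the melanin intensity, 0.16–0.36 mm (40–90
  voxels) above the surface — hairs lie in the ultrasound coupling
  medium clearly above the skin line, which is exactly the outlier
  geometry the exclusion machinery addresses;
* optional Gaussian noise and isolated bright outlier voxels.

Generation is a pure function of spec + seed. With zero noise and no
hairs, a first-above-threshold scan at half the melanin intensity
recovers `⌈z_true⌉` on every column, so detection and flattening can be
scored exactly.

What the phantoms do **not** model: the acoustic point-spread function,
wavelength-dependent fluence decay, reconstruction streaks, motion
between B-planes, and continuous speckle-like texture. Passing the
phantom suite therefore establishes the algorithmic contracts (recovery
under tilt/curvature/outliers at realistic contrast ratios), not
clinical image quality.

The recovery benchmark uses 20 seeded phantoms with plane tilt up to
±30 voxels across the field, quadratic bowing up to 15 voxels, 0–3
hairs and noise at 10% of the melanin intensity; the detector must
reach ≤ 3 depth voxels (12 µm) RMSE against ground truth in at least
18 of 20 runs. These sizes keep the full suite in the minutes range on
a single CPU while leaving the per-run conditions at full scan scale.

## Agreement statistics

Ratings are ordinal 1..4 (bad → perfect). MOS averages a rater's two
sessions first (where a repeat exists), then averages across raters.
Paired differences `d_i = MOS_eMIP − MOS_MIP` are summarized by the
fractions of substantial differences (|d| ≥ 0.5) and binned with the
boundary-to-the-left convention (MOS width 0.125 anchored at the scale
minimum; difference width 1/3 with a zero-centered bin). Mean
differences use a two-sample t-test (two-sided by default, right-tailed
exposed) with the pooled-variance CI; median differences use the
Wilcoxon signed-rank test and a seeded percentile-bootstrap CI.

Agreement uses the generalized weighted Fleiss' κ in disagreement form,
`κ = 1 − D_o/D_e`, with linear weights `w_ij = |v_i − v_j|/(v_max −
v_min)`: `D_o` is the mean within-scan pairwise disagreement over all
ordered pairs of distinct raters, `D_e` the expected disagreement under
the pooled marginal category distribution. This is identical to the
agreement-weight formulation with weights `1 − w`. All ratings in one
category defines κ = 1. Two variance components are reported:

* `v_im` (image sampling) — the delta-method variance of `1 − D_o/D_e`
  over scans, from per-scan influence values (formula in the module
  docstring); non-negative by construction and exercised against
  brute-force κ oracles.
* `v_r` (rater sampling) — delete-one jackknife over raters
  (inter-rater), the unbiased variance of per-rater κ divided by the
  rater count (intra-rater), or the delete-two jackknife over excluded
  rater pairs (group-of-3).

Group-of-3 analysis: all `C(8,2)·C(6,3) = 560` ordered pairs of
disjoint triples, each group's per-scan mean treated as an ordinal
score on the 10-level attainable-average scale with linear weights;
the reported κ_g3 is the mean over pairs. The group image-sampling
variance is the plain sum of per-pair variances (as defined, without
normalization by the pair count; the report notes this). First-session
ratings feed the group analysis so group means stay on the attainable
scale. Agreement gains use `gain = κ_eMIP − κ_MIP`,
`var = v_r,gain + v_im,MIP + v_im,eMIP` (with `v_r,gain` from
jackknifing the paired difference), and the one-sided normal
approximation `p = 1 − Φ(gain/√var)`; zero gain with zero variance
reports p = 0.5 by continuity. Interpretation bands follow the
Landis–Koch benchmark.

## Known limitations

* Surface models are polynomial; strongly non-polynomial skin (scars,
  folds) is out of scope, as is motion correction between B-planes.
* Flattening is voxel-resolution; residual ±1-voxel steps along the
  skin line are expected and visible in the phantom renders.
* The iteration schedule is a reasonable default, not a calibrated
  optimum; real data may need per-site tuning via the config file.
* The v_im closed form is one member of a family of published variants;
  confidence intervals built on it should be read accordingly.
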