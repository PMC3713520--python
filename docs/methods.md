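# Methods

## Segmentation model

Cluster detection operates on a single channel (default YFP/Orai1, since
Orai1 marks the assembled channel cluster; the mask is then applied to both
channels). The stages are:

1. **Uniform scaling.** v ↦ clip((v − P_lo)/(P_hi − P_lo), 0, 1) with
   P_lo/P_hi the p_lo-th/p_hi-th intensity percentiles (defaults 0/100). A
   constant image maps to all zeros. With the default percentiles the
   scaling makes the mask invariant under any affine intensity transform
   of the input, so camera gain and offset drop out.
2. **Otsu thresholding** over a 256-bin histogram of [0, 1]; the returned
   threshold is the bin edge maximizing the between-class variance
   σ²_B(t) = ω₀ω₁(μ₀ − μ₁)², ties broken toward the lower edge. When no
   split produces positive between-class variance (constant input, or all
   values in one bin) a NO_FOREGROUND sentinel is returned. Foreground is
   defined by strict inequality (value > threshold) for bit-exact
   reproducibility.
3. **Localized thresholding.** The image is partitioned into non-overlapping
   tiles of `tile_px` (default 32) pixels; edge tiles may be smaller and a
   tile larger than the image degenerates to the single-tile (= global
   Otsu) case. Each tile receives its own Otsu threshold; thresholds are
   bilinearly interpolated from tile centers to pixels (clamped beyond the
   outermost centers) to avoid blocking seams at tile borders.
4. **Low-contrast fallback.** A tile whose dynamic range (max − min) is
   below `low_contrast_floor` (default 0.15) times the global dynamic
   range is considered structure-free and is assigned a threshold equal to
   its own maximum, so it contributes no foreground of its own. Falling
   back to the *global* threshold instead would mark entire bright tiles
   as foreground whenever the illumination gradient dominates the global
   histogram — the very situation localized thresholding exists for — so
   the fallback is deliberately local. The floor must exceed the min–max
   range of a pure-noise tile relative to the global range (≈ 6.5 noise sd
   plus the per-tile gradient span); 0.15 separates structure-free tiles
   from spot-bearing tiles by several standard deviations of the range
   statistic at the default fixture's signal-to-noise ratio.
5. **Component filters.** Connected components (8-connectivity by default;
   4 available) below `min_area_px` (default 4 px — a diffraction-limited
   spot spans tens of pixels, single-pixel components are noise) are
   dropped. Components whose peak rises less than `min_prominence`
   (default 0.08) of the scaled dynamic range above their local threshold
   are also dropped: Otsu ignores a bright class occupying too small a
   histogram fraction (σ²_B ≈ f·Δ² for the spot split vs ≈ 0.64·σ²_bg for
   splitting the background, so the spot wins only when the foreground
   fraction f exceeds ~0.64/contrast²), and a spot centered just across a
   tile border leaves exactly such an underweighted flank, collapsing that
   tile's threshold onto the background median. The resulting artifacts
   barely clear the threshold (measured ≤ 0.042 of the dynamic range on
   default fixtures), while genuine clusters tower above it (≥ 0.125);
   0.08 sits between the two populations. Labels are renumbered 1..n in
   raster order of each component's first pixel.

The default tile size of 32 px follows from the same small-class argument:
a single ~50 px spot is 5% of a 32-px tile's histogram but only 1.2% of a
64-px tile's, and 5% is safely above Otsu's blind spot at the contrasts the
generator produces.

Tile geometry, interpolation, the fallback rule and the component filters
are all configurable and echoed into the run log; masks from other
implementations of localized thresholding will differ in detail, and no
claim of pixel-exact agreement with any particular one is made.

## Quantification and statistics

Per-cluster intensity means are computed on the **raw** images — the scaled
image exists only to build the mask, and per-image percentile scaling would
distort intensity ratios. The per-cluster ratio is mean_CFP/mean_YFP, NaN
when mean_YFP = 0. No background subtraction is applied by default (a
constant-background option exists for the per-cell total-fluorescence
assay); with a shared background field in both channels the *difference* in
ratio between conditions remains interpretable, and the ratio-recovery
validation uses zero-background fixtures where the measured ratio equals
the true stoichiometry directly. Clusters touching the image border are
kept.

Group comparison uses a two-sided Mann–Whitney U (cluster areas and ratios
are skewed; Welch's t is available as an option and the chosen test is
logged). With both groups ≤ 8 the p-value is computed by full enumeration
of all C(n₁+n₂, n₁) group assignments with midrank handling of ties;
larger samples use the tie-corrected normal approximation. SEM is the
sample standard deviation (n − 1 denominator) over √n.

## Trace model and kinetics

The simulated ratio is r(t) = r0 for t < t_tg; plus a biexponential
store-release transient (rise τ_r = 8 s, decay τ_d = 40 s, normalized to
peak `release_amp`) after thapsigargin at t_tg in Ca²⁺-free buffer; plus,
after Ca²⁺ re-addition at t_ca, a logistic influx ΔR/(1 + e^{−k(t−t_ca−Δ)})
with Δ chosen so the sigmoid equals 1% of ΔR at t_ca (avoiding a visible
discontinuity at re-addition; the 1% onset is the documented convention).
Gaussian noise of sd `noise_sd` is added to the ratio; raw channels are
synthesized as constant F380 with F340 = r·F380, the simplest model
consistent with a ratiometric readout. Sampling is one ratio point per 2 s,
the standard acquisition cadence.

Metrics: baseline = mean ratio before t_tg; release peak = max over
[t_tg, t_ca) minus baseline; SOCE amplitude = max after t_ca minus the mean
of the last 5 samples before t_ca; maximal rate of rise = maximum OLS slope
over sliding windows of 5 consecutive samples starting within 60 s of t_ca
(the "initial" rise window; both window lengths are configurable). Peaks
are taken on the raw ratio without smoothing; the OLS window, not
smoothing, absorbs noise in the rate estimate. Points with non-positive
background-subtracted F380 are excluded; a trace with > 20% such points is
rejected.

### Known properties of the rate estimator

Two sampling properties of the max-of-sliding-OLS estimator are worth
stating precisely, and both are reproduced by the test suite:

* **Curvature attenuation.** The OLS slope over a window averages the
  derivative under the window; for a logistic (derivative ∝ sech²) with
  k = 0.2 s⁻¹ a 5-point/2-s window centered on the inflection recovers
  95.7% of ΔR·k/4, and the worst-case grid phase (inflection midway
  between sample-centered windows, which the default trace timing
  produces) recovers 94.9%. Longer windows attenuate more (91.7% at 7
  points); the 5-point default balances attenuation against variance.
* **Selection bias under noise.** Each window's slope carries noise of sd
  noise_sd/√Σ(t−t̄)² = noise_sd/√40; taking the maximum over ~30
  overlapping windows selects upward, adding a positive bias of roughly
  one window-noise sd. At noise_sd = 5% of ΔR this bias is ≈ +16% of the
  true rate and the median absolute error is ≈ 8–12%. Per-cell rates at
  realistic Fura-2 noise (≤ 2% of ΔR) are accurate to a few percent; at
  high noise the group *comparison* of rates remains valid (both arms
  share the bias) but the absolute rate is overestimated.

Rates are computed per cell; group means, SEMs and comparisons are
reported over the per-cell values. No calcium calibration is applied —
ratios stay dimensionless.

## Synthetic data: what it does and does not emulate

TIRF fields are isotropic 2-D Gaussian spots (σ = 2 px, a typical
diffraction-limited spot at ~100 nm/px) on integer pixel centers, placed by
dart throwing with a minimum separation (default 12 px) and bounded
retries, over a background of 2400 a.u. doubling linearly across the field
(uneven TIRF illumination; an optional Gaussian blob models a centered
illumination hot spot). Per-spot YFP amplitudes are uniform on [600, 800]
a.u. and CFP amplitudes are ρ × YFP. Noise is Poisson shot noise applied
through a gain (value ↦ g·Poisson(v/g), default g = 0.25 a.u./photon)
followed by additive Gaussian read noise (15 a.u.), approximating an
EM-CCD; the weakest spot sits ~16 noise sd above the brightest background.
The stoichiometry-recovery fixtures instead use zero background with shot
noise only, because Gaussian read noise on a zero background clips at zero
and produces a half-mass-at-zero histogram no threshold method handles
meaningfully.

The two-arm generator models the perturbation as spot width × √area_scale
(so expected area scales by area_scale) and stoichiometry ρ × ratio_scale
with YFP amplitudes scaled by 1/ratio_scale — CFP amplitudes are untouched,
so the construction predicts larger clusters, unchanged CFP intensity,
higher YFP intensity and a lower CFP/YFP ratio. Passing the two-arm tests
therefore demonstrates that the pipeline *recovers a stoichiometry change
of that construction*, not any biological claim.

Not modeled: optics beyond a Gaussian profile (no Airy rings, no axial
structure), photobleaching, stage drift, time-lapse stacks, spot shape
variability, clustered spot placement, or background autofluorescence
texture. Performance numbers on these fixtures are therefore upper bounds
on real-data performance; the illumination gradient is the one real-world
nuisance deliberately included, since it is the failure mode localized
thresholding addresses.

## Problem sizes and numerical conventions

Validation fixtures are 512 × 512 fields with 50 spots (segmentation
robustness; 10–20 fields) or 110 spots × 9 cells per arm (two-arm
comparison, ≈ 990 clusters per arm); kinetic ensembles use 100 traces of
301 samples. Coordinates are (row, col), 0-based; areas in px²;
intensities in arbitrary camera units, never rescaled on load; images are
single-plane grayscale TIFF (8/16-bit, values rounded and clipped on
write); tables are comma-delimited UTF-8 with `#` provenance comments.
Every pipeline output carries the configuration hash and seed, all
randomness flows from a single master seed through named SeedSequence
spawns, and reruns of the same configuration are byte-identical.
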