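# focidyn

Quantitative analysis of DNA double-strand-break (DSB) repair-focus dynamics
in time-lapse fluorescence microscopy — plus a fully parameterised synthetic
microscope so every stage can be validated by parameter recovery, without any
external imaging data.

After irradiation, DSB repair proteins (γH2AX, RAD52, 53BP1, RAD51)
concentrate into diffraction-limited nuclear foci. How those foci move —
their mean square displacement, how far they travel, whether they coalesce
into repair clusters — reports on chromatin mobility and repair-pathway
activity. `focidyn` implements the standard measurement chain for such
experiments:

1. **Preprocessing** — maximum z-projection and translation-only drift
   correction by sequential phase correlation with sub-pixel refinement,
   so whole-cell movement is not mistaken for focus motion.
2. **Detection** — single-scale Laplacian-of-Gaussian spot detection with
   greedy non-maximum suppression and quadratic sub-pixel localization;
   nucleus segmentation (Otsu) for per-cell focus counts and region
   intensities.
3. **Tracking** — frame-to-frame linking by optimal assignment on squared
   displacement (LAP) with gap closing.
4. **Mobility statistics** — per-track MSD over all overlapping pairs,

   MSD(Δt) = ⟨(x(t+Δt) − x(t))² + (y(t+Δt) − y(t))²⟩,

   pooled into a pair-count-weighted ensemble curve with the weighted SEM;
   a log-log fit MSD = 4·D·Δt^α giving the apparent diffusion coefficient D
   and anomalous exponent α (α < 1 sub-diffusive, α ≈ 1 Brownian, α ≈ 2
   directed); cumulative travelled distance Σᵢ √((Xᵢ−Xᵢ₋₁)² + (Yᵢ−Yᵢ₋₁)²)
   and mean speed; and clustering events, defined as ≥ 2 foci colocalized
   within a radius (default 0.5 µm) for at least 10 minutes.
5. **Micronucleus scoring** — DAPI-positive objects outside the dilated
   nuclear periphery, flagged heterochromatic when their mean HP1α signal
   exceeds the extranuclear background median + 3·MAD.
6. **Synthetic data** — nuclei with 10–200 foci moving by Brownian,
   fractional-Brownian (exact fGn covariance), confined or directed motion
   over a ~100-min window; scheduled pairwise merges; whole-field drift;
   pixel-integrated Gaussian PSF; Poisson shot noise and Gaussian read
   noise. Ground truth (trajectories, merge schedule, masks, micronucleus
   placements) is returned alongside the rendered TIFF stacks.

## Worked example

`examples/01_simulate_and_recover_msd.py` simulates 200 sub-diffusive
tracks and recovers the motion parameters from the ensemble MSD:

```
simulated 200 tracks, 100-min window, 2-min frames
true      D = 0.0050 um^2/min^alpha, alpha = 0.60
recovered D = 0.0049 um^2/min^alpha, alpha = 0.61
alpha < 1 marks sub-diffusive (chromatin-like) motion; D sets its scale
```

`examples/03_two_condition_pipeline.py` runs the full
simulate → render → register → detect → link → measure pipeline for two
conditions and prints the comparison table:

```
     condition  fitted_alpha  mean_velocity_um_min  mean_cum_distance_full_um  cluster_events_per_nucleus_100min
  control-like      0.795678              0.084561                   8.689927                                4.0
knockdown-like      0.546276              0.079383                   7.938266                                0.0
```

The knockdown-like condition (lower α, merges disabled) shows lower MSD,
velocity, travelled distance and clustering rate — the reduced-mobility
phenotype this analysis is designed to resolve. The other examples cover
drift correction (`02`) and micronucleus scoring (`04`).

A thin CLI wraps the same pipeline for shell use:

```sh
focidyn end-to-end --config run.yaml --seed 1 --out results/
```

with `run.yaml` holding the simulation/analysis parameters (see
`focidyn.pipeline.load_run_config`). Exit codes: 0 success, 2 configuration
error, 3 input error.

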