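# Methods

This note records the models, conventions and numerical choices behind
`focidyn`, and what the synthetic-data validation does and does not
demonstrate about real microscopy data.

## Coordinate and unit conventions

Images are `(frame, z, row, col)` or `(frame, row, col)` arrays; rows are y,
columns are x, 0-based, with pixel centres at integer coordinates. All CSVs
state x before y, in pixels. Physical conversions go through the acquisition
geometry: `pixel_size` (default 0.11 µm/px, typical sampling for a 60×/1.49 NA
objective on a scientific CMOS camera) and `frame_interval` (default 2 min).
The default window of 51 frames × 2 min spans 100 minutes, and the 10-minute
clustering-persistence rule is then exactly 5 frame intervals. These
acquisition defaults are declared choices, not values inferred from any
particular instrument.

## Motion models

Trajectories are simulated in µm relative to each focus's start and converted
to pixels. Per axis:

* **brownian** — i.i.d. Gaussian increments of variance 2·D·Δt, so the 2D
  MSD is 4·D·Δt.
* **fbm** — fractional Brownian motion with exponent α (Hurst H = α/2),
  synthesised by multiplying white noise with the Cholesky factor of the
  exact fractional-Gaussian-noise covariance
  γ(k) = σ²/2·(|k+1|^2H − 2|k|^2H + |k−1|^2H), σ² = 2·D·Δt^α. The exact
  covariance (rather than a spectral approximation) makes small-sample tests
  exact in distribution; a 10⁻¹⁰ diagonal jitter guards the factorisation
  near α = 2, and α = 2 itself is handled as the degenerate perfectly
  correlated limit.
* **confined** — Brownian increments with the radius folded back into the
  confinement disk (repeated radial reflection), so positions never leave
  the disk and the MSD plateaus below (2R)².
* **directed** — constant drift velocity plus optional Brownian noise;
  pure drift is exactly ballistic (MSD = |v|²Δt²).

Foci start uniformly inside their nucleus disk with a minimum spacing of
4·psf_sigma (overridable via `min_spacing_px`). This spacing is a simulator
constraint that keeps detection identifiable, not a biological claim.
Positions are reflected at the field border; at realistic parameters the
border is never reached.

**Merges.** A scheduled merge pins the second track to the first from the
merge frame onward at a fixed random-direction offset of `merge_offset_px`
(default 4.2 px ≈ 0.46 µm). The offset keeps the pair inside the 0.5 µm
colocalization radius — so it counts as a clustering event — while leaving
the two foci optically separable (4.2 px ≈ 2.8·psf_sigma, above the two-point
resolution of the LoG detector). Setting it to 0 gives exact coincidence,
in which case the pair renders as a single diffraction-limited spot of
summed intensity.

## Rendering

Each focus is a pixel-integrated isotropic Gaussian (difference of error
functions per axis, evaluated on a ±6σ window) carrying its expected photon
budget; a constant expected background is added; whole-field drift
translates focus positions by the cumulative per-frame drift. Noise is
Poisson on the expected counts (switchable via `shot_noise`) followed by
additive Gaussian read noise, clipped at zero. Multi-z stacks replicate the
in-focus plane with a 0.6-per-plane attenuation — enough to exercise the
projection path, with no claim to a 3D PSF. Photophysics (blinking,
bleaching) is deliberately absent.

## Drift correction

Registration is translation-only: the rotation of a nucleus over 100 min is
not modelled and the correction targets whole-cell movement. Drift is
estimated by phase correlation with upsampled sub-pixel peak refinement,
sequentially (each frame against its predecessor, shifts accumulated)
because the foci themselves diffuse: adjacent frames remain nearly
identical, while long-baseline correlation against a distant reference
smears the peak by the accumulated independent focus motion. Direct
registration to a fixed reference is available (`mode="direct"`). Offsets
are removed by bilinear interpolation (exact for integer shifts on the
interior) with out-of-field pixels filled by the frame-border median.
All-constant frames are flagged degenerate and inherit the previous offset.

Because the estimator effectively subtracts the ensemble-mean focus
displacement, a small fraction (~1/n_foci) of true motion is removed along
with the drift; with ≥ 20 foci per cell this bias is well inside the
validation tolerances.

## Spot detection and measurement

The detector is a single-scale, scale-normalised LoG filter at the expected
focus width, the same family TrackMate uses; single-scale keeps the quality
score comparable across frames. Candidates are strict 3×3 local maxima
above the quality threshold; greedy non-maximum suppression (strongest
first, minimum separation 2σ) guarantees that lowering the threshold never
removes a previously detected spot. Sub-pixel refinement fits a parabola to
the response along each axis of the 3×3 neighbourhood (offsets clamped to
±0.5 px). Spot intensity is the background-subtracted sum of counts within
2σ, with background the median of a 2σ–4σ annulus; the measurement is
linear in the image by construction.

The quality threshold is acquisition-dependent and therefore exposed rather
than hard-coded; `calibrate_quality_threshold` picks the smallest threshold
whose blank-field false-positive rate falls below a target (default
0.1/frame) on signal-free frames carrying the acquisition's noise.

## Tracking

Consecutive frames are linked by solving the linear assignment problem on
squared Euclidean distances with an alternative (no-link) cost of
max_link_distance²; any feasible link is then preferred over leaving both
ends unlinked, and the chosen links minimise total squared displacement —
verified against brute-force enumeration on small instances. Intensity never
enters the cost. Track ends may bridge up to `max_gap` missing frames with a
distance budget growing linearly with the gap. Tracks shorter than
`min_track_length` (default 10 records) are discarded and counted. Exact
cost ties are resolved deterministically by the solver; on continuous
positions they occur with probability zero.

## Mobility statistics

* **MSD** uses all overlapping (t, t+Δt) pairs — the estimator behind
  msdanalyzer-style analyses — with the per-lag pair count kept as a weight.
  Only lags up to `max_lag_fraction` (default 0.25) of the track length are
  reported, the standard variance-control practice. The printed-formula
  scalar x is implemented as the 2D sum of squared x and y displacements,
  the standard convention for 2D tracking.
* **Ensemble MSD** per lag is the pair-count-weighted mean across curves;
  the error is the weighted SEM: weighted standard deviation divided by
  √n_eff with n_eff = (Σw)²/Σw².
* **Power-law fit**: weighted least squares of log MSD on log Δt (weights =
  pair counts); α is the slope and D = exp(intercept)/4, in µm²/min^α.
  The fit exists for parameter recovery; it requires ≥ 3 strictly positive
  lags.
* **Cumulative distance** is the path length over consecutive observed
  records; **velocity** is path length divided by elapsed time (mean speed,
  TrackMate's convention), with the net-displacement rate available behind
  a flag. In cross-condition tables the cumulative distance is additionally
  reported restricted to tracks spanning ≥ 80 % of the window
  (`mean_cum_distance_full_um`), since a path length is only comparable
  between conditions for tracks observed over comparable spans.
* **Clustering events** are built from pairwise colocalization episodes:
  maximal runs of consecutive frames in which two tracks lie within the
  colocalization radius (default 0.5 µm — the single most consequential
  free parameter, deliberately explicit in every entry point), lasting at
  least 10 min (frames counted inclusively). Episodes overlapping in time
  and sharing a member are merged transitively, so three mutually close
  foci report as one three-member event. Note the merged-event *count* is
  not monotone in the radius (a larger radius coalesces events); the set of
  participating track pairs is, and that is the invariant tested.

## Micronucleus scoring

All DAPI objects are segmented (Gaussian smooth, Otsu, hole filling).
Objects ≥ `min_nucleus_area` are main nuclei; candidates with area within
[median_main/100, median_main/9] — micronuclei are conventionally well
under a third of the nuclear diameter — lying entirely outside the main
nuclei dilated by `periphery_margin` (default 2 px) are scored.
HP1α-positivity compares the candidate's mean HP1α against the extranuclear
median + 3·MAD, strictly: a featureless channel never scores positive. The
3·MAD rule replaces the by-eye call such assays usually rely on and is
configurable.

## Pipeline

A single YAML config drives `simulate`, `analyze` or `end_to_end` runs over
named conditions; CLI flags override config keys. Every CSV artifact carries
a provenance header (version, config hash, seed) and a manifest is written
per run. With a fixed seed, simulation output is bit-identical across runs
and analysis is deterministic. Condition comparisons report means ± SEM and
two descriptive effect sizes (difference of means, rank-biserial
correlation); no significance machinery is attached.

## Validation scope and problem sizes

All validation is against the simulator's ground truth: trajectory-level
recovery uses 200 tracks of 51 frames; image-level checks use 256–512 px
fields with 20–50 foci at a peak-signal-to-noise ratio of ~5, and 20-seed
batteries for clustering and micronucleus scoring. These sizes were chosen
as the smallest at which the estimators' sampling noise is comfortably
inside the tolerances being checked.

Passing these checks shows the chain measures what it claims on data obeying
the stated models. Real acquisitions add what the simulator deliberately
omits: bleaching and blinking, nucleus deformation and rotation (only rigid
translation is corrected), out-of-focus structure and a true 3D PSF,
autofluorescent background texture, and focus appearance/disappearance from
ongoing repair. Parameter defaults — detection threshold above all —
should be re-calibrated per acquisition, e.g. with the blank-field helper.

## Degenerate inputs

Zero-nucleus or zero-focus simulations produce valid empty tables and
background-only stacks; blank frames detect no spots; empty spot lists link
to empty track sets; single-record tracks are rejected by the statistics
that need two points, with explicit errors; all-constant frames register
with a degenerate flag rather than a failure.
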