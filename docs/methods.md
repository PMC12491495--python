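# Methods

`paintbench` simulates and analyzes multiplexed DNA-PAINT experiments that
combine speed-optimized right-handed (R) docking sequences with their
left-handed (L-DNA) mirror analogs. Because L-DNA only hybridizes with
L-DNA, an R and an L sequence library can be pooled into one Exchange-PAINT
workflow with structurally zero cross-chirality crosstalk. The package
provides the quantitative machinery around that idea: a generator that
produces localization lists with the statistical structure such experiments
have, and the analysis stages that turn localization lists into kinetic and
geometric summaries.

## Binding model

Each docking site is an independent two-state (telegraph) process. With
imager concentration `c` (molar), association rate `k_on` (1/(M·s)) and
dissociation rate `k_off` (1/s):

- dark (unbound) dwell times are exponential with mean `τ_d = 1/(k_on·c)`;
- bright (bound) dwell times are exponential with mean `τ_b = 1/k_off`.

Sites start dark with a fresh exponential draw, which by memorylessness
equals the stationary residual dark time, so dark-time estimates carry no
startup transient. A site is retained at all only with probability
`labeling_efficiency`. Off-target binding of same-chirality imagers runs at
`crosstalk_rate · k_on`; opposite-chirality binding does not occur.

A structure with `n` active sites therefore shows events at rate
`≈ n·k_on·c`, which is why whole-structure dark times are converted to
single-site values as

    τ_d,norm = τ_d,raw · (c / 100 pM) · n

with 100 pM as the fixed reference concentration. For nuclear pores `n` is
not taken from clustering but from the expected 16 Nup96 copies at ~50 %
labeling, `n_eff = 8`.

## Rendering and frame discretization

Localizations are emitted per camera frame: a frame yields one localization
for a site when a bright interval overlaps at least `min_on_fraction = 0.5`
of its exposure, approximating detection thresholding without simulating
photons. Localizations are the true site position plus isotropic Gaussian
noise (`σ = localization_precision_xy`; separate `σ_z`). x/y are stored in
pixels (origin top-left, 130 nm effective pixel), z in nm, frames 0-based —
the common localization-file dialect, written as an HDF5 `locs` dataset
with a YAML sidecar or as CSV.

Two systematic effects of discretization matter for kinetics and are
deliberate properties of the model, not bugs: events shorter than half a
frame are lost entirely, and the mean measured bright time is inflated by
roughly half a frame. Both shrink as `τ_b / exposure` grows; see
"Estimator validity" below.

## Structures

- **Origami grid**: rectangular site lattice, default 4×3 at 15 nm pitch
  (the grid arrangement is a design choice; only the pitch is prescribed by
  the benchmark design). The 5-nm variant is a 1×2 grid at 5 nm.
- **Nuclear pore (Nup96)**: two coaxial rings 50 nm apart axially, ring
  diameter 107 nm (standard literature value), 8 corners per ring with two
  sites 14.3 nm apart along the ring tangent — 32 sites total. Rings are
  modeled unrotated relative to each other.
- **Filament**: sites uniform on a cylinder surface, default radius 15 nm
  (the ~30 nm effective antibody-labeled tubulin diameter), Poisson site
  count at a given linear density.

Fiducials (gold beads) emit one localization every frame at higher precision
(1 nm default). Drift is a cumulative 2D Gaussian random walk with
per-frame step `drift_step` (default 0.2 nm/frame in scenarios, ~25 nm of
wander over a 15,000-frame movie).

## Analysis stages

**Drift correction.** Fiducials are detected as localization clusters
present in ≥ 80 % of frames (binding sites are dark most of the time, so
the presence criterion separates them sharply). The per-frame mean
displacement across fiducials, smoothed by a 100-frame centered moving
average, is subtracted. Published correctors such as AIM are external prior art; fiducial
tracking is the fully specifiable equivalent here and is validated by round-trip against the injected walk (≥ 90 % variance
reduction at drift steps ≥ 2× the localization precision).

**Registration and stitching.** Tables are rendered at 65 nm bins with
bilinear (subpixel) weighting and a 1-bin Gaussian blur, then registered by
normalized cross-correlation with 3-point parabolic peak interpolation —
done in the log domain, where the parabola is exact for a Gaussian peak.
Plain histogram rendering quantizes sparse structures to bin centers and
was measured to cost ~0.2 bins of registration accuracy; bilinear rendering
brings the round-trip error below 0.05 bins. Tiles are chained exactly as
in the 2×2 protocol: top-left is the reference, the rest of its row and
column align to it, interior tiles align to the tile above; one shift per
tile is applied to all channels.

**Binding-site clustering.** Fixed-radius density clustering at the
standard single-molecule parameters (radius 6.5 nm, minimum 5
localizations, the point itself counted in its neighborhood). Clusters are seeded at local density maxima (neighbor
counts within the radius, deterministic index tie-break) and members join
the nearest seed within the radius. Seeding at maxima rather than
transitively linking core points is essential at these parameters: with a
6.5 nm radius on a 15 nm lattice, DBSCAN-style transitive linking chains
neighboring sites through their localization tails (measured: a 12-site
grid collapses to ~2 clusters), while maximum seeding resolves all sites.
A 5 nm pair still merges into one cluster — by design the 5-nm analysis
uses a two-component Gaussian-mixture center fit instead.

**Frame analysis.** A cluster is accepted only if (a) its mean frame lies
in the central 80 % of the movie and (b) no contiguous 20 %-of-the-movie
window holds more than 80 % of its localizations. The two thresholds are design
choices of this package; the defaults reject single-burst
sticking artifacts while passing stationary binding, and both are exposed
in the configuration.

**Kinetics.** Localization-bearing frames of a picked structure are linked
into events (gaps ≤ `max_gap_frames` bridged; default 1 as a tolerance for
threshold flicker, set to 0 in the scenario analyses because the simulator
produces no mid-event flicker). Bright time is the plain mean event
duration and the raw dark time the mean inter-event gap (first/last partial
gaps excluded), pooled over picks — plain mean estimators, the convention for such
measurements; an exponential-tail MLE is provided as a cross-check utility
only. Rates follow as `k_off = 1/τ_b` and `k_on = 1/(τ_d,norm · 100 pM)`.

**Metrics.** NeNA localization precision is fitted to nearest-neighbor
distances between consecutive-frame localizations with the model
`p(d) ∝ (d/2σ²)·exp(−d²/4σ²)` plus a linear background term. Site spacing
is the mean nearest-neighbor distance between accepted cluster centers.
Ring separation is a two-component 1D Gaussian mixture on pooled z values.
Filament diameter projects localizations onto the plane normal to the
principal axis, fits a circle algebraically and reports twice the mean
radial distance about the fitted center (robust to the slight inward bias
of the algebraic fit). The crosstalk matrix assigns each localization to
the nearest ground-truth site within 5σ and tabulates per-round species
fractions. FWHM resolution is `2√(2 ln 2)·σ`.

## Scenarios and problem sizes

Scenario defaults encode the benchmark conditions: 75 ms exposure, 130 nm
pixels, 576×576 px field, 100 pM imager unless stated. Kinetic rates
default to `k_on = 5×10⁸ /(M·s)`, `k_off = 2 /s` — typical speed-optimized
sequence values; the measured per-sequence numbers live in supplementary
material outside this package's inputs.

| scenario | structures | frames | precision (xy/z nm) | notes |
|---|---|---|---|---|
| origami12 | 12 species × 12 grids | 15,000 | 1.5 / 5 | labeling 0.9; 12 exchange rounds |
| origami5nm | 12 two-site pairs | 100,000 × 100 ms | 1.4 / 5 | 50 pM imager |
| npc | 120 pores | 40,000 | 2 / 10 | labeling 0.5; picks at 2 px = 260 nm |
| tubulin | 1 filament (4 µm, 50 sites/µm) | 15,000 | 2 / 2 | 25 pM imager |
| neuron13 | 13 species × 8 grids, 2×2 tiles | 7,500 | 5 / 10 | 10 µm tile overlap |

The simulated cohort sizes (120 pores, one filament, 12 five-nm
origami) are chosen so every estimate
has comfortable statistics while a full validation run completes in
minutes on one CPU. The neuron13 scenario places a few structures
deliberately inside each tile-overlap band; the cellular samples the
stitching protocol was designed for are dense everywhere, and sparse
synthetic fields need that guarantee.

## Estimator validity and the parameter-recovery grid

The pick-level mean estimators carry known biases at high duty cycle:

- frame quantization adds ≈ `exposure/2` to the mean bright time;
- sub-half-frame events are dropped, merging their flanking dark gaps
  (≈ `+exposure/(2τ_b)` relative on the dark time);
- simultaneous binding at different sites of one pick merges events
  (relative bright-time inflation ≈ `½·n·c·k_on·τ_b`).

Parameter recovery is therefore validated where the method is valid — the
low-duty-cycle regime in which such measurements are actually performed:
25–50 pM, `τ_b` 0.6–1.25 s, 4–12 sites, 40,000 frames, 300 structures per
grid point. In that regime the full pipeline (simulate → cluster → pick →
link → normalize) recovers `k_off` and `k_on` within 10 % (measured worst
case ≈ −8 %, dominated by the quantization terms above). The scenario
summaries at 100 pM additionally report kinetics for completeness; their
bright times visibly carry the merging bias, as the equivalent real
measurement would.

## What the generator does and does not emulate

Emulated: two-state kinetics with concentration scaling, per-round species
switching with chirality-orthogonal crosstalk, labeling efficiency,
localization noise in 3D, frame discretization and detection thresholding,
always-on fiducials, random-walk drift, tile overlap geometry.

Not emulated: photon statistics and PSF fitting (precision is an input,
not derived from photons), z-dependent astigmatic precision profiles,
non-specific surface sticking, fluorophore photophysics (blinking here is
purely kinetic), directed mechanical drift, sample heterogeneity in site
spacing. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the stated statistical model — not
performance on raw camera data.

## Numerical choices

- Clustering tie-breaks are by input index; permutation invariance holds
  for cluster count and centers (to noise-level tolerance), not labels.
- The NeNA histogram uses 100 bins up to the 99.5th distance percentile
  (capped at 8σ₀), initialized from the median distance.
- The Gaussian-mixture fits (ring separation, 5-nm pairs) use 3 restarts
  with a fixed random state; a ring fit is flagged degenerate when the
  separation falls below 0.1× the pooled z spread or a weight below 0.02.
- Registration falls back to the coarse layout offset with a warning when
  an overlap region holds fewer than 10 localizations or the correlation
  score is below 0.1.
- Every run is driven by one integer seed through a `SeedSequence`
  hierarchy; identical configurations produce byte-identical summaries.

## Known limitations

- Bright-time estimates at ≥ 100 pM on 12-site structures are inflated by
  event merging (tens of percent); this mirrors the underlying mean-based
  method rather than a defect of the implementation.
- The fiducial detector assumes beads drift less than a few pixels over
  the movie; larger excursions need a larger search radius.
- `z` is simulated with a constant precision; no astigmatism model.
- Sequence checks are exact string complementarity, not thermodynamics.
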