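# Methods

This note records the models, conventions and numerical choices behind
`trackforge`, in the order the pipeline applies them.

## Input model and track repair

A dataset is a set of tracks: one integer cell ID, and per timepoint a time
stamp and X/Y(/Z) centroid coordinates, all in the user's units (no unit
conversion is attempted; typical data are µm and seconds or minutes). Cell IDs
must be integers because the division heuristic in contact filtering compares
IDs arithmetically.

Repair happens in a fixed order:

1. **Multiplet averaging.** Multiple rows for one (cell, time) — usually
   over-segmentation — are replaced by their coordinate-wise arithmetic mean,
   flagged `averaged`. Averaging runs first because duplicated timepoints make
   gap detection ambiguous.
2. **Frame-interval inference.** The common Δt is the median of all positive
   within-cell consecutive time differences; the median is robust to the
   doubled/tripled differences that gaps create. All timestamps must sit on
   the global frame grid within a 1e-6 relative tolerance; off-grid data are
   rejected with a suggestion to resample, rather than silently rounded.
3. **Gap interpolation.** Missing internal frames are filled per coordinate by
   linear interpolation between the nearest observed neighbours, flagged
   `interpolated`. Linear is the minimal assumption and is exactly testable
   (deleting any interior point of a constant-velocity track is recovered to
   machine precision). No extrapolation beyond a track's first/last
   observation, and no maximum gap length — instead the interpolated fraction
   per cell is logged so heavily repaired tracks can be excluded by the user.
   No smoothing or denoising of coordinates is performed.
4. **Optional 3D→2D flattening** zeroes the Z coordinate.

Original input files are never modified; the repaired table (with provenance
flags) is written to the `Formatted_Data` sheet.

## Step metrics

Per cell and frame: instantaneous displacement, running path length, net
displacement from the track origin, velocity (displacement/Δt), acceleration
(velocity difference/Δt), and for τ = 1..τ_max the τ-lagged Euclidean distance
and unsigned relative turning angle. Conventions:

- Lagged quantities use **overlapping windows** (every frame where both
  endpoints exist), matching standard time-averaged MSD practice; lags longer
  than a track are simply absent.
- Turning angles are **unsigned, in degrees on [0, 180]**: a 3D trajectory has
  no canonical sign for a turn, so the angle between the incoming and
  outgoing τ-lagged displacement vectors is reported. It is computed as
  `atan2(|v1 × v2|, v1·v2)`, which is numerically exact at 0°, 90° and 180°
  where the arccos form loses ~1e-6 degrees to rounding.
- The **minimum displacement limit** is a per-frame rate: a leg shorter than
  `min_displacement · τ` (total motion over τ frames) marks the angle missing.
  Both legs must pass — a deliberate convention; the alternative (filtering on
  one leg) would keep angles whose other arm is pure noise. With a zero limit,
  exactly-zero legs are still treated as missing (the angle is undefined).
- Leading undefined values (first frame's displacement/velocity, first two
  frames' acceleration) are missing, never zero, so they cannot bias
  downstream means.

## Track summaries

`displacement_ratio` = final net displacement / path length and
`outreach_ratio` = maximum net displacement / path length follow the
definitions in the motility-metrics literature; both lie in [0, 1] and the
displacement ratio never exceeds the outreach ratio. The arrest coefficient
counts steps **strictly below** the minimum displacement limit (a tie counts
as motile). MSD is time-averaged per cell with overlapping windows; ensemble
curves average per-cell MSDs with **equal cell weight**, so long tracks do not
dominate. Mean/median/SD summary statistics of each step metric ignore missing
values; single-point cells are reported with all motion fields missing and are
excluded from PCA. Per-τ aggregate rows (mean/SD of lagged distance, pooled
over all cells and frames) are emitted for the whole dataset and per category.

## Contacts

A contact frame is centroid distance **strictly below** `contact_limit`
("lower than"); a non-motile cell has arrest coefficient **strictly above**
`arrest_limit` ("higher than") — ties fall on the no-contact/keep side in both
cases. Division filtering removes all events of ID-adjacent pairs permanently;
a time-limited variant (dropping only early contacts after cytokinesis) would
need a division-time estimate the data do not carry. The dead-cell filter uses
the same arrest limit for the whole dataset and the same minimum displacement
limit as the summaries. Detection is exact all-pairs/all-frames,
O(cells² × frames); datasets of hundreds of cells and hundreds of frames run
in seconds, so no spatial index is used. Raw events are kept alongside a
`kept_after_filters` flag so the filters are auditable, and events spanning
interpolated positions are flagged.

## Subset statistics

Features entering PCA are all per-cell scalars: path length, final/max
displacement, both ratios, arrest coefficient, mean/median/SD of velocity,
acceleration and turning angle, and the per-τ MSD values (a config option can
subset them). Because units are incommensurate, each column is z-scored;
zero-variance columns are dropped (uninformative, and standardization would
divide by zero) and cells with missing features are dropped, both with logged
warnings. At least two categories with ≥ 3 complete cells are required.

PCA is an exact SVD of the standardized matrix. Components are retained up to
90% cumulative explained variance by default; loadings signs are fixed so each
component's largest-magnitude loading is positive, making scores reproducible
across runs and BLAS builds. Group tests run **per retained component on the
component scores** — the simplest reading of "testing the PCA results" — with
a tie-corrected Kruskal-Wallis H and Dunn's pairwise z-tests on pooled mean
ranks,

  z = (R̄ᵢ − R̄ⱼ) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/nᵢ + 1/nⱼ)],

Bonferroni-adjusted across pairs within a component (Holm or no adjustment are
available). Categories falling below 3 cells after filtering are excluded from
testing with a warning.

## Synthetic data

The generators emulate regular-interval centroid tracks under known motion
models, chosen to make every pipeline guarantee checkable against a closed
form or an independent oracle:

- **ballistic** — fixed random unit direction, constant speed (default
  2 length-units/frame): MSD(τ) = (vτΔt)², ratios 1, turning angles 0.
- **brownian** — i.i.d. Gaussian increments with per-coordinate SD `step_sd`
  (default 1): ensemble MSD(τ) = dims·step_sd²·τ, log-log slope 1.
- **arrested** — Gaussian jitter (default SD 0.01) about a fixed anchor; with
  a minimum displacement limit ≥ 5 SD the arrest coefficient is ~1.
- **persistent** — a persistent random walk (heading perturbed by ~15-20° of
  angular noise per frame), used as the "ballistic-like" class when a PCA
  power test needs two genuinely separable yet stochastic populations.
- **scenarios** script cells with deleted frames (interior only), duplicated
  frames, ID-adjacent division pairs, and approach/contact/retreat pairs whose
  true contact window is known exactly; the generator returns the ground truth
  alongside the CSV-dialect table.

All generators take a mandatory seed and never touch global random state.

What this synthetic world omits about real data: localization noise on
otherwise smooth motion, drift, track fragmentation across different IDs,
variable frame intervals, cell death mid-track, and crowding effects on
contacts. Passing tests therefore demonstrate that the computations are
correct on their mathematical domain, not that any biological inference from
real microscopy is valid — upstream segmentation/tracking quality remains the
user's responsibility.

## Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| `tau_max` | 10 | frame intervals | resolves MSD curvature without outrunning typical 20–100-frame tracks |
| `min_displacement` | 0 | length | no filtering unless the user states their noise floor |
| `contact_limit` | 12 | length | about one cell diameter for ~10 µm cells in µm-scaled data |
| `arrest_limit` | 0.95 | fraction | flags only near-immobile cells as dead |
| `pca_variance_threshold` | 0.90 | fraction | conventional retention level |

These are implementation defaults, logged at every run; any serious analysis
should set them from the experiment's optics and cell type.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: 500 tracks × 100 steps
for random-walk MSD scaling, 2000 null replicates for the type-I error of the
rank-test stage, 50 random small datasets (≤ 15 cells × ≤ 30 frames) for the
brute-force contact oracle, and 200 replicates of a 50+50-cell mixed
ballistic-like/Brownian dataset for end-to-end separation power. These sizes
give sampling errors comfortably below the asserted tolerances (e.g. the
type-I rate over 2000 draws has SE ≈ 0.005 against a ±0.02 band).

## Known limitations

- Tracklets with different IDs are never re-linked; repair assumes the
  tracker's identities are correct.
- The division heuristic (|ΔID| = 1) depends on the upstream tracker's ID
  assignment and may need manual re-IDing of daughter cells.
- Linear interpolation of long gaps underestimates path length for diffusive
  motion; inspect the logged interpolated fractions.
- No MSD model fitting (anomalous exponent, confinement radius) beyond the
  log-log slope used in validation; the MSD curves themselves are reported.
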