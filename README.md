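# trackforge

Post-tracking analysis of 2D/3D cell migration data.

Time-lapse microscopy pipelines (Imaris, TrackMate, CellProfiler, …) end with a
table of cell centroids over time. `trackforge` takes exactly that — a CSV with
a cell ID, time, and X/Y(/Z) coordinates per row — and turns it into motility
statistics a cell biologist can interpret and compare across annotated cell
subsets (e.g. infected vs uninfected cells). It is aimed at researchers who
track cells with any upstream software and want standardized, auditable
downstream numbers.

## What it computes

For a track r(t) sampled at a regular frame interval Δt:

- **Step metrics** per timepoint: instantaneous displacement
  dᵢ = |r(tᵢ) − r(tᵢ₋₁)|, cumulative path length, net displacement from the
  origin, velocity dᵢ/Δt, acceleration, and for each time lag τ = 1..τ_max the
  lagged Euclidean distance |r(t) − r(t−τΔt)| and the unsigned relative turning
  angle between successive τ-lagged displacement vectors (degrees, [0, 180]).
  Angles whose legs moved less than `min_displacement · τ` are treated as
  sub-resolution jitter and omitted.
- **Track summaries** per cell: path length L, final/maximum net displacement,
  displacement ratio (final/L), outreach ratio (max/L), arrest coefficient
  (fraction of steps with dᵢ < `min_displacement`), velocity/acceleration/angle
  statistics, and the time-averaged mean squared displacement
  MSD(τ) = ⟨|r(t+τΔt) − r(t)|²⟩ₜ. For a ballistic track MSD(τ) = (vτΔt)²; for
  an unbiased random walk MSD(τ) = 2dDτΔt (slope 1 in log-log coordinates).
- **Track repair** before any of the above: multiply-tracked timepoints are
  averaged into one centroid, missing internal frames are filled by linear
  interpolation on the frame grid, and 3D data can be flattened to 2D. Repaired
  points carry provenance flags; input files are never modified.
- **Cell-cell contacts** (optional): a contact is a frame where two cells'
  centroid distance is strictly below `contact_limit`; maximal runs of such
  frames form contact events. Events between cells whose integer IDs differ by
  exactly one are dropped as division (daughter-cell) artifacts, and events
  touching cells with arrest coefficient above `arrest_limit` are dropped as
  non-motile/dead. Per-cell contact histories report count, total time in
  contact, and median contact duration.
- **Subset comparison** (optional, needs a categories CSV): per-cell features
  are z-scored and decomposed by PCA; on each retained component (90%
  cumulative variance by default) the categories are compared with a
  Kruskal-Wallis rank test and Dunn's pairwise post-hoc z-tests with Bonferroni
  adjustment.

Results go to a multi-sheet XLSX workbook (plus a separate PCA workbook), or to
per-sheet CSVs for headless pipelines.

## Worked example

```python
import trackforge as tf

# 5 straight movers at 2 µm/frame plus 5 random walkers, 1-frame interval
straight = tf.make_ballistic(5, 20, speed=2.0, seed=1)
cfg = tf.RunConfig(tau_max=5, min_displacement=0.5)
res = tf.analyze(straight, cfg)
print(res.summaries[["cell_id", "path_length", "displacement_ratio",
                     "arrest_coefficient", "msd_3"]].head(3))
```

prints

```
   cell_id  path_length  displacement_ratio  arrest_coefficient  msd_3
0        1         40.0                 1.0                 0.0   36.0
1        2         40.0                 1.0                 0.0   36.0
2        3         40.0                 1.0                 0.0   36.0
```

Each cell walked 20 steps of 2 µm (path length 40), perfectly straight
(displacement ratio 1), never paused (arrest coefficient 0), and its
MSD at lag 3 is (2·3)² = 36 µm² — the ballistic closed form.

From the shell, the same pipeline over files:

```bash
trackforge run --tracks tracks.csv --categories cats.csv \
    --tau-max 10 --min-displacement 1.0 --contacts --contact-limit 12 --pca \
    --out results/run1 --csv
trackforge simulate --scenario scenario.yaml --seed 7 --out sim
```

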