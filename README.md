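# filodyn

Quantitative analysis of signalling filopodium (cytoneme) dynamics from
manually tracked base/tip coordinates, plus wing-disc protrusion-length and
morphogen-gradient quantification.

The pipeline:

1. **Track I/O** (`filodyn.track_io`) — reads MTrackJ data files (per
   filopodium cluster: track #1 = base, track #2 = tip) or a flat CSV dialect
   (`filopodium_id,role,frame,x_um,y_um,group_label`), applies spatial
   calibration and a recording-window rule, and pairs base/tip frames.
2. **Dynamics** (`filodyn.dynamics`) — per frame, the filopodium extent is
   the Euclidean base→tip distance.  Each extent series is fitted with two
   piecewise-linear kinetic models: a two-phase **triangle**
   (elongation/retraction; feet one frame outside the observations at zero
   extent, apex at the maximum extent) and a three-phase **trapezoid**
   (elongation/stationary/retraction; stationary segment anchored at the
   extent at half lifetime).  The better-fitting model (RMSE, with a
   parsimony margin and ties going to the triangle) labels the filopodium,
   and Emax, lifetime, Ve (elongation velocity) and Vr (retraction velocity)
   are extracted.  Filopodia touching the window start/end contribute no
   Ve/Vr (the phase was not observed).
3. **Cohort statistics** (`filodyn.stats`) — per-variable descriptive stats,
   Shapiro–Wilk normality, two-sided Mann–Whitney–Wilcoxon comparison (exact
   for small tie-free samples, tie/continuity-corrected normal approximation
   otherwise), significance stars (`*` p<0.05 … `****` p<1e-4), and
   triangle/trapezoid type proportions.
4. **Gradient quantification** (`filodyn.gradient`) — mean of the ten
   longest protrusions per disc, and expression-domain width from 1-D
   intensity profiles (fractional threshold between distal background and
   peak, sub-sample interpolation at the crossing).
5. **Synthetic cohorts** (`filodyn.synthetic`) — ground-truth track and
   intensity-profile generators used throughout the test suite; noiseless
   grid-aligned cohorts are recovered exactly by the fitting stage.

## CLI

```sh
# analyze tracked cohorts (CSV dialect or MTrackJ .mdf)
filodyn analyze --tracks groupA.csv --tracks groupB.csv --format csv \
    --interval-min 2 --window-min 30 --group A --compare B --out results/

# generate a synthetic cohort with ground truth (and check label recovery)
filodyn simulate --n 200 --p-trapezoid 0.5 --noise 0 --seed 1 \
    --no-truncation --self-check --out sim/

# protrusion lengths and gradient widths
filodyn gradient --lengths lengths.csv --profiles profiles.csv \
    --k 10 --threshold 0.5 --out gradients/
```

`analyze` writes `summaries.csv` (per filopodium: Emax_um, lifetime_min,
model_label, Ve_um_per_min, Vr_um_per_min, phase flags, per-model RMSE),
`comparisons.csv` (per variable: n/mean/median per group, Shapiro–Wilk p,
Mann–Whitney U and p, stars) and `type_proportions.csv`.  Counts of
accepted / rejected / phase-excluded filopodia are logged to stderr.
Outputs are deterministic: identical inputs, seeds and configs produce
byte-identical CSV files.

## Notes and assumptions

- Frames are 1-based as stored; time is `(frame − 1) × frame_interval`
  minutes, velocities are µm/min.  Analysis is 2-D (z and channel fields of
  MTrackJ records are ignored).
- The stationary segment of the trapezoid passes through
  (half-lifetime, Es) with slope Vs = mean of frame-to-frame velocities
  among stationary points; Es is linearly interpolated when the
  half-lifetime falls between frames.
- The gradient-width procedure is a threshold-crossing re-implementation
  (the original length-calling protocol is not reproducible from available
  sources); the threshold fraction is configurable, default 0.5.
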