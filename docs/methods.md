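# Methods

`placecode` analyzes one-dimensional calcium-imaging sessions — a df/F
matrix (cells x samples) aligned to tracked pose — for spatial and speed
coding, within-session remapping, population coactivity, and cross-day
stability. Because such studies rarely deposit raw recordings, the package
ships a synthetic generator that produces sessions with known per-cell
ground truth; every analysis is validated as a recovery or calibration
experiment against that ground truth.

## Timebase and behavior

Neural data live on a 7.5 Hz timebase (30 fps video temporally downsampled
by four). Higher-rate pose tables are block-averaged onto the neural
timebase at load; a non-integer rate ratio is an alignment error. Pose and
speed are smoothed with a centered moving average over 0.5 s. At 7.5 Hz
that is 3.75 samples, rounded to a 4-sample (~0.533 s) window with edge
truncation; for even windows the center is taken as `w//2` samples back.
Speed at sample *t* is the Euclidean step from *t−1* times the sample rate
(first sample copies the second), smoothed with the same window.

The *mapping point* is the tailbase. Movement epochs require **both** nose
and tailbase speed strictly above 3 cm/s; samples inside a session's
`removed_interval` (the excised manipulation junction) are excluded from
every statistic. The strict inequality at the threshold is a deliberate
reading of "exceeded"; ties are excluded.

## Activity maps and place coding

Maps are mean df/F per 3.5 x 3.5 cm bin over movement-masked samples
(occupancy normalization), optionally smoothed with a 5x5-bin Gaussian
kernel (sd 0.85 bins ≈ 2.98 cm) renormalized at edges over occupied bins.
The unsmoothed map satisfies an exact conservation identity — sum(map x
occupancy) equals the summed masked df/F — which the suite checks to 1e-9
relative.

Spatial information is the mutual information between binned position
(3.5 cm bins along the track length; position is 1-D even though maps are
2-D) and binned df/F, in bits:

    I(X;Y) = Σ_x Σ_y p(x,y) log2[ p(x,y) / (p(x) p(y)) ]

df/F bin count follows Sturges' rule, ceil(1 + log2 n), with n the number
of movement-masked samples; bin edges span the masked min–max and the top
edge closes into the last bin. Zero-probability cells contribute nothing.

A cell is a **place cell** when its MI exceeds the 95th percentile of a
deterministic null: the full trace is circularly shifted by k·T/100 samples
(k = 1..100), the movement mask re-applied, and MI recomputed. Shifts
congruent to zero modulo T reproduce the observed value and are dropped,
leaving 99 informative null values. Thresholds are order-statistic
percentiles (`numpy method='higher'`), which makes the nominal tail rate
exactly 5% under exchangeability — the suite verifies the realized
false-positive rate on white-noise populations against a binomial 95% CI.

**Place fields** are 4-connected components of smoothed-map bins exceeding
the occupied-bin mean by 1.5 SD. Field size is bin area times bin count
(12.25 cm² per bin); width is the x-extent from first to last column
spanned; the field center is the x of its maximum bin, and the primary
field is the one with the highest peak. Centers are therefore quantized to
bin centers — recovery is assessed to within one bin (3.5 cm).

## Speed coding

Position is regressed out first: a Gaussian-family, identity-link model of
df/F on one-hot position bins (equivalently, subtracting per-bin means), so
arbitrary unimodal place tuning cannot leak into speed tuning; a single
linear-in-x term could not do this. The speed statistic is the Spearman
correlation of the residual trace with tailbase speed over all kept
samples. The null circularly shifts the speed vector by the same k·T/100
increments (identity dropped); cells above the 95th / below the 5th
order-statistic percentile are speed-positive / speed-negative. The
two-tailed null misclassification rate is calibrated at 10%.

**Decoding** predicts instantaneous speed at the sample rate from the
position-regressed population. Samples are split into alternating 60 s
blocks separated by 10 s guards; odd blocks train an ordinary
least-squares linear model (ridge jitter only on singular fits), even
blocks are scored by the Spearman correlation of actual vs predicted
speed. The statistic averages 100 random cell subsets of fixed size; the
chance threshold repeats the identical block/regression/subsampling
pipeline on circularly shifted speed, drawing one seeded subset per
permutation (the permutation loop, not a nested permutation-by-subset
grid, carries the null). Decoding uses all kept samples rather than only
movement-masked ones — masking would fragment the 60 s block structure.
Session-level exclusion flags path lengths 1 SD below the cohort mean.

## Remapping

2-D maps are flattened by the column-wise maximum over occupied bins (a
3 x 20 map becomes a length-20 profile; empty columns are missing values
excluded pairwise). Profiles from halves of unequal track length are
compared after linear interpolation of the second profile onto the first's
relative positions; correlation is Spearman. The chance level circularly
shuffles all second-half profiles 1000 times with a shared per-iteration
offset (preserving across-cell structure; independent offsets are a config
option) and takes the 95th percentile of the pooled null.

Rotation analysis divides the track into thirds. Cells that are place
cells in half 1 with a middle-third primary center are excluded; cells not
independently place cells in half 2 are "lost"; otherwise the half-2
primary center decides rotate (opposite outer third) vs non-rotate (same
outer third). Fractions are reported over all half-1 outer-third place
cells, so "lost" cells deflate both named fractions rather than being
silently dropped. Width change is primary-field width (half 2 minus half
1, each on its own bin grid) for cells independently classified as place
cells in both halves.

## Population events

Per-cell binary events come from a documented deconvolution stand-in:
samples where the positive first difference of the trace exceeds 3x a
robust scale (1.4826 x MAD) of the differenced trace, adjacent
supra-threshold samples merged onto the onset. Population events are
samples where the coactive-cell count reaches mean + 4 SD of the
session's coactivity series; contiguous supra-threshold samples merge into
one event (the merged count is primary; the raw supra-threshold sample
count is also reported). Event speed profiles report the mean speed within
each event and the cumulative percentage of events below each 1 cm/s step.

## Cross-day matching

Footprint fields are aligned by the integer rigid translation maximizing
the cross-correlation of summed footprint images (rotation/scaling out of
scope). Footprints are binarized at half their peak weight and matched
greedily by descending intersection-over-union, one-to-one, accepting
pairs with IoU ≥ 0.3 and centroid distance ≤ 8 px. This deterministic
matcher replaces probabilistic cluster-based coregistration; it is
adequate for the generator's footprints and fully testable. The
coregistered fraction uses the mean of the two sessions' cell counts as
denominator. Coregistration is validated by the across-day Spearman
correlation of mean peak amplitude (and peak-to-noise ratio) against a
pair-shuffled chance level; across-day stability reports flattened-map
correlations for day-i place cells, plus population-level correlations of
MI and of speed-r across matched cells.

## Peak statistics

Peaks are local maxima with prominence ≥ 2 x trace SD, widths at half
prominence (a deterministic stand-in for an unparameterized local-maxima
routine; sensitivity to the factor is the main caveat). Peak-to-noise
ratio is mean peak amplitude over 1.4826 x MAD of the trace with peak
windows removed — a robust definition chosen because no formula is
standard.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
calcium biophysics:

- **Trajectory**: bout-structured 1-D walk (run bouts 1.5–6 s at 5–25
  cm/s, pauses 0.5–2.5 s below 1.5 cm/s, reflective walls, slow y
  wander). Defaults give ~75% of samples above 3 cm/s and ≥ 90% bin
  coverage. Nose/ear points ride ahead of the tailbase along the heading.
- **Archetypes**: CAMK2A-like cells fire Bernoulli events at 0.11 /s with
  0.9 s single-exponential decay; VGAT-like at 0.17 /s with 1.4 s decay.
  These render detected peak widths of ~0.75 s vs ~1.05 s and preserve the
  rate and width *ordering* between the cell classes under the 2-SD
  prominence rule; longer VGAT decays would merge transients and invert
  the detected-rate ordering, so exact width matching was traded for the
  ordering, which is what the analyses compare.
- **Tuning**: place cells gain a 1-D Gaussian rate profile (sigma =
  width/4, peak 0.8 /s over 0.02 /s off-field); speed cells a linear rate
  gain of ±0.10 per cm/s around 8 cm/s, clipped at zero (slope chosen to
  give tuned-cell Spearman r in the 0.1–0.2 range typical of CA1 speed
  cells; no quantitative tuning shape is established, so linear is a
  documented choice). Events are Bernoulli per sample at rate·dt,
  convolved with the transient kernel, plus Gaussian noise (sd 0.06);
  amplitudes are lognormal per cell with per-event jitter. Every trace is
  exactly bookkept by its latent event raster.
- **Manipulations**: rotation mirrors field centers along x (a 180° turn
  of a linear track); rescaling multiplies centers and widths by the
  length ratio (`scale_with_track`) or leaves them (`fixed`); per-cell
  remap labels (rotate/stable/random) are assigned in exact configured
  proportions. Halves are stitched with an excised 20 s junction.
- **Multiday**: cells survive with probability `p_survive` (Bernoulli);
  survivors keep identity and speed tuning, jitter their footprint center
  within the configured radius, and persist log-amplitude with correlation
  `amplitude_persistence`; place tuning is kept or redrawn per
  `p_keep_place_tuning`. Replacement cells are placed with a minimum
  separation from *all* previous centers — a newcomer at a dead cell's
  location would make identity unrecoverable by any footprint matcher, so
  the generator keeps identity well-posed by construction.
- **Population events**: synchronous frames are injected at sampled low-
  or high-speed samples (≥ 3 samples apart) for a configured participant
  fraction.

What the generator does **not** emulate: 2-D place fields, theta phase,
bursting/refractory structure, correlated noise across cells, slow drift,
non-rigid footprint deformation, or overlapping cells. Passing recovery
tests therefore certify the estimators and the pipeline logic, not
performance on real recordings with those complications.

## Numerical conventions

Coordinates are cm with x along the track from the left wall; samples are
0-based with half-open intervals. All randomness flows from seeded
`numpy` generators; analyses are deterministic given the config seed
(the classification nulls use fixed shifts and contain no randomness at
all), and pipeline outputs are byte-identical across reruns with the same
seed. Degenerate inputs (flat traces, constant position, empty masks,
zero-variance coactivity) return flagged results or raise with the
offending component named.

## Problem sizes

Validation experiments use 600–1200 s sessions at 7.5 Hz: calibration runs
200 untuned cells x 20 seeds; rotation recovery 150 place cells per
session at p_rotate ∈ {0.2, 0.5, 0.8}; rescaling 40 place cells x 20
seeds per condition; decoding 32-cell populations over 20 seeds;
matching 100–200 cells per day. These sizes are the package's reference
conditions; all are arguments to the functions in
`placecode.validation`.
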