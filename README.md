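# placecode

Analyses of hippocampal CA1 population coding from 1-D calcium-imaging
sessions: place-cell classification by spatial mutual information with a
circular-shift permutation null, place-field geometry, rotation and
rescaling remapping, speed-cell classification and population speed
decoding, synchronous population-event detection, and cross-day cell
matching with stability metrics. A synthetic-data generator with per-cell
ground truth drives validation, so every estimator is tested as a
calibration or recovery experiment.

The package is aimed at systems-neuroscience analysts who have df/F traces
(e.g. CNMF-E output), tracked pose, and per-cell spatial footprints, and
want the standard linear-track battery with explicit, testable conventions.

## The core statistics

**Place coding.** For each cell, the spatial information between binned
track position X (3.5 cm bins) and binned df/F Y (Sturges' rule,
ceil(1 + log2 n) bins) over movement-masked samples (nose *and* tailbase
speed > 3 cm/s):

    I(X;Y) = Σ_x Σ_y p(x,y) log2[ p(x,y) / (p(x) p(y)) ]   [bits]

A cell is a place cell when I exceeds the 95th percentile of the null
obtained by circularly shifting the trace by k·T/100 samples (k = 1..100,
identity shifts dropped). Place fields are 4-connected components of
smoothed activity-map bins above mean + 1.5 SD.

**Speed coding.** After regressing df/F on one-hot position bins, the
Spearman correlation of the residual with speed is compared against the
same style of circular-shift null (two-tailed). Population decoding fits a
linear model on alternating 60 s blocks (10 s guards) and reports held-out
Spearman r over 100 random cell subsets, against a permutation chance
level.

**Remapping.** Activity maps are flattened by column-max, correlated
across session halves (Spearman; rescaled halves are resampled to matched
relative positions), with a 1000-iteration circular-shuffle chance level;
rotation is scored by place-field centers moving between outer thirds of
the track.

**Cross-day stability.** Cells are matched across days by footprint
intersection-over-union (greedy one-to-one after rigid alignment), and
stability is quantified by across-day correlations of mean peak amplitude,
flattened maps, spatial information, and speed tuning.

## Worked example

```python
import numpy as np
from placecode import (
    AnalysisConfig, SimulationConfig, classify_place_cells,
    classify_speed_cells, render_session, simulate_population,
    simulate_trajectory,
)

cfg = SimulationConfig(duration_s=600.0, n_cells=40, rng_seed=11)
gt = simulate_population(cfg, seed=11)          # 20 place cells by default
traj = simulate_trajectory(cfg, seed=12)
session = render_session(gt, traj, cfg, seed=13).session

place = classify_place_cells(session)
speed = classify_speed_cells(session)
detected = [r.is_place_cell for r in place]
print(f"place cells detected: {sum(detected)}/{gt.is_place.sum()} true")
print(f"sensitivity on true place cells: "
      f"{np.mean([detected[i] for i in np.flatnonzero(gt.is_place)]):.2f}")
first = next(i for i in np.flatnonzero(gt.is_place) if place[i].fields)
print(f"cell {first}: MI={place[first].mi:.3f} bits, "
      f"field center {place[first].fields[0].center_cm:.1f} cm "
      f"(true {gt.field_center_cm[first]:.1f} cm)")
```

Output:

```
place cells detected: 24/20 true
sensitivity on true place cells: 1.00
cell 0: MI=0.142 bits, field center 61.2 cm (true 60.3 cm)
```

All 20 true place cells are recovered, and the detected field center lands
within one 3.5 cm bin of the generative center. Four additional cells also
pass: this session mixes in speed-tuned cells, and speed covaries with
position along a bounded track, so some speed cells carry real spatial
information — on purely untuned populations the classifier's
false-positive rate is calibrated at 5% (see the test suite).

A command-line interface wraps the same machinery:

```bash
placecode simulate --scenario rotate --kind rotate180 --seed 3 --out demo/
placecode run --session demo/session.h5 --out demo/results/
placecode decode-speed --session demo/session.h5 --n-subsample 32
```

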