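# pupilperim

Analysis pipeline for **chromatic pupilloperimetry**: classifying subjects
at elevated Alzheimer's-disease risk (a positive parental family history,
FH+) from the kinetics of their pupil light reflex (PLR) to small chromatic
light stimuli presented across the visual field.

The package is aimed at pupillometry and biostatistics researchers who want
to reproduce, stress-test or extend this class of analysis. Because the
underlying clinical recordings are not publicly deposited, the package
ships a first-class synthetic-cohort generator with known ground truth, so
every stage — waveform simulation, kinetic-parameter extraction, boosted
classification, bootstrap inference, focal group comparison — can be
validated end to end.

## What it computes

* **Stimulus protocol & geometry** — the four chromatic conditions
  (dim red 624 nm / dim blue 485 nm probing cone/rod pathways over a
  54-target 24-2 grid; bright red/blue 6000 cd/m² probing the
  melanopsin-mediated sustained response at 4 targets), with mirrored
  left/right-eye grids.
* **Synthetic cohorts** — 125 FH+ / 61 FH− subjects by default, with a
  shorter FH+ contraction latency (0.450 s vs 0.477 s) injected at the two
  peripheral temporal-field targets, plus measurement noise, blinks with
  the 2.5 s retest rule, and 0.76% whole-response missingness.
* **17 PLR kinetic parameters** per response: amplitude (AC), percent
  contraction (PPC), response latency (PRL), latency of maximal
  contraction (LMP), the velocity/acceleration/deceleration extrema of the
  contraction arm (MCV, MCA, MCD) and redilation arm (MRV, MRA, MRD) with
  their latencies, and percent recovery (PRP). Velocity and acceleration
  come from Savitzky–Golay local-polynomial fits; PRL is localised by a
  change-point fit on the raw trace.
* **One classifier per feature table** — discrete AdaBoost over threshold
  stumps on each subjects × targets matrix (17 parameters × 4 conditions ×
  2 eyes = 136 models), after mean imputation and min–max scaling.
* **Stratified out-of-bag bootstrap** — per replicate: stratified
  resampling with replacement, in-bag training, out-of-bag AUC-ROC
  (Mann–Whitney form); B = 2000 by default; reported as mean ± SD with
  a 2.5/97.5 percentile CI, plus the replicate-averaged per-target
  weight map.
* **Focal analysis** — selection of targets above a weight threshold,
  then unadjusted (pooled t-test) and age-adjusted (GLM value ~ group +
  age) group comparisons of the focal parameter with Bonferroni
  correction.

See `docs/methods.md` for the full model descriptions, defaults and
limitations.

## Worked example

```python
import numpy as np
import pupilperim as pp
from pupilperim.tables import build_tables
from pupilperim.bootstrap import bootstrap_auc
from pupilperim.focal import focal_comparison

# simulate the default effect cohort, dim blue light, right eye
cfg = pp.CohortConfig(conditions=(pp.Condition.dim_blue,),
                      eyes=(pp.Eye.right,), seed=11)
cohort = pp.simulate_cohort(cfg)
features = pp.extract_features(cohort.traces)
table = next(t for t in build_tables(features, cohort.subjects)
             if t.key == "PRL|dim_blue|right")

res = bootstrap_auc(table, B=200, rounds=50, seed=5)
print(f"AUC-ROC {res.auc_mean:.3f} +/- {res.auc_sd:.3f}, "
      f"95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]")
top2 = np.argsort(res.mean_weight_map)[-2:] + 1
print("highest-weight targets:", sorted(top2))

focal = focal_comparison(table.matrix, table.labels, table.ages,
                         res.mean_weight_map, eye="right", threshold=0.08)
u = focal.unadjusted
print(f"FH+ PRL {u.fh_pos.mean:.3f} s vs FH- {u.fh_neg.mean:.3f} s, "
      f"corrected p = {focal.p_unadjusted_corrected:.2g}")
```

Output:

```
AUC-ROC 0.886 +/- 0.031, 95% CI [0.815, 0.940]
highest-weight targets: [np.int64(27), np.int64(36)]
FH+ PRL 0.452 s vs FH- 0.483 s, corrected p = 7e-31
```

The out-of-bag AUC of the dim-blue pupil-response-latency model is far
above chance; the averaged weight map singles out targets 27 and 36 — the
two peripheral temporal-field targets where the latency effect was
injected — and the focal comparison recovers the configured ~27 ms shorter
FH+ latency there. (The tiny p-value reflects the generator's idealised
noise model, not clinical effect sizes; see `docs/methods.md`.)

The same stages are available from a shell:

```bash
pupilperim simulate --seed 11 --out cohort/
pupilperim extract --traces cohort/traces.csv --out features.tsv
pupilperim evaluate --features features.tsv --subjects cohort/subjects.tsv \
    --replicates 200 --seed 5 --out results.json
pupilperim focal --results results.json --features features.tsv \
    --subjects cohort/subjects.tsv --threshold 0.08 --out focal.json
pupilperim run --seed 7 --out outdir/      # full 136-model pipeline
pupilperim report --results results.json --out plots/
```

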