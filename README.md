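# lipidsens

Machine-learned electrospray ionization (ESI) sensitivity prediction for
semiquantitative LC-MS lipidomics.

## The problem

Nontargeted lipidomics measures peak areas, not concentrations: every lipid
ionizes with a different efficiency, so areas are only comparable within one
analyte and one batch. Targeted quantitation fixes this with matched
isotope-labeled standards, but those exist for only a handful of lipids.
`lipidsens` takes the middle road: it learns each lipid's *relative
ionization sensitivity* from its chemical structure and uses the prediction
as a virtual calibration factor, so that concentrations can be estimated for
lipids that have no standard at all — at moderate ("semiquantitative")
accuracy, which is what cross-batch data harmonization and biomarker
screening in stem-cell and other cell-biology studies actually need.

## The method

For each lipid standard in a spiked calibration series, the sensitivity *m*
is the slope of `area = m·conc + b` (ordinary least squares; series with
R² < 0.8 or non-positive slope are excluded; the top calibrant level is
dropped by default as it commonly leaves the linear range). Slopes are
divided by the slope of a mode-specific reference internal standard
(cholesterol-d7 in positive mode, monoacylglycerol-d7 in negative mode),
giving the unitless relative sensitivity

    m_R = m / m_ref,

which is invariant to instrument gain. A support vector regression learns
m_R from ~340 cleaned 2D molecular descriptors (RDKit's set plus native
ATS/MATS/GATS topological autocorrelations), with a Box-Cox transform of the
target, per-iteration recursive feature elimination, and 5-fold
cross-validated hyperparameters. Because panels are small, the whole
procedure is repeated over many random 80:20 splits (1,101 by default) and
the iteration with the median held-out absolute error in m_R becomes the
final model. Concentrations then follow from

    c = (y − b) · c_ref / ((A_ref − b_ref) · m_R)

where y is the analyte's area, b its blank level, and A_ref, b_ref, c_ref
the reference standard's area, blank and known spiked concentration in the
same sample. Classical surrogate calibration (one-point response factor from
the most similar same-class standard; pooled class calibration curves) is
implemented as a baseline, and a synthetic-data module generates chemically
valid lipid panels and response tables so the whole pipeline is testable
without an instrument.

## Worked example

```python
import lipidsens as ls
from lipidsens.pipeline import run_internal_validation

run = run_internal_validation(ls.SimulationConfig(seed=2), mode="positive",
                              n_iterations=51, model_seed=2)
model = run.ensemble.selected
print(f"held-out MdAPE (m_R): {model.test_mdape:.1f}%")
print(f"R2 predicted vs measured m_R (held-out): {run.r2_internal_mR:.3f}")
rep = run.report
print(f"concentration error, global mean: {rep.global_mean_error:.1f}%")
print(f"  without outliers ({len(rep.outlier_ids)} flagged): "
      f"{rep.global_mean_error_outliers_removed:.1f}%")
print(f"precision (mean CV over 5 replicates): {rep.precision:.1f}%")
```

prints

```
held-out MdAPE (m_R): 13.7%
R2 predicted vs measured m_R (held-out): 0.795
concentration error, global mean: 18.9%
  without outliers (1 flagged): 13.6%
precision (mean CV over 5 replicates): 7.1%
```

This simulates a 69-lipid two-mode study (six-level calibrant ladder with a
50-fold concentration span, 5 % multiplicative area noise), calibrates the
38 positive-mode lipids, trains a 51-iteration ensemble on the included
ones, and quantifies the selected model's eight held-out lipids in five
replicate samples — purely from their predicted sensitivities. The ~19 %
mean concentration error with ~7 % precision is the semiquantitative regime
the method targets: too coarse for strict targeted assays, sufficient for
comparing lipid markers across batches.

The same workflow is available from the shell:

```bash
lipidsens simulate --seed 2 --out-prefix sim_
lipidsens calibrate --panel sim_panel.csv --responses sim_responses.csv \
    --samples sim_samples.csv --mode positive --out calibration.csv
lipidsens train     --panel sim_panel.csv --responses sim_responses.csv \
    --samples sim_samples.csv --mode positive --iterations 51 --seed 2 \
    --out model.bundle
lipidsens quantify  --panel sim_panel.csv --responses sim_responses.csv \
    --samples sim_samples.csv --mode positive --model model.bundle \
    --out quant.csv
lipidsens report    --quant quant.csv --out summary.csv
```

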