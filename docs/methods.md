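# Methods

## Problem and model

Electrospray ionization (ESI) response differs between lipids by orders of
magnitude, so LC-MS peak areas are not comparable across analytes and a peak
area alone cannot be converted to a concentration without an analyte-specific
calibration. `lipidsens` implements a semiquantitative alternative: learn
each lipid's *relative ionization sensitivity* from its structure, then use
the predicted sensitivity as a virtual calibration factor.

The chain of definitions:

* **Sensitivity** m — the slope of the ordinary-least-squares line
  `area = m · concentration + intercept` over a spiked calibration series.
  Fits use an intercept (not forced through the origin): residual background
  is absorbed there, while explicit blank handling happens at quantitation.
* **Relative sensitivity** m_R = m / m(reference), where the reference is a
  mode-specific spiked internal standard (cholesterol-d7 in positive mode,
  a deuterated monoacylglycerol in negative mode). Relativization cancels
  instrument gain: multiplying every area by a constant leaves m_R unchanged
  (tested to 1e-12).
* **Quantitation** — for an analyte with peak area y, blank-level area b and
  (predicted) relative sensitivity m_R, in a sample where the reference
  standard has area A_ref, blank b_ref and known spiked concentration c_ref:

      c = (y − b) · c_ref / ((A_ref − b_ref) · m_R)

  This inverts the linear response model exactly (noise-free roundtrip
  tested to 1e-9 relative) and is invariant to per-sample gain. Negative
  estimates (blank exceeding signal) are floored at zero and flagged. The
  blank b is the mean area over the batch's blank samples.

## Calibration filters

* Series with fewer than 3 usable points are excluded (`excluded_missing`).
* The top calibration level is dropped globally by default (`drop_top`),
  because the highest calibrant commonly exits the linear response regime;
  policies `drop_none` and `drop_top(k)` are available. A policy leaving
  fewer than 3 levels is an error.
* Lipids with R² < 0.8 are excluded (`excluded_linearity`); non-positive
  slopes are excluded as well, since the Box-Cox step downstream requires
  strictly positive targets.
* The reference standard must survive these filters; otherwise the whole
  mode is uncalibratable and the run aborts.

Relativization is computed as a ratio of slopes. A per-sample
response-ratio mode (divide each area by the reference channel before
fitting) is provided for designs where the reference is spiked at a constant
level; with a co-diluted reference that mode degenerates (the ratio is flat)
and the slope-ratio route must be used.

## Descriptors

Descriptors are 2D only — no conformers — so the matrix is a deterministic
function of the canonicalized SMILES. Two families are combined:

* RDKit's full 2D descriptor collection (~210 columns);
* topological autocorrelation descriptors ATS/MATS/GATS (Broto-Moreau,
  Moran, Geary) over lags 1–8 and nine atomic weighting schemes (atomic
  number, mass, valence electrons, Sanderson/Pauling/Allred-Rochow
  electronegativity, polarizability, van der Waals volume, Kier-Hall
  intrinsic state), computed on the heavy-atom graph. Geary autocorrelation
  (GATS) weighted by electronegativity-like properties is the family most
  frequently retained by feature selection, so it is implemented natively
  and verified against a pair-enumeration oracle on path-graph molecules.

Cleaning drops non-numeric columns, columns with any non-finite value
(autocorrelation at lags beyond a molecule's diameter is undefined), and
zero-variance columns; it is idempotent and reports every dropped name. For
the default synthetic panel ~340 columns survive.

Deuterium labels: standards are described by their unlabeled backbone SMILES;
isotope substitution does not change any 2D descriptor used here.

## Sensitivity model

Per training iteration, on the training portion only:

1. **Box-Cox** of m_R (maximum-likelihood λ; m_R is strictly positive and
   right-skewed). The inverse transform is exact; at prediction time the
   regressor output is clipped into the transform's valid domain so
   extrapolated predictions stay finite and positive, and the resulting m_R
   is clamped to the training range widened by a factor of 10 — a relative
   sensitivity orders of magnitude outside everything seen in training is an
   extrapolation artefact of the power transform, not a prediction.
2. **Standardization** of descriptors (mean/variance from training rows
   only — no leakage; verified by mutating held-out rows).
3. **RFE** with a linear-kernel SVR surrogate for feature ranking (RBF SVR
   exposes no coefficients), eliminating half the features per step with the
   retained count chosen by 5-fold cross-validated mean absolute error
   (floor 4 features). The final regressor is refit on the selected set.
4. **SVR** tuned by 5-fold CV over a small grid (RBF and linear kernels,
   C ∈ {1, 10, 100}, ε ∈ {0.01, 0.1}, γ = scale).

Because panels are small (tens of lipids), a single random 80:20 split is
unreliable. The ensemble repeats the full procedure over `n_iterations`
random splits (library default 1,101; iteration i is seeded `base_seed + i`
so any iteration reproduces in isolation) and selects the iteration whose
held-out mean absolute error in predicted m_R is the median — the lower
median for even counts, ties broken by lower seed. Selection by MdAPE is
available via configuration. Everything is deterministic under a fixed base
seed (tested bitwise over two 51-iteration runs).

Whether feature selection should be re-run per iteration is a genuinely open
design point; it is re-run here (each iteration is a complete model), which
also lets the descriptor-importance report count selection frequencies
across iterations and aggregate them by family (GATS/MATS/ATS/RDKit2D).

## Surrogate baselines

* **One-point**: the most structurally similar same-class standard —
  identical class mandatory, then smallest |Δ total chain carbons|, then
  smallest |Δ double bonds|, residual ties to the lexicographically smallest
  id — provides a blank-corrected response factor RF = area/conc.
  Chain compositions are read from shorthand names ("PC 15:0-18:1",
  "Cer d18:1/16:0") by a tolerant parser.
* **Class curve**: one pooled OLS line over all same-class standards'
  (concentration, blank-corrected area) points; the analyte's area is
  divided by its slope. With fewer than two usable members it falls back to
  one-point with a warning.

## Validation battery

* Per-lipid mean absolute percent error across samples; global mean and
  median; both with and without outliers. The outlier rule is fixed — mean
  APE above median + 3·MAD (raw MAD, no consistency scaling), never applied
  with fewer than 5 lipids — and both summaries are always reported, so no
  conclusion depends on the rule.
* Precision = mean over lipids of the CV (%) of predicted concentrations
  across replicate samples.
* Hold-out experiments retrain on the remainder (no internal split) and
  report R² of predicted vs true m_R on the held set in original,
  back-transformed space, where out-of-sample R² can be strongly negative.
  Leave-class-out removes a whole class; size hold-outs remove the k
  heaviest (or lightest) lipids per class, mass ties broken
  lexicographically.
* Recovery = 100 · matrix area / neat (nonmatrix) area per lipid; values
  above 100 % are flagged as possible ionization enhancement, zero neat
  areas as undefined.

## Synthetic data generator

The generator is the package's study-condition definition, not a test dial:

* **Panel**: 69 lipids across two ion modes (PC/TG/DG/LPC positive;
  PG/PI/Cer negative; cholesterol and a monoacylglycerol as the two
  reference standards), programmatic SMILES for ester-linked scaffolds with
  sampled chain compositions (no plasmalogens — valence bookkeeping stays
  trivial; the scaffold table is the extension point).
* **Calibration ladder**: 6 levels at the 1:500, 1:200, 1:67, 1:33, 1:17,
  1:10 dilution spacing, i.e. a 50-fold top:bottom concentration ratio;
  per-lipid base concentrations vary lognormally (σ = 0.3).
* **Sensitivity law**: log m_R = weighted sum of standardized informative
  descriptors + class offset (σ = 0.7) + within-class Normal spread
  (σ = 0.1 by default, per-class overrides for the high-spread classes);
  each mode is renormalized so its reference has m_R = 1 exactly.
* **Responses**: area = m·conc + blank, times multiplicative lognormal noise
  (σ = 0.05, i.e. ~5 % CV — area data are positive and CV-stable) and a
  per-lipid matrix factor (default 1; the reference always 1). The blank is
  5 % of each lipid's lowest calibrant signal. Five replicate study samples
  at level 3; three blanks; optional neat spikes for recovery. Optional
  saturating responders cap the top calibrator at 0.6× the level-5 linear
  response — under this ladder a milder cap would still pass the R² ≥ 0.8
  screen, so the fixture represents strong detector saturation.

What the generator does **not** emulate: chromatography and retention-time
structure, in-source fragmentation, adduct patterns, inter-batch drift,
heteroscedastic integration error at low signal, and real descriptor-
sensitivity physics (the law is imposed). Passing tests therefore show that
the pipeline recovers what its own assumptions encode — correct inference
under the stated model — not that real lipid sensitivities are predictable
to any particular accuracy.

## Scenario configurations and problem sizes

Three named scenario configurations fix the conditions of the statistical
experiments (`lipidsens.pipeline`):

* `recovery_config` — 60 positive-mode lipids, a purely descriptor-driven
  law over 5 randomly chosen cleaned descriptors (no class offsets, no
  unexplained spread), 5 % noise. Expectation: held-out MdAPE ≤ 15 % and
  R² ≥ 0.9 against the true law, averaged over 5 replicate seeds.
* `high_spread_config` — steep size- and saturation-driven law
  (MolWt + FractionCSP3) plus σ = 0.3 unexplained within-class spread,
  emulating classes with a large within-class ionization-efficiency range.
  Composition extremes of each class remain standards and every other
  interior member becomes an analyte, mirroring how external-validation
  species sit inside the composition range their class's standards span. The
  unexplained spread hits one-point calibration twice (analyte and its
  surrogate each carry an independent offset), the class curve once, and
  the descriptor model once; the descriptor-driven part is invisible to the
  surrogates but learnable by the model — this is the mechanism that orders
  mean errors model < class curve < one-point.
* `smooth_size_config` — gentle mass-driven law on classes with tight,
  overlapping chain ranges (double bonds 0–1), so per-class mass extremes
  stay near the global descriptor support. Used by the size hold-outs.
  With wide, non-overlapping ranges the heaviest class's extremes sit far
  outside the training support and the collinear linear fit can overshoot
  badly — a real limitation of descriptor-space extrapolation, documented
  rather than hidden.

Test and script ensembles run 5–51 iterations rather than the library
default of 1,101; the selection distribution stabilizes quickly at these
panel sizes and the larger default changes only the granularity of the
median. `scripts/acceptance.py` uses 51 iterations per mode, 10 replicate
method-comparison studies and 5 hold-out replicates.

## Numerical choices and edge cases

* Flat calibration series: slope 0, R² defined as 0, excluded.
* Constant Box-Cox targets: λ fixed at 1 (the likelihood is flat).
* RFE selecting zero features: fall back to all features with a warning.
* Failed ensemble iterations are logged and skipped; the failure count is
  reported.
* R² is undefined (NaN) for held sets with fewer than 2 lipids or zero
  truth variance; per-lipid APE is still reported.
* Model bundles serialize via joblib with a format version and a config
  hash; loading a foreign version fails loudly.

## Known limitations

* Descriptor-space extrapolation beyond the training support is unreliable
  (see leave-class-out: R² strongly negative by design); predictions for
  classes absent from training should not be trusted.
* The one-point/class-curve baselines assume shorthand names parse; lipids
  with unparsable names are silently unusable as surrogates.
* The response-ratio relativization mode requires a constant reference
  spike across calibrants.
* Only 2D descriptors are used; stereochemistry and conformation are
  invisible to the model.
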