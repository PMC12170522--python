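# eiaofs

Binary metaheuristic wavelength selection for spectral classification.

The package implements an enhanced information-acquisition optimizer (EIAO)
for selecting discriminative wavelength subsets from labeled reflectance
spectra, together with everything needed to use and validate it end to end:

- **`eiaofs.preprocess`** — labeled spectra-table I/O (CSV with a numeric
  wavelength header), the SNV / MSC / Savitzky–Golay chemometric transforms,
  and wavelength-region proportion summaries.
- **`eiaofs.eiao`** — the EIAO optimizer: chaotic-logistic initialization
  with elite opposition learning, sigmoid binarization, three update stages
  (collect / filter / organize), Lévy-flight jumps and Laplace crossover.
  Switching every enhancement off recovers the base IAO algorithm exactly,
  so ablation comparisons are trajectory-exact.
- **`eiaofs.fitness`** — the wrapper objective:
  `alpha * KNN_error + (1 - alpha) * n_selected / n_total` on a fixed,
  seeded evaluation split (stratified holdout or k-fold).
- **`eiaofs.baselines`** — binary PSO and binary SCA comparators sharing the
  same binarization, repair, and trace contracts.
- **`eiaofs.classifiers`** — an extreme learning machine (random hidden
  layer + pseudoinverse output weights), RF and SVM via scikit-learn,
  stratified-CV grid search, and a (preprocessor × selector × classifier)
  experiment grid with macro precision/recall/F1 reporting.
- **`eiaofs.synthetic`** — seed-spectra and tabular benchmark generators
  with planted ground truth, plus an exhaustive-search oracle for the
  wrapper objective at small dimension.
- **`eiaofs.cli`** — the `eiaofs` command.

## CLI

```sh
# synthesize a labeled spectra table with known informative bands
eiaofs simulate --out runs/sim --seed 1 --n-bands 60 --n-per-class 40

# select wavelengths (algorithms: eiao, iao, pso, sca)
eiaofs select --input runs/sim/spectra.csv --out runs/sel \
    --algorithm eiao --preprocess msc --alpha 0.99 --seed 1

# evaluate classifiers on full vs selected wavelengths
eiaofs evaluate --input runs/sim/spectra.csv --mask runs/sel/selection.json \
    --out runs/eval --classifiers elm --classifiers rf --classifiers svm

# paired-seed algorithm comparison
eiaofs benchmark --input runs/sim/spectra.csv --out runs/bench \
    --algorithms eiao --algorithms iao --repeats 5
```

Every output directory contains `resolved_config.yaml` and `inputs.json`
(SHA-256 of inputs), and reruns with the same config and seed are
byte-identical.

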