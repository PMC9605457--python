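# pulsevar

Beat-wise harmonic analysis of arterial pulse waveforms: simulate paired
pre/post pulse recordings, segment them into beats, extract 40 harmonic
variability indices, score subjects with a pulse-variability ratio, and
compare against a multi-classifier machine-learning baseline.

## What it does

* **simulate** — synthetic cohorts of quasi-periodic pulse recordings
  (10-harmonic Fourier beats, beat-to-beat amplitude/phase/period jitter,
  additive noise) with exact segmentation ground truth and configurable
  post-session perturbations for a "vascular effect" group.
* **preprocess** — foot detection (intersecting-tangent construction, with a
  minimum-picking fallback), interval artifact screening, HR and HR_CV.
* **harmonics** — per-beat DFT at exact multiples of each beat's own
  fundamental, aggregated into the 40 indices `C1..C10` (amplitude
  proportion, %), `CV1..CV10` (CV of the proportions, %), `P1..P10`
  (circular mean phase, degrees) and `P1_SD..P10_SD` (circular phase SD).
* **score** — the pulse-variability score (product of the six post/pre
  ratios of `CV2` and `P1_SD..P5_SD`) with single-threshold and
  two-threshold (ambiguity-band / reject-option) classification.
* **evalmetrics** — confusion counts with excluded-subject bookkeeping,
  accuracy over adopted subjects, specificity, sensitivity,
  single-operating-point AUC `(sens + spec)/2`, Mann–Whitney rank AUC,
  positive likelihood ratio, adopted/excluded proportions.
* **mlbaseline** — eight classifiers (SVM, MLP, GNB, DT, RF, LR, LDA, KNN)
  on the 40-index feature table with stratified threefold cross-validation.

## CLI

```sh
# simulate a paired cohort (recordings, labels.csv, features.csv)
pulsevar simulate --config cohort.yaml --out cohort/ --seed 1

# segment one recording; extract its 40-index profile
pulsevar segment cohort/s001_M0.csv
pulsevar profile cohort/s001_M0.csv --cn-norm sum

# score paired features; classify with one threshold or a band
pulsevar score cohort/features.csv --threshold 40 --out decisions.csv
pulsevar score cohort/features.csv --low 0.4 --high 40 --out decisions.csv

# confusion matrix + metrics; ML baseline
pulsevar evaluate decisions.csv cohort/labels.csv --target cv_flag
pulsevar ml cohort/features.csv --labels cohort/labels.csv --mode delta40 --seed 7
```

A cohort config is a YAML mapping of `CohortSpec` fields, e.g.

```yaml
n_per_group: [28, 34, 11]   # groups N, C, V
effect_post_phase_sd: 2.0   # M1 phase-jitter inflation in group V
duration_s: 60.0
fs: 500.0
```

Recordings are two-column CSV (`time_s,amplitude`) with a one-line header
`# fs=<Hz> channel=<BPW|PPG> subject=<id> session=<M0|M1>`.

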