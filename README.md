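# afmspeech

Two-tone AM/FM modeling of vowel phonemes for dysarthric-vs-healthy speech
classification. The package implements the full pipeline:

1. **Signal model** (`afmspeech.signal_model`) — a phoneme is the sum of two
   mono-components, each a carrier with two-tone amplitude modulation and
   two-tone frequency modulation (14 parameters per component).
2. **Component separation** (`afmspeech.fourier_bessel`) — Fourier-Bessel
   series expansion over the zero-order Bessel basis; the two dominant
   coefficient lobes are reconstructed band-wise into mono-components.
3. **Demodulation** (`afmspeech.desa`) — the Teager-energy-based discrete
   energy separation algorithm (DESA-1) splits each component into
   amplitude-envelope and instantaneous-frequency tracks.
4. **Feature extraction** (`afmspeech.features`) — two-tone sinusoidal
   models are fitted to both tracks (FFT peak picking + trust-region least
   squares), yielding a fixed 28-feature vector (14 per component).
5. **Evaluation** (`afmspeech.evaluation`) — five classifiers (LDA, NB,
   KNN, SVM, gradient-boosted trees) under stratified split, stratified
   k-fold, and leave-one-subject-out protocols, with accuracy / precision /
   recall / F1 / AUC computed from first principles.
6. **Synthetic cohorts** (`afmspeech.cohort`) — labeled, subject-structured
   corpora generated from class-conditional parameter distributions, so the
   whole pipeline is testable without any real speech corpus.

## CLI

```bash
# generate a synthetic cohort of WAV phonemes + manifest
afmspeech simulate --preset desk-small --seed 1 -o scratch/cohort

# extract the 28-feature table (labels/subjects come from the manifest)
afmspeech extract scratch/cohort -o scratch/features.csv

# evaluate all five classifiers under a protocol
afmspeech evaluate scratch/features.csv --protocol loso --seed 0 -o scratch/report.json
afmspeech evaluate scratch/features.csv --protocol kfold --k 5 -o scratch/report_cv.json
afmspeech evaluate scratch/features.csv --protocol split --train-fraction 0.8 -o scratch/report_split.json
```

Cohort presets: `balanced-table2` (2,450/2,450 phonemes),
`imbalanced-table2` (2,450/1,050 — a 7:3 ratio), `loso-balanced` (42+42
subjects), `loso-imbalanced` (42+21 subjects), `desk-small` (10+10 subjects
× 10 phonemes; CI scale). `--effect-scale 0` generates a null cohort with
identical class distributions.

## Notes

- All angular frequencies are radians/sample; audio is resampled to 16 kHz
  so `f_Hz = omega * 16000 / (2*pi)`.
- Fourier-Bessel coefficients are computed by an exact collocation solve on
  the sample grid (LU-factorized and cached per signal length), making the
  full-order round trip exact to machine precision.
- Undefined metrics (zero denominators, single-class folds) are reported as
  `null`, never as 0. The positive class is `dysarthric` throughout.
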