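# ppgrr — respiratory rate from photoplethysmography

`ppgrr` estimates respiratory rate (RR, breaths/min) from a PPG
waveform alone — the setting of wearable and bedside monitoring, where
impedance spirometry is impractical but PPG is ubiquitous.  It is aimed
at biomedical-signal researchers who need a complete, reproducible
pipeline: spectral pre-estimation, signal-quality assessment, and a
quality-aware machine-learning correction, plus a synthetic-data
generator so every stage is testable without any data download.

## Method

Respiration modulates PPG through pulse **a**mplitude **m**odulation,
beat-rate **f**requency **m**odulation, and **b**aseline **w**ander.
For each 32-s window (8-s stride), the pipeline:

1. **Pre-extracts a respiratory wave** by ensemble empirical mode
   decomposition (EEMD): IMFs whose dominant frequency lies in the
   respiratory band (0.05–0.5 Hz) are selected and reduced to their
   leading principal component.  The pre-estimate is
   `RR_P = 60 · f_peak` with `f_peak` the dominant FFT frequency of
   that wave (zero-padded ×16, ≈0.12 bpm resolution).
2. **Scores signal quality**: the mean skewness of 2-s PPG subwindows
   (S̄_SQI), and three respiratory quality indices on the wave
   down-sampled to 4 Hz — peak autocorrelation in the 2–20 s period
   range (QR1), spectral concentration around the dominant peak (QR2),
   and the in-band AR(9) pole magnitude (QR3).
3. **Fuses the five features** `(RR_P, S̄_SQI, QR1, QR2, QR3)` in a
   relevance vector machine over the hybrid kernel

   `K(x,z) = d₁·exp(−γ_G‖x−z‖²) + d₂·tanh(a⟨x,z⟩+c) + d₃·(s⟨x,z⟩+1)² + d₄·exp(−γ_L‖x−z‖₁)`,
   `d_m ≥ 0, Σd_m = 1`,

   with kernel widths and weights tuned by the whale optimization
   algorithm against cross-validated error on a random 70 % training
   split.  The output is the final prediction `RR_M`, clipped to
   3–40 bpm.

Evaluation covers MAE, RMSE, Bland–Altman 95 % limits of agreement,
a per-RR-range error breakdown, and per-subject correlations between
the quality indices and the pre-estimate's relative error.  See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The whole workflow is scriptable from Python or the `ppgrr` CLI:

```sh
ppgrr simulate cohort/ --n-subjects 10 --duration-s 180 --profile poor --seed 1
ppgrr extract cohort/ features.csv --ensemble-size 25 --seed 1
ppgrr train features.csv model.json --n-whales 6 --n-iterations 8 --cv-folds 3 --seed 1
ppgrr predict model.json features.csv predictions.csv
ppgrr evaluate predictions.csv report.json
```

The same experiment through the library, on a degraded ("poor")
synthetic cohort with quality-correlated corruption:

```python
from ppgrr import (ExtractionConfig, WOAConfig, build_features,
                   generate_cohort, predict, segment_windows,
                   split_train_test, train)
from ppgrr.evaluation import mae, rmse

records = generate_cohort(n_subjects=10, duration_s=180,
                          quality_profile="poor", seed=1000)
windows = [w for r in records for w in segment_windows(r)]
features, discarded = build_features(
    windows, ExtractionConfig(ensemble_size=25, seed=1000))
split = split_train_test(features, train_frac=0.7, seed=1000)
bundle = train(split, woa_cfg=WOAConfig(n_whales=6, n_iterations=8,
                                        seed=1000), cv_folds=3)
rr_m = predict(bundle, split.test)
ref = split.test.rr_label
print(f"RR_P: MAE {mae(split.test.rr_p, ref):.2f}  "
      f"RMSE {rmse(split.test.rr_p, ref):.2f}")
print(f"RR_M: MAE {mae(rr_m, ref):.2f}  RMSE {rmse(rr_m, ref):.2f}")
```

prints

```
RR_P: MAE 2.28  RMSE 4.14
RR_M: MAE 2.15  RMSE 3.16
```

— the raw spectral pre-estimate RR_P is off by ~2.3 breaths/min on this
heavily corrupted cohort, and the quality-aware fusion model RR_M cuts
the error, most visibly in RMSE because its main effect is suppressing
the catastrophic errors on low-quality windows.

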