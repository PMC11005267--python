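# ecgforecast

One-step-ahead ECG signal forecasting with a Nested LSTM — an LSTM whose
memory-cell update is delegated to a full inner LSTM — plus the complete
preprocessing and evaluation pipeline around it:

1. **Synthetic ECG** (`ecgforecast.synth_ecg`): seeded generator of
   PQRST-like beats (five Gaussian bumps per RR interval) and four additive
   noise classes (baseline drift < 1 Hz, 50/60 Hz powerline, band-limited
   EMG, 5–10 Hz motion artifact, plus white noise), so every stage is
   testable offline.
2. **I/O** (`ecgforecast.signal_io`): CSV records, a native WFDB reader
   (formats 212 and 16) for locally available Holter data, and event-window
   extraction (e.g. 16 s before / 4 s after an annotated onset → 5000
   samples at 250 Hz).
3. **Denoising & normalization** (`ecgforecast.preprocess`): 7-level db6
   wavelet decomposition (own exact-reconstruction DWT in
   `ecgforecast.wavelets`), per-level thresholds minimising an unbiased
   risk estimate over sorted squared coefficients with a MAD/0.6745 noise
   scale, hard thresholding of the detail layers, inverse transform,
   z-scoring, and an SNR metric.
4. **Delay embedding** (`ecgforecast.embedding`): window `m` (default 99),
   delay `tau` (default 1); a length-`N` series yields
   `N − 1 − (m−1)·tau` supervised pairs (5000 → 4901). Chronological
   train/eval splitting with a leakage guard.
5. **Models** (`ecgforecast.model`): Nested LSTM and plain LSTM in pure
   NumPy with hand-derived backpropagation (verified against finite
   differences), squared-error loss with early stopping on an error
   threshold, Adam/SGD, JSON checkpoints.
6. **Harness** (`ecgforecast.harness`): per-record experiments (denoise →
   normalize → embed → train both models → predict), RMSE/MAE comparison
   tables in mV with per-model averages, and relative-reduction reporting.

## CLI

```sh
ecgforecast synth --rate 250 --duration 20 --hr 75 \
    --noise powerline:50:0.1 --noise white::0.1 --seed 7 \
    --out clean.csv --out-noisy noisy.csv
ecgforecast denoise --in noisy.csv --out denoised.csv --report thresholds.json
ecgforecast embed --in denoised.csv --window 99 --tau 1 --out-prefix ds_
ecgforecast train --dataset ds_ --model nested_lstm --epochs 30 --out model.ckpt
ecgforecast predict --model model.ckpt --in denoised.csv --window 99 --report result.json
ecgforecast fetchwin --record noisy.csv --rate 250 --event-index 4000 --pre 16 --post 4 --out win.csv
ecgforecast run --config experiment.yaml --out results/
```

`run` consumes a YAML experiment description (records as CSV paths or synth
specs, embedding and training settings, global seed) and writes `rmse.csv`,
`mae.csv` and `summary.json`; see `tests/test_cli.py` for a minimal config.

## Notes

- Baselines beyond the plain LSTM (SVM, ESN, Bi-LSTM) have registry slots
  but are intentionally unimplemented.
- Metrics are computed on normalized signals and de-normalized to mV for
  table emission; both are kept in per-record results.
- Everything is deterministic given the configured seeds.
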