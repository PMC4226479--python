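# pacorrect

Pulse-artifact (ballistocardiogram) removal for EEG recorded inside an MR
scanner, with ground-truthed synthetic data for validation.

The cardiac cycle couples into EEG recorded in a static magnetic field as a
pulse artifact (PA): a waveform locked to each ECG R peak, drifting in
amplitude over time and flipping polarity between hemispheres. `pacorrect`
implements the standard two-stage cleanup and the machinery to evaluate it:

1. **OBS** — optimal-basis-set template subtraction: per channel, the mean
   plus the first 3 principal components of the cardiac-locked (0–700 ms
   after R) epochs are fitted to every epoch by least squares and subtracted.
   The default fit gates the template against a non-cardiac-locked null grid
   so channels without genuine locked content are left untouched.
2. **ICA** — extended-infomax independent component analysis, fitted either
   on the whole recording (`whole`) or on concatenated PA epochs
   (`pa_epochs`), with four criteria for marking residual PA components:
   - `pvaf` — back-projected variance share within PA intervals > 2.5 %;
   - `corr` — correlation with per-hemisphere PA templates ≥ 40 % of the
     best component's correlation;
   - `pacf` — partial-autocorrelation peak at the R–R lag > 1/3 of the
     largest peak;
   - `wave` — time-locking ratio of the epoch-averaged complex-Morlet CWT
     magnitude (automated surrogate for visual inspection), default
     threshold 3.0.
3. **Validation metrics** — peak-to-peak ratio (PTP), autoregressive (Burg)
   band-power ratios with a quality coefficient
   QC = alpha ratio / mean(delta, theta ratios), time-frequency difference
   maps (`CWT_off`) with their mean absolute time derivative (MD), and a
   Kruskal–Wallis + Tukey-style rank post-hoc comparison across methods.
4. **Synthetic data** — a seeded generator of 1/f background with occipital
   alpha, an R-locked drifting artifact with hemispheric polarity flip, and
   a matching ECG trace; plus a known-mixing source-model dataset for testing
   the selection criteria against ground truth.

## CLI

```sh
# generate a synthetic dataset (BrainVision triplet + R-peak events + manifest)
pacorrect simulate --config cfg.json --seed 1 --out data/

# one correction run: OBS + ICA + one selection criterion + quality report
pacorrect correct --eeg data/mixed.vhdr --events data/rpeaks.txt \
    --method wave --interval whole --out run/

# R peaks can instead be detected from an ECG channel
pacorrect correct --eeg data/mixed.vhdr --ecg-label ECG --method pvaf --out run/

# all 8 variants (2 ICA intervals x 4 criteria)
pacorrect sweep --eeg data/mixed.vhdr --events data/rpeaks.txt --out sweep/

# compare a metric across runs (Kruskal-Wallis + pairwise rank test)
pacorrect report --metric qc --reports run/report_*.json
```

Event files are plain text: one 0-based R-peak sample index per line, `#`
comments allowed. Exit codes: 2 = configuration error, 3 = data error,
4 = numerical failure.

## Library

```python
from pacorrect import (
    SyntheticConfig, generate_dataset, correct_obs, fit_ica,
    score_wave, apply_selection,
)

ds = generate_dataset(SyntheticConfig(seed=1))
post_obs, model = correct_obs(ds.mixed, ds.rpeaks)
dec = fit_ica(post_obs, ds.rpeaks, interval_mode="whole", seed=1)
result = score_wave(dec, ds.rpeaks)
cleaned = apply_selection(post_obs, dec, result)
```

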