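# deti — dynamic electrode-to-image mapping

`deti` links trial-averaged EEG visual-evoked-potential (VEP) variance to
every pixel of natural-scene stimuli through a log-Gabor spatial-frequency
encoder space.  For each electrode and 5-ms time step it produces a "tag
map" over the visible pixels of the stimuli: the spatial frequency of the
encoder whose per-pixel log-power array best explains the first principal
component of the windowed VEPs.  The package also provides the downstream
map statistics (encoder probabilities, electrode dominance, spatial
histograms and marginals, HSF/LSF ratio state-space analyses, time-time
similarity, nine-window local analyses, bubbles-style reconstruction) and
a fully seeded synthetic-data harness so the entire pipeline is testable
offline.

## Layout

| module            | role |
|-------------------|------|
| `deti.stimuli`    | circular windowing, RMS-contrast calibration, edge ramping, angular-distance matrices, embedding-based stimulus sampling, amplitude-spectrum slope |
| `deti.encoders`   | log-Gabor filter bank (Fourier domain), image symmetrization and filtering, log-power encoder-space tensor |
| `deti.veps`       | epoch preprocessing (filtering, artifact rejection, re-referencing, baselining), trial averaging, time-resolved first-PC extraction |
| `deti.mapping`    | pixel-wise OLS linking, Benjamini–Hochberg FDR, image-general and image-specific tagging, label-shuffle permutation null, tuning-curve validation, behavioral-score maps |
| `deti.analysis`   | probabilities, dominance, histograms/marginals, SF ratio, state-space PCA, time-time regression, local windows, window covariation, paired permutation contrasts, reconstruction |
| `deti.synthdata`  | seeded image/VEP generators with ground-truth preference fields and recovery scoring |
| `deti.io`         | HDF5 persistence for every container |
| `deti.cli`        | the `deti` command-line tool |

Key frozen conventions live in `deti.config`, including the circular
window lattice convention calibrated to reproduce 206,643 visible pixels
for a 512-px image with a 512-px-diameter window.

## CLI

```sh
deti calibrate --in images/ --out stimuli.h5 --rms 0.20     # window + RMS-normalize
deti encode    --stimuli stimuli.h5 --out encoders.h5       # log-power encoder space
deti pca       --veps veps.h5 --step 5 --halfwin 20 --out pc.h5
deti map       --veps veps.h5 --encoders encoders.h5 --q 0.05 \
               --variant general --out tags.h5
deti analyze   --maps tags.h5 --what probability --out results/
deti simulate  --seed 1 --out sim/                          # synthetic stimuli + VEPs
deti validate  --sim sim/                                   # tag-recovery report
```

VEP tensors are read from HDF5 with datasets `/veps` `[electrodes,
samples, images]` plus `sample_rate`/`pre_ms`/`post_ms` attributes (see
`deti.io.save_veps` for the exact layout).

## Notes on the synthetic generators

Phase-randomized power-law images alone make every pixel's encoder
response a monotone function of one global statistic (the spectral
slope), which is enough for tagging but not for per-pixel ground-truth
recovery.  `SynthConfig` therefore offers per-band spectral gain jitter
(`band_gain_sigma`) and a local texture mode (`envelope_cells`) that
give bands, and optionally local regions, independent image-to-image
variation.  Recovery tests use gain jitter with uniform per-electrode
preferences; permutation-null tests use the texture mode, whose many
local factors keep false-positive snowballs small.
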