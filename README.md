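# eegmacro

Macroscale resting-state EEG analysis as a tested, reusable pipeline:

* **preprocess** — average reference, anti-aliased decimation (2048 → 1024 Hz),
  spherical-spline channel interpolation (≤ 6 channels, else the subject is
  excluded), selection of the first 15 artifact-free 4 s epochs, zero-phase
  Butterworth band-pass in the four analysis bands
  (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–20 Hz).
* **spectral** — rectangular-window FFT periodograms at 0.25 Hz resolution and
  relative band power (each band divided by the four-band total; shared band
  edges are assigned to the lower band via half-open `[low, high)` intervals).
* **connectivity** — phase lag index (PLI) and orthogonalized amplitude
  envelope correlation (AEC-c, reported as `(r + 1) / 2` so 0.5 means no
  coupling), with whole-head means over the 2016 electrode pairs.
* **mstnet** — maximum spanning tree backbone (64 nodes, 63 edges) and six
  normalized topology measures: max degree, leaf fraction, diameter, max
  betweenness centrality, mean eccentricity, tree hierarchy.
* **features** — the closed 60-name vocabulary (15 features per band:
  relative power, PLI mean, AEC-c mean, and the six tree measures on each
  connectivity basis) and cohort feature tables with exclusion reports.
* **groupstats** — two-sided Mann-Whitney U tests (exact enumeration for
  pooled n ≤ 20 without ties, tie-corrected normal approximation otherwise)
  with Holm-Bonferroni adjustment, plus the exploratory uncorrected per-bin
  power comparison over the 78 bins in 0.5–20 Hz.
* **rfmodels** — balanced-subset random-forest classification (noise-feature
  screening, ntree = 500, mtry = round(√p), stratified tenfold CV, patients
  as positive class) and random-forest regression of PANSS change scores
  with a label-permutation significance test (add-one corrected p).
* **synthetic** — deterministic generators for multichannel EEG-like
  recordings (band-limited oscillators, 1/f noise, controllable phase and
  envelope coupling, instantaneous mixing as a volume-conduction surrogate)
  and cohorts with planted group effects and PANSS trajectories.
* **io / pipeline / cli** — minimal EDF (16-bit) and BDF (24-bit) reading
  and writing, end-to-end orchestration with config-hash stamping, and an
  `eegmacro` command-line interface.

## Command line

```bash
# synthetic cohort (feature + clinical CSV), then each analysis stage
eegmacro simulate --kind cohort --out cohort/ --n-patients 62 --n-controls 106 --seed 1
eegmacro compare  --features cohort/features.csv --clinical cohort/clinical.csv --out comparison.csv
eegmacro classify --features cohort/features.csv --clinical cohort/clinical.csv --out classifier.json
eegmacro predict  --features cohort/features.csv --clinical cohort/clinical.csv \
                  --out regression.json --outcome pos --n-perm 1000

# synthetic EDF recording and 60-feature extraction from file
eegmacro simulate --kind recording --out rec.edf --duration 70 --seed 1
eegmacro features rec.edf --out features.csv

# everything at once (simulated cohort by default)
eegmacro run --out bundle/ --seed 1
```

Exit codes: 0 success, 2 usage error, 3 data error, 4 internal error.

## Conventions worth knowing

* Artifact rejection is an absolute-amplitude threshold (default 100 µV);
  the original analysis used visual rating, which is not reproducible.
* The beta band follows the analysis definition 13–20 Hz (introductory
  texts often use 13–30 Hz); nothing above 20 Hz is analyzed.
* Epoch-edge margins (1/8 of the epoch per side) are discarded around the
  analytic-signal transform before computing PLI/AEC-c.
* The tree-hierarchy denominator uses n − 1, which is simultaneously the
  edge count and the maximum possible leaf count of any tree.
* Synthetic spectral defaults (band amplitudes, 1/f level) are conventions
  of the synthetic module, not literature values.
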