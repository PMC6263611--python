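# File formats

## Signal records (`*.csv` + `*.json` sidecar)

`<name>.csv` — one row per sample:

| column | meaning                     |
|--------|-----------------------------|
| time_s | sample time in seconds      |
| ecg    | electrocardiogram           |
| gsr    | skin conductance            |
| emg    | facial electromyogram       |
| ppg    | photoplethysmogram          |

`<name>.json` — metadata:

| key             | meaning                                                |
|-----------------|--------------------------------------------------------|
| fs              | sampling rate, Hz (200 by default)                     |
| seed            | generator seed of this record                          |
| record_id       | participant/record identifier                          |
| label_intervals | list of [start_s, end_s, emotion]                      |
| truth           | per-channel ground-truth fiducial times in seconds     |

## Feature tables (`*.csv`)

Header row; first column `segment_id` (index), then the 136 feature columns
named `<SIGNAL>_<underlying>_<stat>` (e.g. `ECG_RR_mean`, `GSR_1Diff_std`,
`PPG_PRV_freqmean`), last column `emotion`. Intervals are in ms, amplitudes
in signal units, ratios dimensionless.

## Models (`*.json`)

One JSON object with a `kind` tag:

* `kind: "kpca"` — standardised training matrix, sigma, eigenvalues,
  projection coefficients (alphas), Gram row means/grand mean,
  standardisation mean/std.
* `kind: "gbdt"` — class labels, initial scores, learning rate, and each
  tree as flat arrays (feature, threshold, left, right, value; feature −1
  marks a leaf).

Round-tripping a model reproduces its predictions exactly.

## CV results

`cv_result.json` — overall (pooled) accuracy, mean fold accuracy, per-fold
accuracies, per-emotion recall, config snapshot. `confusion.csv` — rows
true emotion, columns predicted.
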