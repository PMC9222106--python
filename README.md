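# slowwave

Analysis toolkit for cortical slow-wave activity, epileptiform-event
detection and sleep-state coupling in paired-hemisphere LFP, chronic
EEG/EMG and two-photon calcium recordings — together with a seeded
synthetic-data generator that provides ground truth for every analysis
stage, so each estimator can be validated as parameter recovery.

## What it does

- **core** — domain types (`TimeSeries`, `Recording`, `IntervalSet`,
  `EventTable`, `PairedTable`), interval algebra on half-open intervals,
  EDF/CSV recording I/O with a JSON metadata sidecar, and the group
  statistics used throughout (paired Wilcoxon, Mann-Whitney, Bartlett,
  one-sample t).
- **synth** — seeded generator of paired-hemisphere LFP (up/down states,
  1/f^chi background, state-gated gamma, multi-unit spikes, beta bursts,
  hypersynchronous discharges with contralateral up-state coupling),
  chronic EEG+EMG with a Wake/NREM/REM hypnogram, and calcium populations
  with lognormal transient rates. Control and mosaic condition profiles.
- **spectral** — zero-phase band filtering (delta 0.5-4, beta 9-25, gamma
  40-100 Hz), band RMS, Welch spectra, windowed interhemispheric cross
  spectra, and the power-spectrum decay-exponent fit used as an E:I proxy
  (semilog-exponential and log-log power-law models).
- **swa** — hysteresis up/down-state segmentation with automatic polarity
  selection, per-up-state transition slopes (DS→US and US→DS segments,
  max and mean |d/dt| of the delta-filtered trace), paired hemisphere
  metric tables.
- **events** — beta-burst detection (running-median-normalized Hilbert
  envelope), hypersynchronous-spike detection (5-40 Hz candidate band,
  morphology measured on a 0.1-40 Hz trace, 25%-of-peak boundaries),
  event rates, phase locking to contralateral up states, phenotype calls
  (frequent bursts > 3/h, hyperexcitable > 5/h).
- **units** — multi-unit extraction from the > 300 Hz band with a robust
  automatic threshold (median/0.6745), firing rates, percentage of spikes
  inside up states.
- **calcium** — running-percentile dF/F, transient detection with
  re-trigger splitting, per-neuron frequency statistics with the strict
  > 4/min hyperactive criterion, population dispersion comparison,
  field-of-view activity traces, transient-to-up-state synchronization.
- **sleep** — threshold-based Wake/NREM/REM scoring of EEG+EMG (4 s
  epochs) and beta-burst-to-NREM coupling statistics.
- **pipeline** — YAML-config-driven orchestration over a recording
  manifest with per-stage CSV/JSON outputs and a provenance-stamped
  report.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: recovery of the
published event morphology (0.23 s / 0.49 mV), up-state phase locking
(81%), NREM burst coupling (87%), calcium hyperactive fractions
(26.1% / 7.8%) and burst rates, plus property suites (interval algebra vs
a 1 ms grid oracle, Parseval, spectral-exponent recovery, segmentation
IoU, unit-detector sensitivity/precision, sleep-scorer accuracy, and a
100-seed direction-of-effect suite).

## CLI

```sh
slowwave simulate --seed 3 --profile mosaic --kind lfp --duration 600 --out demo.csv
slowwave swa demo.csv --out swa.csv          # up/down metrics per hemisphere
slowwave events demo.csv --channel lfp_injected
slowwave units demo.csv --channel lfp_control
slowwave spectrum demo.csv --model loglog_powerlaw
slowwave simulate --seed 3 --kind eeg --duration 7200 --out eeg.edf
slowwave sleep eeg.edf --out hypnogram.csv
slowwave run-all --config run.yaml           # manifest-driven full pipeline
```

`run.yaml` takes an input `manifest` (paths + per-animal metadata), stage
toggles and every detector threshold; all parameters shown in
`slowwave.pipeline.RunConfig`.
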