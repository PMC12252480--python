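# systoseg

Adaptive joint ECG/PCG segmentation and systolic time interval extraction.

`systoseg` is for researchers and engineers working with synchronously
acquired electrocardiogram (ECG) and phonocardiogram (PCG) recordings —
e.g. from a digital stethoscope plus a single-lead ECG front-end — who want
per-beat cardiac timing without manual annotation. It detects the Q, R and
S waves of each QRS complex in the ECG and the onset and peak of the first
heart sound (S1) and the peak of the second heart sound (S2) in the PCG,
then derives the systolic time intervals

* **EMAT** (electromechanical activation time) = S1 onset − Q,
* **PEP** (pre-ejection period) = S1 peak − Q,
* **LVET** (left-ventricular ejection time) = S2 peak − S1 peak,
* **LVST** (left-ventricular systolic time) = S2 peak − S1 onset,
* **S1–R** = S1 onset − R,

their RR-normalised fractions and the PEP/LVET ratio — quantities used in
the clinical literature to screen for reduced ejection fraction and
left-ventricular dysfunction (e.g. EMAT ≥ 104 ms, EMAT/LVST ≥ 0.40).

Segmentation uses adaptive amplitude thresholds relative to each 10 s
analysis window (squared-PCG threshold `0.1·max(pcg²)`, a signed amplitude
gate, a 425 ms S1 refractory rule, a 40 % amplitude-consistency filter, a
strict 125–500 ms S2 search window, a backward-slope search for the S1
onset on the 40 Hz low-passed PCG, and `0.5·max(ecg)` / `0.2·max(−ecg)`
thresholds for R and Q/S), so detections are invariant to signal scaling.
The algorithm and its constants are described in `docs/methods.md`.

The package also ships:

* readers for the three recording formats such systems produce — CSV serial
  logs (timestamp-ms + channels), mono WAV audio, MAT containers (v5 and
  v7.3) — plus non-overlapping window slicing;
* Bland–Altman method-agreement statistics and error metrics with plotting;
* a fully programmable synthetic ECG+PCG generator with known ground-truth
  fiducials, so every stage is testable without recorded data.

## Worked example

Generate a synthetic recording (28 beats over ~20 s at 2 kHz, programmed
EMAT/PEP/LVET = 74/89/244 ms, 20 dB SNR), segment it, and summarise:

```bash
systoseg simulate --out fx --seed 3
systoseg segment fx/recording.csv --out fid.csv
systoseg intervals fid.csv --out beats.csv
```

which prints

```
fiducials: fid.csv (302 rows)
beats: beats.csv (28 rows); summary: beats.json
```

`beats.csv` holds one row per paired cardiac cycle; `beats.json` contains
per-interval statistics and the screening flags. For this run the EMAT
summary reads (values rounded) mean 71.18 ms, sd 2.86 ms, median 72.00 ms,
IQR 4.75 ms over n = 28 beats — i.e. the pipeline recovered the programmed 74 ms electromechanical
activation time to within ~3 ms on noisy data, with a beat-to-beat spread
of ~3 ms; all four interval means fall inside the typical resting-adult
ranges (EMAT/PEP 50–120 ms, LVET/LVST 150–350 ms) and every screening flag
is `false`. Comparing a table against a reference table gives Bland–Altman
limits of agreement and error metrics (here, a table against itself):

```bash
systoseg compare beats.csv beats.csv --column emat_ms --out agree.json --plot ba.png
# agreement: agree.json (n=28)   -> mean_diff 0.0, loa [0.0, 0.0], mae 0.0
```

The same pipeline is available as a library:

```python
from systoseg import BeatTrainSpec, generate_beat_train, pipeline

pair, truth = generate_beat_train(BeatTrainSpec(seed=3))
beats, summary, flags = pipeline.extract_intervals(
    *pipeline.segment_recording(pair)[:2])
print(summary.mean("emat_ms"), flags.emat_ge_104ms)
```

Real recordings enter through `read_csv_recording`, `read_wav` and
`read_mat_recording`, or via `systoseg segment recording.csv|.mat`.

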