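# mirp — motor-imagery EEG decoding and relative-power factors

`mirp` is a tested re-implementation of a session-wise motor-imagery (MI)
BCI analysis for researchers studying *performance variation*: why the
same decoding pipeline yields very different accuracies across subjects
and across days, and whether band-wise **relative power (RP)** of the EEG
explains it.

The package covers the full chain:

1. **Synthetic study generation** — a cue-based four-task MI paradigm
   (left hand, right hand, both feet, idle; 40 trials/run, 9-s trials,
   500 Hz, 26 scalp electrodes grouped into SMA/PMC/M1/S1 regions) with
   class-dependent event-related desynchronization (ERD), subject-level
   rhythm composition, blink/EMG artifacts, and a known ground-truth
   coupling between baseline SMA alpha RP and ERD depth.
2. **Artifact removal** — linear-phase FIR filtering, ICA with automatic
   EOG-matched component rejection, and single-channel EEMD–CCA muscle
   artifact removal.
3. **Decoding** — one-vs-rest common spatial patterns (CSP) on 1-s task
   sub-epochs, log variance-share features, RBF-SVM (C = 0.8), stratified
   10-fold cross-validation; accuracy and macro-averaged F-score.
4. **Spectral factors** — Welch PSD (500 ms Hamming windows, no overlap),
   band powers for theta (4–8), alpha (8–13), beta (13–30) and low gamma
   (30–50 Hz), RP normalized to 4–50 Hz per trial stage, and the on-task
   change ΔRP = RP(task) − RP(pre-task).
5. **Statistics** — high/low performer group split with electrode-wise
   Welch t-maps, Spearman correlation across subjects, repeated-measures
   correlation (rmcorr) across sessions, Benjamini–Hochberg FDR, and the
   full 11-task-combination correlation grid.

## The model in brief

For two classes with spatial covariances `C_t` (target) and `C_r` (rest),
CSP solves `C_t w = λ (C_t + C_r) w`; filters at the extreme eigenvalues
`λ ∈ [0, 1]` maximize the between-class variance ratio. Per epoch `x`
and model, features are `log(var(wᵀx) / Σ_j var(w_jᵀx))`.

Relative power of band `b` on electrode `e` is
`RP_b(e) = ∫_b PSD_e(f) df / ∫_4^50 PSD_e(f) df`, so the four bands sum
to 1 per electrode and `Σ_b ΔRP_b = 0` identically.

Repeated-measures correlation fits an ANCOVA with subject as factor and a
common slope: `r_rm = sign(β) √(SS_x / (SS_x + SS_err))` with
`df = n_obs − n_subjects − 1`.

## Worked example

```python
from mirp.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo", seed=1,
                     study={"n_subjects": 4, "n_sessions": 2, "n_runs": 2})
run_pipeline(cfg)
print(open("demo/summary.txt").read())
```

prints (numbers from this exact configuration and seed):

```
mirp 0.1.0 pipeline summary
subjects=4 sessions=2 runs=2 coupling=0.8

Per-subject three-class accuracy (mean +/- SD over sessions):
  subject  1:  57.9 +/-  1.3 %
  subject  2:  93.3 +/-  3.3 %
  subject  3:  89.4 +/-  1.9 %
  subject  4:  80.6 +/-  3.5 %

Pre-task SMA alpha RP vs three-class accuracy (Spearman, n=4): r=1.000, p=0.0000
```

Each subject's three-class (left/right/feet) CV accuracy reflects their
generated ERD depth; because the study was generated with coupling 0.8
between baseline SMA alpha RP and ERD depth, the measured pre-task alpha
RP ranks the subjects in the same order as their accuracy. `demo/` also
contains tidy CSVs (`metrics.csv`, `rp.csv`, `delta_rp.csv`,
`subject_performance.csv`) and a JSON manifest echoing every parameter.

The same stages are available from the shell:

```bash
mirp simulate --subjects 2 --sessions 1 --runs 2 --seed 1 --out ds
mirp decode --in ds --tasks left,right,feet --out metrics.csv
mirp rp --in ds --out rp_out
mirp run --seed 1 --out full_out
```

## Layout

```
src/mirp/
  synth.py     synthetic studies with ground truth
  io.py        RawRun/EpochSet, disk format, epoch extraction
  preproc.py   FIR, ICA-EOG, EEMD-CCA
  decode.py    OVR-CSP + SVM cross-validation
  spectral.py  Welch, band power, RP / ΔRP tables
  stats.py     groups, t-maps, Spearman, rmcorr, FDR grid
  pipeline.py  orchestration;  cli.py  the `mirp` command
docs/methods.md   modelling and design notes
```
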