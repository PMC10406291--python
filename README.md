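# taskfmri-qc

Quality control for task fMRI runs. The package screens each run of a
task-based fMRI study on four necessary criteria and assembles the evidence
into two review documents plus a machine-readable decision record:

- **A — excessive motion** (quantitative): censor individual frames whose
  framewise displacement exceeds 0.9 mm; exclude the run when 20% or more
  of its frames are censored.
- **B — improper task presentation** (quantitative): exclude when fewer
  than half of the expected trials have usable data (truncated runs,
  presentation errors).
- **C — invalid task performance** (quantitative + qualitative): exclude
  when the participant failed to respond to five or more trials in a row,
  or to more than 40% of all trials; flag single-button responding for
  review.
- **D — failed acquisition or preprocessing** (qualitative): temporal
  mean / sd / tSNR images and acquisition-metadata consistency checks
  support a human judgment, recorded as an override — never an automatic
  exclusion.

It consumes BIDS-style artifacts: `_events.tsv` trial tables, fMRIPrep
`_desc-confounds_timeseries.tsv` motion tables, and preprocessed 4D NIfTI
volumes with JSON sidecars. A synthetic-data generator produces all three
with planted ground truth, so the entire pipeline is testable offline.

## The statistics

**Framewise displacement** between consecutive frames *t−1, t* with
translations *d* (mm) and rotations *r* (radians):

    FD_t = Σ_i |Δd_i,t| + R · Σ_i |Δr_i,t| ,   R = 50 mm,  FD_0 = 0

i.e. the sum of absolute backward differences, rotations converted to arc
length on a 50 mm sphere (the convention of fMRIPrep's confounds). Frame
*t* is censored when FD_t > 0.9 (strict); the run fails criterion A when
the censored fraction ≥ 0.20 (inclusive).

**tSNR** per voxel is the temporal mean divided by the temporal standard
deviation (sample, *n*−1 denominator), computed over the entire run
without censoring; zero-sd voxels are reported as tSNR 0 and counted.

**No-response screening** treats a trial with no recorded response key as
a no-response trial. The run fails criterion C when the longest
consecutive no-response block ≥ 5 or the no-response fraction > 0.40
(strict). Accuracy is the proportion correct among responded trials only.

## Worked example

Generate a synthetic cohort of 8 runs — four unremarkable, plus one with a
5-trial no-response block, one with attention decaying across the run, one
with motion spikes censoring a quarter of its frames, and one acquired
distorted with deviant sidecar metadata — then QC it:

```bash
taskfmri-qc synth --cohort --seed 1 --out bids
taskfmri-qc run --bids-dir bids --out qc --expected-counts '{"CONTROL":32,"TASK":32}'
```

prints

```
sub-005: excluded (criterion C)
sub-006: excluded (criterion C)
sub-007: excluded (criterion A)
reports: qc/fmri_qc.html, qc/behavior_qc.html
decisions: qc/qc_decisions.json
```

sub-005 and sub-006 fail the task-performance rules (consecutive and
fraction components respectively), sub-007 the motion rule; sub-008's
deviant phase-encoding metadata marks it `needs_review` under criterion D
without excluding it — a human records that judgment explicitly:

```bash
taskfmri-qc run --bids-dir bids --out qc \
    --override sub-008 "acquired with the wrong protocol"
```

Single-run summaries are available per criterion; for the blocked run:

```bash
taskfmri-qc behavior bids/sub-005/func/sub-005_task-synth_events.tsv
```

```json
{
 "n_trials": 64,
 "n_responses_by_key": {"LEFT": 27, "RIGHT": 32},
 "n_responses_total": 59,
 "n_no_response": 5,
 "longest_no_response_run": 5,
 "accuracy_responded": 0.9322033898305084,
 "criterion_c_exclude": true,
 ...
}
```

59 of 64 trials were answered (93% correctly), but the five misses are
consecutive — the signature of a lapse in attention rather than task
difficulty — so the run is excluded.

The `fmri_qc.html` report shows per-run realignment and FD traces with the
threshold, censored frames, and trial onsets marked; axial montages of the
mean/sd/tSNR volumes side by side across runs; and the metadata-mismatch
list. `behavior_qc.html` shows the trial/response raster (one row per run,
responses at onset + response time, correctness ticks, per-key counts and
accuracy in the margin). `qc_decisions.json` stores every number printed
on the figures; the exclusion flag is re-derivable from the per-criterion
fields alone.

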