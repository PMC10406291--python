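# Methods

## Scope and model

The package operationalizes first-pass quality control for task fMRI: for
each run it computes quantitative motion and behavioral statistics, builds
the images a reviewer needs for the qualitative judgment, and consolidates
everything into a decision record. It works on preprocessed data — the
motion parameters and FD a preprocessing pipeline (fMRIPrep-style) wrote
to its confounds table, and the preprocessed BOLD series — because an
error anywhere in the pipeline surfaces in the preprocessed images, while
a clean raw image does not guarantee a clean preprocessed one.

Four exclusion criteria are evaluated per run:

| criterion | kind | rule (defaults) |
|---|---|---|
| A excessive motion | quantitative | frames with FD > 0.9 mm are censored; run excluded when censored fraction ≥ 0.20 |
| B improper task presentation | quantitative | excluded when usable trials / expected trials < 0.5 |
| C invalid task performance | quantitative + qualitative | excluded when longest no-response block ≥ 5 or no-response fraction > 0.40; single-button use flagged for review |
| D failed acquisition / preprocessing | qualitative | never automated — montages and metadata mismatches feed a recorded human override |

### Framewise displacement

FD is the Power-style backward-difference sum: absolute frame-to-frame
changes in the three translations (mm) plus the three rotation changes
(radians) converted to arc length on a sphere of radius 50 mm. FD of the
first frame is 0. The radius is configurable (`head_radius_mm`); 50 mm is
the convention of the confounds generator this package reads from, so
file-provided and recomputed FD agree. When the confounds file carries an
FD column it is used as-is (`fd_source="file"`), with the conventional
first-row "n/a" replaced by 0.

### Boundary conventions

The inequality directions matter at exact boundaries and are deliberate:

- censoring is **strict** (FD of exactly 0.9 mm is kept) — the rule is
  "more than 0.9 mm";
- run exclusion for motion is **inclusive** (exactly 20% censored is
  excluded) — "20% or more". The alternative strict reading exists in the
  field; inclusive is the more conservative choice and the fraction is
  configurable;
- criterion B is **strict** (exactly half of the trials usable keeps the
  run) — "fewer than half";
- criterion C's run-length component is **inclusive** (exactly 5 in a row
  excludes), its fraction component **strict** (exactly 40% keeps).

### Behavioral definitions

A "no-response" trial has no recorded response key; after loading, a trial
with a missing key also has missing response time and correctness (they
are normalized together, so either column identifies the same set). A
response with missing correctness still counts as a response. Accuracy is
computed among responded trials only, and suppressed (reported as
missing, not zero) when the correctness column is absent. Criterion B's
"usable" trial count defaults to the observed row count — the
run-truncation model — and accepts an externally supplied count; the
trial/censor overlap statistic (how many censored frames fall inside
trial windows) is computed and reported but deliberately not wired into
criterion B, since discounting censored trials changes the criterion's
meaning and should be an explicit analyst choice.

Repetitive-sequence detection (e.g. alternating keys) is not automated:
any rule would encode assumptions about the task that the inputs do not
carry. The raster plot makes such patterns visible for review; only
single-button responding is flagged (given ≥ 10 responses as evidence).

### Temporal summaries and montages

Mean, sd, and tSNR are computed voxelwise over the full run without
censoring. sd uses the sample (n−1) denominator, switchable to n for
cross-checking against toolchains that differ. tSNR at zero-sd voxels is
set to 0 and the count reported, so degenerate voxels are visible rather
than hidden as NaNs. No brain mask is applied — whole-image review is the
point; the phantom-recovery statistic in the tests restricts to the known
ellipsoid mask only because there the ground truth is defined inside it.

Montages take evenly spaced slices excluding the outer 10% of the chosen
axis (mostly background), tiled row-major, windowed to [0, 98th
percentile of nonzero intensities]; orientation is neurological and
labeled on the figure. These display choices are conventions, not
inferences — nothing in the inputs constrains them.

### Metadata consistency

Across ≥ 3 runs, each checked sidecar field (phase encoding direction and
repetition time by default) plus spatial shape and voxel size is compared
to the modal value; deviant runs are listed, and a field with no unique
mode is reported as "no consensus". This is review evidence for criterion
D. Criterion D itself can only fail through a recorded override carrying a
note — the decision record enforces that a qualitative exclusion always
documents the human judgment behind it.

## Synthetic data

The generator emulates the structure of a rapid two-condition button-press
task study: 64 trials per run, CONTROL/TASK in equal numbers, about 7
trials per minute with ±10% onset jitter, LEFT/RIGHT response keys,
response times lognormal with median 0.8 s and log-sd 0.3, configurable
accuracy (default 0.95). Missing-response patterns are planted exactly:
`block(k, start)` for consecutive lapses, `scattered(k)` spread so no long
run forms, `decaying(rate)` with miss probability growing linearly over
the run (a participant drifting off task). Motion traces are cumulative
Gaussian walks scaled to a peak drift amplitude (default 0.2 mm, safely
sub-threshold), plus spikes realized as persistent single-frame
translation steps so each planted FD value is exact by construction —
deliberately avoiding rotation-radius coupling in fixtures. Phantoms are
ellipsoids at baseline 1000 with in-brain Gaussian temporal noise of sd
baseline/tSNR-target and an exactly-zero background; the distortion
option shears/scales the ellipsoid and writes deviant sidecar metadata,
mimicking a run acquired under the wrong protocol. Identical seed and
spec reproduce every artifact bit-for-bit.

What the generator does **not** emulate: hemodynamic task responses,
spatial autocorrelation and vascular structure, apparent (respiratory)
motion, task-correlated motion, scanner drift in intensity. Passing tests
therefore demonstrate that the QC statistics and decision logic are
correct on data with known truth — not that the thresholds are optimal
for any particular real dataset; the thresholds are study-level choices
exposed as configuration.

## Numerical and design notes

- FD and all censoring counts are exact elementwise operations; the test
  suite pins them against independent brute-force oracles (elementwise
  |diff| sums, O(n²) substring scan, per-voxel Python loops) at 1e-12 /
  1e-10 tolerances.
- Trial membership of a censored frame uses the half-open window
  [onset, onset + duration); frame times are t·TR with TR taken from the
  sidecar or explicit configuration (an error if neither supplies it).
- Events tables are sorted by onset on load (stable sort); missing cells
  accept "n/a", "NA", or empty on read and are always written as "n/a".
- Adjacent-frame censoring extension (`censor_before`/`censor_after`) is
  available but defaults to 0: single-frame censoring.
- The decision JSON is deterministic (sorted keys, no timestamps unless
  requested), and `excluded` is a pure function of the four per-criterion
  fields, re-derivable from the record alone.
- Problem sizes in the test suite and acceptance script (100–200-frame
  runs, 12–16-voxel phantom grids, an 8-run cohort) are chosen so every
  planted effect is unambiguous at those sizes while the whole suite runs
  in seconds.

## Known limitations

- Criterion D remains human: the package will never exclude a run for
  image appearance on its own, by design.
- DVARS, respiratory filtering of motion parameters, registration-quality
  metrics, and GLM-based positive controls are out of scope.
- The events-table column dialect beyond onset/duration/trial_type/
  response/response_time/correct must be mapped by the caller
  (`column_map`); correctness semantics beyond binary are not modeled.
- Surface (GIFTI/CIFTI) inputs are not supported; all image QC is
  volumetric.
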