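# Methods

This note documents the model behind `gcalign`, the choices made where the
design was genuinely open, and what the synthetic test bed does and does not
establish about real data.

## Problem setting and data model

Input is one peak list per GC×GC/TOF-MS run: rows of (compound name, RT1 [s],
RT2 [s], area, fragment spectrum). Names come from the deconvolution
software's library search and are treated as useful but unreliable evidence:
they may be blank, wrong, or duplicated within a run. Spectra are sparse
non-negative intensity vectors on unit m/z channels (m/z is rounded to the
nearest integer on input, configurable off). The task is to group peaks
across runs by compound without any user-supplied RT window or similarity
cutoff.

Two peaks are compared by three quantities:

* `d` — Euclidean distance of their z-scored retention times. Each sample's
  RT1 and RT2 are standardised separately (sample mean/SD, n−1 convention;
  the convention is fixed for reproducibility, the choice is immaterial at
  realistic peak counts). Z-scoring balances the two dimensions (RT1 spans
  thousands of seconds, RT2 a few) and absorbs any per-sample shift or linear
  drift of the RT axis exactly.
* `Sim` — Pearson correlation of the two spectra laid out on the union of
  their m/z grids, absent channels zero-filled. Zero-filling preserves
  absent-ion evidence; Pearson is scale-invariant so intensities are used
  as-is. A spectrum constant on the union grid has no defined correlation and
  is scored −1 (a flat spectrum must never win a match).
* `mS = w·(1 − (d/d_max)²) + (1−w)·Sim` — the mixture similarity, with
  `d_max` the largest pairwise distance over all peaks of all samples, so the
  distance term lies in [0, 1]. Distances beyond `d_max` (possible for
  non-landmark pairs) are clamped with a warning.

## Stage 1: merging, landmarks, w

**Split-entry merging.** Deconvolution can report one metabolite as several
rows. Peaks chained within `RT1w = 5 s`, `RT2w = 0.1 s` and spectrum
correlation > `R0 = 0.95` are merged: connected components of the pairwise
gate (so chains merge transitively and the result is independent of input
order; window comparisons are inclusive). The representative's area is the
sum, its RTs the area-weighted means per dimension, its spectrum the
area-weighted average on the union grid, and its name that of the
largest-area member (deconvolution confidence tracks peak size). These three
windows are the only user-facing thresholds of the pipeline; the defaults
suit typical modulation periods and split-peak geometry and are config keys
(`merge.rt1_window`, `merge.rt2_window`, `merge.r0`). Area summation uses
compensated summation (`math.fsum`) so merging exactly inverts the
simulator's peak splitting.

**Landmark discovery.** The reference sample is the largest peak list (ties:
lexicographic id; a seeded `random` policy is available). For each target
sample, reference peaks are paired with same-name target peaks
*nearest-first in z-space within each name group*: all (reference,
candidate) distances of a name are ranked ascending and assigned greedily.
When every name is unique this is exactly per-peak nearest-neighbour
matching; when a name is duplicated (a mis-assigned neighbour carrying the
same library hit), ranking globally prevents the impostor from stealing the
true partner of a correctly-named peak — per-reference-peak greedy matching
in RT order was observed to do exactly that. Unnamed peaks never become
landmarks. Reference peaks that find no partner in some target drop out, so
surviving groups span all samples; the reference keeps its original
coordinates throughout.

**Contribution factor.** `w` is chosen from the candidate grid
(0.05, 0.1, 0.2, …, 0.9, 0.95) as the value maximising the summed `mS` over
all landmark pairs and all (reference, target) sample pairs; ties go to the
smaller `w`, favouring spectral evidence. One global `w` is kept (per-pair
scores are reported) because stage 2 needs a single parameterisation. Since
`mS` is affine in `w`, the optimum sits at whichever end the data favour;
with tight RT reproducibility the distance term usually wins (`w = 0.95`).

## Stage 2: thresholds, correction, matching

**Data-derived gates.** For every landmark pair the pipeline collects `d`,
`Sim` and `mS`, removes outliers with an iterative one-sided Grubbs test
(α = 0.05 per step, high tail for distances, low tail for similarities;
survivors keep their order; n < 3 or zero spread leaves data unchanged), and
sets `d0 = max` retained distance, `sim0 = min` retained correlation,
`mS0 = min` retained mixture similarity. Two implementation details matter:

* *Scale.* Grubbs assumes normality. Distances are tested raw, but
  correlations bunch against their upper bound and are strongly left-skewed,
  so `Sim` and `mS` are tested on the Fisher z scale (arctanh) and the
  retained extreme mapped back. On the raw scale the iterative test cascades
  into the legitimate tail and the resulting `sim0` rejects true matches.
* *Demotion.* Stage 2's premise is that landmark pairs are true alignments.
  A landmark group whose distance exceeds `d0` or whose correlation falls
  below `sim0` in any sample pair was flagged by the outlier rejection and
  contradicts that premise — the typical cause is a name mis-assignment
  matched across samples. Such groups are demoted to the stage-2 pool
  (recovered there on their actual evidence, or left unmatched) rather than
  kept as trusted rows, where they would also corrupt the RT-correction
  anchors. Demotion uses a 1e-12 epsilon so floating-point noise between
  identical replicates never demotes exact matches.

`mS0` is derived and reported but not used as an acceptance gate by default
(the matching steps test `d0` and `sim0`; `mS` only ranks);
`partial.enforce_ms0` adds it as a third gate.

**RT-shift correction.** Each target sample is warped onto the reference
frame, per dimension independently, by a local linear fit through the
retained landmark anchors (target RT → reference RT): LOESS of degree 1 with
tricube weights over the k nearest anchors, `k = max(5, 0.3·n)`, linear
behaviour beyond the anchor range. A smoother is used instead of exact
interpolation deliberately: anchors carry RT jitter, and interpolating
through two anchors that nearly coincide in the abscissa produces arbitrarily
large local slopes (z-space errors up to ~0.3 were observed), while the local
fit averages the noise away yet reproduces any consistent linear shift
exactly and tracks smooth non-linear drift locally. Corrected targets are
re-expressed in the reference sample's z frame. The correction is on by
default (`partial.rt_correction`); thresholds are always derived from the
*uncorrected* landmark statistics — after anchoring, landmark distances are
near zero by construction and would gate out everything — so in the corrected
frame the gates act as conservative upper bounds on genuine variation.

**Pairwise matching.** For each (reference, target) pair, candidates are all
combinations passing `d < d0` and `Sim > sim0` (an index on the first
z coordinate keeps the scan near-linear; `d0` itself bounds the search, no
pre-windowing). Same-name candidates are resolved first: a name occurring in
exactly one pair is accepted outright; a contested name keeps its largest-mS
pair; every acceptance purges candidates sharing either peak. Remaining
different-name candidates conflicting with accepted pairs are dropped, and
the rest are accepted greedily by largest `mS` (ties: smaller `d`, then
lexicographic peak id — all tie-breaks deterministic, so output is invariant
to input order). Purging operates on the remaining candidate pool, not on the
accepted set. Pairwise results merge into groups keyed by the reference peak;
every non-landmark reference peak yields one row with whatever targets
matched it. Compounds absent from the reference sample cannot be aligned — a
known limitation of anchoring all pairs at one reference.

## Evaluation

A compound present in all N samples is a positive (`Np`); a table row with a
member in every sample is a match (`Nm`). A full row is a true positive iff
every member traces to one and the same ground-truth compound; a row mixing
compounds counts as one false positive, with no partial credit. Then
`TPR = TP/(TP+FN)`, `PPV = TP/(TP+FP)`, `F1 = 2·TPR·PPV/(TPR+PPV)`, with
`FN = Np − TP`, `FP = Nm − TP`, and 0 reported on empty denominators. Rows
covering only part of the samples are reported separately and excluded from
the Np/Nm bookkeeping.

## Synthetic test bed

The generator emulates replicate runs of one mixture. Defaults — the study
conditions used by the acceptance analysis — are 100 compounds, 4 samples,
RT1 uniform on [300, 3000] s, RT2 on [0.8, 4.8] s, a per-sample linear RT
drift (offset SD 5 s / 0.05 s, slope SD 0.5 % / 1 %), RT jitter SD 0.3 s and
0.005 s, 10 % split-peak probability (2–3 sub-entries whose areas sum exactly
to the original and whose area-weighted RT mean equals the original RT, so
merging inverts the split), 5 % compound dropout, 10 % name corruption
(equally: blanked, swapped with the nearest-RT1 compound's name, random
string — exercising the same-name and different-name matching branches), and
multiplicative log-normal spectral noise with SD 0.1. Fragment spectra have
8–20 channels with a 999 base peak and intensities log-uniform over
2.5 decades, the decade-spanning pattern of electron-ionisation spectra;
this keeps replicate-pair Pearson correlation high, the property the mixture
similarity exploits. `constant` and `piecewise` (two-slope) drift models are
available. A fixed seed makes output byte-identical.

What the simulator does *not* model: chromatographic peak shapes and
co-elution, deconvolution failure modes beyond simple splitting, spectral
contamination between co-eluting compounds, heterogeneous instrument
configurations, or systematic RT distortions sharper than a two-slope warp.
Passing tests therefore demonstrate correct algorithmic behaviour under
controlled drift/noise/corruption, not performance on arbitrary instrument
data.

## Numerical and degenerate-input choices

* Sample SD uses n−1; z-transform requires ≥ 2 peaks and positive spread in
  both dimensions, else the sample is rejected as degenerate.
* `d_max` is computed once over all merged, transformed samples and reused in
  stage 2.
* Grubbs critical values come from the t distribution
  (`G = (n−1)/√n · √(t²/(n−2+t²))`, `t` at α/n for the one-sided test); this
  reproduces the published one-sided 5 % table for n = 3…30.
* An empty landmark set aborts the run with a diagnostic — no thresholds can
  be derived. A single-landmark run falls back to that pair's own values with
  a warning. If demotion would empty the landmark set, the set is kept.
* With a single input sample the "table" is that sample's peaks as singleton
  rows.
* All randomness (reference policy `random`, simulation) flows from one seed;
  the default policies are deterministic and need none.
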