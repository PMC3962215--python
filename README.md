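# gcalign

Two-stage landmark-based peak alignment for GC×GC/TOF-MS metabolomics.

Comprehensive two-dimensional gas chromatography coupled to time-of-flight
mass spectrometry characterises each analyte by two retention times (a long
first-dimension RT and a short second-dimension RT, both in seconds) and a
fragment-ion mass spectrum. Deconvolution software (e.g. ChromaTOF) turns each
run into a *peak list*: one row per detected peak with an assigned compound
name, RT1, RT2, peak area and spectrum. Retention times drift between runs —
temperature and pressure fluctuations, matrix effects, column ageing — so
comparing compound profiles across samples first requires *peak alignment*:
deciding which peaks in different runs are the same compound. Classical tools
gate candidates with a user-chosen RT window and a user-chosen spectral
similarity cutoff, and the right values change from experiment to experiment.

`gcalign` removes that tuning burden. It aligns peak lists in two stages and
derives every matching threshold from the data itself:

**Stage 1 (full alignment).**
Split entries of one compound are merged (area-weighted RT mean,
summed area). Retention times are z-scored per sample and dimension,
`RT_z = (RT − μ)/σ`, so both dimensions contribute comparably, and the
largest pairwise peak distance `d_max` is recorded. *Landmark peaks* —
compounds present under the same assigned name in every sample — are found by
nearest-neighbour matching in z-space against a reference sample. Peak pairs
are scored by the mixture similarity

```
mS = w · (1 − (d/d_max)²) + (1 − w) · Sim
```

where `d` is the Euclidean z-space RT distance, `Sim` is Pearson's
correlation of the two fragment spectra on their union m/z grid, and the
contribution factor `w ∈ [0, 1]` is chosen by grid search as the candidate
maximising the summed `mS` over all landmark pairs.

**Stage 2 (partial alignment).**
The landmark pairs are trusted matches measured under the same conditions as
everything else, so their statistics calibrate the gates for the remaining
peaks: after iterative one-sided Grubbs outlier rejection, `d0` is the largest
retained landmark distance, `sim0` the smallest retained spectral correlation
and `mS0` the smallest retained mixture similarity. Landmark groups flagged by
the outlier test are demoted back into the unaligned pool. Each target sample
is then warped onto the reference frame by a landmark-anchored local linear
fit per RT dimension, and remaining peaks are aligned pairwise: candidates
pass `d < d0` and `Sim > sim0`, same-name pairs are resolved first, and the
rest are accepted greedily by largest `mS`, never using a peak twice.
Alignment quality against a known ground truth is reported as
`TPR = TP/(TP+FN)`, `PPV = TP/(TP+FP)` and their harmonic mean F1, counting a
compound present in all N samples as a positive and a full table row as a
match.

A synthetic-data module generates multi-sample peak lists with known ground
truth (per-sample RT drift and jitter, split peaks, compound dropout, name
mis-assignment, spectral noise) for testing the whole pipeline.

## Worked example

Simulate a four-sample study at the default moderate-noise conditions, align
it, and score the result against the generated ground truth:

```console
$ gcalign simulate --out demo/data --seed 7
wrote 4 peak lists and demo/data/truth.csv

$ gcalign align -i demo/data -o demo/out
aligned 4 samples: 98 rows (58 landmark, 40 partial); w=0.95 d0=0.046 sim0=0.9389

$ gcalign evaluate --table demo/out/alignment.csv --truth demo/data/truth.csv
Np=87 Nm=87 TP=87 FP=0 FN=0
TPR=1.0000 PPV=1.0000 F1=1.0000 (partial rows: 11)
```

Reading the output: 58 compounds were present under one name in all four
samples and became landmarks; from their pair statistics the pipeline derived
a z-space distance gate `d0 = 0.046` and a spectral-correlation gate
`sim0 = 0.939`, and chose `w = 0.95` for the mixture similarity. The
remaining peaks were aligned in 40 partial rows. Of the 87 compounds truly
present in all samples (`Np`), all 87 were recovered as full rows with no
false positive (`TPR = PPV = 1`); 11 rows cover only a subset of samples
(compounds dropped from some runs) and are reported but not counted as
matches. `demo/out/alignment.csv` holds the compound table (one row per
aligned group, per-sample RT1/RT2/area columns) and `demo/out/report.json`
the calibrated parameters and per-stage counts.

The same pipeline is available as a library:

```python
from gcalign import SimConfig, generate, align_peak_lists, score

samples, truth = generate(SimConfig(seed=7))
table, report = align_peak_lists(samples)
print(score(table, truth))   # EvaluationResult(n_p=87, n_m=87, tp=87, ...)
```

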