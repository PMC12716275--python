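# Methods

This note documents the models, algorithmic conventions and default
parameters behind `sleepwarp`, the choices made where several reasonable
designs exist, and what the synthetic data do and do not establish.

## Spectral representation

Band powers are computed per non-overlapping 12-s bin with a DPSS
multitaper estimate. The time–bandwidth product is NW = 4 with K = 7
tapers (the standard K = 2·NW − 1 pairing), giving a spectral resolution
of ±0.33 Hz over a 12-s window — narrow enough that the 1-Hz-wide edges of
the δ band are respected. Band integration is a trapezoid over PSD bins
whose frequencies fall in [low, high); the five bands tile 1–30 Hz, so the
summed band power matches the total 1–30 Hz power up to integration
tolerance (tested against a periodogram oracle and against MNE's
multitaper implementation). Bins with more than 50 % masked samples are
flagged invalid but still estimated.

Artefact masking is window-based (1-s windows): a window is unusable when
its peak |voltage| exceeds 350 µV (the recording device's dynamic range),
when its line-length (mean |first difference| × fs, µV/s) exceeds a
threshold, or when it is flat-lined (line-length < 1 % of the night's
median — a disconnection). The line-length threshold defaults to 8× the
night's median windowed line-length, a robust self-calibrating choice;
`calibrate_linelength_threshold` offers the alternative of a high quantile
taken from a known-clean recording. Masking never alters sample values.

The σ-band envelope is the magnitude of the analytic signal of the
11–16 Hz band-passed trace (`mode="power"` squares it, for users who
prefer absolute power). Envelope spectra are Welch estimates on the
envelope decimated to 2 Hz, averaged over contiguous N2/N3 runs of ≥2 min
and restricted to <1 Hz, with enough frequency resolution (≤2 mHz) to
separate the ~0.22 Hz (slow, ~4–5 s) and ~0.022 Hz (infra-slow, ~40–50 s)
spindle periodicities.

## Open-ended DTW

Nights are 5×L matrices of per-night z-scored band powers between sleep
onset and final awakening, down-averaged to 60-s bins by default (≈480
bins for 8 h; the full 12-s resolution is available at ~25× the cost,
since each pairwise alignment is O(L²)). The local metric is the
Euclidean distance between 5-vectors. The dynamic program uses steps
{(1,0),(0,1),(1,1)} with no warping-window constraint (nights differ
grossly in length); the path is anchored at (0,0) (sleep onset is the one
fixed point) and terminates at the minimum accumulated cost over the
longer night's columns once the shorter night's last bin is consumed.
D is the accumulated cost divided by the number of path cells, so D = 0
iff the aligned feature vectors coincide — in particular for identical
nights and exact prefixes. For equal-length inputs both orientations are
evaluated and the smaller D taken, which makes the operation exactly
symmetric; the dynamic program is verified against exhaustive path
enumeration for short sequences.

Quality control mirrors longitudinal-recording practice: nights with
fewer than 1.5 NREM-REM cycles or with >20 % invalid bins inside the
sleep period are rejected with typed reasons (`min-cycles`,
`disconnection`); small interior gaps are linearly interpolated per band
so the warping input is gap-free. In cohort matrices, pairs of
consecutive calendar nights of the same subject are excluded
("non-adjacent" pairs only); the within- vs across-subject comparison is
a Student's t-test whose unit of analysis is the per-subject mean
(within) and per-subject-pair mean (across), avoiding pseudo-replication
of correlated night pairs.

## Barycenter averaging and clustering

OE-DBA initialises at the medoid night and iterates the classic DBA
update: align every member to the current average, then replace each
average bin by the arithmetic mean of all member vectors mapped to it
(bins unmatched by shorter members keep their previous value). Because
the objective here is the sum of *length-normalised* D — for which the
DBA update carries no monotonicity guarantee — iteration stops at
`max_iter` (10), at relative improvement < `tol` (1e-3), or at the first
non-improving update, keeping the recorded objective trace non-increasing
by construction. Archetype dendrograms use average-linkage agglomerative
clustering on the pairwise archetype D matrix with a flat cut at k = 2 by
default.

Stage-conditioned dissimilarity buckets each path cell's local cost by
the pair of scored stages it aligns. On clean synthetic cohorts the
optimal path essentially never aligns the most antagonistic stages (N3
with REM) — the mismatch is warped around instead — so that cell is
empty; with human-scored data it is populated by genuine scoring
disagreements. The populated cells show the expected ordering: same-stage
< neighbouring-stage (N2–N3) < REM-vs-NREM alignments.

## Point-process GLM

Transitions are modelled at 1-min resolution with a Poisson GLM on the
log conditional intensity: intercept, cumulative time in the current
stage (T_stage, minutes), and the five log10 band powers of the preceding
minute. Stages are collapsed to NREM = {N1, N2, N3} vs REM; wake bouts
break runs and contribute no rows. For horizons h ≤ 0 the design contains
source-stage rows, labelled 1 on the minute |h| ahead of a scored
transition; horizons h > 0 are detection horizons and use target-stage
rows labelled 1 on the h-th minute after the transition. Features are
standardised on the training fold only; coefficients are reported on both
the standardised scale (for cross-horizon comparison) and the original
scale with standard errors. λ maps to a per-bin transition probability as
p = 1 − exp(−λΔ), Δ = 1 min; AUC is rank-based, so this monotone mapping
does not affect it.

Cross-validation draws, per fold, a random half of the nights for
training and the rest for testing (night-level splits, never
within-night; 10 folds by default). Significance per horizon follows the
strict rule: the *minimum* full-model fold AUC must exceed both the
*maximum* trivial-model fold AUC and the *maximum* surrogate AUC, where
surrogates retrain the full model on labels circularly shifted within
each night (preserving label count and feature autocorrelation; 10–20
surrogates by default).

## Synthetic cohort generator

The generator is a semi-Markov stage process with stage-conditioned
log-normal band powers — the minimal structure reproducing every
qualitative dynamic the analyses target. All randomness descends from one
root seed via `SeedSequence(root, subject, night, stream)`.

Hypnograms: each night draws 3–5 cycles; cycle lengths are normal with
subject-specific mean (population 98 min) and SD 20 min, scaled ×0.94 for
the first and ×1.13 for the second cycle (the shorter-first/longer-second
pattern); cycles unfold N1 → N2 → (N3 ⇄ N2) → REM with an N3 share that
declines across cycles; REM fraction rises 10→36 % across cycles
("increasing" trend) or stays at 22 % ("fixed", the cluster-2 trait),
yielding ~25 % REM overall; brief awakenings overwrite N2 epochs with
per-night probability 0.5 and geometric durations (<5 min).

Band powers (12-s grid, log10 µV²): per-stage baselines with realistic
contrasts in *all five* bands (δ peaks in N3, σ in N2, α and β suppressed
in deep sleep and higher in wake/REM, θ intermediate). This matters for
the method, not just realism: per-night z-scoring rescales each band by
its within-night SD, so a band with near-flat stage structure would
contribute pure amplified noise to every alignment and drown planted
effects. On top of the baselines: δ in N2/N3 is multiplied by
(1 − 0.15)^cycle (homeostatic decline); within N2 runs σ and δ ramp up
together, within N3 runs σ decays while δ keeps rising (producing the
positive-N2/negative-N3 σ–δ correlations); σ is boosted by ×1.5 over the
3 min before each REM onset (the surge that carries the forecasting
signal; both parameters configurable); i.i.d. Gaussian log-power noise
with SD 0.1 (≈26 % power fluctuation per 12-s bin). The spindle-frequency
trait propagates mechanistically: a Gaussian spindle spectral bump
centred at the subject's spindle peak (13.5 Hz, or 12.3 Hz for cluster 2)
is split across the 12 Hz σ/α band edge, so slow spindles drain σ and
leak into α in N2/N3.

Raw EEG (207 Hz, optional): stage-coloured background noise, a 0.85 Hz
slow-wave carrier in N2/N3 with discrete high-amplitude slow-wave events,
and spindle bursts (0.9–1.4 s, Tukey-windowed) planted in trains gated by
the top quarter of the infra-slow cycle — within-train onsets ~4.5 s
apart, trains recurring every ~45 s. Spindle onset phases relative to the
carrier are von Mises draws whose concentration is solved (I₁/I₀
inversion) to hit the profile's PLV target, and onsets are micro-shifted
to land exactly at the drawn phase. Spindle amplitude is calibrated
self-consistently so that the envelope peak is 6× the *final* mean N2/N3
σ-envelope (the planted spindles themselves inflate that mean; without
the correction a "6×" spindle would sit below the detector's 5×-mean
threshold). Artefact injection adds high-amplitude noise transients
(0.3–1.5 s, 10× background SD) and flat gaps (2–8 s) at a Poisson rate
per hour, with ground-truth intervals.

What the generator does **not** emulate: realistic EEG waveform
morphology (no neural-mass dynamics, K-complexes, or microarousals),
inter-night dependence (each night is independent given the profile),
circadian modulation, scorer disagreement, and any correlation between
the spindle trait and other traits. Passing tests therefore establish
that the *algorithms* behave as designed on data with planted structure
— recovery of the planted contrasts, exactness and invariances of the
alignment, calibration of the detectors and GLM — not that effect sizes
on clinical recordings will match; cohort-level numbers reported for the
original device data are treated as direction-of-effect references only.

## Numerical conventions and edge cases

- DTW ties in the accumulated-cost backtrack prefer the diagonal step;
  with continuous-valued features, exact ties are measure-zero.
- Zero-variance bands abort z-scoring with an error naming the band;
  fewer than 2 valid bins likewise.
- The spindle detector fuses above-core excursions separated by <0.3 s
  (waxing–waning of one event) before applying the overlap rule, which
  discards both members of any pair of distinct candidates sharing
  samples (a merge alternative is available).
- Slow-wave "peak" is the positive peak of the 0.5–4 Hz filtered trace
  (phase 0 in the analytic-signal convention); PLV magnitudes depend on
  the slow-wave detector and phase convention and are interpreted
  qualitatively.
- Poisson GLM fits flag |standardised coefficient| > 15 as separation;
  non-convergence raises with the iteration count. Cross-validation folds
  with no training positives or single-class test labels record NaN AUC.
- Pipeline runs are deterministic given (config, seed): two runs write
  byte-identical numeric outputs (the manifest differs only through the
  output path). The config hash covers the scientific configuration,
  excluding the output directory.

## Problem sizes

Defaults are sized for a laptop-class single core: the demo cohort is 8
subjects × 10 nights, DTW at 60-s resolution (~3,100 pairwise alignments
in a few seconds via the numba-compiled dynamic program), DBA with ≤10
iterations, 10 cross-validation folds and 10 surrogates per horizon. The
raw-EEG analyses in the test suite use 2–3-h N2/N3-rich nights, which
plant several hundred spindles — ample for detector calibration.

## Persistence

Hypnograms, band powers, event lists and dissimilarity matrices are TSV;
reports, ground truth and model outputs JSON; dendrograms Newick. EDF
recordings are read through MNE; EDF *export* requires MNE's `edfio`
backend and raises a clear error when it is absent.
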