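# Methods

This note documents the models, numerical choices and known limitations of
`sotmr`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic sleep-EEG model

The generator (`sotmr.synthetic.generate_sleep_eeg`) emulates the signal
class the analysis stack assumes: N3 sleep containing high-amplitude slow
oscillations, spindles coupled to the SO up-phase, and 1/f background noise.

**SO waveform.** Each SO is one period of a raised-cosine biphasic template:
a negative (trough) half-wave followed by a positive (peak) half-wave, each
`0.5/f` seconds long for an SO frequency `f` drawn uniformly from the SO band
(default 0.5–1.5 Hz). The raised cosine starts and ends at zero with zero
derivative, and its trough and peak times are analytically known — that is
the reason for choosing a template over filtered noise: the generator can
hand every downstream stage an exact oracle. An asymmetry factor
(`so_updown_asymmetry`) lets the peak half-wave differ in duration from the
trough half-wave (default symmetric); it exists to probe why real Down-phase
cue means deviate from 180°.

**Amplitudes.** Trough amplitude is drawn from Normal(−130, 20) µV, with the
positive peak at 0.65 of the trough magnitude (≈ +85 µV). These defaults are
the generator's statement of the study conditions it emulates: the online
detector thresholds the *causally filtered* signal at −80 µV in both
polarities (the Down detector sees the inverted signal, so it needs real
positive peaks beyond +80 µV), and a functioning closed-loop night delivers
cues by the hundred in both Up and Down. A shallower, nominally plausible
choice (−100 µV, peak ratio 0.5) produces a night in which the Down detector
almost never fires — the causal band-pass attenuates an isolated SO transient
by roughly 30%, which is easy to underestimate. Both parameters are
config-exposed.

**Placement.** SOs are placed only inside N3 segments of the stage plan, as
a renewal process: gaps are a hard-core minimum (one maximal SO duration
plus 0.2 s, so templates never overlap) plus an exponential tail whose mean
makes the overall spacing equal `60/so_rate` seconds. Expected counts
therefore match the configured rate exactly, while spacing stays irregular.
Default rate: 8 SOs per minute of N3, a typical young-adult N3 density.

**Spindles.** With probability `spindle_prob_per_so` (default 0.5) a spindle
is attached to an SO: a Gaussian-windowed sinusoid at 9–16 Hz, 0.8 s long,
centred on the SO positive peak — the up-phase coupling the closed-loop
rationale rests on.

**Topography and noise.** A single source is mixed onto the scalp through a
fixed frontal-maximal Gaussian weight map centred on the F3/Fz/F4 centroid
and normalised so F3 (the detection channel) has weight 1. There is no
forward model; the map provides just enough spatial structure for
adjacency-aware cluster tests. Background noise is independent per channel,
spectrally shaped to `1/f` (exponent 1) and scaled to 15 µV RMS. Arousals
are metadata-only intervals (Poisson, 2/h) used by the stimulation gate;
they carry no special waveform.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume conduction and realistic channel
covariance, N1/N2/REM microstructure, K-complexes, sweat/movement/cardiac
artefacts, non-stationary SO trains, and any physiological coupling between
cues and subsequent oscillations. The pipeline's statistical calibration
(cluster FWER, decoding null, CI coverage) transfers to real data only to
the extent that its noise is exchangeable across the units being permuted or
resampled, which is the same assumption the methods themselves make.

## The closed-loop engine

Detection is strictly causal. The F3 signal passes a causal 2nd-order
Butterworth band-pass (0.5–4 Hz, forward only — the true online filter of
such rigs is rarely published, so the simplest stable IIR is used). When the
filtered trace (times the polarity: +1 for Up, −1 for Down) crosses −80 µV,
the engine tracks the running minimum; the trough is confirmed once the
trace has risen for 20 ms (`confirm_window_ms`). The cue fires at trough +
500 ms, which lands on the positive peak for Up and — because the Down
detector's "trough" is the real positive peak — on the next trough for Down.

**Trough-time refinement.** A causal filter distorts timing inside its own
passband, and not by a constant: a steady 1 Hz oscillation is detected
~44 ms early (steady-state phase lead of +16° at 1 Hz), while an isolated SO
template is detected ~10 ms late (transient delay). No constant offset
corrects both, so the engine refines the trough as the argmin of the *raw*
detection channel within ±100 ms of the filtered minimum — the
filtered-detect / raw-refine scheme hardware rigs use. The 100 ms lookahead
is well below the 500 ms cue delay, so causality is preserved: truncating
the recording at any time never changes the cues already delivered (tested).

**Gating and scheduling.** A cue is delivered only if its onset falls in an
N3 hypnogram epoch, neither onset nor sound offset overlaps an arousal, and
the pause since the previous sound's offset is at least 4 s (so onsets are
≥4.2 s apart with 200 ms sounds; an onset-to-onset mode is a config switch).
The night plan is blocks of the four sound sets (Experimental-Up, Novel-Up,
Experimental-Down, Novel-Down), set order drawn without replacement from the
24 permutations so orders balance across blocks; within a set the six sounds
play in hierarchy order A…F on consecutive qualifying SOs, and sets never
interleave. The detector's polarity always follows the next pending sound.

## Phase validation

Offline, the recording is band-passed 0.5–2 Hz with a two-pass (zero-phase)
Butterworth filter, order 2 per pass (order unstated in the underlying
protocol; 4 total is conventional), and the phase is the analytic-signal
angle: 0° at the positive peak of an in-band cosine, 180° at the trough.
Reports use degrees in [0, 360); internal maths uses radians. Circular SD is
`sqrt(−2 ln R)` and is reported in **radians** (values like 0.5 rad ≈ 29°
are the plausible scale for cue-phase spreads; 0.5° would not be). The
circular mean is flagged undefined when R < 0.1. Equality of circular means
uses the Watson–Williams F test when both samples have n ≥ 5 and pooled
resultant length ≥ 0.45, otherwise a permutation test on the angular
distance between the two means, flagged in the result.

## EEG pipeline

Preprocessing band-limits to 0.5–30 Hz with cascaded zero-phase high-pass
and low-pass Butterworth filters, order 4 per pass (order 2 leaves a 50 Hz
tone attenuated by < 20 dB, which defeats the purpose of the 30 Hz cut).
Linked-mastoid re-referencing applies when mastoid channels exist, otherwise
the original reference is kept with a logged warning. Artifact handling on
synthetic data reduces to a bad-channel list interpolated by the average of
the four nearest neighbours; ICA is out of scope.

Epochs span −1 to 3 s around cue onset; events without full coverage are
dropped and counted in the log. Time-frequency power uses Morlet wavelets,
4–20 Hz in 0.5 Hz steps, sampled −1 to 2.4 s in 50 ms steps; wavelet width
is `max(4, f/2)` cycles, so the slowest wavelet (4 Hz, 4 cycles, 1 s) never
runs past the 3 s epoch tail at the last time bin — which is exactly why the
grid stops at 2.4 s. Bins whose wavelet half-width overruns the epoch are
flagged in an edge mask rather than dropped.

Baseline normalisation is relative change, `(P − mean_bl)/mean_bl`, per
channel and frequency over −1 to 0 s, applied **after** averaging across
trials: dividing per trial is biased upward because `E[1/bl] > 1/E[bl]` for
a noisy single-trial baseline. The baseline mean excludes edge-masked bins
(they underestimate power and would bias the whole map positive).

## Cluster statistics

Per-bin one-sample t statistics (paired tests are one-sample tests on the
difference) are thresholded at the two-tailed t quantile for the
cluster-forming alpha (0.05) with df = n_subjects − 1. Clusters are
contiguous same-sign runs — for channel × frequency × time arrays,
4-neighbourhood in the frequency–time plane plus cross-channel links from a
distance-threshold adjacency graph (default 6 cm on the standard 10-20
positions, mean degree ≈ 6). Cluster mass is the summed t; the family-wise
null is the permutation distribution of the maximum |mass| under subject
sign-flipping (2000 permutations by default, seeded), and
`p = (1 + #{null ≥ observed}) / (n_permutations + 1)`. Zero-variance bins
(possible with planted constant effects) get a large finite stand-in t so
saturated effects report the permutation floor instead of NaN. Time-window
restriction (e.g. post-cue 0–2.4 s) masks cluster-forming bins. Band
summaries for topographies use theta 5–8 Hz and the broad spindle band
10–20 Hz.

## Decoding

Per time point, the feature vector is the 4–20 Hz band-passed amplitude of
all channels. Cross-validation is stratified 5-fold with 2 repetitions,
seeded; the fold split is fixed across time points within a repetition so
the time course is comparable bin to bin. Within each training fold —
never on the test fold — features are z-scored and projected on a
20-component PCA basis (per-fold PCA is the leakage-safe reading; a global
fit is the only alternative and was not taken). Classifiers are LDA and a
linear SVM; ACC is fold-size-weighted accuracy at the native decision rule
and AUC is computed from decision scores in rank (Mann–Whitney) form.
Group-level inference stacks per-subject time courses and runs the cluster
machinery with chance (0.5) as the null value. A `time_decim` switch trades
the native 2 ms grid for coarser grids in simulation studies; analyses in
the test suite use 50 ms.

## Behavioural model and statistics

The behavioural generator draws per-trial Bernoulli responses with
`logit(p_cell) + u_subject`, `u ~ Normal(0, 0.3)` on the logit scale shared
across cells. The default accuracy table encodes the emulated design:
premise accuracy in the mid-to-high 70s% before sleep (74.7/79.2/79.6% for
Down/Control/Up), flat overnight, declining by two weeks; inference pairs
only from the morning test, with the Up condition strongest at the
2nd-degree pair, the Down condition below chance the next morning (46.4%)
and recovered two weeks later (58.6%); anchor pairs easy everywhere. These
cells are the generator's definition of its study conditions, not fitted
quantities.

Chance-level tests gate between the one-sample t and the Wilcoxon
signed-rank by a Shapiro–Wilk test at alpha 0.05 (logged); a cohort exactly
at chance is flagged degenerate. The decoding–behaviour link is a Pearson
correlation whose CI is a BCa bootstrap over paired subject resampling —
chosen over the percentile flavour because percentile intervals undercover
at follow-up-sized cohorts (n ≈ 17), and the package's own coverage
simulation is the arbiter — with a percentile fallback when the BCa
correction degenerates (perfectly collinear input). The p value comes from
an index-permutation null (two-sided on |r|), and multiplicity over the
declared family of classifier/metric × behaviour combinations uses the
Holm bound (`holm_correct` implements the full step-down procedure for
vectors of p values). Robust trimmed-means RM-ANOVAs are intentionally not
re-implemented; `score_behaviour` exports tidy tables shaped for the
established routines that do.

## Transitive-inference protocol choices

"Over 66%" in the learning exit criterion is read strictly (> 66.0; a
config flag relaxes it to ≥). The evaluation window is the last three
completed blocks counting from block 1, switchable to counting only blocks
≥ 3 — the protocol description supports either reading. Test blocks
interleave the three hierarchies' trial streams at random while enforcing
the no-shared-item constraint within each stream; the late test shows each
of the 9 pairs once plus one repeat per hierarchy to keep 10 trials per
hierarchy per block. The trial scheduler falls back from bounded random
reshuffling to randomised backtracking, so a satisfiable constraint set
never fails by bad luck.

## Problem sizes in the test suite

The acceptance-style suites run at sizes chosen to make their statistical
assertions sharp while staying desk-scale: cluster FWER calibration uses
500 simulated 12-subject × 200-bin datasets at 500 permutations; decoding
recovery uses 20 cohorts of 8 subjects × 40 trials on a 50 ms grid with a
60-channel montage; behavioural calibration uses 200 subjects; CI coverage
uses 500 simulations at n = 17. Rates and tolerances quoted in those tests
(FWER 0.05 ± 0.02, coverage 0.95 ± 0.03, ±15° phase error, AUC 0.5 ± 0.03)
are binomial/Monte-Carlo bands at those sizes.

## Known limitations

- The generator's SO trains are stylised; detector performance on real,
  artefact-laden sleep EEG will be worse than the simulated figures.
- The online filter, its order, and the rig's internal latencies are
  modelled generically; absolute phase offsets of a few degrees between
  this replay and any specific hardware are expected.
- Watson–Williams assumes comparable concentration in both samples; the
  permutation fallback is exact but slower and tests mean direction only.
- EDF/BrainVision reading requires MNE at runtime; recordings are otherwise
  persisted as NPZ + TSV sidecars, and no EDF writer is provided.
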