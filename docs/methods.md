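# Methods

This note documents the models, conventions and design choices behind
`ersp_attn`, in the order data flow through the pipeline.

## Task paradigm

One condition is a schedule of 500 stimuli (default), one every 2 s, each
shown for 1 s: one of five patterns at one of five vertical screen
positions, every (pattern, position) pair occurring equally often
(`n_trials` must be divisible by 25). Targets follow the condition rule —
in the *spatial* condition all trials at designated target *positions*, in
the *nonspatial* condition all trials showing designated target *patterns*.
With two designated ids the default schedule has 200 targets and 300
nontargets. Which ids are designated is a free parameter (`target_ids`),
since target assignment is part of the experimental counterbalancing rather
than the analysis. Trial order is a seeded permutation; onsets start at one
inter-stimulus interval so the first epoch has a full pre-stimulus baseline.

## Synthetic electrode atlas

Real subdural grids require MRI/CT coregistration and normalization; the
package instead scatters electrodes uniformly inside eight axis-aligned
boxes in a Talairach-like frame, one per (hemisphere, region) group for the
frontal, superior parietal (SPL), inferior parietal (IPL) and temporal
regions. The default per-group counts (L/R frontal 166/186, IPL 20/30,
SPL 7/41, temporal 56/22; 528 total) reproduce the region sizes of a
realistic multi-patient subdural cohort, so the counting statistics operate
at realistic and *asymmetric* group sizes — the small left SPL (7) is
exactly the kind of group where the chi-square/Fisher switching rule
matters. `ElectrodeAtlas.subsample` shrinks the atlas proportionally while
keeping every group non-empty (desk-scale demos).

## Signal model of the generator

Each channel is independent and is the sum of:

* **1/f^β background** — spectrally shaped white noise; default β = 2.5
  (power slope), RMS 5 µV. Within the ECoG-typical 2–4 range, β = 2.5 is
  chosen high enough that each band's *oscillation* dominates the band's
  total power (see below).
* **Per-band oscillations** — band-pass filtered white noise (4th-order
  Butterworth, forward–backward) at band RMS amplitudes
  theta 2, alpha 6, beta 3, low gamma 1.5, high gamma 1.2 µV. Narrowband
  noise rather than sinusoids keeps the phase random across trials: the
  injected power changes are non-phase-locked, which is exactly what ERSP
  is designed to see and what trial-averaged evoked potentials cancel.

An **effect** multiplies one band's oscillation envelope by √(power ratio)
inside a post-stimulus latency window on every trial of the affected
(hemisphere, region) group. The plateau covers the full stated window; 50 ms
raised-cosine on/off ramps sit just *outside* its edges. Two consequences,
both deliberate: (i) a direct band-power measurement inside the window
recovers the injected ratio without ramp erosion, so the generator's ground
truth is well-defined at the stated latencies; (ii) the amplitude defaults
above keep the background's share of each band small enough that the
recoverable band-power ratio stays within a few percent of the injected
ratio (e.g. alpha: oscillation ≈ 7.2 µV²/Hz vs background ≈ 0.12 µV²/Hz at
10 Hz). Effects must end at least one ramp before the next stimulus.

Default condition effect maps: spatial — alpha ERD (ratio 0.5) and high-
gamma ERS (ratio 2.0) in right SPL; nonspatial — alpha ERD in right IPL
(0.5) and bilateral frontal (0.6); all at 400–600 ms, the analysis's focus
window. Magnitudes are generator parameters chosen to be strong but
realistic single-region effects, not measured values.

**Artifacts**: a Bernoulli fraction of trials (default off; 2% in the
pipeline default, 10% in stress tests) receives a 100 ms, 150 µV biphasic
transient on one to three random channels at a random epoch latency. The
generator returns the corrupted trial indices and per-effect affected
channels as ground truth.

**Behavior**: target trials are hits with probability `hit_rate` (default
0.92, typical sustained-attention performance); hits get a response time
drawn from a truncated normal (default 0.9 ± 0.2 s, floored at 0.2 s),
misses and nontargets get none. These feed the rank-sum behavioral
comparison; they do not influence the neural signal.

What the generator does **not** emulate: volume conduction and channel
covariance, physiological artifact structure (eye/muscle), epileptiform
activity, non-stationary background drift, and evoked (phase-locked)
components. Passing tests therefore demonstrate correctness and calibration
of the *analysis machinery* under a known spectral model — not robustness
to every property of clinical recordings.

## Preprocessing

1–200 Hz band-pass, 4th-order Butterworth applied forward–backward (zero
phase, so latencies are preserved; ≈48 dB attenuation one octave outside
the edges); common average reference over retained channels (an exclusion
list for channels with epileptiform discharges is applied before the mean);
2000 ms epochs from −500 to +1500 ms; automated noisy-epoch rejection.
Rejection reduces each epoch × channel to its peak absolute amplitude,
robust-z-scores the peaks across epochs per channel (median / 1.4826·MAD),
and flags an epoch when any channel exceeds the threshold (default z = 6).
This replaces manual review and ICA-based artifact removal with a
deterministic, thresholded surrogate; flags are monotone in the threshold,
and z = 6 recovers ≥95% of the generator's injected transients while
flagging ≲1% of clean epochs at z = 8.

All intervals are half-open `[start, end)`; epochs are indexed in ms
relative to stimulus onset.

## Time–frequency analysis

A 500 ms Hann window sliding in 7.5 ms steps tiles the 2000 ms epoch into
exactly 200 bins: window starts are the points k·7.5 ms in the half-open
interval [0, 1500) ms. (The fractional 7.5-sample hop is rounded per
start.) Each tapered 500-sample segment is zero-padded to 1000 samples —
1 Hz spacing, interpolating the native 2 Hz resolution — and converted to a
one-sided power density; the 2–150 Hz range gives 149 bins. A bin's
timestamp is its window center.

ERSP is normalized **per trial**: the baseline of trial k at frequency f is
the mean power over bins whose windows lie wholly inside the 500 ms
pre-stimulus interval — at the default geometry exactly one bin. This keeps
the baseline strictly uncontaminated by post-stimulus activity at the cost
of a noisy denominator; the noise is shared across all bins of a trial and
frequency, cancels in expectation (E[log P − log P₀] = 0 under
stationarity), and is absorbed by the across-trial t-test. It is the main
variance term at small trial counts, which is why the packaged experiments
run at 50–300 trials.

Significance: two-sided one-sample t-test of the per-trial dB values
against 0, per bin, Bonferroni-corrected with family = all 200 × 149 bins
of the electrode (per-electrode familywise control). The family size is a
parameter: the band × window reduction below uses family = 40 (5 × 8
cells), matching its coarser grid. Bins with zero across-trial variance —
structurally, the baseline bin itself — are marked non-significant with a
warning.

Temporal smearing: a 200 ms effect probed with a 500 ms window never fills
any bin's support, so the STFT reads an injected −3.01 dB ERD as roughly
−2.3 dB in the 400–600 ms cell. The acceptance experiments therefore report
effect *recovery* with a matched-resolution periodogram oracle (200 ms
segments at the effect latency, expectation −3.01 dB) alongside the
pipeline's smeared cell value; *detection* and all counting statistics use
the pipeline unchanged.

## Band–window reduction and classification

Bands: theta 4–7, alpha 8–13, beta 13–30, low gamma 30–50, high gamma
70–150 Hz. The printed edges overlap at 13 and 30 Hz; membership is
half-open on the upper edge (13 → beta, 30 → low gamma) except high gamma,
which includes 150 Hz. On the 1 Hz grid, 7 Hz and 50–69 Hz fall in gaps and
belong to no band. Windows: eight 200 ms windows, onsets every 100 ms from
0 to 700 ms; bins are assigned by center membership.

Each cell's statistic is the t-test on the cell-averaged per-trial dB
values (not a vote over bin-level masks — the averaged statistic is
well-defined and more powerful), Bonferroni family 40. An electrode is
labeled ERD in a cell if significantly negative in a low band (theta,
alpha, beta) and ERS if significantly positive in a gamma band; significant
changes of the non-quantified sign are reported in the raw summary but map
to "none" for counting.

## Counting statistics

Fractions of significant electrodes per (condition, hemisphere, region,
band, window) are compared as 2×2 tables (significant / not × group) for
three contrast families: task vs task, left vs right, right SPL vs IPL.
Test choice: Pearson chi-square when every expected count exceeds 5,
otherwise Fisher's exact test, both two-sided, uncorrected at P < 0.05.
The chi-square is used *without* continuity correction: at the electrode
counts involved here the Yates correction deflates the null rejection rate
to ≈3.4% where the uncorrected test sits at ≈5%, and calibration of the
contrast machinery is one of the package's acceptance properties. The
strict "> 5" rule also sends borderline tables (expected counts exactly 5,
e.g. [[10,0],[0,10]]) to the exact test. `contrast(..., method=...)`
forces either test. ERD and ERS are always counted as separate families.

Behavior (reaction time, hit rate) is compared with a two-sided Wilcoxon
rank-sum test: exact rank permutation null for tie-free groups of ≤25,
normal approximation with tie correction otherwise; identical constant
samples return P = 1 with a warning.

## Topographic maps

Vertex value = value of the Euclidean-nearest electrode × max(0, 1 −
d/r_fade), ties to the lowest electrode id; r_fade defaults to 15 mm
(≈1.5× typical inter-electrode spacing), giving the familiar
"color fades with distance from the nearest electrode" construction a
concrete, documented fade law. A generic
half-ellipsoid mesh stands in for a template cortical surface; any
(vertices, triangles) pair can be substituted. Panels are orthographic
lateral projections, diverging colormap symmetric about 0 dB (ERD blue,
ERS red), rendered without antialiasing so identical inputs give
byte-identical files.

## Pipeline, configuration, determinism

`PipelineConfig` (pydantic) validates every parameter before any compute —
filter edges against Nyquist, baseline strictly pre-stimulus, effect
specifications, trial selection — and each run writes the resolved
configuration next to its outputs. Analysis defaults to nontarget trials
(no motor response in them); `trial_selection` switches this. One seed
drives paradigm, noise, artifacts and condition-level child seeds
(`numpy.random.SeedSequence`); fixed seed ⇒ bit-identical arrays and
byte-identical TSV outputs. Per-channel spectra are computed in single
precision in trial chunks, bounding memory at ≈100 MB regardless of channel
count.

## Packaged experiment sizes

The self-check experiments (`ersp_attn.experiments`, also run by
`scripts/acceptance.py`) use sizes chosen to give stable statistics on a
single CPU in minutes: null calibration over 500 electrodes × 50 trials
(familywise rate, plus contrast calibration on 12 random half-splits × 40
cells using uncorrected per-cell significance, since Bonferroni-corrected
null labels are almost all zero and would make every table degenerate);
ERD recovery at the paradigm-scale 300 trials on six affected electrodes;
detection over 10 replicates × 300 trials; SPL-vs-IPL discrimination over
10 replicates × 50 trials on the full 41-SPL/30-IPL right-parietal counts.

## Known limitations

* The single wholly-pre-stimulus baseline bin makes single-trial ERSP noisy
  at the default geometry; a longer pre-stimulus interval (or a
  center-based baseline, at the cost of post-stimulus contamination) would
  reduce this.
* Bonferroni over 29 800 strongly correlated bins is very conservative;
  the measured familywise rate under the null is far below 5%.
* Channels are simulated independently; contrasts that would be affected by
  inter-channel correlation (shared reference, volume conduction) are only
  calibrated under independence.
* The STFT's 500 ms window under-reports effects briefer than the window
  (see "Temporal smearing" above).
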