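# Methods

This note documents the statistical procedures implemented in `cahub`,
the assumptions they rest on, the defaults of the synthetic generators,
and the numerical choices made where the procedures left room.

## Data model

All analyses start from a binary onset raster `A ∈ {0,1}^{n_cells × n_frames}`
with a frame rate `f_s` (slices are simulated at 5 Hz, in vivo sessions
at 9.85 Hz).  Frames are 0-based; every interval is half-open
`[start, end)`.  Binning is epoch-wise: bins restart at each epoch start
and trailing partial bins are dropped, so no bin straddles an epoch
boundary.

The universal null model is the **circular-shift surrogate**: each
cell's row is rotated by an independent uniform offset in `[1, T)`
(offset 0 excluded whenever `T > 1`).  This preserves each cell's rate
and autostructure exactly while destroying cross-cell timing.

## Slice pipeline

**GDP detection.**  The per-frame population onset sum is thresholded at
the 99th percentile of the sums pooled over 1000 circular-shift
surrogates (linear-interpolation percentile, computed from an integer
histogram; strictly-above frames are candidates).  Candidates are kept
greedily by height subject to a minimal separation (default 1 s); the
greedy-by-height rule makes the detected set at a high percentile a
subset of the set at a lower one.  By construction ~1% of frames exceed
the threshold on featureless data, so the detected rate overestimates
the true rate by the nominal surrogate rate; the detection benchmark in
the tests therefore uses sharp-recruitment sessions (onset jitter SD
0.3 s) where this bias is a small additive constant, and the detected
rate falls inside the Poisson 95% band of the generative 0.02 Hz.  When
recruitment jitter is comparable to the merge radius (the locking
sessions below use SD 0.6 s) flank frames can split into extra detected
bursts; the locking statistic is insensitive to this because its
normalisation constant cancels between observed data and surrogates.

**Frequency effect.**  Within each of pre / stim / post, the average IGI
is computed in windows of `t_s` frames (300 or 400) opened at each
burst, discarding windows that overlap the epoch boundary; the three
distributions are compared pairwise with two-sample KS tests at
α = 0.05.  "Increase in frequency" means the pre-vs-stim test is
significant with a smaller stim median.  A session whose control-IGI
coefficient of variation exceeds 1 is flagged as not includable
(unstable baseline rhythm); epochs with fewer than two windowed values
make the comparison not assessable.

**Phase.**  With `Δt` the mean control IGI, the i-th burst (1-based) is
expected at `i·Δt` and its phase is `Φ_i = (t_i − i·Δt)/Δt` cycles.  A
session is excluded when the control-condition drift exceeds ±2 cycles.
The identity (periodic train → Φ ≡ 0) and translation covariance
(shifting all times by `k·Δt` shifts Φ by `k`) hold exactly.

**Locking test.**  The observed statistic is the highest peak of the
population onset histogram over post-stimulation trials (trial length
2.5 or 5 s, 1-frame bins), divided by the number of detected bursts in
the stimulation epoch.  Surrogates repeat the construction on the
concatenated control + post frames with 100 pseudo-protocol start
frames drawn uniformly without replacement (same trial count, length
and spacing), divided by the same constant — the normalisation scales
peak heights for comparability across sessions and cancels from the
significance comparison.  Significance requires the observed peak to
fall within the top 5% of surrogate peaks (`p = #{surrogate ≥ observed}/100`).

*Calibration.*  The 100 surrogate spans are drawn from one finite
segment and are therefore correlated; when histogram peaks are dominated
by single sharp burst spikes the effective number of independent
surrogates drops to roughly segment/span and the test becomes
anticonservative (we measured ~6–7% type-I at recruitment jitter
≤ 0.4 s).  The default slice conditions are chosen so that the peak
statistic is noise-dominated and decorrelates quickly: 1500 s sessions
split 45/10/45% into pre/stim/post, recruitment jitter SD 0.6 s,
background onsets at 0.08 Hz/cell.  Under these conditions the measured
type-I error is 5.3% (21/394 null sessions) and a planted effect
(latency 2.2 s, lock probability 0.9) is detected in every run with the
latency recovered to ±0.2 s.

## In vivo pipeline

**Epochs.**  Locomotion epochs are maximal runs of treadmill-sensor
deflection; rest epochs are movement-free runs strictly longer than
200 ms.  Shorter movement-free gaps belong to neither set.

**Locomotion-ON.**  Method 1: 10 s onset-aligned PSTH at 1-frame bins
(~101.5 ms; the window is stated by the procedure, the bin width is our
choice of the finest available resolution), z-scored against the bins
ending before −200 ms; significant if two consecutive bins from −200 ms
onward exceed Z = 2.  Method 2: the locomotion/rest spike-count ratio
against the per-cell 95th percentile of the same ratio under 1000
circular shifts; a half-count (+0.5) regulariser keeps the ratio finite
for cells silent at rest.  A cell is locomotion-ON if either test
passes.

*Calibration caveat.*  On unmodulated Poisson cells the ratio test runs
at its nominal 5%, but the onset test runs at ~8% rather than the
Gaussian-independence expectation of ~2.6%: per-bin counts are
Poisson-skewed, and all test bins share one baseline mean/SD estimated
from ~47 bins, which correlates their exceedances.  The union of the
two tests therefore false-positives at ~12% on null data, essentially
independently of firing rate (sparse rates are worse — a single-spike
bin can exceed Z = 2).  The modulation contrasts the pipeline is used
for are far larger than this, but absolute locomotion-ON proportions
should be read with that base rate in mind.

**SCEs.**  Rest-restricted 200 ms bins; the population count is
thresholded at the 99th percentile of per-bin sums pooled over 1000
circular-shift surrogates of the binned matrix; strictly-above bins are
kept greedily at ≥ 1 s separation.  SCE-ON: 4 s SCE-aligned Z-PSTH at
1-frame bins, baseline = the pre-event half-window, significant iff the
zero-lag Z strictly exceeds 3 (cells with zero baseline variance are
flagged indeterminate).  On Poisson rasters (100 cells, 0.5 Hz, 10 min
rest) the suprathreshold-bin fraction is 0.6–0.7% — slightly below 1%
because counts are integers and "above" is strict.  The calibrated
generator reproduces SCE rates of ~0.08 Hz of rest.

**Assemblies.**  Rest counts (200 ms bins) are convolved with a
Gaussian kernel (SD 1 bin, circular boundary — circularity makes the
smoothing commute exactly with circular shifts, so the shuffle
threshold can roll the preprocessed matrix) and z-scored per cell.  The
number of significant patterns is the count of PCA eigenvalues above
the maximum eigenvalue over 500 shuffled matrices (200 in the heavier
test loops); patterns are FastICA components of the PCA-projected data,
back-projected, unit-normalised, sign-aligned so the largest-magnitude
weight is positive.  Activity is the zero-diagonal quadratic form
`R_k(t) = (w_k·z(t))² − Σ_i w_ki² z_i(t)²`.  Per-cell modulation
cross-correlates raw binned counts with each activity over ±4 s,
averages across assemblies, and thresholds at the per-cell 95th
percentile of circularly shifted correlograms — computed exactly, since
every shifted correlogram is a window of the single full circular
cross-correlation — with two consecutive of the five central bins
required.

**Connectivity.**  Pair lags are the frame-quantized time differences
of B's spikes within ±1 s of each A onset.  Exclusions, in order:
sparse (< 20 samples); uniform — an exact KS test obtained by dithering
the quantized lags by ±half a frame (randomised PIT; testing raw
quantized values against a continuous uniform is anticonservative
through ties and the unreachable window edges); zero-centred —
|mean lag| smaller than one frame period.  The zero-centred rule is
deliberately mean-based rather than gated on a normality test: the
realistic zero-delay distributions (a transmission-jitter bell over a
uniform background, as produced by common drive or shared events) are
strongly leptokurtic, so a fail-to-reject-normality gate never fires on
exactly the pairs the rule exists to remove.  The D'Agostino–Pearson
p-value is still computed and reported per pair as a shape diagnostic.
Retained pairs contribute one directed edge oriented by the sign of the
mean lag.

**Hubs.**  A cell is a hub iff it (1) projects to ≥ 5% of the cells in
its field of view, (2) has an out-degree at or above the 95th
percentile of the out-degree distribution pooled across all fields of
view, and (3) has betweenness centrality (directed, normalised) at or
above the pooled 80th percentile.  Comparisons are inclusive (≥): in a
network whose only structure is one connected cell, all betweenness
values are zero and a strict rule would flag no hubs at all; the
inclusive rule keeps the hub set monotone in the criteria.

**Group statistics.**  `matched_subsample_test` draws, per field of
view, as many untagged cells as there are tagged cells (without
replacement), recomputes the statistic (proportion or mean) 1000 times,
and calls the tagged value significant when it exceeds the surrogate
95th percentile (a two-sided 2.5/97.5 variant is available; the
upper-tail rule is the operational default).  Under random tagging at
the study scale (9 tagged vs 776 untagged in 7 fields of view) the
measured significance rate is 4.6–5.0%.  `fisher_exact_test` is the
exact two-sided test under the sum-of-≤-probability convention
(delegated to `scipy.stats.fisher_exact`; an exhaustive hypergeometric
enumeration serves as the independent oracle in the tests); a table
with a zero margin returns p = 1 by convention.

## Synthetic generators

`gen_slice_session` produces background Bernoulli onsets (homogeneous
Poisson thinned to one onset per frame), Poisson burst times, per-burst
participation (default 80%) with normal onset jitter, and a three-epoch
stimulation protocol (pulses at 0.1 Hz, 5 s trials inside the stim
epoch).  The hub effect is either `frequency` (burst-rate multiplier
during stimulation) or `locking`, modelled as entrainment: spontaneous
bursts are suppressed during the stimulation epoch and replaced by
stimulation-triggered bursts at the given latency/probability —
stimulation redirects the rhythm rather than adding to it.

`gen_invivo_session` alternates exponential rest (mean 20 s, floored at
2.5 s so every rest bout is unambiguous and can host an SCE with a 1 s
flanking margin) and locomotion (mean 10 s, floored at 0.5 s) bouts;
cells fire at 0.4 Hz baseline, a configurable fraction gains a rate
multiplier during locomotion; SCEs are Poisson within rest at 0.08 Hz
with ≥ 1 s margins and separation; assembly activations place joint
member spikes on single rest frames away from bin-dropped epoch tails;
hub sources are echoed by their targets at a fixed lag (default 300 ms)
with per-spike transmission jitter (SD 1 frame) and probability.
Identical spec + seed yields bit-identical sessions, and ground truth
is returned as a JSON-serialisable dict.

What the generators deliberately do **not** model: fluorescence
dynamics and spike-inference errors (the pipeline starts at onset
rasters), imaging noise and motion, non-stationary firing rates,
overlapping assemblies, and polysynaptic network structure.  Passing
recovery tests therefore show that the statistics recover the planted
structure under idealised rasters with realistic rates and timing — not
that upstream spike inference is reliable.

## Problem sizes used by the test suite and acceptance script

Slice calibrations run 150–200 null sessions and 50 recovery sessions
of 1500 s each; the SCE null uses 20 rasters of 100 cells × 10 min; the
assembly recovery uses 25–50 sessions of 150 cells × 20 min with 200
eigenvalue shuffles; connectivity recovery uses five 30-min sessions of
100 cells at the sparse-firing rate (0.04 Hz) where pair tests are
well-posed; the matched-subsampling null uses 500 datasets × 1000
bootstrap draws.  These sizes give each rate estimate a standard error
small relative to its acceptance band while keeping a full run within a
few minutes on one CPU.

## Known limitations

* The locking test inherits correlation between its 100 surrogate
  spans; in regimes with very sharp, sparse bursts it is mildly
  anticonservative (see calibration above).
* The onset Z-PSTH locomotion test has an elevated per-bin false-positive
  rate at frame-resolution bins (see caveat above).
* Connectivity inference assumes stationary rates; rate co-modulation
  (e.g. shared locomotion drive) can create lagged correlations that
  are real but not synaptic.
* Hub percentile criteria are degenerate in nearly empty graphs; the
  inclusive comparisons handle them predictably, but hub flags from
  graphs with a handful of edges should not be over-interpreted.
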