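# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package, in the order data flows through it.

## Synthetic recordings

The generator produces data with the statistical structure the analysis
assumes, plus the ground truth needed to verify every stage. It is a
statistical emulator, not a biophysical model: no conductances, anatomy or
neuromodulation are simulated, and passing tests demonstrate correctness of
the *estimators* under the stated generative model, not physiological
fidelity of any particular dataset.

**Coupled LFP pair.** Each channel is a noise-driven AR(2) resonance at the
theta frequency (default 7 Hz, pole bandwidth 2 Hz) superposed on 1/f
background noise (spectrally shaped white noise, exponent 1, flat below
1 Hz), sampled at 2 kHz and scaled to ~50 µV RMS. The oscillator-to-
background RMS ratio (`snr`, default 1) keeps coherence well below 1 so
jackknife errors are exercised. Directed coupling adds the *theta-oscillator
component* of the source channel, delayed by `coupling_delay` (default
13 ms, the conduction-latency scale of the cerebello-prefrontal pathway)
and scaled by `coupling_gain` (default 0.8), to the target. Coupling the
component rather than the whole signal is deliberate: both channels have
proportional broadband spectra, so whole-signal coupling would produce
frequency-flat coherence, whereas the recordings this emulates show
band-limited theta coherence. The true underlying coupling strength is
unknown; the default places theta coherence in a detectable mid-range
(~0.4–0.6 band average).

**Speed traces.** Rest level ~1 tracker unit (jitter SD 0.4) alternating
with gamma-distributed locomotion bouts (mean 8 s, ~3/min) at level 8
(jitter 1.5), 25 Hz video rate. These spreads make rest and running
separable by the z > 0 rule while leaving frame-level ambiguity for the
merge/min-duration logic to handle.

**Stimulation protocols.** Triplet bursts (3 pulses, 3 ms apart, one burst
every 2 s; field-potential protocol) and 1-s 100-Hz trains of 100 pulses
every 5 s (single-unit protocol).

**Unit responses.** Spikes are inhomogeneous Poisson by thinning. Baseline
5 Hz; `decrease`/`increase` multiply the rate by 1 ∓/± depth for 1 s from
stimulus onset; `biphasic` suppresses during the train and adds a Gaussian
rebound bump (SD 0.25 s) centred 2 s after train onset with its own
amplitude, `rebound_gain` × baseline above baseline (default 2, i.e. peak
3× baseline). The rebound is parameterized separately from the suppression
depth because recorded rebound excitations are several-fold the baseline
rate — far stronger than the ~1.7× a depth-tied rebound would give.

**Slow-wave co-modulation.** All units share a ~1 Hz sinusoidal rate
modulation whose phase performs Brownian drift (0.8 rad/√s). The drift
matters: a slow oscillation phase-locked to the stimulation schedule would
be absorbed by the shuffle predictor, while the physiological oscillation is
not stimulus-locked; drift preserves local ±1 s periodicity but decorrelates
the phase across trials. Suppression epochs can remove the modulation to
emulate stimulation-induced disruption.

**Evoked fields.** A deterministic biphasic template (cosine rise 7 ms to
+150 µV, fall 13 ms to −80 µV, recovery 40 ms; peak-to-trough 230 µV
≈ 0.23 mV) is inserted 13 ms after each burst's final pulse, plus white
noise (SD 40 µV) and one-sample ±2 mV artifacts at pulse times for blanking
tests.

**Cluster features.** Unit-covariance Gaussian clusters displaced a
controlled Mahalanobis distance from a standard-normal noise cloud in 8
dimensions (two features per tetrode channel by convention).

## Behavioral-state segmentation

Locomotion: z-scored speed (population SD over the whole session) above 0,
with subthreshold gaps ≤ 0.5 s merged and runs < 1 s discarded — multitaper
windows need ≥ 1 s of stationary data, which fixes both defaults. Quiet
rest: z ≤ 0 *and* no frontal sleep-spindle activity, where a spindle is a
10–15 Hz Hilbert envelope above mean + 2.5 SD for ≥ 0.4 s, excluded with
0.5 s padding — conventional rodent spindle detection, fully exposed in the
config. Limitation: in a session containing *no* locomotion the z > 0
threshold sits in the middle of the rest noise; for rest-box-style data,
raise `speed_z_threshold` (the rest-coverage tests do exactly this) or
supply an epoch-override file.

## Multitaper spectra and coherence

2-s windows tiled without overlap across the epochs of a state; K = 3
unit-energy DPSS tapers (NW = 2, realizing the 1-Hz half-bandwidth); FFT
zero-padded to the next power of two (~0.49 Hz grid). Power is one-sided
|X|²/fs in µV²/Hz, reported as 10·log₁₀ with no reference constant (the
reference is unspecified in the field's figures; all comparisons used here
are differences, which are invariant). PSD error bars: Student-t jackknife
over window×taper estimates on the dB scale. Coherence: averaged cross- and
auto-spectra pooled over all windows of a state (not per-epoch averaging),
leave-one-window-out jackknife on the arctanh scale, and the analytic
α-level √(1 − α^{1/(n−1)}) with n = windows × tapers. The theta ratio uses
[5, 10] Hz against (0, 5) ∪ (10, 45] on the computed grid; whether
frequencies below the lowest resolvable bin belong in the denominator is
ambiguous, so the open interval at 0 is used and documented here.

## Directed coherence

Signals are FIR-decimated (zero-phase) to 200 Hz: AR models of 0–45 Hz
structure at 2 kHz would need impractically high orders. A bivariate AR
model is fitted by multichannel least squares over windows that never span
an epoch boundary; order by AIC over 1..20 (≤ 100 ms memory at 200 Hz);
stability is verified via the companion-matrix spectral radius. The directed
measure is the noise-weighted, row-normalized DTF given in the README —
chosen because it is bounded in [0, 1], invariant to per-channel amplitude
rescaling, and matches the "which signal best predicts the other"
formulation; the exact formulation used by the original custom scripts is
not published, so this estimator is validated by simulation (directionality
recovery, calibration under the null) rather than by curve matching.
Zero-lag residual correlation is reported separately and attributed to
neither direction. Significance: surrogates pair each x window with a
non-simultaneous y window (random window permutation, fixed points broken),
the AR model is refitted per surrogate at the same order, and the
per-frequency (1−α) quantile is the threshold. Circular window shifts were
rejected as the pairing scheme: with n windows they give only n−1 distinct
pairings, too few to estimate a 95% quantile.

## Evoked fields

Trials align to each event's final pulse; ±1 ms around every pulse is
blanked (excluded from mean and SEM, interpolated for display) — triplet
pulses are 3 ms apart, so 1 ms preserves the inter-pulse signal. Onset
detection is two-step: detect where |mean − baseline| > 2 SD of baseline
(50 ms pre-burst window) for ≥ 5 consecutive samples, then localize by
walking back from the crossing until the trace re-enters the baseline
noise band (within half a baseline SD of the baseline mean). The
backtracking step removes the crossing-delay bias of a pure threshold rule
(~1.5 ms at the default noise level, which would consume most of a ±2 ms
error budget). With a noise-free baseline the threshold is zero with strict
inequality, so clean deflections are detected at their first nonzero
sample. Peak-to-trough is max − min of the mean in 0–100 ms post-reference
(responses complete well within 100 ms); depth profiles are normalized to
the maximum across depths (ties all get 100%).

## Single units

PSTH: −2 to +5 s in 100-ms bins; rate = trial-mean count / width; bootstrap
error = SD over 1000 trial resamples (1000 gives a stable SE at 33 trials);
smoothing by a Gaussian kernel (σ = 0.1 s) with a mass-conserving edge
correction, so smoothed area equals binned area exactly.

Permutation test: each trial's spikes are rotated circularly by an
independent uniform offset within the 7-s window (≥ 10,000 rotations; the
guard can be overridden explicitly for calibration studies at 1000). The
per-bin statistic is the bin count minus the pre-stimulus baseline count,
with the baseline recomputed inside every permutation — a null centered on
the pooled trial mean would be inflated by the response's own spikes,
costing power exactly when a response exists. The statistic is computed on
*unsmoothed* bins: under the rotation null unsmoothed bins are
exchangeable and effectively independent, so the ≥2-consecutive-bin run
rule controls the family-wise false-call rate across the 70 bins (measured
any-detection ≈ 5% on null units); smoothed bins are correlated (ρ ≈ 0.78
at σ = 1 bin) and would defeat the run rule. Alternatives the literature
leaves open — shuffling bin labels or permuting trial identities — are not
implemented. A bin is called significant when its two-sided permutation
p < α *and* rate ∓ bootstrap error lies entirely above/below baseline.

Classification: runs of ≥ 2 consecutive significant same-sign bins after
train onset; negative only → decrease, positive only → increase, both →
biphasic, none → none. Response magnitude is the mean *binned* rate over
the dominant run (the run with the largest smoothed deviation), as % of
baseline — the quantity "decreased to X% of baseline" describes, and
unbiased where a noisy extremum is not (the extremum of the smoothed rate
under-reports by ~6 percentage points at 33 trials). Time-to-peak is the
maximum of the smoothed rate within 0–5 s, referenced to train onset
("following stimulation" is ambiguous between onset and offset; onset is
the default and the reference is configurable).

Correlograms: 40-ms bins over ±1.02 s (a bin centred at each of −1, 0, +1 s;
the ±1 s extent captures 1-Hz slow-wave periodicity), computed in 2-s pre-
or stimulation windows per trial. The shuffle predictor averages 100 random
non-identical trial pairings (the full pairing matrix is O(n²) and adds
little); corrected = (raw − predictor) / reference-spike count. For
autocorrelograms spike self-pairs are excluded and the zero-lag bin is
masked. The pre/stim comparison computes central-peak height and width,
overall modulation depth, and ±1-s side-peak amplitude per pair, each
compared with a paired t-test (which statistic the original comparison used
is unstated, so all are reported).

## Cluster quality and cell type

Isolation distance: squared Mahalanobis distance (cluster mean/covariance)
of the nth-closest non-cluster spike, n the cluster size; undefined when
non-cluster spikes are fewer than cluster spikes. L-ratio: Σ over
non-cluster spikes of the χ²(d) upper tail of D², divided by the cluster
count. Both are affine-invariant; singular covariances are
ridge-regularized with a warning. Gate: isolation distance > 15 *and*
L-ratio < 0.35, strict. Putative pyramidal cells: trough-to-peak width
> 0.3 ms *and* mean rate < 10 Hz (standard rodent cortical conventions for
criteria the source describes only qualitatively; both are config keys).
Threshold-exact values are excluded by the strict inequalities.

## Statistics

Pearson χ² on group × category counts with margin-derived expected values,
df = (r−1)(c−1), *no* continuity correction (the published statistic on the
printed counts is reproduced only without it); cells with expected count
< 5 trigger a warning but do not alter the statistic. One-way ANOVA with
Tukey HSD. Wilcoxon rank sum means the two-sample Mann–Whitney test
(independent session groups of unequal size): exact null for n ≤ 10 per
group without ties, normal approximation with tie correction otherwise.
Paired t on differences; zero-variance differences are an error rather than
an infinite statistic.

## Problem sizes and reproducibility

Every stochastic stage takes an explicit seed and is bit-reproducible.
The verification suites use the study's native scales where stated (33
trials/unit, 72 evoked trials, 60-s LFP sessions, 100-seed recovery and
calibration runs, 200-seed null batches) and 1000 permutations in batch
calibration runs versus the ≥10,000 default for single-unit analysis.
Monte-Carlo pass rates (e.g. ≥95/100 directionality recovery) are
properties of the generator defaults above; they are not guarantees about
recordings with weaker coupling, lower rates, or fewer trials.

## Known limitations

* No time–frequency (spectrogram) or phase–amplitude coupling analysis;
  coherence assumes within-state stationarity.
* The bivariate AR model covers exactly two channels; no conditional or
  multivariate extensions.
* Rest detection assumes spindles are the only non-rest LFP signature
  worth vetoing; no sleep staging.
* The evoked onset estimator reports the average's onset; single-sweep
  latencies are out of scope.
* Amplitudes are treated as µV by convention; absolute calibration is not
  asserted.
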