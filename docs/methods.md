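# Methods

## Signal model and unit conversion

The acquisition front end is modeled as an ideal voltage divider: a
known series resistance `R` (500 kΩ) and the unknown skin resistance
`X` across a supply `V` (5 V), with a 10-bit ADC reading the drop `Vx`
across the skin in integer counts ("Arduino Units"), one count being
`λ = V/1024 = 0.0048828125 V`. Conversion follows the circuit
equations exactly — `I = (V − Vx)/R` in µA, `X = Vx/I` in kΩ,
`Y = 1/X` in µS — in double precision with no modeling of ADC code
bin centers: a count is treated as a pure multiplier of λ. The
mapping count → conductance is strictly decreasing (a more conductive
hand drops less voltage across itself). Degenerate samples
(`Vx = 0`, implying infinite conductance) are converted to NaN and
flagged rather than raised, so one bad sample cannot abort a
recording. The simulator provides the inverse mapping
(`X = 1/Y`, `Vx = V·X/(R+X)`, nearest-integer count, clamped), which
round-trips with the forward conversion to within one quantization
step across the physiological range.

## Validity screening

Human skin conductance lies in 1–20 µS; both band edges are inclusive.
A sample is invalid when non-finite or outside the band, and a trace is
invalid when more than half its samples are (threshold configurable).
A second, independent invalidity rule lives in the categorizer: a
trace whose sample standard deviation falls below 0.005 µS is a flat
line — a sensor-contact fault — even when its constant level happens to
sit inside the band (a constant ≈2 µS reading is air conductivity, not
physiology). Both rules are needed because contact faults manifest
either as out-of-band levels (≈0.93 µS open air) or as in-band
constants.

## Phasic extraction

The tonic (baseline) component at each sample is the mean of all
samples within ±4 s (closed interval, truncated at the boundaries, the
mean over a straight ramp's symmetric window returning the center
value); a median variant is available (`baseline_method: median`), the
mean being the default operative definition. Phasic = raw − baseline.
The returned pair is an exact additive decomposition: the baseline is
re-centered onto each sample (a ≤1-ulp perturbation of the windowed
average) and any residual floating-point defect is folded into
whichever component has the finer resolution, so
`phasic + baseline == raw` holds bit for bit wherever the phasic
magnitude does not exceed the signal's own scale — always true of
physiological traces, where phasic excursions are a few µS on a ≥1 µS
signal. Min–max normalization to [0, 1] maps a constant series to all
zeros rather than dividing by zero.

## SCR detection and characterization

An SCR onset is operationalized trough-to-peak: an excursion qualifies
when it rises at least the onset amplitude criterion (0.05 µS default,
0.01 µS alternative) above its preceding local minimum, and the event's
onset is that minimum — which is what makes a reported amplitude "peak
minus onset" a trough-to-peak difference. Candidates come from local
maxima of a 5-sample moving average (matching the ±4 s window at the
2 s sampling rate); the excursion test is one-sided on purpose, because
an SCR whose slow recovery is censored by the end of the recording has
little height on its right flank but a full-sized rise. Plateau peaks
take the first plateau sample.

With 2 s sampling and noise (0.02 µS) comparable to the onset
criterion, trough/argmax sample estimates localize onsets no better
than ±3 s. Each candidate is therefore refined by a bounded
least-squares fit of a canonical SCR template — constant local
baseline, linear rise, exponential recovery parameterized by its
half-life — over the candidate's support. Onset and peak times are the
fitted kink positions snapped to sample times; onset and peak values
are the fitted baseline and baseline + amplitude (denoised estimates).
Sub-sample interpolation is used only for the 50 %-recovery crossing.
The classical sample-value route remains available as
`refine="samples"` and as `characterize(trace, onset_index,
peak_index)` for manual annotation, where values are the raw samples.
On the generator's default conditions the template route recovers
injected amplitudes within 10 % and rise times within one sample
interval for well over 90 % of traces, while quiet traces fire the
detector in under 1 % of cases; the sample route satisfies neither
margin, which is why the template fit is the default.

Recovery time is the interpolated first crossing of
`peak − amplitude/2` after the peak; if the recording ends first the
recovery is censored with lower bound `t_end − t_peak` (or
`t_end − t_recovery_start` when the caller places the start of the
recovery phase after a plateau). Peak width — never standardized in
the field — is defined here as full width at half amplitude with
interpolated crossings. Latency classes: onset 1–5 s (inclusive)
after the stimulus is event-related (ER-SCR); earlier is non-specific
(NS-SCR); later is NS-SCR by default but configurable, since field
reports sometimes treat 5–7 s latencies as stimulus-related.

## Categorization rules

Invalid screens first (band rule or flat line). Otherwise a trace is
stressed when at least one event exhibits the onset→peak→recovery
pattern with positive rise time *and* passes the magnitude check —
amplitude at least `max(onset criterion, 0.1 µS)`, an amplitude margin
standing in for a formal test of "latency phase differs from peak
phase", chosen to stay descriptive rather than inferential. Everything
else is not stressed. Cohort percentages are integers rounded half-up
(Decimal), the convention under which 36/12/3 of 51 prints 71/24/6;
the three percentages are rounded independently and need not sum
to 100.

## Synthetic cohorts

The generator encodes the study conditions: 120 s recordings sampled
every 2 s; tonic level uniform in 2–8 µS; sensor noise Gaussian with
σ = 0.02 µS, deliberately well below the 0.05 µS criterion so both
criterion settings are testable; stressed traces carry one (70 %) or
two (30 %, when the spacing rule lets the second fit) SCR bumps with
latency U[1,5] s, amplitude U[0.2,3] µS, rise U[5,35] s and recovery
half-time U[1.2,3]×rise, enforcing recovery slower than rise; calm
traces are noise-only; invalid traces alternate between 0.93 µS and
1.99 µS flat lines. The bump is a linear rise plus exponential decay
whose half-life equals the recovery half-time, making the detector's
50 %-recovery estimate analytically checkable (a triangular variant
exists). Consecutive bump onsets must be at least
`rise + 2×recovery half-time` apart — overlapping-SCR decomposition is
out of scope. Bumps pushing conductance past the 20 µS ceiling are
clipped with a warning and flag. Randomness is a single numpy
Generator per trace, spawned from the cohort seed via `SeedSequence`,
so cohorts are reproducible trace by trace and across platforms.

What the generator does *not* emulate: superposed/overlapping SCRs,
tonic drift, motion and respiration artifacts beyond the flat-line
fault, and inter-subject autocorrelation structure. Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
behavior under the stated noise model, not robustness to every field
artifact.

## ML layer

Features per trace: largest-event amplitude and width (0 when
eventless), mean conductance, peak-minus-mean, and phasic maximum,
each also min–max normalized across the cohort. K-means (k=2,
scikit-learn, `n_init=10`, seeded) clusters amplitude-type features;
the cluster whose centroid has the larger peak amplitude is named
"stressed" — a semantic assignment rule, so labels are invariant to
cluster index permutation. The pseudo-labels feed an SVC (linear or
RBF) tuned by grid search over C ∈ {0.01,…,100} (and γ ∈ {0.1,…,5},
containing the reference γ = 2.0) by mean 5-fold CV accuracy with
shuffled, seeded folds; ties resolve to smaller C then smaller γ.
NuSVC covers the ν-parameterized variant (reference settings ν = 0.02
and 0.2). Because clustering splits by magnitude, weak true responses
can be pseudo-labeled "relaxed"; the SVM's contract is fidelity to its
given labels, and agreement with generator truth is reported separately.
Metrics are computed from first-principles confusion counts with
undefined ratios reported as 0; scikit-learn's metric functions serve
as an independent cross-check in the test suite, not as the
implementation.

## Problem sizes and determinism

The reference cohort is 51 traces (36/12/3) at 60 samples each; the
parameter-recovery batches use 60–100 single-event traces. Every
stochastic stage takes an explicit seed, and identical configuration
yields byte-identical reports (no timestamps are embedded). The
acceptance script pins the cohort generator seed (7) as part of the
cohort recipe, keeping its three reported percentages deterministic.

## Known limitations

* Amplitudes below ≈0.1 µS are indistinguishable from noise at the
  default acquisition settings and are deliberately not counted as
  stress evidence.
* The template fit assumes a single dominant response per excursion;
  compound SCRs are characterized as one event.
* The ML layer is a workflow demonstration on features whose
  class-conditional structure comes from the generator; numbers
  obtained on real field recordings depend on data this package does
  not ship.
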