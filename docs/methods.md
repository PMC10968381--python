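# Methods

This note records the models, conventions and numerical choices behind
`alphanet`, and what the synthetic validation does and does not establish.

## Synthetic data model

A recording is `mixing @ (oscillators + 1/f noise)` per scalp channel, at
64 channels (60 scalp in a 10-10 layout on a unit sphere, plus two EOG-like
and two mastoid-like channels that exist only to exercise channel
selection).  Defaults mirror an eyes-closed resting session: 1000 Hz,
210 s, two groups of 24 subjects.  Tests and the analysis scripts use
smaller problem sizes (typically 250 Hz, 60–210 s, 2–12 subjects per
group), chosen so each experiment still has the statistical resolution its
assertion needs.

**Oscillators.**  Each scalp channel carries a narrowband alpha oscillator
`A · cos(2πf·t + φ₀ + random walk)`.  The random-walk phase (per-sample
increment SD σ, default 0.1 rad) gives an approximately Lorentzian line of
width ≈ σ²·fs/2π Hz — a controllable stand-in for the finite coherence
time of real alpha.  Amplitude defaults to 10 μV against 5 μV RMS of 1/f
background (exponent 1.0, spectral shaping of white noise), a
peak-dominated but not noise-free regime typical of eyes-closed posterior
channels.

**Coupling.**  Two constructions plant phase relationships:
`CouplingSpec` couples one pair through a shared source (the second
channel mixes a lagged copy at fraction `coupling_strength` of its
oscillatory power), and `ModuleSpec` phase-locks any number of channels to
one source at channel-specific lags `i · lag_spacing`.  Lags of 0 or π
carry no imaginary cross-spectrum and therefore no expected wPLI; module
lag spacings are kept small enough that no pairwise lag approaches π.

**Volume conduction.**  A row-stochastic, diagonally dominant Gaussian
smoothing over electrode distances, applied instantaneously — the worst
case a phase-lag measure must reject, with no temporal structure that
could masquerade as lagged coupling.

**What the generator does not emulate:** realistic forward head models,
event-related structure, eye-blink/muscle artifacts (amplitude-rejection
tests use injected square pulses), heterogeneous per-subject alpha peak
frequencies, or non-stationarity beyond phase drift.  Passing tests
therefore certify the *estimators and inference machinery*, not robustness
to every property of real EEG.

**Determinism.**  All randomness descends from one integer seed through
`SeedSequence(seed, spawn_key=(group, subject))`, so studies are
bit-reproducible and subjects independent.

A matrix-level sampler (`sample_wpli_matrices` / `sample_study_wpli`)
complements the signal model for permutation-testing experiments: it draws
subject connectivity matrices around one shared population of edge means
(clipped normal, defaults base 0.25 ± 0.08 across edges, 0.06
between-subject), with planted deltas on chosen edge sets for group A.
Where an experiment's subject matter is the permutation/NBS machinery
itself, tests use this sampler; the signal-level pipeline is exercised
end-to-end separately.

## Preprocessing

Zero-phase filtering uses a single pass of a symmetric (linear-phase)
windowed-sinc FIR with exact group-delay compensation and reflective
padding; for symmetric FIRs this is exactly zero-phase and O(N log N) on
long records.  The band-pass is two cascaded Hamming-window stages.  The
0.1 Hz high-pass edge cannot carry its nominal transition width in a
practical FIR, so the high-pass transition is one cutoff width with the tap
count `ceil(3.3 · fs / Δf)` capped at 8193; the residual DC gain of the
capped design is removed exactly by redistributing the tap sum.  Notches
are two narrow FIR band-stops at 48 and 52 Hz (stop edges ±1 Hz),
implementing the stated pair literally rather than substituting a single
50 Hz notch.  Epochs are non-overlapping 2-s segments; the rejection rule
reads "exceeding 75 μV" strictly, so an epoch peaking at exactly 75.0 μV
is kept (with a warning).

## Spectra

PSD is the epoch-averaged one-sided periodogram of Hanning-windowed 2-s
segments, normalized by the window energy `fs · Σw²` (density convention):
the integral over frequency recovers variance (Parseval) and a unit
sinusoid integrates to 0.5 regardless of window.  Bands are half-open
`[lo, hi)`, so the 10.5 Hz boundary belongs to α2 only and the sub-bands
partition α exactly.  Band power is the mean PSD over in-band bins.  Group
comparisons are pooled-variance two-sample t-tests, applied per frequency
bin to grand-average spectra and per electrode to band powers; reported
p-values are uncorrected (an optional Benjamini–Hochberg column is
available).  Zero variance in both groups with equal means yields p = 1 by
convention.

## wPLI

For Hanning-windowed Fourier coefficients, the cross-spectrum is
`S_ab = X_a · conj(X_b)` and `wPLI = |⟨|Im S|·sign(Im S)⟩| / ⟨|Im S|⟩`.
The estimator offers three granularities for the expectation ⟨·⟩:

* **pooled** (default): over all in-band epoch × bin observations;
* **epochs**: across epochs at each bin, then averaged over the band (the
  common trial-based estimator; per-bin null bias ≈ √(2/(π·n_epochs)),
  which band averaging does not reduce);
* **per_epoch**: over the bins of one epoch, per-epoch values averaged.

The default matters.  For uncoupled narrowband signals the in-band sign of
Im S barely varies within a single epoch, so the per-epoch form is
strongly positively biased (measured ≈ 0.7 for independent zero-lag-mixed
sources); only expectations that span epochs let the fluctuating imaginary
parts cancel, which is the entire point of the index.  Under the study
conditions (105 two-second epochs) the measured null levels are ≈ 0.08
(pooled) versus ≈ 0.11 (per-bin across epochs), so the pooled form is the
default.  The debiased/squared wPLI variant is deliberately not
implemented; the estimator is the plain weighted form.

Pairs whose denominator falls below `1e-12 ×` the mean in-band auto-power
(identical or exactly zero-lag channels) contribute 0, not NaN.  Matrices
are symmetric with zero diagonal, entries in [0, 1].  A naive
loop-per-observation oracle implements the identical estimator for tests.

## Permutation tests and NBS

Subject labels (never edges) are permuted without replacement, preserving
within-subject dependence; group sizes are maintained.  Per-edge p-values
are two-sided by |t| with the `(1 + exceedances)/(1 + n_perm)` convention,
so p never reaches 0.  When the requested permutation count covers all
distinct relabelings, the null is enumerated exactly (identity included;
exact p = exceedances/total).

NBS forms connected components among suprathreshold edges — positive
(A > B) and negative (B > A) edges separately, so findings are directional
— and corrects each component's size (edge count) against the permutation
distribution of the maximum component size over both directions.  The
component statistic is extent; intensity is not currently offered.

**Primary threshold.**  Default |t| corresponds to two-sided p = 0.001 at
the pooled degrees of freedom, configurable both as raw t and as a
p-equivalent.  At lenient thresholds (p ≈ 0.05) the ~5% of chance
suprathreshold edges percolate on a 60-node sensor array into one giant
component that swallows any true effect — family-wise error control still
holds, but localization is destroyed (measured: planted-component Jaccard
≈ 0.01 at p = 0.05 versus 1.0 at p = 0.001).  The FWER calibration
experiment in the validation suite deliberately runs at primary p = 0.05,
where the max-component null distribution is non-degenerate and the
nominal-level check is informative.

## Graph topology

Matrices are proportionally thresholded: the `round(s · n(n−1)/2)`
largest-weight edges are retained with their weights, ties broken by
lexicographic label order so edge sets are deterministic and nested across
the grid (0.05–0.50 in steps of 0.05).  Weights are normalized to the
graph maximum; path lengths are inverse normalized weights.  Metrics:
Onnela weighted clustering (geometric-mean triangle intensity), weighted
local efficiency (mean inverse shortest-path length within each node's
neighbor subgraph; degree < 2 ⇒ 0), and unnormalized shortest-path
betweenness.  Connectedness is not enforced at low sparsity; disconnected
pairs contribute zero efficiency.  Hubs are nodes whose betweenness
strictly exceeds mean + 1 SD (multiplier configurable).

Because weights are max-normalized, these weighted metrics are invariant
to uniform scaling of a matrix and respond to *relative* weight structure:
a small set of exceptionally strong edges can lower a group's mean
clustering/efficiency by depressing every other normalized weight.  Group
differences in these metrics therefore reflect topological reorganization
(e.g. a broadly synchronized module concentrating the retained edges into
a dense subgraph) rather than global connectivity strength — the planted
designs in the validation suite are constructed accordingly.

Rich-club curves use the binary skeleton: φ(k) = 2E/(N(N−1)) over nodes of
degree > k, normalized by the mean curve of degree-preserving
double-edge-swap null graphs (10 × E swaps each; 50–100 nulls).  Levels
with fewer than two qualifying nodes are flagged undefined, not errored.
Hemispheric comparison restricts the matrix to one hemisphere's scalp
channels by label convention (odd = left, even = right, z = midline;
midline excluded), thresholds each subnetwork, and compares the mean
normalized rich-club over the k levels where both curves are defined.
The laterality recovery experiment plants a six-node left parietal hub
core (hub–hub edges +0.40) with three spokes per hub (+0.25) over the
0.25 ± 0.08 background — a rich-club structure by construction, since
degree-preserving rewiring dilutes hub–hub edges into hub–periphery ones.

## File formats and EDF

Recordings travel as EDF or tab-delimited text with a JSON sidecar;
matrices and montages as labeled tab-delimited tables at full float
precision.  EDF writing is a minimal built-in implementation (1-s records,
16-bit samples, μV units) whose physical scaling is derived from the ASCII
header fields as written, making round-trips exact up to the format's
quantization; reading EDF files from elsewhere goes through `mne`.  In
tests, `mne`'s independent EDF parser serves as the round-trip oracle for
the built-in writer.

## Pipeline

Stages communicate through files under the run directory, so each stage
reruns standalone and a full run is exactly the chained stages; rerunning
with the same seed is byte-identical.  The single run seed expands into
fixed per-stage offsets (simulation uses the seed itself; each band's
permutation stream and each subject's rich-club nulls get disjoint
offsets), so changing one stage's workload does not perturb another's
draws.  Configuration is a flat YAML file whose defaults are the protocol
values: 0.1–50 Hz, notches 48/52 Hz, 2-s epochs, 75 μV, bands α/α1/α2,
1000 permutations, sparsities 0.05–0.50, significance level 0.05.

## Known limitations

* The current-source-density transform some protocols apply before
  connectivity is not implemented; wPLI is computed on (synthetic) sensor
  signals, which changes absolute connectivity levels though not the
  estimator's contracts.
* ICA-based artifact removal is out of scope; amplitude rejection is the
  only artifact defense.
* Weighted rich-club variants, component-intensity NBS, and
  threshold-free cluster enhancement are not implemented.
* The EDF writer requires an integer sampling rate and pads partial final
  records with zeros.
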