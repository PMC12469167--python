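# Methods

This note documents the models, conventions and design choices behind
`mngsort`, in the spirit of a methods appendix: what each stage computes,
which parameters matter, what the synthetic generator does and does not
emulate, and where genuinely open choices were settled.

## Recording model and lab dialects

A recording is a single continuous voltage trace (float64, volts) with a
sampling rate, background-stimulation onset times, and spike events that
carry fiber-track labels obtained via the marking method. Times are
seconds; sample `i` covers the half-open interval
`[t0 + i/fs, t0 + (i+1)/fs)`, which makes the time-to-sample mapping for
window extraction unambiguous. Spikes without a track label survive I/O
but are excluded from every evaluation — only tracked spikes have ground
truth.

Two acquisition chains are harmonized by *dialect* corrections:

- **Dialect B** (30 kHz chain): the raw polarity is inverted, so the
  signal is negated and then smoothed with a centered rolling mean. The
  window length is a parameter (default 3 samples) because no canonical
  value exists; edge samples average over the available neighbors
  (`min_periods = 1` convention).
- **Dialect A** (10 kHz chain): acquisition occasionally drops short
  stretches. Gaps are declared in the container as `(start, end)` second
  pairs and padded with zeros on read so the time base is uniform —
  downstream window extraction assumes continuity. The pad value 0 V is
  neutral for averaging and alignment.

The HDF5 container uses a minimal layout (`/signal`, `/stimuli`,
`/spikes`, `/meta`) that maps one-to-one onto NIX/Neo concepts; a CSV
triplet plus YAML sidecar serves as a plain-text fallback.

## Window extraction, resampling, alignment

A C-fiber spike is ~3 ms wide. Windows are 30 samples (`[t−15, t+15]`) at
10 kHz and 60 samples (`[t−30, t+30]`) at 30 kHz, centered on the sample
containing the annotated spike time. 30-sample windows are resampled to 60
points with the Fourier method so both rates share one grid and derivative
estimates improve. Derivatives are `numpy.gradient` difference quotients
(central in the interior, one-sided at the ends) in volts/sample; the
second derivative is the gradient of the first.

Spikes are aligned on the **maximum negative peak of the first
derivative** — the steepest falling flank — which is far more stable
against annotation jitter than the spike time itself. The canonical
alignment index is 30 of 60 (0-based): the window center. The shift is
realized by *re-extracting* the window from the raw signal at a moved
center (up to 8 iterations), which avoids wrap-around and zero-pad
artifacts; sub-sample residuals (possible at 10 kHz, where one grid step
is half a raw sample) and windows without raw-signal access fall back to a
zero-padded in-window shift. Ties at the minimum break to the earliest
index. A flat first derivative has no negative peak: the spike is excluded
and counted (`alignment` reason), as are spikes whose window crosses the
signal edge (`boundary` reason). The conservation
`aligned + excluded = labeled spikes` is enforced and reported per
recording.

Per-track **templates** are plain means of the aligned waveforms. The
**waterfall** assigns each labeled spike to the latest onset at or before
it, with latency in ms; a spike before the first onset is assigned to the
first sweep with a warning.

## Feature sets

- **simple** `[a, w]`: `a` is the positive peak voltage; `w` is the full
  width at half maximum, located by linear interpolation on both sides of
  the peak (accurate to < 0.05 samples for Gaussian pulses with σ ≥ 2).
  Spikes with no positive peak or a missing half-crossing on either side
  are excluded. (The upstream width definition needs both crossings; this
  exclusion rule is the package's own, documented choice.)
- **SPDF_raw** (23 features) and **SPDF_FV3** `[f14, f18, f19]`: computed
  from the first/second derivatives and six *fundamental points*, P1 being
  the first zero-crossing of the first derivative (sign change between
  consecutive samples; index of the first sample after the change). A
  spike whose first derivative never changes sign has no P1 and is
  excluded — both SPDF sets share this one mask. Four definitions are
  fixed: feature 4 of the original 24-feature catalogue is dropped (it
  depends on an external reference waveform); f8 is the mean of the
  squared first-derivative amplitudes from the window start up to
  (excluding) P1 — summing to P1−1 and dividing by P1−s makes it a proper
  mean of squares; f14 = max(fd), f18 = max(sd), f19 = min(sd). The
  remaining 19 features follow this package's documented interpretation of
  the shape/phase/distribution taxonomy (each a pure registered function
  in `mngsort.spdf` with its own docstring): shape = time-domain geometry
  of fd anchored on P1–P4, phase = fd/sd amplitudes at the fundamental
  points, distribution = moments of the fd and sd amplitude distributions.
  Ratios use a bounded asymmetry form `(a−b)/(|a|+|b|)` so degenerate
  denominators cannot blow up; moments of zero-variance inputs are 0.
  On noisy windows P1 can fall in pre-spike noise; the features remain
  finite and defined, only the flat-derivative case excludes.
- **W_raw**: the 60 aligned samples; never excluded.
- **W_2-PCA / W_3-PCA**: mean-centered PCA fitted per recording on the
  W_raw matrix (full SVD, deterministic); scores are the features.

No standardization is applied before the SVM or PCA (a configurable
choice left at the upstream default of none).

## Supervised evaluation

Per recording and feature set: stratified 5-fold cross-validation
(80/20), RBF-kernel SVM with library defaults — C = 1, kernel width
γ = 1/(d·Var(X)), one-vs-one multiclass — scored with accuracy (correct /
total predictions) and macro-averaged precision, recall and F1. Folds are
assigned after sorting rows into a canonical (label, feature) order, so
reports are invariant to input row order given the seed (default 0).
Stratification keeps the near-balanced class design in every fold; every
class must have at least 5 members. The chance baseline is 1/k for k
tracks (a majority-class baseline is available by flag). A random forest
(library defaults, seeded) is the alternative classifier.

## Unsupervised evaluation

k-means (k-means++ initialization, 10 restarts, seeded) with k fixed to
the known track count — deliberately flattering to clustering — scored
against the ground truth with ARI, NMI and V-measure (β = 1). The PCA
component sweep repeats this for 2–8 components of W_raw and reports the
cumulative explained variance per count.

## Template similarity

Templates are compared on the aligned 60-sample grid without
renormalization, so MSE/MAE/RMSE stay in data units. For recordings with
more than two fibers the headline distance is that of the *most similar*
pair (ties break lexicographically), flagged `reduced_to_pair` in the
sortability table because it can misrepresent multi-fiber recordings; no
correction for this is defined or attempted.

## Cross-recording statistics

Feature sets are compared pairwise with the two-sided Wilcoxon signed-rank
test on matched per-recording accuracies: zero differences discarded, the
exact null distribution for ≤ 25 non-zero differences (exact sign
enumeration with midranks also covers tied magnitudes), normal
approximation with continuity correction beyond. Identical columns are
degenerate (p = 1, logged). Significance uses the strict inequality
p < α_adj with α_adj = α/n; α = 0.01 is adopted as the analysis convention
despite being stricter than the usual 0.05.

## Synthetic generator

The generator emulates the *study conditions* of a marking-method session:

- background stimulation at 0.25 Hz (default) for 80 sweeps — roughly
  320 s and 80 labeled spikes per fiber, a typical session length;
- per-fiber base latencies in the 200–600 ms range of human C-fibers
  (defaults 250/420 ms for two fibers, evenly spread otherwise), with
  0.05 ms Gaussian jitter for the "almost constant" conduction latency;
- ADS: a per-fiber slowing state grows by 2 ms per evoked extra spike and
  decays exponentially (τ = 30 s) between sweeps —
  `latency = base + s + jitter`, `s ← (s + inc·m)·exp(−Δt/τ)`. This is the
  simplest dynamics in which slowing tracks the number of previously
  elicited spikes and recovers to baseline under continued background
  stimulation; quantitative ADS magnitudes are free parameters, and the
  defaults are order-of-magnitude choices.
- spike shapes: tri-lobe (negative–positive–negative) Gaussian-lobe
  waveforms. Two base shapes bracket a morph family; because morphing,
  Fourier resampling and averaging are all linear,
  `RMSE(T(0), T(λ)) = λ·RMSE(T(0), T(1))` exactly, so a pair with any
  target distance up to the base-pair RMSE (≈ 1.35) can be constructed
  *exactly*. Both base shapes place their first-derivative minimum at the
  canonical index 30, and a convex combination of functions minimized at
  the same point is minimized there too — so every morph is born aligned
  and noise-free pipeline recovery is exact to machine precision;
- additive white Gaussian noise (default sd 0.3 V against peak amplitudes
  ≈ 0.98–4.9 V, i.e. per-fiber SNR ≈ 3–16), with an optional 1/f flag;
- a 3 ms overlap guard: configurations whose spikes would collide are
  rejected, mirroring the exclusion of overlapping-spike recordings from
  the analysis.

What the generator does **not** emulate: stimulus artifacts, electrode
drift and waveform non-stationarity, bursting/spontaneous activity,
sympathetic confounds, overlapping spikes, and non-Gaussian noise
structure. Passing tests therefore demonstrate correctness of the
pipeline's computations and its behavior across SNR/similarity/fiber-count
regimes — not performance on any particular recorded dataset.

## Validation design and problem sizes

Recorded human microneurography datasets cannot be redistributed, so the
acceptance checks run on synthetic surrogates
(labelled as such) at sizes chosen to keep the full suite fast:

- template-distance recovery uses clean 30 kHz recordings (80 sweeps,
  noise sd 0.1 — weak-fiber SNR ≈ 10, the "visually distinct templates"
  regime) with generated pair distances 1.20 and 0.21 (a distinct and a
  near-identical pair); recovery is accurate to ≈ ±0.03, dominated by
  per-spike alignment jitter, within the ±0.05 band used by the tests. At
  higher noise the recovered distance inflates because alignment errors
  smear the weak fiber's template — visible in
  `examples/03_template_similarity.py`;
- chance-level and trend suites use 25-sweep recordings (50–150 spikes)
  over 10–20 seeds: identical templates give accuracy within 3 binomial
  standard errors of 1/k; accuracy is decreasing in fiber count
  (Spearman ρ < 0 over k = 2…6) and increasing in template distance
  (ρ > 0 over 8 distances at fixed noise 0.6);
- the cross-recording statistics suite uses 8 recordings spanning
  4 template distances × 2 noise levels.

## Known limitations

- SPDF features f1–f3, f5–f7, f9–f13, f15–f17, f20–f24 are this package's
  documented interpretation of the shape/phase/distribution taxonomy; other
  implementations of the same taxonomy may differ in detail.
- At 10 kHz the alignment grid step is half a raw sample, so a ±1-step
  residual shift can remain after re-extraction and is finished by a
  zero-padded in-window shift.
- The generator's latency dynamics are per-sweep, not continuous-time;
  extra pulses are evenly spaced within their interval and every extra
  pulse evokes a spike in every fiber.
- Unlabeled (untracked) spikes are carried through I/O but never
  evaluated; detection of spikes from the raw trace is out of scope.
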