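# Methods

This note documents the models, estimators and design choices behind
`caim`, in the spirit of the methods appendices of the mature simulation
and statistics packages the library is modelled on.  Empirical claims
below are the ones the test suite and `scripts/acceptance.py` themselves
compute; nothing is asserted that the code does not measure.

## Signal model of the synthetic generator

The generator (`caim.synthetic`) is the package's verification
instrument: every analysis stage is tested by recovering parameters it
plants.  Per neuron,

```
F_clean(t) = B · (1 + a · (s ⊛ k)(t) + d(t) + ε(t)),      k(t) = exp(−t/τ)
F_roi(t)   = F_clean(t) + α_true · F_neuropil(t)
```

* `s` is a binary spike train: background Bernoulli thinning at
  `background_rate_hz` per frame (multiplied by `movement_rate_gain`
  inside movement bouts), plus assembly events at
  `assembly_event_rate_hz` that activate **all** members of an assembly
  in one frame (the analysis only assumes ≥ 90% co-activation; full
  co-activation is the simplest generator satisfying it).
* `k` is a single-exponential kernel with instantaneous rise and
  τ = 1.8 s, the GCaMP6S decay constant; only the decay constant is
  physiologically constrained, so no rise time is modelled.  The
  convolution is implemented as the exact IIR recursion
  `y[t] = s[t] + e^(−1/τf) y[t−1]`, which makes the model invertible — a
  test deconvolves noiseless output and recovers the raster exactly.
* `d` is a slow sinusoid (amplitude `drift_amplitude` in ΔF/F units,
  period 120 s by default) standing in for slow baseline drift; `ε` is
  white Gaussian noise (`noise_sd`, ΔF/F units).  The real noise spectrum
  of two-photon recordings is not characterized here; whiteness is an
  assumption, stated rather than hidden, and the baseline estimator is
  additionally verified against a brute-force sliding-window oracle.
* Neuropil contamination is **plain additive**, `α_true · F_neuropil`,
  so the standard correction `F_raw − α·F_neuropil` recovers `F_clean`
  *exactly* when α matches.  (Centering the contamination on the neuropil
  mean was considered and rejected: it leaves a constant offset
  −α·mean(F_neuropil) in the corrected trace, which shifts F₀ and biases
  recovered ΔF/F amplitudes by ≈ α·mean/B — with the defaults a 25%
  error.  Exact invertibility is what makes the correction testable.)

Defaults represent a 15-minute-scale awake recording: 100 neurons, 25 Hz,
baseline 100 a.u., transient amplitude 0.5 ΔF/F, noise sd 0.05 ΔF/F,
background 0.1 Hz, assembly events 0.05 Hz, neuropil level 50 a.u. with
2% fluctuations, α_true = 0.4.  Speed traces are generated at the same
25 Hz as the imaging clock (mirroring a tracking stream aligned to
acquisition frames), piecewise-constant at `resting`/`moving` speeds
(5 / 60 mm/s) with 1 mm/s Gaussian jitter — the 30 mm/s threshold then
separates the states by 25 jitter sd, so planted movement masks are
unambiguous.

What the generator does **not** emulate: pixel-level movies (ROI traces
are generated directly, so motion correction and segmentation are out of
scope), correlated or 1/f noise, photobleaching trends beyond the
sinusoid, rise-time kinetics, and any biophysics of stroke.  Passing
tests therefore demonstrate algorithmic correctness and calibration under
the stated statistical model, not robustness to every artifact of real
recordings.

## ΔF/F preprocessing

Processing order mirrors the standard chain: pair-average frames
(25 → 12.5 Hz effective), neuropil-correct with α = 0.4, estimate F₀,
divide.  F₀ is the running 8th percentile over a centred 30 s window,
smoothed by a centred 30 s running mean.  Both windows truncate at the
session edges rather than padding — fabricating data at the boundaries
would bias the first and last ~15 s, and the tests exclude those edges
when asserting drift tracking.  The double pass (percentile, then mean)
is this package's concrete reading of a "running average of the running
percentile"; it is verified against a brute-force loop and tracks drift
much slower than the window to within 5% of the drift amplitude.

A deliberate consequence of a low-percentile baseline: for a pure-noise
stretch, F₀ sits ≈ 1.4 noise-sd *below* the mean, so ΔF/F carries a small
positive offset.  Downstream stages therefore measure amplitudes
relative to the trace median, never to absolute zero.

## Noise model and transient detection

Per-neuron noise sd is estimated from the lower tail of the ΔF/F
distribution: `(q25 − q8) / 0.7309`, the 8th-to-25th interquantile
distance scaled to a normal sd.  Calcium transients are positive-going,
so both quantiles sit in transient-free territory; on 10⁴-frame traces
the estimator is within 10% of truth with or without sparse planted
transients, and it is exactly scale-equivariant.  (Estimators centred on
the median — MAD, mirrored negative deflections — were measured to be
2–3× more biased once transient tails occupy tens of percent of frames.)

Detection declares a frame significant when median-centred ΔF/F exceeds
`z₀.₉₈ · sd` (one-sided 98% bound) **and** the surrounding event decays
like the indicator.  Supra-threshold runs separated by less than τ/2 are
one event (noise dips mid-decay do not end a transient); the decay
constant is fitted from the event peak over a ≤ 3τ window (truncated at
the next event) by least squares of `A·exp(−t/τ̂)` in **linear** space,
profiling A over a fixed τ̂ grid (0.2–8 s, 80 log-spaced points).
Linear-space fitting matters: the additive noise is linear, and log-space
fits are destabilized by the small-value tail.  An event is kept iff
τ̂ ∈ [τ/2, 2τ] — "compatible with" the indicator read as a factor-of-two
band.  Measured calibration (acceptance suite): noise-only traces yield
≈ 0.1% event frames (budget ≤ 2.5%), and 5×-noise transients are detected
with sensitivity ≥ 0.96.

Event *rate* counts onsets, not active frames.  Known limitation: when
inter-event intervals approach the transient footprint
(≈ τ·ln(amplitude/threshold) + τ/2 ≈ 3.5 s at the defaults), consecutive
events merge and counted rates saturate; the movement-gain recovery test
is therefore run in a sparse regime (0.02 Hz background) where the
planted moving/resting ratio of 2 is recovered within 15%.  Movement
masks are debounced at the tracking rate (runs shorter than 6 frames =
240 ms absorbed into their surroundings, shortest first) and aligned to
pair-averaged imaging frames by block majority.

## Functional connectivity

Pearson r between z-scored traces for all pairs; significance by the
stationary block bootstrap: per iteration a resampling schedule is drawn
(uniform block starts, geometric lengths with mean 23 frames = 1.84 s at
12.5 Hz — matched to the indicator decay — and circular wrap) and applied
to one member of each pair, preserving its autocorrelation while
destroying cross-dependence; the pair's threshold is the 99th percentile
of its null r.  Two economies are deliberate: (1) one shared schedule per
iteration across all pairs (one matrix product instead of n² independent
resamples; the marginal null of each pair is unchanged, only nulls of
different pairs become weakly dependent, which thresholds do not use);
(2) resampling one series rather than both (the standard construction for
a pairwise-dependence null; a both-sides variant would only widen nulls
marginally).  Calibration is measured, not assumed: thresholds learned on
one white-noise population flag ≈ 1.0% ± 0.5% of 2016 fresh independent
pairs, and the mean threshold matches the analytic 2.33/√T within 20%.

Graph summaries follow field conventions: per-neuron significant degree,
connections/neuron (edges ÷ population size), strong edges at r > 0.3,
density = 100·edges/(n(n−1)/2).  Undefined pairs (zero variance) never
become edges but stay in the density denominator.  Distances are
Euclidean between ROI centroids in µm (0.848 µm/px at 512 px over
434 µm).

## Assembly detection

**How many components.**  The significant-PC count is the number of
correlation-matrix eigenvalues above the Marchenko–Pastur upper bound
(1 + √(n/T_eff))².  The plain bound (T_eff = T) assumes temporally
independent samples; calcium traces are autocorrelated by the indicator
kernel, which inflates sample-correlation noise by the Bartlett factor
1 + 2Σ_k ρ(k)² and would make the naive bound admit ~20 spurious
components on kernel-smoothed data.  T_eff = T / (1 + 2Σρ̂²) with ρ̂ the
mean FFT autocorrelation (truncated at the first negligible lag) restores
calibration: i.i.d. noise yields 0 ± 1 components, five planted
assemblies yield exactly 5.

**Rotation and membership.**  Loadings (eigenvectors × √eigenvalue) are
Promax-rotated at power 4 (the conventional default) via
`statsmodels.multivariate.factor_rotation`; obliqueness is the point —
it lets one neuron load on several components, and the overlap test
plants exactly that.  Each component's loadings are z-scored across
neurons and membership is `z > z_max`.  z_max is picked automatically as
the first local minimum of a Gaussian-KDE of each ROI's maximal z-scored
loading (the algorithmic stand-in for a manual "first clear minimum"
pick), with a config override for manual choice and a 1.96 fallback
(flagged) when the distribution has no interior minimum.  Components
with fewer than 2 members are dropped — a singleton is not an assembly.

**Merging.**  Membership indicator vectors are unit-normalized; while
any pair's dot product exceeds 0.6 the highest-dot pair (ties to lowest
indices, for determinism) is unioned, and every merge is logged with its
dot product.  Hand check: sizes 9 and 16 sharing 3 members give
3/√(9·16) = 0.25 — kept apart.

**Synchrony validation.**  Surviving assemblies must beat surrogates:
the statistic is the maximal number of members whose transient *onsets*
fall in one 3-frame (240 ms) coincidence window; each of 1000 surrogates
circularly shifts every member's onset train independently;
p = (1 + #{surrogate ≥ observed})/(N+1), dropping assemblies at
p ≥ 0.05.  Onsets — not whole active spans — carry the synchrony: with
τ = 1.8 s tails a moderately active population has tens of percent of
frames active per neuron and the span-based statistic saturates at the
assembly size, destroying the test's power (measured, not hypothesized —
span-based validation rejected 80% of genuine planted assemblies).

**Activation statistics.**  The matching index of assembly a at frame t
is |members(a) ∩ active(t)| / |members(a)| ∈ [0, 1].  Per-frame
significance is the exact hypergeometric upper tail of drawing ≥ k
assembly members among the m active neurons from a population of N — the
canonical parameter-free null for "this many members co-active by
chance" — thresholded at p < 0.05 and requiring k ≥ 1.  The test is
discrete, so its attained level is necessarily ≤ 5% and approaches it
only for fine-grained (large N, K, m) settings; the calibration check
runs at N = 2000, K = 500, 50% activity, where the attained level is
≈ 4.5%.  Assembly–assembly correlations use the matching index ×
significance mask ("significant activations only"), Pearson r per pair
with the same stationary-bootstrap null, averaging only significant
pairs; assembly–speed correlations are tested two-sided on |r| at
α = 0.01.

An alternative Jaccard-style matching index (intersection over union
with the active set) is a plausible reading of the literature; the
proportion-of-members definition is implemented as the default because
it is the one the activation-significance null (hypergeometric in k)
pairs with exactly.

## Widefield maps

Trials are averaged first; the response map is
(mean of 10 post-stimulus frames − mean of 10 pre-stimulus frames) /
(mean pre), i.e. (post − pre)/pre rather than post/pre — the former is in
ΔF/F units consistent with the rest of the package (the two differ by 1;
a flag is not provided because every downstream metric would simply
shift).  The baseline-sd map is the per-pixel sd (ddof 1) of the
pre-stimulus ΔF/F frames of the trial average; masking at k = 5 × sd,
area = mask count × pixel scale², peak within the mask, and an
intensity-weighted centroid over the mask (robust and deterministic,
given that "map position" is otherwise undefined).  Pixels with
non-positive baseline are invalid (NaN) and never enter masks.
Coordinates are 0-based row-major pixels, origin top-left, x = column;
physical units via `pixel_scale_mm`.  On Gaussian phantoms the
thresholded area matches the analytic level-set area
π·2σ²·ln(A/(5·sd)) within 10%, and centroid shifts recover planted
offsets to ~1%.

## Behaviour

Beam runs: slip counts per side; distance to first slip is the first
slip's beam position, and a slip-free run scores the full beam length —
the choice that keeps "farther is better" monotone for aggregation
(reporting 0 would rank a perfect run worst).  String pull: path
circuity Σ‖Δp‖ / ‖p_end − p_start‖ (≥ 1 by the triangle inequality,
undefined for closed paths); movement scaling is Pearson r between
per-reach path lengths and peak speeds (≥ 3 reaches required); bimanual
correlation linearly detrends both vertical paw traces (removing
postural ramps) before Pearson r, with a numerical-dust guard so
constant or purely linear series return NaN rather than noise
correlations.  Reach segmentation from video is upstream of this
package; the module consumes segmented events.

## Pipeline, reproducibility, problem sizes

`run_pipeline` chains simulate/load → preprocess → detect → segment →
connect → assemble, writes tidy CSVs (one row per neuron / event / edge /
membership), and a manifest with the config hash, seed, package version
and per-file SHA-256 checksums.  One master seed is expanded through
`numpy.random.SeedSequence.spawn` into independent per-stage substreams,
so stages stay reproducible if the chain is reordered or run piecemeal;
CSV floats use a fixed `%.10g` format, making repeat runs byte-identical
(asserted in the acceptance suite).  Config defaults are the workflow's
standard constants (α = 0.4; 30 s / 8th percentile; 98% CI; τ = 1.8 s;
30 mm/s and 6 frames; 5000 iterations, 23-frame blocks, 99th percentile;
r > 0.3; dot 0.6; p < 0.05; k = 5).

The test and acceptance suites size their simulations for a single CPU:
bootstrap calibration at 1000 iterations on 64 neurons × 5000 frames
(2016 pairs), assembly recovery at 100 neurons × 600 s × 10 seeds,
hypergeometric calibration at 2000 × 4000, end-to-end determinism at 40
neurons × 300 s with 200-iteration bootstraps.  These are the package's
chosen verification sizes; the defaults used for real sessions (5000
iterations, full durations) are unchanged.

## Known limitations

* Event-rate estimates saturate at high firing rates (transient merging);
  see the detection section.
* The Marchenko–Pastur criterion with the Bartlett correction is
  calibrated for approximately stationary autocorrelation; strongly
  non-stationary sessions may still over-count components (the z_max cut
  and synchrony test are the safety net, and both are exercised).
* The hypergeometric activation test is conservative for small
  populations (discreteness).
* The generator's independence and whiteness assumptions mean real-data
  artifacts (motion residue, correlated noise, bleaching) are outside the
  validated envelope.
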