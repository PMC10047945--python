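# Methods

This note documents the models, conventions and numerical choices behind
`mventropy`: what each estimator computes, which knobs matter, what the
synthetic signals emulate, and where the design was genuinely open.

## Signal model and normalization

All estimators operate on a `p x L` real matrix `U = {u_{k,a}}` (channels
`k = 1..p`, samples `a = 1..L`). `multiscale_curve` z-scores every channel
once on the original series (sample SD, divisor `L-1`) before any
coarse-graining. Consequences:

* the similarity tolerance `r` is expressed in SD units of the original
  signal and is a fixed absolute number (default 0.15) at every scale; it
  is *not* recomputed per scale. This is the standard multiscale-entropy
  convention and keeps values comparable across scales;
* all estimators become invariant to per-channel amplitude rescaling.

The sample-SD convention (ddof = 1) is used everywhere an SD appears
(z-scoring, the dispersion map, increment quantization).

## Coarse-graining

Scale `s` replaces each channel by means of non-overlapping windows of
width `s`; output length `floor(L/s)`; `s = 1` is the identity. The
refined-composite variant computes, for offsets `t = 1..s`, the series of
window means starting at sample `t`. An offset-`t` series has
`floor((L-t+1)/s)` complete windows — the window never reads past the end
of the data — and all `s` series are truncated to the common minimum
length so every offset contributes equally to the averaged statistics.

## The six estimators

**mvMSE** (multivariate multiscale sample entropy). Composite delay
vectors concatenate, channel block by channel block, `m` delayed samples
of each channel (length `m*p`; start indices `i = 1..N - m*d`). `phi^m` is
the mean over `i` of the fraction of other vectors within Chebyshev
distance `r`. For dimension `m+1` there are `p` ways to grow one channel's
block by one delayed sample; the `p` families (same start-index range) are
pooled and the match fraction is computed over the pooled set with
normalizer `p*(N-n) - 1`. The entropy is `-ln(phi^{m+1}/phi^m)`; if either
count is zero the value is *undefined* and reported as NaN, never raised.

Two non-obvious consequences of this pooled construction, inherited from
the canonical algorithm rather than introduced here:

* vectors from different extension families are compared positionally, so
  the value is only *approximately* invariant to channel reordering for
  `p >= 3` (exactly invariant at dimension `m`);
* hard matching in `m*p + 1` dimensions becomes extremely sparse for
  `p = 3` at large scales — with `N = 6000`, three 1/f channels and
  `s = 10` the expected match count is below one and the value is
  undefined. This is the algorithm's own behavior at these conditions; the
  fuzzy variants exist precisely to repair it.

**mvMFE** replaces the hard threshold by the fuzzy weight
`D(d) = 1` for `d <= r`, `exp(-ln2 * ((d-r)/r)^2)` beyond — continuous at
`d = r`, equal to 1/2 at `d = 2r`, and strictly positive, so the entropy
is always finite.

**RCmvMFE** applies two refinements: the `s` offset coarse-grained series
each yield fuzzy match statistics at dimensions `m` and `m+1` (membership
anchor relaxed to `lambda*r`, `lambda` in [0.5, 1.5], default 0.8), and
the statistics are *averaged across offsets before* the log ratio. As
printed, the offset-averaged quantities omit the outer mean over `i`
present in the mvMFE definition; we include it so the averaged quantities
remain probabilities — with it, RCmvMFE at `s = 1`, `lambda = 1` equals
mvMFE at scale 1 exactly (a unit test asserts bit-level agreement).

**mvMPE** maps each per-channel window of `m` delayed samples to its
ordinal pattern (stable argsort; the earlier index wins ties) and pools
pattern counts across channels with normalizer `(N-(m-1)d) * p`. Bounded
by `ln(m!)`; exactly channel-permutation invariant.

**mvMDE** maps each channel through a normal CDF, digitizes into classes
`1..c` by `round(c*y + 0.5)` (half away from zero, clamped to `[1, c]`),
builds the `m*p`-long composite class vector per window, and counts one
dispersion pattern for each of the `C(m*p, m)` index combinations
(lexicographic order, original index order kept inside a selection).
Bounded by `ln(c^m)`. In a multiscale sweep the CDF parameters are
**frozen from the z-scored scale-1 series** (`mu = 0`, `sigma = 1`): if
instead each coarse series re-adapts its own mean and SD, the variance
shrinkage of coarse-graining is normalized away, white-noise curves stay
flat across scales and the 1/f-vs-WGN ordering inverts at large scales —
contradicting the canonical multiscale dispersion-entropy behavior the
estimator is meant to show. Direct calls to `mv_dispersion_entropy`
default to the self-adaptive map; `mu_sigma` selects the frozen one.

**mvMIE** differences each channel, embeds windows of `m` increments, and
maps every window to a word of `(sign, magnitude)` pairs: sign is the
signum of the increment; the magnitude quantizes `|z|` against the
window's sample SD, `q = min(R, floor(|z| * R / sd))`, with `q = 0` when
the window SD is zero. The magnitude formula is stated in the literature
with `z` rather than `|z|`, which would collapse every negative increment
to the same symbol and could never reach the advertised
`(2(R+1)+1)^m` pattern count; the sign/magnitude split restores it. Word
counts pool across channels; bounded by `ln((2(R+1)+1)^m)`.

Natural logarithms are used throughout.

## Default parameters

| parameter | default | applies to | rationale |
|---|---|---|---|
| `m` | 2 (SE/FE/RCFE), 3 (PE/DE/IE) | embedding dimension | conventional settings for each family |
| `d` | 1 | delay | standard |
| `r` | 0.15 | SE/FE/RCFE | in SD units of the normalized signal |
| `lambda` | 0.8 | RCmvMFE | within the typical 0.5–1.5 range |
| `c` | 3 | mvMDE | class count |
| `R` | 4 | mvMIE | quantization resolution (usually <= 4) |
| `max_scale` | 20 | all | scale sweep 1..20 |

`mv_dispersion_entropy` refuses to run when `C(m*p, m)` exceeds 100 000
selections per window (resource guard for large channel counts).

## Synthetic signals

* **WGN**: i.i.d. standard Gaussian channels.
* **1/f noise**: spectral synthesis — FFT of white noise, amplitude at
  frequency `f` scaled by `1/sqrt(f)` (DC zeroed), inverse FFT, then
  standardized to mean 0, SD 1. The log-log PSD slope is verified near -1
  by a Welch-periodogram oracle in the tests.
* **Correlated pairs**: linear mixing `z2 = rho*z1 + sqrt(1-rho^2)*z1'` of
  two independent unit-variance processes; targets the *population*
  correlation and preserves the marginal spectrum of both kinds.
* **MIX(p)**: `x(t) = 2 sin(2*pi*t/fs)` on `t = 0..N-1` (fs = 12), with
  `round(N*p)` positions, chosen uniformly without replacement, replaced
  by Uniform(-3, 3) draws. Complexity rises with `p`.
* **Coupled MIX**: `A = C*MIX(p0) + (1-C)*MIX(p1)`,
  `B = C*MIX(p0) + (1-C)*MIX(p2)` from three independent MIX draws on a
  common grid. `C = 0` gives independent random components (the
  deterministic sinusoid is still shared, so the raw Pearson correlation
  of the two channels is not zero at `C = 0` unless `p1 = p2 = 1`);
  `C = 1` duplicates the channel. Note the channel *marginal* changes with
  `C` (the sum of two independent MIX draws is most Gaussian-like near
  equal mixing), so even with `p0 = p1 = p2` the single-channel entropy is
  not exactly constant across `C`.
* **SNR injection**: per channel, additive WGN scaled so
  `10*log10(P_signal/P_noise)` hits the requested dB, with power the mean
  squared deviation from the channel mean.

Every generator is a pure function of its arguments including the seed.

## Simulation experiments

Defaults are the study conditions: 20 replicates, length 6000, scales
1–20, `rho = 0.95`, SNR levels {20, 10, 0, -10, -20} dB, coupling grid
0..1 step 0.1, coupled-MIX reference parameters (C=0.4, p0=0.2, p1=0.5,
p2=0.8), length grid 100..2000 step 100. Replicate `j` of condition `i`
uses seed `base + 1_000_000*i + j`; auxiliary noise streams live in a
disjoint block. The noise and length experiments derive the base signal
seed from the replicate only, so the clean arm of the noise experiment and
the matching length-grid entry follow the same generator path.

The equal-probability grid of the coupling experiment defaults to
`p0 = p1 = p2 ∈ {0.1, 0.3, 0.5, 0.7, 0.9}`: equal triples pin the
single-channel construction so the sweep isolates the effect of `C`;
arbitrary triples can be passed explicitly.

Detector conventions: `detect_ordering_threshold` returns the largest
scale at which the strict ordering of ensemble means fails (0 if it never
fails; a no-threshold marker if it fails at the top scale);
`find_peak_coupling` is the grid argmax of replicate means with ties
resolved to the smaller `C`; `find_stabilization_length` returns the
smallest grid length from which all means stay within the tolerance
fraction of the final-length mean, with a no-stabilization marker when
only the final point itself qualifies.

The length experiment runs scales 1–16: the refined-composite estimator
needs `floor((N-s+1)/s) >= m*d + 3` complete windows at every offset, and
16 is the largest scale the shortest grid length (N = 100) supports. This
bound is structural, not tuned.

## EEG pipeline

Recordings are cut into non-overlapping fixed-length epochs (default 5 s;
the trailing remainder is dropped). Per region — channels grouped by a
user-supplied map with the six canonical scalp regions F, C, P, O, LT,
RT — RCmvMFE runs per epoch; per scale, epochs farther than 3 scaled MADs
(x1.4826) from the epoch median are excluded and the survivor mean forms
the region curve. The outlier rule is deliberately parameter-light and
configurable (`n_mads`); exclusion is per scale, so an epoch may be
dropped at some scales and kept at others. Band summaries average the
curve over the short (scales 1–4) and long (scales 10–15) bands.

Group comparison: Welch's two-sample t-test per (region, band) — Welch by
default because variance homogeneity is rarely credible in small clinical
groups; Student's is a flag away. Benjamini–Hochberg FDR correction is
applied across regions *within each band* (and across region x score
pairs within each band for the score correlations); the family choice is
configurable. Flags at adjusted p <= 0.05.

The shipped 32-channel region map is a 10-20-style *example montage* for
demonstrations and simulation, not a reproduction of any clinical
study's montage; real analyses must supply their own.

### Synthetic cohort

Clinical resting-state EEG with patient labels is typically
access-restricted, so the pipeline is validated on a generated stand-in.
Each subject's channels are region-wise mixtures: a shared within-region
1/f component (weight `w`) plus a private mixture of white noise (weight
`alpha`, the subject's "complexity fraction") and 1/f noise. The impaired
group draws `alpha` around `0.6 - effect` (controls around 0.6) and uses
shared-component weight `0.5 - coupling_gap`. Because white noise carries
short-scale irregularity and 1/f noise carries long-range structure, a
lower `alpha` depresses short-scale entropy and raises it at long scales —
the short/long reversal reported for impaired cohorts. Scores (MoCA,
AVLT delayed recall) are noisy increasing functions of `alpha`.

What passing tests show: the pipeline recovers a planted group difference
in direction and significance and is calibrated on null cohorts. What they
do not show: anything about real EEG — the surrogate has no 1/f-band
structure beyond its two noise families, no alpha rhythm, no artifacts,
no volume conduction, and its coupling is a single shared component per
region.

## Problem sizes used in the tests

Statistical reproductions of the simulation behavior run at the study
conditions (20 replicates, N = 6000) for the scale-10 ordering checks and
the three headline readouts; the coupling monotonicity/flatness checks use
N = 2000, and the signal-level cohort tests use small montages (4–12
channels), short recordings and scale sweeps of 2–8 — sizes chosen so the
whole suite completes in minutes while the assertions remain qualitative
(orderings, monotonicity, direction and calibration of effects).
Table-level statistical contracts (BH adjustment, power of the planted
1.5-pooled-SD difference, type-I calibration) are exercised by direct
Monte-Carlo on band-entropy tables, where 100–200 repeats are cheap.

## Known limitations

* mvMSE's undefined region (sparse hard matches) appears already at
  moderate channel counts and scales; curves carry NaN gaps there.
* The composite-vector estimators are only approximately invariant to
  channel reordering (see mvMSE above); differences are far below the
  entropy differences the estimators are used to detect.
* The increment-entropy magnitude quantization and the dispersion-map
  freezing are documented readings of ambiguous printed formulas; both are
  exposed as explicit knobs (`increment_word`, `mu_sigma`).
* The EEG pipeline consumes already-clean matrices; filtering, artifact
  removal and montage handling are out of scope.
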