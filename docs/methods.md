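# Methods

This note records the model conventions, parameter choices and numerical
decisions behind the package, and what the synthetic experiments do and do
not establish.

## Oriented areas and the lead matrix

The oriented area of a channel pair is computed as the shoelace sum
½ Σᵢ (xᵢ Δyᵢ − yᵢ Δxᵢ) over consecutive frames. This is the *exact* line
integral ½∮(x dy − y dx) of the piecewise-linear interpolant, so no
quadrature rule is open to choice; discretization error relative to the
underlying continuous curve is bounded by 2·C_k·C_l·Δ for perturbations
with C¹ norms C_k, C_l and step Δ (exposed as
`discretization_error_bound`). The formula contains no time stamps — the
source of invariance under monotone reparametrizations, which the tests
exercise by refinement (inserting interpolated points) and by explicit
monotone warps.

Sign convention: positive a_kl means channel k leads channel l. For
x = cos t, y = cos(t − α) over one period the area is π·sin α > 0 — the
delayed copy follows.

Channels are centered and scaled to unit quadratic variation
(Σᵢ(x[i+1] − x[i])² = 1) before lead-matrix computation. Dividing by the
square root of the quadratic variation (an energy normalization) rather
than by the quadratic variation itself is a deliberate choice: it makes
the normalized series dimensionless with unit "energy", and it is
idempotent. Constant channels cannot be normalized and raise a named
error. No detrending beyond centering is performed. The sampling interval
dt is metadata only; event spacings are reported in frames and, via dt,
in seconds.

All cumulative trajectories a_kl(t) are computed on normalized series.

## Spectral ordering

The eigendecomposition of the (skew-symmetric) lead matrix is computed as
the Hermitian eigenproblem of iA, which guarantees exactly imaginary
eigenvalues, orthonormal eigenvectors and deterministic LAPACK ordering.
Conjugate pairs are counted once; "the second eigenvalue" in dominance
contexts means the second distinct magnitude (pair index 2). The
dominance ratio |λ₁|/|λ₃| returns an infinity sentinel below a 1e−12
relative floor.

The conjugation ambiguity of the leading eigenvector is resolved against
the most confident lead–lag pair: for (k*, l*) = argmax |a_kl|, the signed
angle from component k* to component l* must match the sign of a_{k*l*}.
With that orientation, ascending constellation phase is excitation order
(leaders first).

The constellation ellipse is the unit level set of an origin-centered
quadratic form q(z) = ax² + 2bxy + cy², fitted by linear least squares on
the design (x², 2xy, y²) against the target 1. If the minimizer is not
positive definite (collinear constellations), the form matrix's
eigenvalues are clipped at 1e−6 of the largest (or at 1e−6 if both are
non-positive) and the result flagged degenerate. Ranking uses the elliptic
norm q(z)^{1/2}, rank 1 largest; all ties anywhere in the package break by
channel-label order, keeping every operation deterministic and seed-free.

Phase ordering rotates the kept points so their centroid lies on the
positive real axis and lists channels by ascending phase in (−π, π]
(counterclockwise from the negative real axis). A centroid at the origin
is reported as a degeneracy rather than silently picking a rotation; for
constellations spread around the full circle, cyclic order should be read
from the raw arguments instead (as the order-recovery experiments do).
The default cutoff for "dominant" channels is the top 20 by average
elliptic rank (24 is also exercised in tests as a robustness choice).

## Sublevel persistence and reversals

`sublevel_persistence` implements the standard 0-dimensional sublevel
filtration of a 1-D sequence with union-find and the elder rule; ties in
value are resolved by index (earlier = older), endpoints count as local
extrema when their single neighbour is larger/smaller, and exactly one
essential class (the global minimum) survives. The implementation is
validated exactly — births, deaths, and their time indices — against an
independent brute-force threshold-sweep oracle that recomputes connected
components from scratch at every insertion, on a thousand random
sequences including heavily tied integer-valued ones.

A *reversal* is a persistent change of direction of a_kl(t). Because
direction changes happen at maxima as well as minima, the default mode
runs the filtration on the trajectory and on its negation and merges the
kept features (`signed_mode="both"`; `"f"` restricts to the plain
filtration). Events are the birth (extremum) and death (merge) frames of
the p longest-lived *finite* features of each filtration. Two exclusions
are deliberate:

* essential classes are not events — for a trending trajectory the global
  extremum marks where accumulation starts or stops, not a direction
  change, and including it produced a spurious event pile-up at the
  recording edges of steady (rest-like) pairs;
* extrema at the first or last frame are not events — an endpoint has
  one-sided behaviour.

Interior minima that the essential class would have marked are still
recovered, as deaths of the negated filtration's features.

Burstiness is the summed span of the n_bars = 10 longest finite bars
(both filtrations pooled in the default mode; 8 and 20 give rank-wise
nearly identical results, which a dedicated experiment quantifies as
Spearman ρ ≈ 0.97). `reversal_events` also accepts an optional
noise-floor filter (`min_span_fraction`, relative to the longest finite
bar) for exploratory use; no shipped experiment relies on it.

Carpet summaries count, per frame, the pairs recording a birth or death.
Task-locked dynamics shows as synchronized carpet peaks; the package
provides a uniform-scatter permutation null (`uniform_null_max_count`)
against which a rest-like carpet's maximum count is indistinguishable.

## The synthetic generator and study conditions

The generator emulates three regimes, with additive i.i.d. Gaussian noise
per frame and channel and SNR defined as (signal RMS / noise sd)² over the
noiseless recording:

* **Chain-of-offsets (rest-like)** — x_k(t) = a_k φ(ωt − α_k) + noise.
  Default study conditions: n = 10 channels, φ = cos with a 50-s period
  (infraslow, ~0.02 Hz), 1,200 frames at dt = 0.72 s, amplitudes uniform
  in [0.8, 1.2], offsets random on the circle with a guaranteed 0.2-rad
  minimum separation (so the planted cyclic order is well defined),
  SNR 10. For Fourier seeds the continuous-limit lead matrix is available
  in closed form: one rank-2 skew-symmetric term per harmonic,
  a_kl = (duration/period)·4π·a_k a_l Σ_m m|c_m|² sin(m(α_l − α_k)) for
  exponential-convention coefficients c_m. The constant and orientation
  were fixed against direct quadrature of the oriented-area integral on a
  dense period, and a test pins the agreement at 1e−4 relative Frobenius
  error.
* **Ripple trains** — solitary Gaussian pulses emitted across channels
  with per-channel lags and rest in between; the length of the calm
  interval provably does not affect the oriented areas, and a test checks
  this to 1e−9.
* **Task blocks** — a two-channel pulse-train pair whose lag sign follows
  a block design, so a_12(t) zigzags with persistent extrema at block
  boundaries. The *social* emulation alternates the leader at every 38-s
  segment boundary over 1,200 frames, with a 2-frame lag, 1-s pulses
  every 4 s. The *motor* emulation uses 13 contiguous 15-s blocks (ten
  movement blocks — 3-s cue plus 12-s movement — and three fixations)
  with the leader alternating at each boundary, a 4-frame (≈2.9 s,
  cue-scale) lag, and one smooth hemodynamic-scale activation lump per
  3 s (2.5-s pulse width): at the 195-s run length the per-block signal
  must be concentrated in few smooth events to stand above the
  noise-induced fluctuations of the area trajectory at SNR 10.

What the generator does *not* emulate: hemodynamic response convolution,
1/f or physiological noise spectra, spatial correlation between channels,
or session-level nonstationarities. Passing tests therefore establish the
pipeline's correctness and its behaviour under the stated wave/ block
models with white noise — not performance on real BOLD data.

## Replication experiments

All experiments regenerate their inputs from a seed; sizes are chosen for
desk-scale runs.

* *order-recovery*: 100 draws of the 10-channel chain at SNR 10; success
  = exact cyclic order of constellation arguments vs planted offsets.
* *rank2-dominance*: noiseless single-harmonic chain sampled at 2,000
  points per period; reports |λ₃|/|λ₁| (machine-precision small; uniform
  sampling of a single harmonic is exactly rank 2).
* *reversal-spacing*: 50 social pairs; the kept-feature events (top 5 per
  filtration) are pooled across pairs, clustered (gap > 5 frames), and
  clusters supported by fewer than 10% of pairs discarded — the
  carpet-peak criterion; reports the mean spacing of consecutive epoch
  centers in seconds (≈ 37.9 s for the 38-s segment interval).
* *epoch-count*: 50 motor pairs; per-pair event clusters (gap > 5 frames)
  with a per-filtration feature budget p = n_blocks // 2 = 6 — an
  alternating 13-block design has at most six upward and six downward
  persistent turns, and a larger budget only admits noise bars; reports
  the median count (≈ 12, the number of interior block boundaries).
* *burstiness-contrast*: 200 task-like (alternating social design, lags
  cycling 1–3 frames) vs 200 steady chain-of-offsets pairs; one-sided
  Mann–Whitney test that task burstiness stochastically dominates.
* *bars-robustness*: Spearman correlation of 8-bar vs 20-bar burstiness
  over the 200 task-like pairs.

## Known limitations

* The constellation-ellipse fit assumes the informative channels dominate
  the eigenvector; with many silent channels clustered at the origin the
  fit is driven by the active ones only to the extent the least squares
  weights allow. No iterative robust fit is attempted.
* Phase ordering requires a half-plane-concentrated constellation
  (centroid away from the origin); full-circle constellations need the
  cyclic reading.
* Epoch counting depends on the cluster gap (5 frames) and the feature
  budget; both are surfaced as parameters, with defaults chosen for the
  block designs above.
* The CLI reads one dialect (delimited text, label header, rows =
  frames); no imaging formats are parsed — parcellation and denoising are
  upstream concerns.
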