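# Methods

## Model and coordinates

Three agents moving in a bounded arena form a triangle; the analysis
variable is the triple of interior angles θ = (θ₁, θ₂, θ₃), which always
satisfies Σθᵢ = π. The triple is treated as the state of a ring of three
identically coupled oscillators with D₃ symmetry. Equivariant Hopf
bifurcation theory classifies the generic periodic states of such a ring
by their isotropy subgroups; only the resulting *phase relations* are
used here, never a specific dynamical model. The package therefore never
integrates coupled ODEs: synthetic trials realize each predicted phase
relation directly with cosine carriers, which is the weakest waveform
assumption consistent with the catalog (the theory constrains phases and
waveform equality, not shape).

The phase plane is the barycentric embedding
p = (θ₁V₁ + θ₂V₂ + θ₃V₃)/π with fixed vertices V₁ = (0,0), V₂ = (1,0),
V₃ = (1/2, √3/2). The embedding is affine in θ, so the distance from p to
the edge opposite vertex *i* is (√3/2)·θᵢ/π. Consequences used throughout:
a rotation pattern of amplitude A embeds as a circle of radius
(√3/2)·A/π about the centre; a partial anti-phase pattern with dead value
c embeds as a line parallel to the edge opposite the dead vertex at height
(√3/2)·c/π (through the centre exactly when c = π/3); a partial in-phase
pattern embeds on the median through the anti-phase vertex. These closed
forms are verified against brute-force geometry in the tests.

## Synthetic generators

Defaults: 30 Hz sampling, 90 s trials, amplitude A = 0.3 rad, frequency
f = 0.5 Hz (the realistic band for this kind of task is roughly
0.2–0.8 Hz). Generator closed forms:

- rotation: θᵢ = π/3 + A·cos(2πft + φ₀ − 2π(i−1)/3), A < π/3;
- partial anti-phase: dead channel ≡ c ∈ (0, π); the other two are
  (π−c)/2 ± A·cos(2πft + φ₀), A ≤ (π−c)/2. The catalog records both the
  operational reading (dead channel) and the full theory's alternative
  (odd channel at twice the common frequency); only the operational form
  is generated and detected — the half-period variant deliberately falls
  to OTHER;
- partial in-phase: pair ≡ c + A·cos(·); odd channel = π − 2c − 2A·cos(·)
  (the 2:1 amplitude ratio is forced by the sum-π constraint), requiring
  A < c and c + A < π/2;
- all in-phase: the sum constraint forces all channels constant at π/3;
- asymmetric (negative control): three cosines at incommensurate
  frequencies (ratios 1, √2, √3) with seeded random phases, renormalized
  to sum π.

Pattern-switching trials concatenate segments with a linear cross-fade of
the angle triples; convexity preserves the sum-π constraint exactly.

Track realization places the three agents on a circle of configurable
circumradius (default 2 m, centred in a 6 m arena) at cumulative central
angles 2θ₃, 2θ₁ — by the inscribed-angle theorem the interior angles of
that triangle are exactly θ, so angle extraction inverts the construction
to machine precision. Gaussian position noise (seeded) is applied in
position space only, never on angles, so recovered angles always satisfy
the sum identity. What this generator does *not* emulate: realistic player
kinematics (accelerations, tactical structure), a defender, occlusion
errors, or amplitude/frequency drift within a segment — so passing tests
demonstrate correctness of the measurement and classification chain, not
that real play matches the templates.

## Preprocessing

Calibration is a 2-D eight-parameter DLT (plane-to-plane projective map)
solved by linear least squares on the standard linearized system; with
≥ 4 non-collinear, noise-free correspondences the fit is exact to 1e−9.
No lens-distortion model is included. Track smoothing is a second-order
Butterworth filter, zero-phase (forward–backward) by default, applied per
axis and restarted on every contiguous possession run so no transient
crosses an exclusion gap; runs shorter than the filter's edge padding are
flagged invalid instead of filtered. Default cutoffs are 1.0 Hz (x) and
0.5 Hz (y), appropriate for recordings where slow translation dominates.
For *synthetic* tracks the pipeline uses 2.0 Hz on both axes: the
circle-construction places the full oscillation band on both world axes,
and an asymmetric 0.5 Hz cutoff would distort the signal itself rather
than just the noise. Angle extraction uses the four-quadrant arctangent
of the incident edge vectors; frames that are non-possession, non-finite
or near-collinear (smallest angle < 1e−6 rad) are marked invalid, never
raised. Exclusion splits the series into maximal valid segments and drops
segments shorter than two periods of the slowest expected oscillation
(default 2/0.2 Hz = 10 s), below which peak-based phase estimation is
meaningless.

## Classification

The classifier is deliberately peak-based (no Hilbert or wavelet phase).

1. **Extrema.** Peaks and valleys per channel via prominence- and
   distance-constrained peak picking, merged and forced to alternate
   (the more extreme of two same-kind neighbours wins). Defaults:
   minimum separation 1.0 s (true peaks in the 0.2–0.8 Hz band are
   ≥ 1.25 s apart), prominence floor 0.05 rad adaptively raised to 0.4×
   the median channel amplitude so measurement ripple on large signals
   does not read as extra cycles.
2. **Pair phase.** For each ordered pair, at every reference-channel peak
   t with local period T (forward difference; the last peak uses the
   backward one): Δφ = wrap(2π(t* − t)/T) ∈ (−π, π], t* the nearest peak
   of the other channel (ties to the earlier peak, undefined beyond ±T).
   Local amplitudes are half the extremum span of each channel within
   [t−T, t+T]. For a noise-free delay the estimator's error is bounded by
   one sample of phase, 2π/(rate·T).
3. **Pair labels.** Oscillator death first: if either local amplitude is
   below the death threshold the entry is DEAD. Otherwise tolerance bands
   of ±π/6 around 0 (IN), ±2π/3 (SHIFT±) and π (ANTI) — equal,
   non-overlapping bands covering the circle; everything else (including
   undefined phases) is OTHER. The death threshold is 0.30× the median of
   the three per-channel amplitude scales (median extremum-to-extremum
   half-span). The fraction must sit above the residual relative
   amplitude that tracking noise leaves on a truly constant channel after
   smoothing (~25% at 0.05 m noise on a 0.3 rad signal) and well below 1;
   0.30 is the midpoint of that admissible range.
4. **Triple labels.** The reference channel is the one with the most
   extrema among channels whose amplitude clears the death threshold; its
   consecutive extremum spans (half-cycles) are the labelling intervals.
   Each interval looks up each pair's label from the entry nearest its
   midpoint, *only* if that entry lies within 1.5 local periods —
   otherwise the pair has no phase evidence there (e.g. a channel stopped
   oscillating mid-trial) and the decision falls back to local
   amplitudes (DEAD/OTHER). Rules: all three cyclic pairs SHIFT with one
   common sign → R; one ANTI and the two pairs containing the remaining
   channel DEAD → PA, sub-labelled PA1/PA2 by the dead channel's interval
   mean below/above π/3; one IN and two ANTI → PI, sub-labelled by the
   in-phase pair's mean below/above π/3 (the "1 = below π/3" convention
   mirrors PA); all IN → ALL_IN; anything else OTHER. A constant triple
   has no extrema and hence no intervals, so ALL_IN is in practice
   unobservable by this estimator — consistent with it never occurring in
   data of this kind. Occurrence frequencies are percentages of valid
   time per label.

## Occupancy density

Valid embedded samples (pooled over trials when comparing groups) are
binned on a 60×60 grid over the triangle's bounding box; bins outside the
triangle are masked; heights are min–max normalized over in-triangle bins
(a flat field maps to zero by convention). Bin count is configurable; the
default trades resolution against occupancy at 30 Hz × 90 s.

## Permutation tests

Groups are compared on per-unit frequency vectors over {R, PA, PI}
(PA = PA1+PA2, PI = PI1+PI2) with the omnibus statistic
S = Σ_k (mean_a,k − mean_b,k)² — symmetric in the groups and sensitive to
any pattern shift. Units are trials, or subgroup means in the subgroup
variant (which respects within-squad dependence). Designs with at most
20,000 distinct re-assignments are enumerated exactly; otherwise B
re-assignments are sampled and the add-one estimator
p = (1 + #{S* ≥ S})/(B + 1) is used, making the test exact-level. The
calibration experiment in the tests (2000 replicates of an exchangeable
null, B = 999) measures a rejection rate within ±0.02 of the nominal
0.05; replicate data and permutation seeds are drawn from separate
substreams because coupling them measurably biases the rate.

## Reproducibility

All randomness flows from one root seed through named, CRC-keyed
`SeedSequence` substreams per stage and trial; reports embed the package
version, configuration hash and seed. Problem sizes used by the default
test run and the acceptance script (90 s or 60 s trials at 30 Hz, 8
trials per group, 999–9999 permutations, 2000 calibration replicates)
keep a full run in the seconds-to-a-minute range on one CPU.

## Known limitations

- Tolerance bands (π/6), the death fraction (0.30) and the minimum
  segment length are field-reasonable defaults, not fitted to any
  recording; all are configurable.
- The peak-based phase estimator needs ≥ 2 cycles per segment and
  degrades when amplitude approaches the noise floor; no instantaneous
  phase is available between extrema.
- The theoretical half-period partial anti-phase variant is catalogued
  but intentionally not detected as PA.
- The DLT is plane-to-plane; out-of-plane motion (jumping, varying head
  height) biases reconstruction.
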