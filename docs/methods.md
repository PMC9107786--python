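# Methods

## Model and pipeline

`phenodiv` treats a community's phenology as S nonnegative curves
z_1(t) … z_S(t) on one evenly spaced time grid and summarizes them by
distance-weighted Hill numbers. The pipeline is

1. **read** — parse a wide or long CSV onto a validated `TimeGrid`
   (strictly increasing, spacing constant to a relative 1e-9, length
   ≥ 2). Missing cells become zeros and are listed per species in a gap
   report; the smoothing stage is the gap-filling mechanism, so gaps are
   never interpolated at read time.
2. **smooth** — continuous wavelet transform per species, scale
   selection by the attenuation threshold τ, column-sum reconstruction.
3. **distance** — modified Morisita–Horn overlap distance for every
   unordered pair, composite trapezoidal integrals on the shared grid.
4. **diversity** — relative intensities p_i, standardizing factor
   Q = ΣΣ O_ij p_i p_j, and qPD at requested orders or on a profile
   grid.

Assumptions: intensities are nonnegative and comparable across species
within a survey (the measure is invariant to one common rescaling, not
to per-species rescalings, since p_i carries intensity information);
time units are arbitrary and never parsed as dates — the measure is
invariant to uniform time rescaling; a single observation window
represents the cycle of interest.

## Wavelet smoothing

The transform follows the standard FFT formulation for analytic
kernels: the demeaned series is extended evenly (reflection) to a
2N-periodic signal and transformed circularly, so the kernels see no
window-edge leakage. The default kernel is the analytic Morlet with
center frequency ω₀ = 6 — the conventional choice when the series'
dominant frequencies are unknown — with a real second-derivative-of-
Gaussian ("mexican hat") kernel available for comparison.

**Scale ladder.** Dyadic, `scales_per_octave = 12` rungs per octave.
The in-band part spans 2·step … N·step (N = series length); two further
octaves of coarser *trend* scales are appended and always retained.
They are needed because the even extension is 2N-periodic: a single
seasonal pulse concentrates energy at period ≈ 2N, and without the
trend octaves the reconstruction of exactly the kind of one-pulse-per-
year series the package targets errs by tens of percent. With them,
full-ladder reconstruction of pulse series is accurate to ≲1.5%
relative L2. Series shorter than 8 points are rejected; 25+ points are
recommended.

**Reconstruction.** smoothed = mean + Σ_retained Re W(s, t)/√s ÷ gain,
where the gain is computed numerically as the mid-band plateau of the
summed kernel response Σ_j √(2πs_j/δt) ψ̂(s_j ω*)/√s_j (halved for
analytic kernels, whose negative-frequency half is discarded),
evaluated at the geometric mid-band frequency ω* = 2π/(√(2N)·δt). This
numerical calibration replaces tabulated reconstruction constants and
adapts automatically to kernel and ladder density. Negative
reconstructed values are clipped to 0 — curves are intensities, and the
[0, 1] bound of the overlap distance holds only for nonnegative curves.
`clip=False` disables the clip, making the operation exactly linear
(used by the linearity test).

**τ semantics.** τ > 0 selects retained scales via s ≥ N·step/(1+τ),
referenced to the in-band top so the always-retained trend scales are
unaffected. τ → 0 keeps only the coarsest scales (maximal smoothing);
τ → ∞ keeps the whole ladder and reproduces the raw series to ≲1.5%;
τ = 2 is the default, the conventional standard value. The L2 distance
between smoothed and raw series is non-increasing in τ (tested). The
cutoff rule is a declared convention of this package: the threshold's
published descriptions fix only its two limits, not a formula.

**Community smoothing** drops all-zero species with a warning (they
carry no phenological signal and make the overlap distance undefined);
a community left with fewer than two species is an error.

## Distances and diversity

O_ij = 1 − 2∫z_i z_j / (∫z_i² + ∫z_j²), trapezoidal integrals. The rule
adds no information beyond the grid points, so higher-order quadrature
is not used. O is 0 iff the curves are pointwise identical, 1 iff their
supports are disjoint, invariant to joint rescaling, and in [0, 1] for
nonnegative curves; values in (−1e-12, 0) arising from float roundoff
are clamped to 0. One all-zero curve against a nonzero partner scores 1
with a warning; two all-zero curves are an error.

qPD uses Q = ΣΣ O_ij p_i p_j over all ordered pairs (the diagonal
contributes nothing since O_ii = 0). Conventions:

- **Q = 0 → qPD = 0.** All curves identical; reported as zero effective
  phenological curves rather than an error.
- **q = 1 window.** |q − 1| < 1e-6 switches to the exponential limit
  form; the order-q form is numerically unstable at its removable
  singularity. Agreement at q = 1 ± 1e-4 is within relative 1e-3.
- **0·log 0 = 0** in the limit form.
- Default profile grid: 41 points on 0 ≤ q ≤ 2.

Properties the implementation guarantees (all tested): qPD ≥ 0 and
qPD = 0 iff Q = 0; non-increasing in q; invariant to a common intensity
rescaling and to uniform time rescaling; qPD = S for S disjoint
equal-weight curves at every q.

Two consequences of the equations worth knowing. First, ⁰PD can exceed
S whenever Q < 1 (partially overlapping curves), so qPD is not bounded
by species richness at low orders. Second, for S = 2 the order-q double
sum collapses to (p₁p₂)^(q−1), so the profile is identically
(p₁p₂)^(−1/2) — flat in q, independent of the distance, and above 2
whenever the two intensities differ. Because O/Q is scale-free in O,
uniformly small distances do not drag qPD toward zero: a community of
near-identical-but-unequal constant curves still evaluates to a large
effective number. Zero is reached only in the exact-identity limit.

## Simulator

`simulate_case` reproduces nine benchmark scenarios crossing temporal
arrangement (staggered pulses vs year-round presence), intensity
equality, and community size (S = 40 vs S = 2); `simulate_random` draws
parameterized random pulse communities for property testing. Choices:

- **Pulse shape**: Gaussian bump truncated at ±4σ (support = 8σ). The
  truncation (≈3×10⁻⁴ of peak height at the cut) makes non-adjacent
  pulses *exactly* disjoint on the grid, so the closed-form ceiling
  qPD = S is met to 1e-9 rather than approximately. Peak k sits at
  (k + ½)/S of the period for "equally distributed" cases; the
  two-species "not equally distributed" cases displace the peaks to
  0.40/0.60 of the period, forcing partial overlap.
- **Support width**: 0.02 of the period for the 40-species staggered
  cases (pairwise disjoint at spacing 0.025) and 0.25 for the
  two-species cases.
- **Intensity inequality**: geometric series with ratio 0.9 — a
  documented, reproducible gradient.
- **Normalization**: each curve is rescaled so its trapezoidal area
  equals its prescribed intensity; "equal intensities" is then exact by
  construction, not approximate.
- Generated curves are already smooth and are flagged as such,
  bypassing the wavelet stage by default; end-to-end tests re-smooth
  raw synthetic series explicitly.
- Randomized quantities in `simulate_random`: peaks uniform over the
  period (clipped so supports stay inside the window), supports uniform
  in [½, 1]× the nominal width, unequal amplitudes log-uniform over one
  decade, all from a seeded generator — identical specs and seeds give
  identical communities.

What the simulations do not emulate: observation noise, missing
surveys, multi-year records, autocorrelated within-season variation,
and multimodal species phenologies. Tests passing on them establish the
algebraic behavior of the measure (ceilings, collapse, profile shape,
oracle agreement), not robustness to field-data artifacts; the wavelet
tests use separate noisy pulse fixtures for that purpose.

## Problem sizes in the shipped tests

The benchmark scenarios run at their native S (40 or 2) on 180–360
point grids; property tests use 100 seeded random communities of S ≤ 8
on 120-point grids, and the oracle comparisons use S ≤ 4 step-curve
fixtures on 48 points, where the explicit-loop reference is exact.

## Known limitations

- Presence/absence (binary) phenology tables are out of scope; the
  overlap distance needs graded intensities.
- The τ cutoff is this package's convention; other smoothing software
  parameterizes attenuation differently, so τ values are not portable
  across tools even at the shared default of 2.
- Curves are compared on a single shared window; no circular/periodic
  alignment is applied, so a phenophase split across the window
  boundary is seen as two pulses.
- No uncertainty quantification (bootstrap/rarefaction) is provided.
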