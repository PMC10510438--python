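# Methods

## The physical model

A membrane-bound electrochromic dye such as di-8-ANEPPS changes its emission
spectrum when a transmembrane potential is applied, because the ground and
excited electronic states carry different charge distributions (the excited
state moves positive charge from the pyridinium nitrogen near the interface
to the amino nitrogen deeper in the membrane). In a classical-trajectory
treatment the two states are represented by two force fields evaluated on
identical nuclear configurations (vertical, Franck–Condon transitions):

* **absorption** gap: ΔE = E_es − E_gs on configurations sampled from the
  *ground*-state trajectory;
* **emission** gap: the same difference on configurations from the
  *excited*-state trajectory.

The peak wavelength is obtained from the ensemble-averaged gap,

    λ = hc / (⟨ΔE⟩ − c),

i.e. the mean gap is computed first and then inverted (the alternative
⟨hc/ΔE⟩ differs only at second order in the fluctuations, but the
average-then-invert form is the defining convention here). The empirical
offset `c` is voltage-independent and absorbs all nonradiative vibrational /
reorganization energy not captured by classical force fields. Defaults:
`c_em = 12.6` kcal/mol, calibrated against the membrane emission peak, and
`c_ab = 4.99` kcal/mol from a solvent-series calibration (no
voltage-dependent absorption data exist in membrane). Their ~7.6 kcal/mol
difference is consistent with twice a ~2.9 kcal/mol (1000 cm⁻¹)
reorganization energy expected for shifted harmonic surfaces. `offset_from_reference`
inverts the same relation, so calibration and mapping round-trip exactly.

The conversion constant is `hc·N_A = 2.85916 × 10⁴ kcal·nm/mol`
(thermochemical kcal), documented to 6 significant figures. This is the
value that makes the bundled wavelength table and its gap means mutually
consistent; a CODATA re-derivation differs from it only in the 6th
significant figure (≈2 ppm), far below every tolerance used anywhere in the
package.

An applied potential V enters the simulations this package analyses as a
uniform field E_z = V/L_z along the membrane normal. Its spatial profile is
summarized by the dimensionless potential fraction

    f(z) = ⟨φ(r; V) − φ(r; 0)⟩_xy / V,

the xy-averaged difference of electrostatic maps at two voltages divided by
the applied voltage. f plateaus at 0 in the bulk on one side and 1 on the
other; no symmetrization across leaflets and no re-binning beyond the grid's
native z spacing are applied, and f is deliberately not clipped to [0, 1]
(real maps over/undershoot near interfaces). A set of point charges couples
to the potential as Σ qᵢ f(zᵢ) with linear interpolation between z nodes,
clamped to the end values outside the profile's range.

## Ratiometry

Experiments rarely report peak shifts directly; they report the intensity
ratio at two fixed emission wavelengths (620 and 560 nm), which cancels dye
concentration and collection efficiency. The emission band is modeled as a
Lorentzian with a voltage-dependent peak:

    F(λ; V) = I_max Δλ² / ((λ − λ_max(V))² + Δλ²),
    λ_max(V) = 605.97 − 0.0071·V  [nm],  Δλ = 51.1 nm,  I_max = 153.4.

**Width convention.** Δλ is the half-width at half-maximum. The source
material does not render the formula unambiguously, so the convention is
pinned by an oracle test: with the HWHM reading, the relative 620/560 ratio
change at 0 mV referenced to −100 mV evaluates to −0.0353, matching the
published −0.0352 calibration line; reading Δλ as a full width yields
≈ −0.156 and is rejected by the suite. The published calibration line's
printed slope sign is internally inconsistent with its own zero at −100 mV,
so tests assert the value at 0 mV and the slope magnitude, not the sign of
the printed linear form.

`invert_ratio_slope` converts a measured ratio-vs-voltage slope into a
peak-shift slope by dividing by the analytic sensitivity
d(ratio)/d(peak) evaluated at the 0 mV peak. This linearization is accurate
because peak shifts over the ±100 mV window (≤ 0.71 nm) are tiny against
the 51.1 nm width; the forward/inverse round trip is verified to 1 % across
randomized geometries. The sensitivity vanishes where
(λ_num − peak)(λ_den − peak) = Δλ², and the inversion refuses such blind
geometries instead of returning a huge number.

## Error estimation

All trajectory means carry block-average standard errors: the series is cut
into `n_blocks` contiguous blocks (default 10; remainder frames join the
last block), and SE = sd(block means, ddof=1)/√n_blocks. For blocks much
longer than the correlation time this estimates the true SE of a correlated
mean. Wavelength SEs follow by the first-order delta method,
SE(λ) = λ²·SE(⟨ΔE⟩)/hc. Summary tables report the *population* SD over
frames (divisor n) because those ± values describe the configurational
spread, not the uncertainty of the mean.

The headline voltage-response fit is ordinary least squares restricted to
the ±100 mV window: the ±500 mV conditions are far outside the dye's
experimentally established linear-response range and would bias the slope
(they are logged as warnings, not errors). The full-range "average shift
per 100 mV" is a separate endpoint statistic,
|λ(min V) − λ(max V)|/(span/100).

## Synthetic surrogate data

The generators replace μs-scale membrane MD, which is not recomputable at
desk scale. They emulate exactly the statistical structure the analysis
consumes, and nothing more:

* **Scalar series** (energy gaps, atom z-tracks): stationary Gaussian AR(1),
  `x_t = μ + ρ(x_{t−1} − μ) + √(1−ρ²)·σ·ε_t`, initialized from the
  stationary distribution, so mean, SD and lag-1 autocorrelation equal
  (μ, σ, ρ) at every frame.
* **Tilt angles**: the same AR(1) driver mapped through a Gaussian copula
  onto a normal marginal truncated to [0°, 180°], then a uniform azimuth;
  vectors are unit length by construction. Truncation shifts the stationary
  mean by ≤ 0.17° for the bundled parameter cells, well inside every test
  tolerance; recovery tests compare against the truncated marginal's exact
  mean.
* **Potential grids**: the biased grid carries V·f(z) from a prescribed
  profile plus iid voxel noise of SD `noise_sd/√2` per grid, so the grid
  *difference* has noise SD exactly `noise_sd`.

Defaults are the published tables: per-(state, voltage) tilt and atom-z
means/SDs, and gap means obtained by inverting the published wavelength
table through the offset relation, so the end-to-end pipeline reproduces
both tables in expectation. Parameters the published record does not
constrain were fixed once:

* `ρ = 0.9` for all series. No correlation times are published; at the
  100 ps frame interval implied by 10,000 snapshots per μs, ρ = 0.9
  corresponds to a ~1 ns relaxation time, typical of probe position and
  orientation dynamics in a bilayer. It inflates the SE of a mean by
  √((1+ρ)/(1−ρ)) ≈ 4.4 over iid sampling, which the block-average machinery
  must (and does) capture.
* gap SD `σ = 2.0` kcal/mol, a typical instantaneous spread for a
  chromophore energy gap in a fluctuating polar environment; with ρ = 0.9
  and 10⁵ frames this puts emission SEs at ~0.3 nm, the same scale as the
  published ±0.14–±0.5 nm.
* default synthetic f(z): a logistic drop centered at z = 14 Å with 3 Å
  width on a 60×60×72 Å box (1.5 Å spacing), mimicking the interfacial
  potential drop on the dye-bearing side.

What the surrogates deliberately do **not** reproduce: real anharmonic or
multi-timescale dynamics, cross-correlations between observables, non-Gaussian
tails, and any back-coupling of voltage onto fluctuation magnitudes.
Passing recovery tests therefore demonstrates that the *analysis chain* is
correct and unbiased at realistic noise and correlation levels — not that
the generative model is a faithful membrane simulator.

## Problem sizes and numerical choices

The recovery suites use 10⁵ frames per condition (10 conditions) and
40×40×48 grids — chosen so 3-SE parameter-recovery bands are a few tenths
of a nm/Å/degree, tight enough to catch mapping errors, while the whole
suite runs in seconds. Fixed seeds make every generated dataset
bit-reproducible; the pipeline derives per-condition sub-seeds
deterministically from one master seed and echoes it in the run manifest.

Degenerate inputs are contracts, not accidents: σ = 0 series are exactly
constant; a constant series has block SE exactly 0; zero-length or
non-increasing frame indices, non-congruent grids, zero applied voltage,
non-positive effective transition energies, and sub-3-point line-shape fits
all raise with actionable messages. Line-shape fitting uses
Levenberg–Marquardt least squares with a data-driven initial guess (tallest
point as peak, quarter-span as width) and reports parameter SEs from the
covariance; the model is even in the width, which is reported positive.

## Known limitations

* The ratiometric calibration is tied to one line-shape family; other band
  shapes would change the inversion factor by a few percent.
* The absorption offset is a solvent-series value; absolute absorption
  wavelengths inherit that calibration's uncertainty.
* Block-average SEs are biased low if blocks are shorter than a few
  correlation times; with the defaults (10⁴-frame blocks, ~10-frame
  correlation) this is negligible, but short custom runs should reduce
  `n_blocks`.
* `range_of_motion` compares the two extreme voltages only; it is not a
  fitted sensitivity.
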