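# Methods

This note records the models, conventions, parameter choices and known
limitations behind `fetalshim`, in the order the pipeline runs.

## Field-map estimation

The B0 map is the inter-echo phase of two gradient echoes,
`f = angle(e2 · conj(e1)) / (2π ΔTE)` (Hz), so its unambiguous range is
±1/(2 ΔTE) (±217 Hz for the default ΔTE = 2.3 ms). Echo times default to
4.6 / 6.9 ms: one full water-fat beat period apart, so fat accrues ≈ −2π
between echoes and appears (almost) on-resonance instead of aliasing —
the in-phase condition `TE2 = TE1 + 1000/|shift|`. With the package's
default shift of −430 Hz (rather than the 3.4 ppm value of −434.8 Hz that
makes 2.3 ms exact), a 95%-fat voxel retains a small apparent offset of a
few Hz; this is a property of the acquisition, not an artifact of the
implementation.

Voxels are trusted when their mean echo magnitude exceeds 5% of the
99th-percentile magnitude — a robust threshold that excludes background
air without clipping low-signal fetal tissue.

## Goldstein unwrapping

Unwrapping is 2-D per slice: residues are the 2×2 loop integrals of
wrapped gradients; opposite charges are paired greedily (nearest first,
or cut to the border when that is closer), cuts are rasterized as blocked
pixels, and the phase is integrated by flood fill that never crosses a
cut; cut pixels are attached last and flagged less reliable. On a
residue-free slice this reduces to exact path-independent integration
(verified against 1-D Itoh unwrapping in the tests). Two freedoms remain
and are resolved explicitly:

* slice-to-slice: each slice is shifted by the 2π multiple that zeroes the
  median difference to its neighbour inside the joint valid mask (the
  acquisition gives no constraint here; the rule assumes fields vary
  smoothly through-plane);
* global: each connected component is shifted by the multiple of 1/ΔTE
  that brings its median frequency into the Nyquist band — i.e. bulk
  tissue is assumed near the water resonance. A region whose true median
  offset exceeds ±217 Hz cannot be anchored from this acquisition alone.

## Dixon water-fat separation

Three echoes at 4.6/5.6/6.6 ms are inverted per voxel under the
single-peak model `s(te) = (W + F·e^{i2πσte})·e^{i2πf0·te}` by variable
projection: a 4 Hz grid over f0 with the complex amplitudes solved
linearly at each candidate, followed by Gauss-Newton refinement
(weighted phase-slope updates). Multi-peak fat spectra are deliberately
omitted — the result only feeds a 0.5 fat-fraction threshold.

The model family has an exact two-fold ambiguity: swapping W and F while
moving f0 to `wrap(f0 − σ)` reproduces the data identically (for the
default σ = −430 Hz and 1 ms spacing the partner sits 430 Hz away,
modulo 1000 Hz). Both candidates are therefore refined and the one whose
f0 is closer to a per-voxel prior is kept. The prior defaults to zero,
which is provably correct while |f0| stays below roughly half the partner
spacing; the pipeline instead passes the B0 map measured with matched
geometry, which resolves the swap at any attainable off-resonance. This
is the package's substitute for the spatial region-growing used by
full-scale Dixon reconstructions.

Fat segmentation thresholds the fat fraction F/(W+F) at 0.5 (configurable)
above the magnitude noise floor; an empty mask degrades the constrained
solve to the localized one with a warning rather than failing.

## Shim model

The basis is the eight first- and second-order real solid harmonics
X, Y, Z, Z2 = 2z²−x²−y², ZX, ZY, X2−Y2, XY, evaluated at voxel centers in
mm from isocenter. Coefficients are expressed in "Hz at the reference
radius" (default 200 mm): each term is scaled so a unit coefficient
produces 1 Hz at the radius along the term's principal direction (the
maximizer of |term| on the reference sphere). Conversion to coil amperes
is an external calibration table and out of scope; the default hardware
bounds of ±2000 Hz-at-20-cm are placeholders that real systems must
replace. The constant (center-frequency) term is excluded from the solve —
scanners apply it as a transmitter offset — and reported instead as the
residual brain mean.

Sign convention: the solvers fit `A·s ≈ ΔB0`, so hardware must apply the
negated coefficients; the residual map is always `ΔB0 − A·s`.

## Solvers

Both objectives carry the Tikhonov term λ‖s̃‖² with λ = 0.03, where s̃
are coefficients after scaling each column of A to unit RMS over the ROI;
this makes the dimensionless λ meaningful regardless of units and
guarantees a unique solution even for degenerate ROIs (fewer than 8
voxels triggers a warning). The bound-constrained problem is solved by
active-set bounded least squares (BVLS) on the stacked system — exact to
machine precision.

The fat-constrained QP adds two inequality rows per fat voxel. It is
solved by outer constraint generation: start from the bound-clipped
unconstrained minimum, add (up to 20) most-violated rows, solve the small
working-set QP with a trust-region iteration, and repeat until no row is
violated — exact for a convex QP. Each inner solution is polished by
solving the equality-constrained KKT system on the identified active set
(trying several activity tolerances and keeping the best candidate that
is primal feasible with non-negative multipliers). Returned solutions
satisfy every fat constraint within 1e-6 Hz; band endpoints count as
feasible. Fat voxels may be subsampled (`fat_subsample=k`) for speed;
default is every voxel.

Infeasible constraint sets (e.g. a gas pocket adjacent to the fat ring)
are handled per policy: `strict` raises with the most-violated voxels,
`relax` (default) widens the band symmetrically by the smallest ε that
admits a solution — found by linear programming — and records ε in the
solver report, because in-vivo gas pockets can make strict feasibility
impossible while a minimally-relaxed solution is still the best available
compromise.

A multi-scale dense grid-search oracle (`qp_oracle`, ≤ 3 free
coefficients) cross-checks both solvers in the tests; its parameter
accuracy is limited to a few grid steps when an active constraint face is
oblique to the grid, so oracle comparisons use axis-aligned or diagonal
constraint rows.

## SPIR simulation

The vendor's pulse shape is proprietary; the documented stand-in is a
Hamming-windowed sinc with the published parameters (duration 7.5 ms,
time-bandwidth product 6.20, nominal flip 110°, offset 550 Hz on the fat
side; the band center sits at −offset internally). Note the published
parameters are mutually inconsistent (752 Hz × 7.5 ms = 5.64 ≠ 6.20);
the package treats TBP and duration as primary, giving a small-tip FWHM
of ≈ TBP/duration = 827 Hz. Amplitude is calibrated so the on-resonance
rotation equals the nominal flip.

Saturation profiles are hard-pulse Bloch products (piecewise-constant
rotations, 512 samples by default; relaxation during the 7.5 ms pulse is
neglected since T1,fat ≈ 380 ms ≫ duration). The effective band is the
contiguous range where saturation 1−Mz ≥ 95% of its peak, edges located
by linear interpolation, also expressed as fat deviation by subtracting
the −430 Hz shift. Under these choices the optimized pulse yields a
fat-deviation band of [−295, +55] Hz: the center matches the published
constraint window [−350, +100] Hz (−120 vs −125 Hz) but the width is
350 vs 450 Hz — the real vendor pulse evidently has a flatter top than a
Hamming sinc. The shape assumption therefore bounds the accuracy of all
band-derived numbers at roughly ±50 Hz, and the lower edge sits just at
that limit.

Signal-vs-offset sweeps weight the post-pulse Mz (after mono-exponential
T1 recovery over the SPIR delay, default timed to null fat:
T1,fat·ln(1−cos 110°) ≈ 112 ms) by synthetic spectral histograms —
fat Gaussian(−430, 80) Hz, water Gaussian(0, 25) Hz, emulating the narrow
fetal-brain water line. T1 defaults: fat 380 ms, water 2000 ms.

## Phantom

The generator emulates a maternal-abdomen field-map acquisition:
70×70×10 voxels at 5×5×10 mm (350×350×100 mm FOV), an elliptic torso
(160×120 mm semi-axes) of water signal, a 15 mm subcutaneous fat ring at
95% fat fraction carrying the chemical-shift species, an ellipsoidal
fetal-brain ROI, a background field that is an exact combination of the
eight shim harmonics, optional spherical gas pockets adding the analytic
external dipole field `strength·(3cos²θ−1)/r³` (zero field and zero
signal inside; Lorentz correction ignored), Gaussian field noise
(`noise_sd`, Hz) and optional receiver noise (`snr`; default noise-free —
`noise_sd` is the primary noise knob). Echo images are forward-simulated
from the two-species model at the protocol echo times; all randomness is
fixed by the seed.

The default background coefficients (300, −200, 100, 150, −100, 80, 120,
−60 Hz-at-20-cm) are calibrated so the zero-shim brain-ROI SD is ≈ 36 Hz,
the inhomogeneity level reported for unshimmed fetal acquisitions. Three
presets cover the regimes of interest: `pure-sh` (field exactly in the
shim span — both solvers recover ground truth and constraints stay
inactive), `fat-conflict` (off-center brain beside a gas pocket; the
localized fit extrapolates badly to the fat ring, the constrained solve
repairs it), and `gas` (a dipole the 8-term basis cannot represent; the
best-SH-fit residual is the floor any solver can reach, and the localized
solver reaches it).

What the phantom does not emulate: anatomical tissue structure, motion
(respiratory or fetal), B1 inhomogeneity, multi-peak fat, coil
sensitivities. Passing tests therefore demonstrate the correctness of the
computational pipeline under the stated physics, not robustness to
real-world confounds.

## Evaluation metrics

Brain homogeneity is the population SD of the residual field over the ROI
(valid voxels only); fat-suppression compatibility is the percentage of
fat voxels whose residual leaves the closed band [d1, d2]. EPI
displacement arithmetic: shift in acquired pixels =
|Δf| · ETL · echo-spacing, with echo spacing = 1/(2·f_switch) from the
readout switching frequency. For the protocol values (434 Hz, 490 Hz
switching, ETL 73) this gives 32.3 pixels; the corresponding published
figure is 33, a discrepancy attributable to an unstated rounding or
matrix convention, so the function returns the unrounded value.

## Parameter-recovery measurements

Coefficient-recovery experiments (and the noise-scaling check) run the
localized solver at λ = 0: the Tikhonov term deliberately shrinks
coefficients (≈ 0.01 Hz-equivalent at λ = 0.03 on the default phantom),
which is negligible for shimming but incompatible with machine-precision
recovery bounds. λ = 0.03 remains the default everywhere else.
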