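# Methods

This note documents the models behind `retromoco`, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate about real data.

## Rigid motion model

Head motion is parameterized by six degrees of freedom: translations
(tx, ty, tz) in mm and rotations (rx, ry, rz) in degrees.  Rotations are
intrinsic, applied in the order x, then y, then z, right-handed, about the
volume centre; mm and degrees at every interface, radians internally.
Registration packages differ in their rotation conventions; ours is fixed
and documented here rather than matched to any particular tool — only the
6-DOF rigid model itself matters to the correction.

Motion is piecewise-constant per shot: every k-space shot (the lines
acquired contiguously between two navigators, a few seconds of scanning) is
assumed to share one head pose.  Intra-shot motion, spin-history effects,
eddy currents and gradient delays are out of scope.

## Forward model and correction

For a shot whose pose moves the object by (R, t), the measured sample at
Cartesian coordinate k (cycles/FoV) is

    m(k) = exp(-2πi k·t_fov) · F(Rᵀk),

with F the spectrum of the static coil-weighted object — the Fourier
rotation and shift theorems.  The correction inverts this per RF channel:
multiply by the conjugate phase ramp, reassign each sample to the rotated
coordinate k' = Rᵀk, accumulate all shots, and reconstruct with the adjoint
(type-1) NUFFT on the target grid.  No density compensation is applied:
under small motion the rotated pattern stays near the Cartesian grid, and
the gaps/overlaps that larger rotations create in k-space are an accepted
limitation of the approach.  Unacquired partial-Fourier regions stay
zero-filled.  Channels are combined by root-sum-of-squares; the corrected
image sits in the reference navigator's head position (reference pose =
identity).

Two approximations are deliberate and shared between the simulator and the
corrector: (a) coil sensitivities are fixed to the scanner frame but are
applied to the object *before* the motion, valid for small motion; (b)
rotated coordinates that leave the Nyquist box are wrapped periodically —
the spectrum of a gridded object is periodic, so this is the
self-consistent convention for both directions (the affected samples are
the extreme k-space corners).

For pure translations the correction is exact: the phase ramp cancels
analytically, and the tests verify bit-level (1e-9) agreement with the
motion-free samples.  For rotations the residual error is set by the NUFFT
accuracy and the gap/overlap geometry and grows with the rotation angle.

## NUFFT

No external NUFFT library is used; `retromoco.nufft` implements types 1 and
2 by Kaiser–Bessel gridding: 2× oversampled FFT, kernel width 8, Beatty's
shape parameter, exact adjoint pairing, and deapodization by the kernel's
continuous transform.  Relative accuracy against the brute-force DFT is
~1e-7 (contract: 1e-6).  Inner gather/scatter loops are numba-compiled.
With the default normalization the adjoint reduces to the centred inverse
FFT on fully-sampled Cartesian data.

## Phantom and coils

The phantom is a set of nested ellipsoids (scalp fat / skull gap / CSF /
GM / WM) with per-compartment PD, T1, T2, T2\* and fat fraction, plus an
optional smooth seeded PD texture.  Default 7T-like values (WM T1 1200 ms,
GM 2000 ms, CSF 4000 ms) are fixture choices, freely editable via the
compartment table.  Two design points matter for the method:

* the fat shell is the **only** fat-bearing compartment and moves rigidly
  with the brain — it is the object the fat-selective navigator sees;
* the head ellipsoids have three distinct semiaxes (longer front–back,
  like a head).  A spherical shell would make rotations unobservable to
  the navigator registration.

Coil sensitivities are Gaussian lobes on a ring with smooth seeded phase,
normalized so the root-sum-of-squares is ≈1 over the object.

What the phantom does **not** model: anatomical detail, susceptibility,
chemical-shift displacement of fat, B0/B1 inhomogeneity, RF excitation
physics (fat selectivity is modelled as imaging the fat map, not as a
binomial pulse simulation), and relaxation during readout trains (the TSE
variable-flip-angle evolution is reduced to an optional k-space weighting
and is unvalidated).  Passing tests therefore demonstrate the correctness
of the geometry/Fourier machinery and the estimation pipeline, not
robustness to the full physics of in-vivo data.

## Navigator simulation and motion estimation

Navigators are simulated by rigidly resampling the fat map under each
shot's pose, weighting by the coil RSS, and band-limiting to the navigator
grid by Fourier cropping.  The default navigator grid is 3/4 of the
phantom grid so the head spans ~40 navigator voxels — a desk-scale stand-in
for the real 2 mm navigator, in which the head spans ~85 voxels.  An
optional k-space path applies the navigator's own undersampling
(partial-Fourier zero-filling plus GRAPPA) before RSS combination.

Motion is estimated by registering every navigator to the first
(magnitude-to-first; the reference choice is a convention).  The registrar
is a three-level multi-resolution Levenberg-damped Gauss–Newton on the mean
squared intensity difference with trilinear resampling, central-difference
Jacobians over the six parameters (fixed steps: quarter voxel / quarter
degree), and an FFT phase-correlation translation initialization at the
coarsest level.  Convergence: parameter update < 1e-3, at most 100
iterations per level.

One numerical choice is essential: navigators are **sinc-upsampled 2×**
(Fourier zero-padding) before registration.  On the native coarse grid the
combination of aliasing from band-limiting a voxel-thin bright shell and
the smoothing loss of trilinear interpolation displaces the MSE minimum by
up to a degree — the optimizer finds the true minimum of a biased cost.
After upsampling, trilinear resampling of the band-limited volumes is
nearly exact and the bias collapses: over 20 random poses within
3 mm / 3°, the median absolute recovery error is ~0.04 mm / 0.05°
(requirement: < 0.2).  A residual rotation cross-talk of up to ~0.3° can
appear for particular pose/geometry combinations; the same upsampling at
3× removes it at triple cost, and the default stays at 2×.

## GRAPPA

Missing lines are synthesized from the bracketing acquired lattice lines
(2 source positions per undersampled PE dim, 3 taps along each fully
sampled dim including the readout), with weights fitted by
Tikhonov-regularized least squares (λ = 1e-4 × mean source energy) on a
fully-sampled central calibration block.  Source indexing is periodic:
coil weighting in image space is a circular convolution in the DFT domain,
so wrap-around is the exact boundary treatment for gridded data and edge
lines need no special-cased kernels.  Acquired lines pass through
bit-exact.  On noiseless 8-coil data at R=2 with a 24-line calibration
block the full-volume NRMSE is ~0.2%; 4×4 undersampling (the real
navigator's factor) needs the coil count of a real 32-channel array to
reconstruct well and is exercised in reduced form.

## MP2RAGE

One cycle of the sequence — inversion (Mz → −η·Mz), relaxation, n pulses of
α1 around TI1, relaxation, n pulses of α2 around TI2, relaxation to the
cycle end — is an affine map of the longitudinal magnetization, so the
periodic steady state is its closed-form fixed point (the fixed-point
iteration agrees to 1e-9 and serves as the test oracle).  Each RF pulse is
centred in its echo-spacing cell; TI is referenced to the train centre
(the k-space centre of a linearly ordered train), and signals are
S_i = sin(α_i)·Mz just before the central pulse.  S1 is signed — tissue
still recovering at TI1 yields negative values — and the lookup is built
on the signed UNI.

Defaults mirror a 7T 350 µm protocol: TI 800/2700 ms, flips 5°/7°, echo
spacing 7.8 ms, 166 echoes per train (442 lines × ¾ partial Fourier /
GRAPPA 2), 6000 ms cycle.  The adiabatic inversion efficiency is not
knowable from protocol sheets; it defaults to η = 0.96 and is exposed as a
parameter.  The lookup table keeps the largest strictly monotone branch of
UNI(T1) (167–5000 ms for the default protocol and 1 ms grid — the curve
folds at very short T1) and inverts by linear interpolation with clamping
and a clamp count.

## PSF, effective resolution and scan economics

Zero-filling the unacquired quarter of a ¾ partial-Fourier dimension
broadens the point-spread function.  Two width measures are reported,
because they answer different questions:

* **half-max FWHM of |PSF|**: the magnitude of the transform of the
  asymmetric window is a scaled Dirichlet kernel, so this ratio is exactly
  1/fraction (4/3 for ¾) and is strictly monotone in the fraction;
* **Gaussian-equivalent width of the in-phase PSF**: for a real-valued
  object the quadrature component of the PSF lands orthogonal to the
  signal in a magnitude image, so the blur is governed by the in-phase
  (real) part.  Matching a Gaussian to its peak curvature gives
  σ_x = n/(2π σ_k) with σ_k² the second moment of the acquired band
  (taken as the continuum interval spanned by the acquired cells; the
  densely evaluated PSF curvature reproduces it within 0.3%).  For ¾
  coverage this ratio is exactly √(4/3) ≈ 1.155 — the ~15% effective
  broadening that turns 350 µm nominal into ~400 µm and 380 µm into
  ~440 µm.

`effective_resolution` uses the second measure.  The undersampling buys a
9/16 scan-time fraction (43.75% saved) when both PE dimensions are ¾
covered.  `voxel_economics` implements the SNR arithmetic (SNR ∝ voxel
volume × √time): 500 µm → 350 µm shrinks the voxel volume by 2.92 (~3) and
demands 8.5× (~9, as the square of the rounded volume ratio, protocol-sheet
style) the scan time at matched SNR.

## Scan-time model

GRE: host time = acquired lines × TR; the navigator (1152 ms, a stored
protocol constant — it is not derivable from the navigator matrix and
undersampling by simple arithmetic) follows every partition loop and adds
to the scan: 36 min host → 42 min total, one navigator per 7.6 s.
MP2RAGE: one shot per 6000 ms inversion cycle, 312 cycles → 31 min;
navigators fit in dead time.  TSE: shots × TR with one train per TR;
navigators in dead time.  The TSE model is a simplification — the printed
total of the real protocol is not reproducible from matrix/turbo-factor
arithmetic alone (vendor sequences insert preparation and recovery periods
the protocol sheet does not itemize) — and TSE timing carries no headline
number here.  Printed minutes round half-up.

## Bias-field correction

A smooth field is fitted to voxels above a user-chosen threshold by
penalized least squares on the DCT basis (the discrete Laplacian is
diagonal there), with missing-data fixed-point iteration and the smoothing
parameter chosen by generalized cross-validation over a logarithmic grid
(s ≥ 1; the GCV trace is pro-rated to the masked voxel count).  The volume
is divided by the fit, guarded by a floor at 5% of the mean fit magnitude,
and rescaled to preserve the mean over the threshold region.  On a
piecewise-constant phantom under a low-order multiplicative field this
cuts within-tissue coefficient of variation ~5× and is idempotent to <1%.

## Fourier resampling

Downsampling mimics acquiring a coarser scan: centred spectral cropping
with pass-band amplitudes preserved.  The default crop is sharp, making
downsample-then-upsample an exact orthogonal projection (idempotent to
machine precision); a raised-cosine `taper` option softens ringing at the
cost of that property.  Unpaired Nyquist planes are split symmetrically on
zero-padding and folded back on cropping, which keeps real volumes real
and the projection exact for even grid sizes.

## Problem sizes and determinism

Every generator and simulation is a pure function of its arguments and an
integer seed.  The standard synthetic experiment used throughout the tests
is a 64³ phantom, 8 coils and 16 shots with poses within 3 mm / 3°
(navigators at 48³): large enough that the head spans ~56 voxels and the
correction's 3× error-reduction criterion is meaningful, small enough that
the full suite runs in minutes on one CPU.  Known limitations worth
restating: no intra-shot motion, no noise in the default experiments
(noise injection is available and seeded), small-motion approximations in
both simulator and corrector, and a navigator geometry that is a
deliberately simplified stand-in for scalp anatomy.
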