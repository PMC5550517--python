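# Methods

## Imaging model

The package models a Köhler-illuminated brightfield microscope as a 6-f
partially coherent system: a spatially incoherent source S(u') in the
condenser aperture plane, an object of complex transmittance t(x), and an
aberration-free objective pupil |P(u)| of normalized radius 1.  Quasi-
monochromatic light and unit magnification are assumed (the pixel pitch is
the object-space pitch).  Defocus by a distance z is modelled rigorously as
the angular-spectrum propagation factor exp(ikz√(1 − λ²|u|²)) applied inside
the pupil — not the Fresnel (paraxial) chirp — so the transfer functions
remain valid at high NA.  The evanescent argument 1 − λ²|u|² is clipped at
zero and the pupil is zero beyond |u| = 1/λ.

All spatial frequencies are expressed in pupil-normalized units
ū = |u|·λ/NA_obj: the coherent diffraction limit sits at ū = 1 and the
incoherent limit at ū = 2.

### Weak-object transfer function (WOTF)

For a weak object, t ≈ a₀ + Δa + i·a₀φ, the image intensity becomes linear
in the object and is governed by the linear part of the transmission
cross-coefficient:

    WOTF(u) = ∬ S(u') |P(u')||P(u'+u)|
              · exp{ikz[√(1−λ²|u'+u|²) − √(1−λ²|u'|²)]} du'

normalized by the background WOTF(0) (source energy inside the pupil), so
that curves express image *contrast*.  The real part transfers absorption,
the imaginary part transfers phase.  For any axisymmetric source the WOTF
is Hermitian in defocus — Re even, Im odd in z — so subtracting two images
taken at ±Δz isolates phase contrast and adding them isolates absorption.

Quadrature: the source integral is evaluated as a Riemann sum on a
Cartesian lattice whose step equals the radial evaluation step (default
2/1024 in ū).  This lattice alignment is load-bearing: for an annular
source [s1, s2] the map p → (−pₓ−ū, p_y) pairs samples with opposite
integrand sign whenever ū ≥ 1 + s1, so the discrete Im WOTF cancels to
rounding beyond the theoretical phase cutoff 1 + s1 (= 2 − Δs for a matched
annulus) instead of leaving a quadrature-noise tail.  By radial symmetry
the profile is computed along one frequency axis only (each sample is still
a full 2D source integral); 2D maps for deconvolution are synthesized by
radial interpolation.  Delta (coherent) sources bypass interpolation and
evaluate the closed form |P|²·exp(ikz[√(1−λ²u²) − 1]) directly on the grid.

Sign convention: with numpy's FFT conventions the coherent/circular phase
WOTF imaginary part is negative at small positive defocus
(≈ −sin(πλz|u|²)), and matched annular illumination yields the *opposite*,
single sign — "inverse contrast": optically thick structures appear dark on
over-focus.  Publications using the e^{+i2πux} analysis convention print
these curves with flipped sign; the physics (which structures darken, and
the inversion formula below) is convention-free and is what the tests pin
down.

### Aperture comparison metrics

Total phase contrast is the trapezoidal integral of |Im WOTF| over ū from 0
to the profile end (≥ 512 samples over [0, 2]); the phase-contrast cutoff
is the largest ū with |Im WOTF| above 1e-6 of its peak (meaningful because
of the exact cancellation above); pointwise gains between two apertures are
ratios of |Im WOTF| linearly interpolated on a *common* radial axis.

## Forward simulation

`abbe_image` implements Abbe's source-point superposition: each source
sample u_s contributes a coherent sub-image |F⁻¹[F[t](ν)·P_z(ν+u_s)]|², with
the shifted pupil evaluated at the true (unwrapped) frequency ν + u_s, and
the sum is normalized by the empty-object (t ≡ 1) background so a uniform
object gives unit intensity — the same normalization as WOTF(0).  Source
samples live on the image FFT lattice (bit-reproducible; an integer
`supersample` factor refines the lattice for convergence checks, and the
default 256² study geometry yields ~1.4·10³ samples for the Δs = 0.1
annulus).  `weak_object_image` is the linearized alternative — one WOTF
application instead of a source loop — and doubles as the simulator's
oracle: the two agree to a few percent in relative L2 for peak phases
≲ 0.1 rad, with the discrepancy scaling quadratically in the phase.

Noise is additive i.i.d. Gaussian in normalized intensity units, applied
after normalization, with per-plane seeds derived as `seed + plane_index`.

## Phase reconstruction

Two routes, both returning mean-free phase in radians (the global offset is
unobservable; the DC of Im WOTF is zero):

**TIE Poisson.**  −k·∂I/∂z = ∇·[I∇φ] with the axial derivative from the
central difference of a ±Δz pair.  FFT inverse Laplacian for the auxiliary
potential (DC pinned to zero), pointwise division of its gradient by the
in-focus intensity, and a second Poisson solve; a one-step path exists for
declared-uniform intensity.  Periodic boundaries are FFT-native; phantoms
keep their margins object-free, and RMSE comparisons exclude a 4-pixel
border to discount residual wrap-around.

**WOTF deconvolution.**  In the package's FFT conventions the weak-object
model gives (Ĩ_{+Δz} − Ĩ_{−Δz})/(4Ĩ₀) = −Im[WOTF]·φ̃, inverted by Tikhonov
division

    φ = F⁻¹{ F[(I₊ − I₋)/(4·mean I₀)] · (−Im W)/(Im W² + α) }.

The background normalization uses the *mean* of the in-focus image (its DC
value) rather than a pointwise Fourier division, which is undefined off the
object spectrum support.  Default regularization: α = machine epsilon for
annular illumination, whose phase response has no zero crossings in its
pass-band, and α = 10⁻³·max|Im W|² for circular/coherent illumination,
which does have transfer nulls.  Independently of α, the filter is applied
only where |Im W| ≥ 10⁻² of its peak (`BAND_FLOOR`): outside that pass-band
the data carry no phase signal, and because the 2D Im W map is interpolated
from the radial profile, the modes just inside the cutoff would otherwise
multiply pure noise by up to ~10⁶.  The 10⁻² floor bounds the inverse-filter
gain at ~100/peak, matched to percent-level camera noise.

**Multi-distance combination.**  With stacks at several ±Δz_j the phase is
the per-frequency least-squares solution
φ̂ = −Σ_j Im W_j·D̂_j / (Σ_j Im W_j² + α); frequencies where the short
distance transfers weakly are carried by the long distance and vice versa.
This interprets the "least-squares weighting" family of multi-distance
schemes; it reduces exactly to single-pair deconvolution for one distance.
In the noisy comparison study all circular-illumination reconstructions
share one Wiener-matched regularizer α = (σ√2/4)²/(φ_peak/2)² — the
per-mode noise-to-signal ratio of the normalized difference image — so that
small/large/combined are compared under identical damping.  What the
combination is guaranteed to improve (and what the tests assert) is the
low-frequency error of the *small*-defocus reconstruction and the total
RMSE of either single distance; for a strong (1 rad) object the low band is
bias- rather than noise-dominated, and the large-defocus single
reconstruction can already be the low-band optimum.

Sign and defocus conventions (+z = over-focus) are fixed by a round-trip
test: a known positive phase bump must be recovered positive from an
Abbe-simulated stack.

## Synthetic data

The study phantom is a Siemens star: binary spokes (0 or `peak_phase`,
default 1 rad) with angular period 2π/n_spokes (default 40 spokes) inside a
disk of 90% of the half-field, on the study grid of 256² pixels at 0.13 µm
pitch; its local pitch decreases linearly toward the centre, so resolution
maps to a radius.  Neither the spoke count nor the amplitude changes any
conclusion that the tests assert, because those are orderings and ratios,
not absolute RMSE values.  Additional phantoms: flat-top disks,
spherical-cap lenslets, and Gaussian-bump "cells" for the segmentation
layer.  The generator family is deterministic under fixed arguments.

What the phantoms do *not* emulate: partial temporal coherence, shot noise
(noise is Gaussian, per the study definition), camera quantization,
aberrations beyond defocus, and non-weak scattering beyond what the Abbe
model itself captures.  Passing tests therefore validate the optics and
inversion chain, not robustness to instrument non-idealities.

A star is called resolved at a radius when the modulation depth
(mean bright-sector − mean dark-sector)/peak_phase, referenced to the
outside-the-star background, exceeds 0.1 on that ring; the innermost radius
of the contiguous resolved run ending at the star's edge is reported.  (A
Michelson ratio is equivalent for a unit-background intensity pattern but
is ill-conditioned on zero-mean phase maps, where bright + dark passes
through zero.)

## Cell analysis

Phase converts to optical thickness OPD = λφ/2π and, through the protein
refractive increment γ = 0.2 ml/g ≡ 0.2 µm³/pg, to dry-mass surface
density ρ = λφ/(2πγ) in pg/µm²; per-cell mass integrates ρ over the cell's
pixels.  Segmentation: Otsu threshold on the phase image, binary dilation
with a disk filling a 7×7 window, Gaussian smoothing with 25-pixel support
(σ = 25/6, the ±3σ truncation convention), local maxima of the smoothed
phase *inside* the mask (8-connected, minimum separation 10 px) as seeds,
and a seeded watershed on the negated smoothed phase confined to the mask.
The pipeline contains no randomness.  Confluence is the percentage of the
field covered by labelled pixels.

Computational contrast: DIC as I = 2I₀[1 + δx̂·∇φ] with a unit shear vector
(default 45°) and periodic central differences; Zernike-style phase
contrast by multiplying the Fourier components of the recovered complex
field at ū ≤ 0.1 by e^{iπ/2} and squaring the modulus.

## Numerical choices and limitations

* Radial quadrature step 2/1024 in ū (source lattice aligned, see above);
  halving the step changes contrast areas by < 1%.
* All lengths in µm, phases in radians, NA dimensionless — in code, config
  files and reports.
* Annulus membership uses closed intervals; a sample exactly on the pupil
  edge belongs to both source and pupil (the matched annulus is inscribed
  in the pupil).
* The study problem size (256², 0.13 µm, ~10³ source points per aperture)
  is the reference geometry of the simulation comparison; unit tests use
  128² versions of the same physics.
* Aberrations are restricted to defocus; the pupil hook accepts any
  complex map but nothing beyond defocus is exercised.
* The open question of which aperture pairing the published low-frequency
  gain figures (5.79/8.02 at ū = 0.05) refer to was examined numerically:
  annular Δs = 0.1 vs circular s = 0.1 gives ≈ 6.1 (closest to 5.79); no
  pairing tried reproduces 8.02.  These quantities are not used anywhere.
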