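# Methods

`irai` simulates and analyses ionizing-radiation acoustic imaging
(iRAI): volumetric mapping of relative radiotherapy dose from the
thermoacoustic transients that pulsed megavoltage X-ray beams generate
in tissue-like media.  This note records the models, the numerical
choices, the calibration of the default pipeline, and what the
simulation world does and does not establish.

## Coordinate frame and units

A planar 32 x 32 matrix receive array (3.45 mm elements, 0.2 mm kerf,
116.6 mm aperture, 0.35 MHz centre frequency) lies on the `z = 0`
plane, centred on the origin and receiving on +z; +z is the axial
("array normal") direction, x and y are lateral.  Internally all
lengths are millimetres and all times microseconds.  The gantry rotates
about the x axis, so beam axes stay in the y-z plane — at gantry 0 the
beam travels along -y ("from above"), with the field's transverse axis
on z.  Beam isocenters sit 100 mm from the array on its axis.

## Dose model

A static photon field is separable in beam-local coordinates: an
error-function edge pair across each field dimension (penumbra
`sigma = 2 mm`, a typical 6 MV value) times `exp(-mu s)` depth
attenuation along the beam axis (`mu = 0.005 / mm`, an effective 6 MV
attenuation in water-like media; `s` measured from the isocenter
plane).  There is no scatter, build-up, or heterogeneity correction —
this is a declared stand-in for a treatment planning system (TPS), not
a dose engine.

The C-shaped plan targets a smoothed annular sector (outer radius
25 mm, inner 12.5 mm, 90 degree gap opening toward +y, extruded 20 mm
along x; dimensions chosen to fit a 15 cm phantom and the array field
of view).  Twenty-three equally spaced beams receive non-negative
transverse aperture fluences obtained by sparse non-negative least
squares against the target, restricted to each beam's-eye-view
silhouette.  Negative fluence being unphysical, the optimal composite
necessarily leaves residual dose in the cold core and gap — exactly as
clinical plans for ring-shaped targets do (the best achievable
normalized r.m.s.e. between the composite and the *ideal* annular
target is about 0.24).  The plan's "planned dose" is therefore the
deliverable composite, the quantity a TPS reports and the reference the
dose-comparison metrics use; the ideal target remains available
separately (`cshape_target`).

## Acoustic forward model

For an instantaneous deposition of initial pressure
`p0 = Gamma rho D` (Grueneisen efficiency x density x dose; lard
preset: c = 1440 m/s, rho = 920 kg/m3, Gamma = 0.9; soft tissue:
1540 / 1000 / 0.2 — literature-range stand-ins whose absolute scale
cancels in the normalised images), the exact homogeneous-medium
solution is the retarded spherical-mean formula.  Discretising the
shell integral with a Gaussian radial footprint per voxel collapses
analytically to

    p_v(t) = p0 V / (4 pi r) * phi'_sigma(c t - r),

one bipolar Gaussian-derivative wavelet per voxel (volume `V`,
source-receiver distance `r`).  The footprint width is
`sigma = 0.55 V^(1/3)` by default: wide enough to suppress the
voxel-lattice comb that otherwise aliases into the shell integral,
narrow enough that its spectral roll-off sits far above the receive
band.  Validation against the closed-form N-wave of a uniform sphere
(regularised at the jump by the same known `sigma`) reaches < 2%
relative L2 at `sigma/spacing = 1`; the default 0.55 trades ~10%
out-of-band quantisation noise (invisible after the pulse and receive
convolutions) for a shorter deposit support.  An earlier per-voxel
"equivalent-sphere N-wave value sampling" scheme was abandoned: its
discrete sum is dominated by radial lattice quantisation noise (~350%
L2 error on the same oracle).

Voxel sums are convolved with the unit-area temporal profile of the
approximately square 4 us accelerator pulse (fractional boundary
weighting keeps unit area at any sampling) and with a zero-phase
Gaussian-modulated cosine receive kernel whose magnitude spectrum falls
to sqrt(0.5) of its peak at `f0 (1 +/- bw/2)`.  Finite element aperture
is modelled by 3 x 3 sub-element point receivers with an obliquity
cosine each; a point-receiver mode exists for the oracles.  Default
sampling is 4 MHz over 768 samples (~275 mm of acoustic path).

## Acquisition chain

A 4:1 multiplexer digitises one fixed contiguous block of 256 elements
per accelerator trigger (360 Hz pulse repetition frequency), so a full
1,024-element acquisition takes four pulses; display frames average 25
full acquisitions (100 pulses, 25 reads per element).  Within a frame
each pulse uses the beam scheduled at its timestamp, so frames can mix
beams at transitions.  Gaussian read noise is added per digitised
sample; its s.d. is calibrated so that the single-pulse peak signal of
the 5 x 5 mm calibration beam at the per-pulse dose
(1,400 MU/min x 0.01 Gy/MU / 360 Hz = 0.65 mGy) has SNR 1 — averaging
and coherent summation then matter, and the repeatability statistic is
meaningful.  The default noise path draws the statistically identical
averaged noise (`N(0, sigma/sqrt(25))` per element sample) in one step;
a literal per-pulse mode exists and is used to verify the sqrt(K)
averaging law.

## Reconstruction

Volumetric delay-and-sum with uniform weights: every element's RF trace
is back-projected at the one-way time of flight (linear interpolation
in time) and summed; multiple frames are summed coherently
(channel-wise) before one back-projection, which is exact by linearity.
A delay offset of 2 us aligns the image to the centroid of the causal
square pulse.  The non-negative relative-dose image is the per-(x, y)
column analytic-signal magnitude along z (envelope along the array
normal), normalised to its own maximum (per-sequence global maximum for
temporal snapshot series, so accumulation is visually monotone).
Cumulative mode reconstructs frames 1..k; difference mode reconstructs
only the frames since the previous snapshot.

## Calibration of the default pipeline

The receive-kernel fractional bandwidth is the single tuned knob,
calibrated once against the bench resolution protocol and frozen at
0.40 (array nominal is 0.5); the delay offset is fixed at the pulse
centroid.  With these defaults (all figures computed by the package's
own experiments):

* the 1 x 3 cm beam front-edge line-spread FWHM is ~4.9 mm,
* the 5 x 5 mm beam fitted lateral profile FWHM is ~10-11 mm,
* beam widths 1-5 cm are recovered to <= ~1 mm.

The first two fall short of the reference bench figures this toolkit
aims at (<= 4 mm axial, ~5 mm lateral).  This appears structural rather than a tuning failure:
laterally, the diffraction-limited spot of a 116.6 mm aperture at
0.35 MHz and 100 mm depth is ~3.5-5 mm FWHM, so the *image* of a 5 mm
field with a 2 mm penumbra cannot fit a 5 mm Gaussian (the object alone
fits ~6.5 mm); axially, the 4 us pulse (5.8 mm of path) plus the
band-pass edge response bound the edge rise.  No bandwidth setting met
either figure; 0.40 minimises the lateral width while keeping the width
linearity accurate.

## Axial width measurement

The band-pass receive chain (no DC response) renders a uniform axial
slab as two bright edge humps with a dim interior, so a literal 50%
threshold width is biased by half a hump width on each side.  The width
experiments therefore measure the outermost 50% crossings of the
envelope profile (averaged over the uniform beam cross-section, as in
standard edge QA) and subtract the span excess measured once on the
noiseless 1 x 3 cm calibration beam — a constant of the imaging chain,
not of the measured field.  The generic `beam_width` (single-run
threshold crossings, exact on erf-edged slabs at the 50% level) and
`superlevel_span` primitives are exposed separately.

## Dose-comparison metrics

All metrics first normalise images to unit maximum and are invariant to
global positive rescaling.  The r.m.s.e. between two normalised images
is evaluated over the union 20%-of-max superlevel mask (empty
background would deflate it); "repeatability variation" is 100 x the
mean, over that mask, of the voxelwise s.d. across max-1-normalised
repeats — the statistic itself is a design definition; no standard
definition of such a "variation" exists.  The digital area histogram (DAH) is the
area fraction of a 2D region at or above each relative dose level;
isodose contours come from marching squares.  PSF/LSF fits use a
Gaussian family with a free baseline.

## Known limitations and honest disagreements

* **C-shape fidelity.**  Coherent summation of all beams' signals
  focuses the closed annular target's energy into its centre of
  curvature (near-central elements see the whole ring at nearly equal
  delays), so the reconstruction's maximum lands in the cold core and
  the normalised r.m.s.e. against the planned dose is ~0.25 — well
  above the 0.0987 reference figure.  Envelope-compounding the frames
  incoherently (`compound='incoherent'`) suppresses the artifact
  (~0.18) but adds background haze and still falls short.  The package
  reports the coherent (as-described) pipeline's value honestly.
* **Resolution figures** as above: the fitted lateral PSF (~10-11 mm)
  and axial LSF (~4.9 mm) do not reach the 5 mm / 4 mm reference
  figures in this simulation world.
* The medium is homogeneous and attenuation-free; no transducer
  element-to-element variation, trigger jitter, or amplifier effects
  are modelled.  Synthetic plans use the analytic dose stand-in, not a
  clinical TPS.  A green test therefore establishes internal
  consistency of the simulation/reconstruction/metrics chain and
  reproduction of the geometry-driven bench numbers (aperture, width
  linearity, repeatability scaling), not agreement with in-vivo data.
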