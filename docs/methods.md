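# Methods

## Scope and model

`metalsim` simulates the insertion of voxelized metallic devices into
CT projection data. The guiding principle is that the *baseline*
projections play the role of measured data (in the intended clinical
use they come from a scanner), while the *inserted metal* is synthetic;
consequently the baseline chain is monochromatic-equivalent — HU
volumes are converted to linear attenuation with the effective water
LAC of the configured spectrum and forward projected as-is — and the
polychromatic physics enters only where the metal perturbs the
measurement: the added noise element and the beam-hardening rescaling
of the metal projections.

The acquisition is desk-scale 2-D multi-slice: a parallel- or fan-beam
system in the axial plane, with detector rows indexing independent
slices. In-plane reconstruction physics is what generates metal
artifacts (streaks from view inconsistency, blooming from hardening),
so a helical cone-beam geometry is deliberately out of scope; probes
that cross slices are handled by the 3-D placement machinery, not by
the projector.

### Noise element

For each ray crossing the metal, the inserted noise is
`Pn = sigma·x`, `x ~ N(0,1)` i.i.d. per (view, channel, row), with

    sigma^2 = [Ne(e^{2Pm} - 1) + N0 e^{-Por}(e^{Pm} - 1)] / (N0 e^{-Por})^2.

This is exactly the difference between the log-domain projection
variance `(N + Ne)/N^2` evaluated with and without the metal in the
beam, under compound Poisson counting plus an electronic floor of `Ne`
noise-equivalent quanta; the unit test suite re-derives it from that
oracle. `N0` may be a scalar, per-view, or per-(view, channel) array,
so mA-modulation- and bowtie-like flux profiles can be expressed, but
no automatic exposure controller is modeled. Noise is applied *after*
the beam-hardening rescaling, because the corrected metal projection is
the better estimate of the actually transmitted flux; the metal-ray
mask (`Pm > 1e-6`) is always computed on the uncorrected projection.
The Gaussian log-domain model diverges when rays are driven into
photon starvation (tens of photons or fewer); scenes with long
in-plane metal paths (e.g. a solid 12.7-mm rod lying exactly in the
imaging plane, `Pm ≈ 50`) are outside its validity and produce
unbounded streaks by construction.

### Beam hardening

Per metal-crossing ray: (1) the water-equivalent path is found by
inverting the polychromatic attenuation curve of water at the ray's
*total* line integral `Por + Pm` — the hardened spectrum the detector
would record has traversed object and metal alike; (2) the source
spectrum times the detector weighting is attenuated by that much water
and renormalized; (3) the effective mass attenuation coefficient of the
reference metal (titanium, k-edge-free in the diagnostic range) is the
weighted mean of its tabulated mu/rho under that spectrum; (4) `Pm` is
scaled by `mu_m / mu_m_ave`, where `mu_m_ave` is the *unweighted*
arithmetic mean over the metal-ray mask. Only this ratio enters the
correction, which makes the artifact pattern robust to the absolute
spectrum model; the absolute `mu_m` values it computes (0.946 / 0.493 /
0.445 cm²/g for the default 120-kV chain unhardened / 30 cm / 40 cm of
water — recomputed by `scripts/acceptance.py`) depend directly on the
spectrum and detector weighting, and vendor-calibrated chains with
proprietary spectra and detector responses are often quoted with
substantially lower effective coefficients. Water-equivalent hardening
also understates the spectral selectivity of the metal itself: a beam
that truly traversed centimeters of titanium is harder than a beam
attenuated by water to the same total transmission.

### Spectrum and materials

The built-in source is Kramers bremsstrahlung `w(E) ∝ (kVp − E)/E` on
1-keV bins from 10 keV to the tube potential, filtered by a
configurable aluminum thickness. The default 9 mm Al approximates the
heavy total filtration of a CT tube assembly; 2 mm would be a
radiography-like tube. The default detector weighting is the ideal
energy-integrating `d(E) = E`; a photon-counting `d(E) = 1` is
selectable and any measured spectrum can be supplied as CSV. Mass
attenuation tables (water, titanium, iron, aluminum, soft tissue) are
transcribed standard-reference values on the conventional 10–150 keV
grid and interpolated log-log; energies outside the table raise rather
than extrapolate.

## Projector and reconstruction

Forward projection is Joseph-style: bilinear sampling at half-voxel
steps along each ray, in mm internally, emitting dimensionless
`∫mu dl` (mu 1/cm × path cm). View angle 0 sends rays along +y; world
origin is the isocenter; volumes are (slice, row, column) with +y up.
The projector is linear in the volume to machine precision — the
property that makes insertion by sinogram addition exact — and is
cross-checked in the tests against analytic disc/ellipse chords and
against an independent Radon implementation. Objects whose support
projects beyond the detector raise a truncation error naming the
offending views.

Reconstruction is filtered back projection (scikit-image `iradon`)
after resampling detector channels onto the output pixel pitch;
fan-beam data are first rebinned to parallel geometry
(`theta = beta + gamma`, `s = SID·sin(gamma)`, Delaunay-based linear
interpolation with periodic continuation at the 0/pi seam). Kernel
names are `smooth` (Hann-apodized ramp, medium-sharp analog) and
`sharp` (pure ramp); they set qualitative sharpness only, with no claim
of equivalence to any vendor kernel. A 20-cm water disc reconstructs to
0 ± 10 HU in a central ROI; writers clamp HU to the 12-bit scanner
range [−1024, 3071] unless the extended 16-bit scale is requested —
necessary for metal, whose CT number under the default chain is
≈ 19,500 HU for solid titanium.

## Probes

Device models are HU volumes at a reference tube potential with a tip
anchor. Segmentation from a scan uses a threshold (Otsu over the
> 300 HU candidates when the candidate distribution is bimodal,
otherwise 300 HU; always overridable), 26-connectivity labeling, a
minimum component size, and a bridging distance that merges separated
device parts (shaft/coil/handle); the group containing the largest
component is kept. The tip anchor is the support voxel most distal
along the principal axis, oriented toward the lighter half (real
probes are handle-heavy). Placement is a rigid transform
(azimuth/elevation/roll about the tip) resampled on a 2× supersampled
target grid and mean-downsampled: averaging preserves the attenuation
integral (mass conservation within 5% across rotations is a tested
invariant) while the supersampling limits thin-structure erosion;
"max" enters only when compositing probe and volume (image-domain
insertion resolves overlaps voxelwise by maximum). An exactly
grid-aligned, rotation-free placement takes a lossless direct-paste
path. When a probe is stored at one tube potential and inserted at
another, no HU rescaling is applied by default, mirroring how such
models are used in practice.

## Synthetic scenes: what they do and do not emulate

The generator produces water-equivalent discs (20-cm head analog,
35-cm tank analog), a 30 × 40 cm ellipse (body analog), titanium/iron
rods (12.7-mm validation rod; thinner rods standing in for probe
shafts), and extruded multi-slice sections. Rasterization is
center-point membership with a 10% air margin so projections never
truncate. These scenes reproduce the *mechanisms* — noise inflation by
metal, hardening-driven blooming, coregistration of dual-domain
insertions — but not textured anatomy, AEC/bowtie flux profiles,
scatter, or real probe substructure; passing tests therefore certify
the physics models and the pipeline plumbing, not image realism on
patient data.

Default study conditions: 120 kV, 9 mm Al, N0 = 1000 photons per
detector element per view per effective mAs (200 eff. mAs → 2·10⁵,
20 eff. mAs → 2·10⁴), Ne = 20 NEQ. Under these, the head-phantom
insertion gives reconstructed ROI noise ≈ 11 HU (no noise model) vs
≈ 33 HU (with model) at the high dose — the ordering, not the absolute
level, is the validated property, since absolute levels depend on the
flux calibration of a real scanner.

## Numerical choices

* WEP inversion: vectorized bisection on the monotone attenuation
  curve, bracket [0, P/mu_min + 1], terminated at bracket width
  < 1e-12 cm and verified to |ΔP| < 1e-6.
* Ray sampling: half the smallest in-plane voxel; grid-boundary ties
  resolve toward the lower index via `floor`.
* Metal-ray mask threshold 1e-6 (dimensionless line integral).
* Coregistration reports: metal masks at 500 HU; connected components
  counted with 26-connectivity, ignoring speckle below 5 voxels.
* ROI noise follows the per-slice-SD-then-average protocol, with the
  across-slice SD reported as spread; a single-voxel ROI is flagged
  degenerate instead of yielding NaN.
* One RNG stream (`numpy` PCG64) per insertion run, seeded from the
  run config and recorded in the provenance log; replaying a run from
  its provenance is bit-exact and tested.

Problem sizes in the shipped tests and acceptance runs — 256² grids
(512² for the high-resolution coregistration case), 360 views, one or
two slices — were chosen as the smallest scenes in which each effect
is cleanly measurable; every scene parameter is an argument, so larger
studies only cost runtime.

## Known limitations

* Scatter, focal-spot size, detector crosstalk and afterglow are not
  modeled; the metal's own perturbation of the scatter field is
  ignored.
* Beam hardening uses water-equivalent (not through-metal) spectra and
  a single reference metal; k-edges are excluded by construction.
* The noise model is Gaussian in the log domain and diverges under
  photon starvation (see above).
* At a fixed metal threshold, FBP blur *widens* a device's apparent
  footprint in the projection-domain image by roughly the PSF width;
  apparent shortening of probes by artifact obscuration — reported for
  tapered real probes in measured helical data — does not reproduce in
  this 2-D chain, and is not asserted by the tests.
* Fan-beam support goes through rebinning; short-scan (partial
  rotation) fan acquisitions are not implemented.
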