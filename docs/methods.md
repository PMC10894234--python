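# Methods

This note documents the physics model, the estimators, the numerical
choices and the limitations of `gridmc`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Geometry and coordinates

The beam axis is +z with the source (focus) at z = 0 and the isocenter at
z = 100 cm.  The optional collimator assembly consists of a 0.6 cm PMMA
tray and, immediately below it, the grid block: a brass or cerrobend slab
whose exit face sits 35 cm upstream of the isocenter, pierced by 127
conical holes converging on the source.  Projected to the isocenter plane
the holes are 1.0 cm circles on a 2.0 cm hexagonal lattice (one hole on
the axis, six complete rings).  The 50 x 50 x 50 cm^3 water phantom
surface is placed at the configured SSD (100 cm for PDD/profile/spectrum
runs; 80 and 90 cm for the TPR20/10 procedure).

Two collimator dimensions are not vendor-published and are therefore
explicit assumptions: the mounting distance (exit face at 65 cm from the
source) and the block thickness.  The thickness default is **7.2 cm**,
calibrated once so that the simulated in-air fluence attenuation of the
block matches the published ~50% attenuation of the commercial device;
both values are configurable in `GridSpec`.

## Source model

The linac head is not simulated.  Photons are drawn from the
two-parameter family

    Phi(E) ∝ E^alpha * exp(-beta * E),   0.01 < E <= 6.02 MeV,

emitted from a dual-Gaussian virtual source: a 1.2 mm FWHM focal spot
carrying 90% of the fluence and a broad sigma = 1.5 cm extra-focal
component (flattening-filter/collimator scatter) carrying 10%.  The
extra-focal component matters for grid fields: an extended source is what
the focused cones partially clip, and without it the primary-fluence
reduction under the central hole is a few percent instead of the observed
~10-13%.  Directions fill the pyramid subtending the collimated field
(plus a 2 mm penumbral margin) at the isocenter plane, so planar fluence
obeys the inverse-square law by construction.

The defaults `alpha = 0.9`, `beta = 0.97` are the shipped tuning result:
they were fixed, once, by scanning (alpha, beta) against the in-water
observables of the validated machine — TPR20/10 of the open 10 x 10 field,
the spectrum average energy at 1.5 cm depth, and d_max — and were not
revisited afterwards.  `tune_beam` exposes the same grid-search loop
against user-supplied reference PDD/profile curves with 3%/3 mm gamma
scoring.  The nominal 6.02 MeV peak and the 1.2 mm / 1.2 MeV widths of
the electron beam that the family emulates are carried as metadata on
`BeamSpec`.

## Photon physics

Per-element photon cross sections ship as generated CSV fixtures
(`gridmc/data/`, regenerated by `scripts/generate_physics_tables.py`):

- incoherent scattering: exact integrated Klein–Nishina on Z free
  electrons (no Doppler broadening/binding — adequate above the 10 keV
  cutoff, slightly overestimating attenuation below ~50 keV for high-Z);
- photoelectric: per-element two-term fits `a E^-3 + b E^-1` anchored on
  handbook mass-attenuation values;
- coherent (Rayleigh): `c E^-1.9` power law scaled as Z^2.5/A, sampled
  with a forward-peaked Thomas–Fermi characteristic angle;
- pair production: a universal energy shape scaled as Z(Z+1)/A, zero
  below 1.022 MeV.

The generator asserts the resulting water total attenuation against NIST
anchor values (worst deviation < 1% between 0.05 and 6 MeV, water being
Compton-dominated).  High-Z photoelectric/pair coefficients are 20-40%
approximations below ~0.5 MeV; they only steer the collimator
attenuation, which is dominated by Compton interactions of the 1-6 MeV
spectrum.  Mixture-rule materials (water, air, PMMA, brass 37/63 Zn/Cu,
cerrobend 10/13.3/26.7/50 Cd/Sn/Pb/Bi) use handbook densities (1.000,
0.0012, 1.19, 8.49, 9.38 g/cm^3), all configurable.

In-phantom transport is analog: exponential free paths on the total
attenuation coefficient, process sampled from the partials, Klein–Nishina
Compton kinematics (recoil electron at cot(phi_e) = (1+k) tan(theta/2)),
photoelectric termination (fluorescence ignored), pair production with an
equal energy split and two isotropic back-to-back 511 keV annihilation
photons at the positron track end.  Every post-interaction photon is
tagged *scattered*; the tag otherwise rides unchanged from the source.
Photons below 0.01 MeV deposit locally.  Russian roulette (threshold
1e-4, survival x10) bounds deeply attenuated grid-transmitted weights.

## Collimator transmission

Because every hole cone shares the focus, a ray's projection onto the
isocenter plane moves along a straight line and the in-hole condition per
hole is a quadratic inequality in the ray parameter; block path lengths
are therefore exact (slab chord minus the union of in-cone intervals),
implemented in compiled per-ray kernels with a vectorised reference
implementation kept for cross-checking.  The uncollided component is
attenuated deterministically (it keeps the *primary* tag and its
trajectory, which keeps paired open/grid runs history-correlated);
interactions in tray and block are sampled as analog indicator events and
their progeny transported with full multi-generation scattering inside
the slab.  The multi-scatter build-up matters: narrow-beam attenuation
alone underestimates the transmitted fluence of a ~2.7 mean-free-path
block by roughly a factor of two.

## Electron transport

Secondary electrons (and positrons) above the 0.5 MeV cutoff are stepped
in 1 mm sub-steps with the Møller collision stopping power (Bethe theory
with mean excitation energies and an asymptotic density-effect term;
radiative losses are deposited locally, consistent with ignoring
bremsstrahlung below 6 MeV in water).  Electrons below the cutoff deposit
at creation.

Pure straight-ahead stepping makes every electron deposit along its full
CSDA range, which pushes the build-up peak several millimetres too deep
and leaves grid-field valleys with no electron crossfire.  The default
transport therefore adds a **multiple-scattering transverse walk**: per
sub-step the transverse slope receives a Gaussian increment with variance
from the Highland scattering power `(13.6 MeV / beta p c)^2 / X0`
(water X0 = 36.08 cm).  This single mechanism foreshortens the forward
penetration (projected/CSDA range ratios 0.73-0.79 over 1-6 MeV, matching
handbook electron detour factors) and produces the lateral dose spread
that fills the valleys between beamlets.  `detour_correction=False`
restores the pure straight-ahead contract (used by the range
self-consistency tests).

## Tallies and estimators

All scoring follows the standard grid-dosimetry setup: tag-resolved
energy deposition on the axial cylinder mesh (4 mm radius x 2 mm voxels,
0-30 cm), 0.5 x 0.5 x 0.1 cm^3 profile voxels at 10 cm depth,
track-length fluence spectra in 4 mm x 2 mm cylinders at 1.5/5/10 cm
(100 photon bins, 92 electron bins), and a 50 x 50 x 0.1 cm^3 in-air
plane below the grid.  Voxels are half-open `[lower, upper)`; every tally
keeps one accumulator per statistical batch (default 10) and reports the
standard error over batches.

Two variance-reduction estimators compensate for running ~10^6-10^7
histories where the original study used 2 x 10^10:

- a **track-length collision-kerma mesh** on the same axial geometry
  (fluence x E mu_tr, with the Compton transfer fraction from
  Klein–Nishina quadrature).  Under charged-particle equilibrium
  collision kerma equals absorbed dose, so the TPR20/10 doses at 10 and
  20 cm depth are read from this estimator; the analog deposition mesh
  agrees with it at the few-percent level beyond build-up, which is
  asserted in the tests.
- an **expected-value estimator for the axial deposition mesh**: every
  photon flight crossing the scoring cylinder spawns one virtual electron
  per <= 1 cm sub-chord carrying the expected collision weight
  `w mu dl exp(-mu t*)`, while analog electrons born inside the chord
  skip cylinder scoring.  This is unbiased (same expectation as the
  analog game) and cuts the voxel variance about four-fold.

Monitor-unit calibration follows the standard definition: the number of
histories that deliver 1 cGy at d_max of the open 10 x 10 field at SSD
100 defines one MU; fluences then convert to 1/cm^2/MU.  When fields of
different sizes are compared on a fixed-machine-output footing (output
factors in the benchmark matrix), per-history doses are scaled by the
collimated emission area.

## Analysis choices

- **d_max** is located by a two-stage fit: the effective attenuation
  coefficient comes from a weighted log-linear fit of the 5-25 cm tail,
  then `A (1 - exp(-(d-d0)/lambda)) exp(-mu d)` is fitted over the first
  8 cm with mu pinned.  A local parabola around the maximum voxel (the
  textbook estimator) is retained for short or toy curves and as the
  fallback, but on a desk-scale noisy curve with the characteristically
  flat 6 MV build-up top it wanders by several millimetres and biases
  deep, while the constrained model fit is stable to a fraction of a
  voxel.  PDDs are normalised to the fitted maximum, so individual noisy
  voxels may exceed 100.
- **Spatial fraction**: peaks are searched in windows of half a pitch
  around the expected beamlet centers (the 2 cm pitch projected to the
  profile depth), valleys between adjacent peaks.  No smoothing is
  applied by default: with 0.5 cm voxels a beamlet peak is only two
  voxels wide and a median filter clips it, inflating the ratio.
- **Dose components** attribute each electron's deposit to the tag its
  parent photon carried *into* the interaction, i.e. "dose delivered by
  primary photons" versus "by scattered photons".  Under this standard
  convention the primary component dominates the central-axis dose at
  all depths (the primary fluence is larger and harder); the tests
  assert the partition and cross-modality orderings rather than any
  particular share.
- **Gamma index**: reference interpolated at DTA/10 steps on a lattice
  anchored at the reference origin plus the evaluated point itself
  (identity is exact); search window ±3 DTA; 10% low-dose threshold;
  truncated windows at the curve edges are flagged, never extrapolated.

## Randomness and reproducibility

Every source history owns a counter-based RNG stream: an xorshift128+
generator seeded by SplitMix64 hashing of (run seed, history index).
Results are bit-identical for a given (seed, n_histories) regardless of
batch execution order, and paired runs at the same seed (open vs grid,
brass vs cerrobend, the two TPR geometries) stay correlated history by
history, which the paired difference estimators exploit.

## Problem sizes

Default runs use 2 x 10^6 histories; the acceptance script uses
2.4 x 10^7 for the 10 x 10 phantom runs (the PDD-difference and d_max
statistics are the binding constraint), 6 x 10^6 per TPR geometry and
2 x 10^6 per in-air run, about 8 x 10^7 histories and ~12 minutes on one
core in total.  Batch uncertainties are reported for every tally; the
1/sqrt(n) scaling of the batch standard error is verified in the tests.

## What the generator does and does not emulate

The synthetic source reproduces the in-water observables of a validated
6 MV beam (depth dose, beam-quality index, spectrum averages) and the
fluence topology of the commercial 127-hole collimator.  It does **not**
include: electron contamination from the head (simulated surface doses
below ~5 mm are low and are excluded from gamma scoring and fit windows),
off-axis spectral softening and horns, exact vendor block dimensions,
Doppler/binding corrections, atomic relaxation, bremsstrahlung transport
in water, or energy-loss straggling.  Passing tests therefore demonstrate
internal consistency and agreement with the published desk-scale
observables, not a clinical beam-model commissioning.
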