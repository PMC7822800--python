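# Methods

`dosekit` estimates absorbed dose in voxel phantoms from C-arm X-ray
exposures with a simplified Monte Carlo photon transport, and accelerates
the estimate with a down-sampling / guided-filter super-resolution scheme
that reconstructs a high-resolution dose distribution from a coarse
simulation.  This note documents the models, the defaults and why they were
chosen, and what the synthetic test bed does and does not show.

## Photon transport model

Photons are tracked one history at a time through a labelled voxel grid.

**Free flight** uses Woodcock delta-tracking: path lengths are sampled
against the majorant linear attenuation (the maximum over the tissues
present, evaluated at the photon's current energy) and a fictitious
interaction is rolled back with probability `1 - mu(voxel)/mu_majorant`.
This avoids per-voxel boundary crossings entirely, at the cost of extra
no-op samples in low-density regions.

**Interactions.** At a real interaction the channel is selected from the
material's tabulated photoelectric/Compton/Rayleigh shares:

* *photoelectric* — the full photon energy is deposited in the voxel and
  the history ends;
* *Compton* — the scattered energy and angle are sampled from the
  Klein–Nishina distribution with Kahn's rejection method; the recoil
  electron's energy is deposited locally;
* *Rayleigh* — elastic, Thomson angular shape (no atomic form factors);
  direction changes only.

This is the **kerma approximation**: secondary electrons are not
transported (their CSDA range is sub-millimetre below 150 keV, smaller than
a voxel), and characteristic X-rays and bremsstrahlung are neglected.
Photons falling below a 5 keV cutoff are absorbed on the spot.  Bound-
Compton/Doppler effects and polarization are out of scope.  These
simplifications mean absolute dose is approximate at tissue interfaces and
in the first ~0.1 mm of the entrance surface; relative distributions in
soft tissue at diagnostic energies are barely affected.

**Primary/scatter taxonomy.** A photon is *primary* until its first
non-photoelectric event; the Compton electron energy of that first event is
still scored as primary dose, everything afterwards as scatter.  (The
distinction is conventional; this choice keeps "primary dose" equal to
first-interaction dose of unscattered photons.)

**Reference-point air kerma.** Free-in-air collision kerma is scored with a
track-length estimator over a 1 cm³ spherical air cell at the
interventional reference point — by default 15 cm from the isocenter toward
the source (IEC convention), upstream of the phantom, so only unattenuated
primary tracks contribute.  The ratio of a measured air kerma to this value
scales the whole dose distribution (`scale_to_air_kerma`), mirroring how an
X-ray system's reported kerma calibrates a simulation.

**Randomness.** Every history seeds its own xorshift64* stream from
(seed, history index) via SplitMix64.  Batch decomposition therefore does
not touch the physics: 2 or 10 batches give identical dose, and runs are
bit-reproducible.  Batch-to-batch variance yields the voxelwise relative
2σ uncertainty; zero-dose voxels are flagged at 100 %.

**Energy accounting.** Emitted = deposited + escaped is tracked per run and
holds to < 1e-6 relative (double-precision accumulation).

## Material data

Packaged tables (`dosekit/data/materials/`) give mass attenuation
(mu/rho), mass-energy absorption (muen/rho) and interaction shares for
air, water, soft tissue, adipose, cortical bone, inflated lung, brain,
aluminum and copper on a log-spaced 5–150 keV grid (log-log interpolation
in between; no extrapolation).  They are generated offline
(`scripts/build_material_tables.py`) from a three-channel model: exact
Klein–Nishina Compton per electron, and Z-power-law photoelectric and
Rayleigh terms least-squares calibrated to standard compilation values for
water and cortical bone (max misfit ≈ 2–3 % over 10–150 keV).  Absorption
edges and coherent form factors are not modelled — the tables are smooth by
construction.  Elemental compositions and densities follow ICRU-44-style
recipes.  Because muen/rho is assembled from the same channels the
transport samples (photoelectric + Klein–Nishina energy-transfer fraction),
the guidance maps and the scored dose are self-consistent.

## Beam model

The imaging setting is parameterized directly: primary C-arm angle about
the phantom's longitudinal axis (0° posteroanterior, 90° lateral),
source-to-isocenter and source-to-image distances, and rectangular-pyramid
collimation with half-opening angles (phi in-plane, theta axial) matching a
flat detector.  Secondary/table angles are fixed at zero.  Spectra come
either from two-column CSVs or from an analytic tungsten model: Kramers
bremsstrahlung shape `(kVp − E)/E` hardened by 2.3 mm Al inherent
filtration plus optional Cu.  The analytic model has no characteristic
lines; the packaged tabulated spectra are generated from it so both paths
agree.

## Down-sampling and super-resolution

Dose noise in Monte Carlo scales as 1/sqrt(histories per voxel), so halving
the in-plane resolution buys a 4x statistics gain per voxel.  The package
trades resolution for speed and then reconstructs:

1. **Mode down-sampling** replaces each in-plane `s x s` window of the
   label volume by its most frequent label (ties: higher mass density,
   then lower label id — deterministic).  The simulation then runs on the
   coarse phantom.
2. **Fluence decoupling.** Under charged-particle equilibrium
   `D = psi * (muen/rho)`; dividing the coarse dose by the coarse
   absorption map gives a coarse photon-energy-fluence estimate — a field
   much smoother than dose because tissue contrast has been divided out.
3. **Guided-filter up-sampling.** The coarse fluence is replicated to the
   fine grid (nearest neighbour, one value per window — deliberately no
   interpolation, so all smoothing is done by the edge-aware step), then
   filtered with the 2-D guided filter using the high-resolution
   spectrum-averaged muen/rho map as guidance, radius
   `r(s) = round(s/2) + 1` (half rounds up), and finally multiplied by the
   high-resolution absorption map to restore tissue detail.

All 2-D steps act on axial slices (the axial spacing is coarse already and
is never down-sampled).  The guided filter uses border-shrunken (valid
area) box windows and matches a brute-force per-pixel windowed ridge
regression to 1e-10.  The ridge parameter defaults to
`(0.01 * range(guidance))²` — reconstruction accuracy is insensitive to it
over four orders of magnitude because the guidance is piecewise constant
(windows are either uniform, where the linear coefficient vanishes
regardless, or strongly contrasted, where the variance dwarfs eps).
Division by the guidance floors it at the smallest positive guidance value
(never zero; the fluence relation only holds in matter), negative filter
output is clamped to zero, and partial trailing windows are processed at
their actual size rather than cropped.

The **fraction-of-mass (FoM)** operator — the mass-weighted window mean
`sum(m_x f_x)/sum(m_x)` — is kept as a comparison arm applied to dose
volumes directly; it conserves the mass-weighted total exactly.  The
simulation path always uses mode down-sampling (FoM mixture materials in
the transport itself would need per-window hybrid cross sections).

Doses are scored per unit mass, so values on coarse and fine grids are
directly comparable; no inter-grid mass bookkeeping is needed.

## Synthetic head phantom

Nested ellipsoids on a configurable grid: air background, soft-tissue
scalp (~7 % of the outer semi-axis), a cranial bone shell (~13.5 %, the
thick end of the adult calvaria range), brain interior, and a few seeded
adipose pockets carved out of the scalp.  After rasterization the vault is
explicitly closed along all grid axes: with 5 mm slices the thin cranial
cap can fall between slice centres, so brain-containing columns are capped
with bone where needed.  Generation is bit-reproducible under a fixed
seed.

What it emulates: a four-to-five-tissue segmented head with realistic
proportions and attenuation contrast.  What it does not: real anatomical
texture (trabecular bone, sinuses, facial bones), partial-volume labels,
CT segmentation noise.  Passing reconstruction tests on it shows the
method's behaviour under clean piecewise-constant anatomy; real heads have
more minority-tissue structure that mode down-sampling degrades further.

## Reconstruction benchmark (the standard evaluation)

`dosekit.experiments.reconstruction_benchmark` is the package's standard
evaluation and what `scripts/acceptance.py` runs:

* phantom 256×256×8, 0.7×0.7×5 mm (165×139 mm head), phantom seed 0;
* 120 kVp tungsten spectrum with 0.9 mm Cu pre-filtration (packaged
  table);
* posteroanterior beam, SOD 800 mm, SID 1200 mm, field 112×25 mm at the
  isocenter — collimated to the brain, as in neuro-interventional
  practice, which also keeps the beam's axial edges between slices;
* reference: 3×10⁸ histories (in-beam voxelwise 2σ ≈ 2–14 %, single-digit
  over most of the beam); reconstruction arms: 1.5×10⁸ (half the
  reference statistics); low-statistics arm: 100× fewer;
* in-beam, in-body mean absolute percentage error against the reference,
  reported per window size s ∈ {2, 4, 8, 16} and maximized over s.

Grid and spacing were chosen to keep the anatomy-to-window proportions of
a full 512² study as close as a minutes-scale run allows: at 128² the bone
shell erodes under mode down-sampling at s=16 and interior fluence is
biased by tens of percent, which says more about the analog than about the
method.  Even at 256² the beam is only ~7 windows wide at s=16 (a full-
scale study is ~20), so the beam-edge band — where the guided filter
smears the penumbra, since the guidance map knows nothing about the field —
carries several times more relative weight, and the measured maxima
(mode arm ≈ 7–8 %, FoM arm ≈ 6–7 %, low-statistics ≈ 9–10 %) sit above the
1.6–4.9 % / 1.2–3.1 % ranges reported for full-scale studies, while
reproducing their qualitative structure: error grows monotonically with s
at high statistics, is non-monotonic at low statistics, and concentrates
at the field edge and tissue interfaces.  Both arms also sit on the
reference's own noise floor (≈ 0.8 × its mean in-beam σ ≈ 2.5–3 points
here): the reconstruction is compared against a reference that is itself a
Monte Carlo estimate.

## Numerical choices and degenerate inputs

* Energies: transport lookup tables on a uniform 0.25 keV grid, linear
  interpolation; spectra must lie within 5–150 keV (no extrapolation).
* World convention: arrays are `[z, y, x]`; spacing/origin are `(x, y, z)`
  in mm; the origin is the grid corner (`center = origin + (i+0.5)·spacing`);
  I/O converts to/from the ITK voxel-centre convention.
* Mode tie-break and adipose placement are fully deterministic; every
  stochastic component takes an explicit seed.
* All-zero-mass FoM windows fall back to the unweighted mean with a
  warning; an empty beam–phantom intersection warns and returns zero
  patient dose; a single uncertainty batch, unknown labels, points outside
  the dose grid, and zero simulated reference kerma raise errors.

## Known limitations

* No secondary-electron transport: skin/interface dose and anything below
  ~0.5 mm build-up depth are approximate.
* Power-law cross sections without edges: worst near 5–10 keV and for
  copper below its K-edge; irrelevant above ~20 keV where these beams
  carry their energy.
* The guided filter cannot reconstruct structure absent from the guidance
  (beam edges, scatter gradients); errors concentrate there, exactly as
  full-scale studies report outside the primary field.
* 2-D slice-wise filtering assumes the axial spacing is already coarse;
  isotropic volumes would warrant a 3-D filter (not implemented).
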