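# Methods

This note documents the models behind `pbtrack`, the defaults and why they
were chosen, the numerical choices that matter, and what the synthetic
acquisition does and does not emulate.

## Forward model

### Phantoms and WET

Phantoms are ordered lists of geometric primitives (boxes, spheres, circular
and elliptic cylinders), each with a material of relative stopping power
(RSP).  The WET of a ray is the sum over traversed segments of geometric
length × RSP; overlaps are resolved deterministically, with later primitives
in the list overriding earlier ones.  Two integrators exist: an exact
general-ray integrator (interval partition at every primitive entry/exit,
midpoint ownership) and a fast vectorised path for beam-axis-parallel ray
bundles valid for containment-nested phantoms (`Σ chord · (RSP − RSP_parent)`),
with per-ray timestamps so every pencil beam sees the moving insert at its
own acquisition time.  The two are cross-checked against each other and
against a 0.01 mm ray-marching oracle in the tests.

Material RSPs default to the quoted mass densities of the phantom materials
(lung 0.21, soft tissue 1.04, trabecular bone 1.20, cortical bone 1.91, in
g cm⁻³), with PMMA at 1.16 and the water-equivalent insert at 1.00.  For
tissue-like media RSP ≈ density holds to within a few percent, which is ample
here because tracking depends on contrast, not absolute calibration; all
values are overridable.

The **thorax phantom** interior is not fully specified by its real-world
counterpart, so its dimensions are parameterised with these defaults: an
elliptical soft-tissue body (semi-axes 150 × 120 mm) whose axis lies along
the motion (superior–inferior) direction; lung compartments as cylinders with
the same axis (imaged lung radius 50 mm, concentric with the body
cross-section); a spine (cortical shell, trabecular core) posterior to and
outside the imaging field; and the spherical insert centred in the imaged
lung.  Two consequences of this construction are deliberate.  First, the lung
path length of a beam-axis ray is constant along the scan's fast (motion)
axis and varies across the slow (vertical) axis — the background gradient
lands in the direction the strip-wise segmentation is designed to absorb,
which mirrors how the imaging field sits over a lung in practice.  Second,
making the imaged lung concentric with the body leaves the field's background
symmetric about the insert, so residual segmentation spill is unbiased along
the measured axis.  The **slab phantom** is exactly its physical description:
70 mm PMMA, an air gap holding the 30 mm water-equivalent sphere, 40 mm PMMA.

### Motion

The printed form of the motion waveform, `y = −2A·cos(4πt/T) + A`, sweeps an
excursion of 4A with fundamental period T/2, which is inconsistent with the
study's own field-sizing margin rule and its description of A as the motion
amplitude.  Both readings are therefore implemented: `as_printed` evaluates
the formula literally, and `peak_to_peak` (the default for the tracking
study) treats A as the peak-to-peak excursion,
`y = (A/2)(1 − cos 2πt/T)` ∈ [0, A] with fundamental period T.  Expected
positions are re-centred by the waveform's time average (A/2), matching a
field of view centred on the mean insert position.

### Acquisition

Beams are Gaussians of 7.8 mm FWHM (clinical 230 MeV line) or 9.3 mm (slab
experiments, 180 MeV), decomposed into sub-rays on a 0.5 mm grid over ±2σ.
Each sub-ray accumulates WET at the beam timestamp and deposits an analytic
Bragg depth-light curve at depth `(R₀ − WET)/RSP_scint` with
`R₀ = α E^p` (α = 2.2·10⁻³ cm·MeV⁻ᵖ, p = 1.77) and a 1 mm Gaussian
range-straggling kernel; the singular power-law peak `(R − z)^(1/p − 1)` is
bin-integrated before convolution.  The 3-D light volume is summed along the
camera axes into top (x–depth), lateral (y–depth) and distal (x–y) views at
the 0.4004 mm camera pixel pitch; the distal view is simulated for
completeness but unused by reconstruction, which works from top + lateral.
cos⁴ vignetting (working distance 425 mm, optical axis at the scintillator
centre) is applied in simulation and exactly inverted in the signal chain so
the correction path is exercised; noise is multiplicative Gaussian (σ = 2% of
local intensity) plus additive background at 0.5% of the view peak, all
seeded.

Numerically, the per-beam image is formed by splatting each sub-ray's weight
at its peak depth and convolving once with the shared depth-light template —
algebraically identical to depositing the curve per sub-ray, since the
template is shift-invariant.  The template is kept on a window of
[−28, +6] mm around the residual-range depth: only the peak region drives
peak localisation and column weighting, and truncating the entrance plateau
keeps the full multi-seed replication fast without changing any extracted
quantity.  Spot dwell time is `frame time / n_spots` (≈ 6.7 ms), which
reproduces the published frame times of 1.4/1.0/0.7 s for the three field
sizes.

## Signal extraction and reconstruction

For each camera column whose integrated intensity reaches 5% of the strongest
column (rejecting scatter tails but keeping penumbra), the peak is localised
at 80% of the column maximum on the distal falling edge with linear
interpolation between pixels; this is more robust to peak-shape distortion
than the argmax (available as an option).  The template's known offset
between that falloff point and the residual-range depth is subtracted, making
the depth→WET conversion `WET = R₀ − d·RSP_scint` unbiased: over random
noiseless slabs the round trip is accurate to ~0.01 mm, and with camera noise
single-beam errors stay within a couple of millimetres before frame-level
averaging.

Per beam, the top view yields a lateral WET profile WET(x) and the lateral
view a vertical profile WET(y); they are combined as an outer product
(weights multiply and are normalised per beam; WETs average).  This separable
approximation stands in for the full scatter-aware reprojection of the
published estimator, whose exact weighting lives in prior work; it preserves
the column-level (sub-millimetre) lateral resolution that tracking relies on.
Samples are back-projected onto a 0.5 mm grid (finer than the 5 mm spot
spacing, coarser than camera pixels) with a Gaussian deposition kernel
(σ = 1 mm, truncated at 3σ); pixel values are weight-normalised mean WET,
pixels below 2% of the maximum accumulated weight are masked and never
inpainted.  A frame's timestamp is the acquisition time of its median beam.

## Tracking

The radiograph is divided into 11 horizontal strips (bands stacked
perpendicular to the motion, so every strip sees the insert at all phases)
and an Otsu threshold is computed per strip over a 256-bin histogram with a
deterministic lower tie-break; per-strip foreground is the higher-WET class.
Two guards make the combination robust on synthetic images: constant strips
are degenerate and contribute nothing, and a strip whose two classes differ
in mean WET by less than 1.5 mm also contributes nothing.  The latter is a
WET-resolution floor: an Otsu split always exists mathematically, but a split
smaller than the system's WET resolution reflects noise or a smooth
background gradient rather than an object edge.  (Real integrated-mode
images carry enough noise that such splits dissolve into speckle on their
own; clean synthetic backgrounds need the explicit floor.)  The strip
foregrounds are united, the largest 8-connected component is kept, and its
binary centroid (intensity weighting available behind a flag) gives the
measured offset from the field centre along the motion axis.  Frames whose
segmentation fails are excluded from the MAE and reported.  σ is the standard
deviation of the per-frame absolute errors.

For the artifact study the slab background is flat, so a single global
threshold (`n_strips = 1`) is used; on round objects the strip-wise variant
leaves threshold steps at strip boundaries that masquerade as shape
distortion.

## Interplay artifact study

The slab scene (30 mm sphere, 20 mm peak-to-peak excursion, 4 s period,
6 × 6 cm field) is imaged with horizontal, vertical, spiral and interleaved
patterns.  The experimental spot timing is machine-specific and unpublished,
so the dwell time is a study parameter; the default gives ≈ 1 s frames (a
quarter period), the regime with clearly visible distortion, and only
orderings and qualitative signatures are asserted — never the published
eccentricity values.  With these defaults the simulation reproduces: diagonal
skew under horizontal scanning with the most consistent eccentricity range;
expansion (contraction) under vertical scanning when the slow-axis
progression runs with (against) the motion; and eccentricities well above the
static reference for every pattern.  The spiral double-sampling split — the
sphere imaged as two disjoint sections in one frame — requires scanning slow
enough that the sphere leaves the sampled region and returns; it appears
robustly when one frame spans a full motion period, and that configuration is
what the corresponding test exercises.  Ellipse fits use central second
moments with axis length 4·√eigenvalue (the equivalent uniform ellipse) plus
the pixel-square moment correction.

## Seeding and reproducibility

One master seed drives everything through `numpy.random.SeedSequence`
spawning (per-stage, per-frame children), so a run is byte-reproducible from
config + seed.  In multi-seed replications each seed additionally draws a
uniform breathing phase offset, so seed averages marginalise over the
uncontrolled phase between acquisition start and the motion cycle — without
this, a single fixed phase can flatter or punish particular period/frame-time
combinations.

## Problem sizes

The replication of the positional-accuracy study runs each of the seven
configurations at full size — 20 frames of 209/153/105 beams — over 10 seeds,
about a minute per configuration on one CPU.  The artifact study simulates
8 frames × 169 beams per pattern.  Unit tests use smaller fields and frame
counts; all expensive results are computed once per session and shared.

## What the generator does not emulate

Lens distortion and the camera calibration procedure (the perspective
correction is an identity contract with a homography slot), refraction
physics, scintillation quenching, CCD shot/readout noise structure,
synchrotron spill timing, depth-dependent lateral beam broadening (a
Highland-style option exists conceptually but scattering inside the phantom
is not modelled), and heterogeneous lung anatomy (ribs, vasculature,
diaphragm).  Passing tests therefore demonstrate the *method* — range
extraction, reconstruction, strip-Otsu tracking, interplay characterisation —
under an idealised detector, not the absolute accuracy attainable on a real
system; consistent with that, the simulated MAEs sit well below the
experimentally reported values, which is why the published numbers are
treated as upper bounds.

## Known limitations

- The separable (outer-product) combination of top/lateral profiles halves
  the contrast of structure that is diagonal in (x, y); overlapping beams
  recover most of it, but sharp corners blur more than in the full estimator.
- Column-wise peak extraction is biased toward the longest-range
  subpopulation within a beam at object edges, eroding high-WET objects by a
  fraction of the beam width; this cancels in the binary centroid of a
  symmetric insert but matters for shape metrics near the resolution limit.
- The strip-contrast floor (1.5 mm) is a tunable heuristic; objects with
  contrast below it are invisible to the tracker by construction.
- `max_beams_crossing` sweeps grid offsets at 0.01 mm; counts for diameters
  that are near-exact multiples of the spacing can be sensitive at the
  open/closed boundary (nodes exactly on the circle are excluded).
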