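# Methods

## Model

`prpsim` simulates panretinal photocoagulation (PRP) on a *flattened
equal-area* model of the human retina. The retina is treated as the curved
surface of a spherical dome; with base radius *c* and height *h* its curved
area is

S = 2πrh = π(c² + h²),

exactly the area of a flat disc of radius √(c² + h²). Using standard-eye
dimensions, the whole retina maps to a disc of equivalent radius
**18.6 mm**, the retina up to the equator to **15.6 mm**, and the central
region that is never photocoagulated (vascular arcades, macula, optic
disc — a 5 mm circle on the curved retina) to **5.14 mm**. These three radii
are stored as named defaults in `EquivalentDisc` and can be overridden; no
spherical coordinates are used downstream. The flattening preserves areas,
which is the only geometric property the simulation consumes; it does not
preserve distances far from the center, a known and accepted distortion of
this construction.

Photoreceptors enter as a rotationally symmetric surface density ρ(e)
(cells/mm², e = eccentricity in mm on the flattened disc). Revolving the
eccentricity–density curve about the vertical axis gives an island-shaped
solid of revolution; with the density axis scaled so 1 mm of height ≡ 10⁴
cells/mm², solid volume (mm³) × 10⁴ is the photoreceptor count exactly. The
optic disc is a photoreceptor-free cylinder subtracted from the solid
(default radius 0.75 mm at eccentricity 3.4 mm, ordinary human anatomy;
configurable — calibration of the total absorbs the choice).

A laser burn is a vertical (right-angle) cylindrical punch through the
solid, so the photoreceptors destroyed by one spot equal the area integral
of ρ over the spot disc. Burn spots never overlap, so a layout's total
destruction is the plain sum over spots. Two summary metrics:

- **photoreceptor destruction index** = 100 × destroyed / total (%),
- **photocoagulation index** = 100 × burn area / retinal area (%),

the former weighting the latter by where the photoreceptors actually are.

## Numerics

*Whole-retina integral.* ρ is piecewise linear on its eccentricity grid and
zero beyond the last node, so 2π∫ρ(e)·e·de has a per-segment cubic closed
form; `total_count` evaluates it exactly (no quadrature error).

*Spot integral.* `count_in_spot` evaluates ρ on a Cartesian midpoint grid
(default step 10 µm) clipped to the spot disc and reports exact spot area ×
mean lattice density. Normalising by the lattice mean rather than summing
cell areas cancels the O(step) boundary-cell error, which for a 400 µm spot
otherwise dominates the (tiny) interior error of the smooth integrand; the
residual bias is far below the Monte-Carlo 3-standard-error band used to
validate it. `count_in_spot_converged` performs an automatic step-halving
check (default tolerance 0.1%), and `mc_count_in_spot` is an independent
rejection-sampling oracle (estimate = spot area × mean sampled ρ, with its
standard error), seeded and reproducible.

*Tolerances.* Layout invariants (containment, non-overlap) use an absolute
1e-9 mm tolerance so that exact tangency — spots touching each other or a
boundary — is allowed, matching the border rule below.

## Spot layouts

Spots are equal discs (default diameter 0.4 mm, edge-to-edge spacing
0.4 mm, i.e. "one spot apart": center pitch 0.8 mm) on concentric rings:

- first ring centers at `inner + d/2`, tangent to the inner boundary;
- radial pitch: `square` = center pitch; `hex` = √3/2 × center pitch (the
  hexagonal row spacing), the default, as it packs closer to the published
  spot totals;
- each ring holds ⌊2πR / pitch⌋ evenly spaced spots (capped so neighbouring
  chords are at least one diameter), with alternating half-step angular
  offsets to avoid radial alignment;
- a spot is kept iff its closed disc lies in the closed treatment annulus —
  crossing a boundary excludes a spot, touching does not;
- for tight spacings where hex rows would collide, spots overlapping the
  previous ring are dropped deterministically.

Generation is fully deterministic, and enlarging only the outer radius
appends rings without disturbing inner ones, so a scatter layout
(annulus 5.14–15.6 mm) is a subset of the full-scatter layout
(5.14–18.6 mm).

With the default burn geometry, hex packing yields 1193 scatter and 1718
full-scatter spots — 5–6% below the published CAD counts of 1261 and 1837,
whose exact arrangement is not derivable from the stated rules. For
replication runs, `count_match` mode keeps the hex ring structure and
deterministically adds (or removes) spots ring-by-ring — largest fractional
ring capacity first — until the total matches a target exactly. A scaled
pitch cannot guarantee exactness because the count is a step function of
pitch that can jump past the target; per-ring adjustment is exact by
construction and perturbs the geometry minimally (ring pitches shrink by at
most a few percent, never below one spot diameter of chord).

The "one extra row inside the vascular arcade" scenario is a single ring
tangent to the inside of the PRP-free circle (center radius
5.14 − 0.2 = 4.94 mm). ⌊2π·4.94/0.8⌋ = 38 spots; a ceiling rule would give
39. We use the floor rule everywhere for consistency with ring packing and
report 38; the index increment is insensitive to that ±1 spot.

## Synthetic density profiles and the packaged fixture

The averaged rod-density curve underlying the published totals was never
released as a table, so the package generates a parametric stand-in with
the qualitative anatomy of human rod density: near-zero rods at the foveal
center (a narrow cone peak stands in for the foveal summit), a rod ridge of
peak density a few mm out, and a peripheral decline:

ρ(e) = A_cone·exp(−e²/2w_cone²) + A_rod·exp(−(e−e_r)²/2w_rod²) (e ≤ e_r)
     + A_rod·exp(−(e−e_r)/L) (e > e_r)

Defaults (frozen): A_cone = 1.5e5 cells/mm², w_cone = 0.3 mm, A_rod = 1.6e5
cells/mm², ridge at e_r = 4.0 mm, inner flank width w_rod = 2.0 mm, decay
length L = 9.0 mm, evaluated on a 0.1 mm grid out to 18.6 mm (grid fine
enough that spot quadrature converges below 0.1%). The ridge position and
the two length scales were set from the constraints the published counts
impose on any rotationally symmetric profile: destroyed-count per burn area
implies an area-mean density of ≈0.98e5 cells/mm² over the scatter annulus
and ≈0.5e5 between equator and ora serrata, and the flank width keeps rods
low at the fovea. These are closed-form bracketing calculations, not fits;
the parameters were frozen after that derivation.

`packaged_fixture()` hollows the optic-disc cylinder and calibrates the
profile by a single multiplicative factor (counts are linear in density,
so calibration is exact) to the published total of 96,571,900
photoreceptors (9657.19 mm³). The identical table ships as
`src/prpsim/data/fixture_profile.csv` and a test asserts the two agree
bit-for-bit. A rods-only variant calibrates to the 92,000,000 average rod
count from the underlying retinal-wholemount study.

`perturbed_profile` multiplies each grid node by a unit-mean lognormal
factor (relative SD = `noise_sd_fraction`), emulating inter-eye
variability; because the destruction index is a ratio of integrals over
the same profile, node-level noise largely cancels (tested: coefficient of
variation of the index ≪ the noise fraction).

**What the fixture does and does not show.** Passing tests demonstrate that
the pipeline reproduces the published indexes *given* a density profile
consistent with the published aggregate constraints — not that the fixture
is the true anatomical curve. Real rod maps are mildly non-concentric
(quadrant differences ≲15%); the model averages that away by construction,
as the original simulation did.

## Problem sizes and expected numbers

The standard run (fixture profile, count-matched 1261/1837-spot layouts,
10 µm spot quadrature) takes ~1 s. It yields destruction indexes of 16.47%
(scatter) and 20.45% (full-scatter) against the published 16.2% and 19.8% —
inside the ±2-point band that is the documented substitute for exact
reproduction, impossible without the untabulated source curve — and
photocoagulation indexes of 14.58% / 21.24% from
100·n·(d/2)²/R² with the published counts. The published table prints
14.3% / 21.3% for the latter; the small discrepancy (≤2% relative) is
inherited from the earlier area-based study and is reported, not resolved.
Property tests (conservation over 100 random profile/layout pairs, MC
oracle agreement, rotation invariance) run in under a minute.

## Known limitations

- Burns are ideal cylinders: no partial photoreceptor survival inside a
  burn, no atrophic creep, no axial-length adjustment.
- Cones are not counted separately; in the treated annulus they are 10–60×
  rarer than rods.
- The PRP-free region is a circle; real vascular-arcade exclusion zones are
  not circular.
- The ring-packing lattice is an idealisation of manual/CAD spot placement;
  `count_match` matches published totals, not the unpublished arrangement.
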