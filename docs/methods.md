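# Methods

`coroseg` segments the coronary artery wall — the region between the
contrast-filled lumen and the outer vessel boundary, where atherosclerotic
plaque lives — from 3D CT angiography volumes, and derives the centerline,
straightened (curved multiplanar reformatted) views and wall-thickness
profiles used to review and quantify plaque. Because no patient data ship
with the package, every claim is exercised on synthetic vascular phantoms
with analytic ground truth; this note records the models, the defaults and
their rationale, and what the phantom results do and do not establish.

## Pipeline model

The framework runs six stages per vessel branch, from two user seeds (the
ostium and a distal target):

1. **Vesselness (Frangi) filtering.** Multiscale Hessian eigenvalue analysis
   enhances bright tubular structure. Second derivatives are taken against
   physical mm coordinates (per-axis `sigma_mm / spacing`), so anisotropic
   voxels are handled; responses are gamma-normalized with the Hessian
   scaled by sigma^2 and the output is the per-voxel maximum over scales.
   Defaults: scales {0.5, 1.0, 1.5, 2.0, 2.5} mm (covering calibers from the
   2 mm analysis floor upward), alpha = beta = 0.5, and a data-adaptive
   structureness constant c = half the maximal Hessian Frobenius norm per
   scale, which makes the response invariant to global HU rescaling. A
   relative noise floor (1e-4 of the data maximum) zeroes the response on
   (near-)constant volumes, where the truncated derivative kernels would
   otherwise amplify a ~1e-7 per-unit residual.

2. **Lumen initial contour (S1).** Seeded region growing runs independently
   on the HU volume (default window [175, 800] HU — contrast-enhanced blood
   minus calcium-free tissue) and on the vesselness image (default: the top
   2% of nonzero responses); the two binary masks are intersected. The HU
   growth alone leaks into every connected blood-pool structure (aorta,
   chambers); the vesselness growth alone picks up tube-like confounders
   (interfaces, adjacent structures). Their intersection keeps only voxels
   that are both HU-connected to the seed and tube-shaped. Growth
   connectivity is 26-neighborhood.

3. **Lumen level set (S3).** See "Level-set evolution" below; the front
   expands outward from S1 to the inner wall boundary.

4. **Outer initial contour (S2).** The final lumen is extended outward by a
   fixed geodesic distance of 5.5 mm — sized so that even the thickest
   reported plaques (about 4.4 + 0.7 mm) are enclosed — propagating only
   through non-fat tissue: voxels below 0 HU are barriers, not merely
   excluded afterwards, so a perivascular fat sheath bounds the dilation.
   Implementation: the reported distance is a certified lower bound on the
   continuous geodesic distance, `max(exact Euclidean EDT, 26-neighbor
   shortest-path distance / worst-case chamfer overestimation factor)`,
   where the factor is the reciprocal inradius of the convex hull of the
   normalized step vectors (exact for any anisotropy). Reachability is
   gated by 6-connected flood fill, so a face-connected closed barrier is
   never crossed, not even through diagonal pinholes. Wherever a source
   sees a voxel along an unobstructed straight segment the result equals
   the exact Euclidean distance transform; in geometric shadow zones behind
   barriers it can include voxels up to the chamfer gap (about 12%) too
   far — a deliberate inclusive bias, since S2 only needs to *contain* the
   vessel.

5. **Vessel level set (S4).** The front shrinks inward from S2 to the outer
   wall boundary. Lumen and vessel are then joined: vessel := vessel OR
   lumen, wall := vessel minus lumen, enforced voxel-exactly.

6. **Visualization.** Marching cubes extracts lumen/vessel surfaces from a
   Gaussian-smoothed occupancy field (level 1/2), which removes the voxel
   staircase; volumes are padded by one voxel first so masks touching the
   volume faces still yield watertight meshes. The centerline is the medial
   path of the mesh interior: the interior is voxelized (0.3 mm pitch), the
   Euclidean distance transform supplies the inscribed-sphere radius, and a
   minimum-cost path between the seeds with cost 1/radius rides the medial
   ridge — a distance-transform realization of the Voronoi medial axis,
   held to the same accuracy oracles (cylinder axis within half a voxel,
   quarter-torus length within 3%). The raw path is smoothed by a cubic
   B-spline whose smoothing factor is reduced until the deviation from the
   raw path is below 0.3 mm, then resampled at 0.25 mm. Frames follow
   Frenet–Serret where curvature >= 1e-4 / mm and rotation-minimizing
   parallel transport below that threshold (straight coronary spans are
   common and the Frenet normal is undefined there); sign continuity is
   enforced across inflections. CMPR resamples the volume on planes spanned
   by rotation-minimizing normals (literal Frenet frames torsion-spin the
   cross-sections), trilinear for HU, nearest-neighbor for masks; defaults
   half-width 10 mm, in-plane step 0.2 mm, arc step 0.25 mm. Radial
   longitudinal sections at `k * 180deg / n` reproduce the reader protocol
   (5 sections -> 36 deg gap; 20 supported). Wall thickness per slice is the
   mean over 360 rays of (outer boundary radius − lumen boundary radius);
   an area-equivalent annulus variant is available behind a flag.

## Level-set evolution

The speed ("feature") image is a sigmoid of the Gaussian-gradient magnitude,
normalized so zero gradient maps to speed exactly 1. The sigmoid center is
data-adaptive: beta = 0.25 x the 95th-percentile gradient magnitude in a
±2 mm band around the initial contour (an estimate of the edge strength the
front is heading for), with width alpha = beta/2. Centering the sigmoid well
*below* the edge strength is deliberate: propagation then switches off over
the whole shoulder region — including wall texture at a substantial fraction
of the edge gradient — and the final boundary placement is left to the edge
attraction term. This matches the observation that maximum-gradient points
represent neither boundary exactly; the profile shoulders do.

The PDE is discretized morphologically (the standard morphological
geodesic-active-contour operators): per iteration a balloon step (dilation
for the outward lumen front, erosion for the inward vessel front) applied
only where speed exceeds a stopping threshold (0.3); an attraction step
that moves the front down the slope of the *raw* gradient-magnitude field
toward edge crests (the sigmoid saturates near edges and flattens exactly
the extrema the advection term needs, so attraction uses the unsaturated
field); and curvature smoothing by 3x3x3 majority vote (threshold-dynamics
discretization of mean-curvature motion). Every term is gated by local
speed or slope, so numerically-flat regions are strictly stationary; a
speed image that is identically zero returns the initial mask unchanged.
The scheme moves at most one voxel per iteration, terminates on a fixed
point, a changed-fraction tolerance (1e-3) or a detected limit cycle, and
is bit-reproducible (pure integer/float numpy, no threading).

Coronary lumina span only ~4 voxels at 0.4 mm spacing, so boundary accuracy
is gained by evolving on a locally supersampled grid: the initial contour's
bounding box plus 4 mm is cropped, resampled to an isotropic grid at
`min(spacing)/supersample` (3x for the lumen, 2x for the vessel), evolved
there, and the result is read back at native voxel centers. A
finite-difference sparse-field evolution was evaluated first and rejected
at this caliber: its CFL-coupled global timestep freezes slow front
segments and its equilibria park half a voxel off the boundary with
knife-edge parameter sensitivity.

The inward vessel front runs with attraction disabled: the wall is thinner
than the attraction stencil (~4 voxels), and a sign-based attraction update
straddles the narrow gradient crest between the two wall edges and carves
the wall. The balloon + gating alone stops the inward front crisply at the
wall–fat edge. Propagation weight acts through its sign (balloon
direction); advection weight acts as on/off at unit strength — both
documented in `LevelSetParams`.

## Phantom generator

The generator emulates the image structure the method assumes: a single
vessel along a parametric curve (line, arc, helix) with lumen ~400 HU
(contrast), wall/soft plaque 50 HU, calcified plaque 800 HU, perivascular
fat −80 HU, myocardium 40 HU, background −800 HU. Geometry defaults: lumen
radius 1.5 mm and wall thickness 0.75 mm (the typical healthy values); a
plaque narrows the lumen by a raised-cosine factor and thickens the wall
over a stated arc window. A 1.5 mm fat sheath abutting the outer wall is on
by default — perivascular fat supplies the outer-wall contrast, and its
absence is precisely the hard case the method acknowledges. HU values are
supersampled 3x per axis near interfaces and averaged (partial-volume
rendering); truth masks are noise-free center-sample rasterizations and
reference volumes come from arc-length integration of pi r(s)^2.

Motion artifact is modeled as a localized anisotropic Gaussian blur over an
arc-length window (default for the robustness fixture: sigma 1.0 mm
in-plane and axial over a 5 mm window, which drops the axis HU to ~265 —
enough to defeat a naively initialized front while remaining inside the HU
region-growing window, the regime in which the guided initialization is
claimed to help). Confounders: a bright sheet near (but disjoint from) the
vessel, and a parallel vein tube at wall-like HU at a stated surface gap;
neither touches the truth masks. Noise is additive Gaussian, seeded;
identical seeds give bit-identical volumes.

What the phantoms do *not* emulate: CT physics (no sinogram, beam
hardening, or blooming), branching trees (single vessel per call),
eccentric or lobulated plaque cross-sections, HU inhomogeneity within a
tissue class, and reader variability. Passing phantom tests therefore
demonstrates the geometric and algorithmic correctness of each stage and
of their composition under controlled degradations — not clinical
performance on patient data.

## Findings worth recording

- With the default edge-adaptive vessel stage, a vein touching the artery
  is *absorbed and removed* by the inward front (the vein interior is
  homogeneous, so the erosion passes through it and stops at the artery's
  own edges): gap-0 and gap-2 fixtures segment equally well. The documented
  failure mode — the touching vein retained as if it were plaque — appears
  when the inward front is configured to stop at weak edges (fixed low
  sigmoid center), the sensitivity regime edge-based schemes classically
  operate in; the regression test demonstrates the gap ordering under that
  configuration.
- A bright sheet 1.5 mm from the vessel enters the vesselness-only region
  growth only under an inclusive vesselness window (lower threshold 0.03,
  the kind needed in practice to keep faint distal segments); the
  HU-intersection rejects every sheet voxel under the same window. With the
  strict top-2% window the sheet never connects to the seeded component.
- For a solid tube the best-responding Frangi scale under sigma^2
  normalization lies near half the radius, not at the radius; tests assert
  agreement with the single-point Hessian eigen-analysis oracle rather than
  a nominal scale-radius identity. Likewise the tube-to-sphere response
  ratio is bounded by exp(2) ~ 7.4 at beta = 0.5 (a sphere has RB = 1), so
  the discrimination test asserts the oracle-derived ratio.

## Numerical choices and degenerate inputs

- Voxel indices are 0-based; a voxel's physical coordinate is its center;
  all geometric quantities are mm. Only `grid.py` converts between index
  and physical space.
- Tie at the front: voxels on the zero level are foreground.
- Region growing rejects a seed whose voxel value lies outside the window,
  naming the seed and value; the S1 intersection always contains the seed
  voxels, so an empty intersection is defensive-only.
- `wall_thickness_profile` reports NaN (flagged) for slices with an empty
  lumen; CMPR samples outside the source volume carry a sentinel and a
  per-slice flag; a severed lumen interior raises a no-path error from the
  centerline stage and the pipeline records it as a QC flag and returns
  the partial result.
- QC flags arc-length spans whose area-equivalent lumen diameter falls
  below 2.0 mm, excluding declared focal-stenosis windows.
- Determinism: phantom noise is seeded, all stages are single-threaded
  numpy/scipy; two runs with the same configuration and seed produce
  bit-identical masks and stage hashes.

## Problem sizes

The test suite and the acceptance script run phantoms of 48x48x130 to
90x90x90 voxels at 0.4 mm isotropic spacing (vessels 36–60 mm long), with
the level sets evolving on supersampled crops of roughly 1–9 million fine
voxels. These sizes exercise every code path at realistic caliber-to-voxel
ratios; the library itself is size-agnostic.
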