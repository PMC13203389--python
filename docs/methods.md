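# Methods

`meshdose` simulates the geometric and dosimetric core of external-beam
radiotherapy planning on triangulated organ models: it refines labeled
point clouds into surface meshes, traces beam axes through them, estimates
tumor-center dose with a correction-based depth-dose model, scores
organ-at-risk burden with the LKB/NTCP formalism, and checks machine
clearance with conservative axis-aligned boxes. This note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Segmentation refinement

A sparse labeled prediction (e.g. the output of any point-cloud segmenter)
is densified and surfaced in five steps:

1. **Label propagation.** Each dense point takes the majority label among
   its `knn_label = 10` nearest sparse points (Euclidean, physical mm —
   anisotropic voxel spacing is already folded into the coordinates).
   Majority ties go to the label of the single nearest neighbor: local,
   deterministic, and exact when sparse = dense.
2. **Statistical outlier removal.** The per-point statistic is the *mean*
   distance to its `knn_outlier = 30` nearest neighbors; points above
   (global mean + 2 × global sd) are dropped. The statistic is computed
   once over all points (single pass, no iteration), which makes removal
   invariant to point order. "Distance to the k neighbors" could also be
   read as the max or the full set of k distances; the mean reading is the
   conventional one (it is what PCL's StatisticalOutlierRemoval does) and
   is the implemented contract.
3. **Voxelization.** Binary occupancy on the voxel-center convention
   `physical = origin + index * spacing` (no half-voxel shift), default
   spacing 0.97656 × 0.97656 × 2.99 mm matching common CT acquisition
   geometry. Occupancy is taken as-is from the (volume-filling) cloud; no
   morphological closing is applied, so surface-only clouds must be
   densified first.
4. **Marching cubes** at iso level 0.5, step 1, vertices mapped back to
   physical mm. A one-voxel zero border is padded so every component
   closes. Discretization band to know about: a single occupied voxel
   yields the mid-edge octahedron (1/6 of the voxel volume); volumes
   converge to truth as spacing shrinks, and the point density must be
   high enough (≳ 10 points per voxel in expectation) that interior voxels
   are actually hit — under-sampled interiors read as cavities and bias the
   enclosed volume low.
5. **Laplacian (umbrella) smoothing**, 80 iterations at relaxation 0.1 with
   uniform 1-ring weights, then retention of the largest face-connected
   component (ties broken by area). Umbrella smoothing shrinks convex
   surfaces by roughly edge² × mean curvature per step; at the default
   mesh resolutions this bias is well below a millimetre, but it is the
   reason the smoothing test uses a fine sphere.

Farthest-point sampling (greedy max-min, seeded first pick) and the Dice
coefficient 2|A∩B|/(|A|+|B|) round out the module. Dice on two empty sets
is an error, not 0 or 1.

## Ray casting

Beam axes are single rays (the divergent field is not modeled; doses are
central-axis point estimates). For each mesh face the ray-plane parameter
is t = (n̂·P − n̂·r₀)/(n̂·r⃗d), rejected when |n̂·r⃗d| < 1e-9 (parallel) or
t ≤ 1e-9 mm (behind/at the origin); containment uses the cyclic same-side
test — for every vertex i, the cross products (P−Pᵢ)×(Pᵢ₋₁−Pᵢ) and
(P−Pᵢ)×(Pᵢ₊₁−Pᵢ) must not point the same way — with edge contact counting
as inside. Hits closer than 1e-6 mm merge (shared-edge crossings).
Entering/exiting is classified by sign(r⃗d·n̂), but pairing into intervals
is by parity of the sorted hit list: marching-cubes meshes can carry local
normal flips, and parity is robust to them. An odd crossing count raises an
open-mesh error naming the organ.

Nested organs (tumor inside lung) partition the path by a priority order —
smallest enclosed volume wins by default, overridable — applied on the
elementary intervals between all crossing parameters. The brute-force
all-faces sweep is the reference path; an AABB-tree face prefilter is
available and tested to produce identical hit sets.

## Depth-dose model

Central-axis depth dose uses the buildup-tail shape
f(d) = d/(d²+n) · e^(−μd) with d in cm, n a dimensionless diffusion
parameter and μ (cm⁻¹) the attenuation coefficient. The shape is
normalized to 100 % at its own peak: PDD(d) = 100 · f(d)/f(d_max), with
d_max located by bounded scalar maximization on (0, 50] cm (tolerance
1e-8 cm). The peak is unique for this family (verified by grid scan); at
μ→0 it approaches √n. The demonstration parameters n = 2.25,
μ = 0.0465 cm⁻¹ give d_max ≈ 1.41 cm and a 6 MV-like curve; they are
illustrative defaults, not measured beam data — fit your own with
`fit_pdd`, which least-squares the normalized shape in log-parameter space
(positivity for free, deterministic for a fixed init) and refuses samples
that do not span both sides of the fitted peak.

SSD dependence follows inverse-square practice: the SSD-explicit form
100 · ((SSD+d_max)/(SSD+d))² · e^(−μ(d−d_max)) · Ks, whose ratio at two
SSDs is the Mayneord factor
F = ((SSD₂+d_max)/(SSD₁+d_max))² · ((SSD₁+d)/(SSD₂+d))². Ks, the scatter
factor between d and d_max, defaults to 1 and is a calibration field.

Heterogeneity is handled by equivalent depth: each traversed segment
contributes z·η, with η the water-equivalent attenuation ratio (soft
tissue/bone 1, lung 0.275, heart 1.05 — mass-density proxies for relative
electron density). Gaps covered by no organ mesh count as water. Geometry
is mm, dosimetry is cm; `effective_depth` is the single conversion point.

Monitor units convert as
TD = MU · Dref · PDD/100 · Scrc · Spr · ((SSD₀+dref)/(SSD+dref))^e.
The distance-correction exponent e defaults to 2 (inverse-square,
consistent with the Mayneord treatment); some sources quote the factor
unsquared, so e = 1 is selectable rather than silently chosen.

## LKB / NTCP

The DVH reduction is Vol_eff = (1/Vol_ref) Σ Volᵢ (Dᵢ/D_max)^(1/n); the
probit argument is t = (D_max − TD50(v))/(m · TD50(v)) with the partial-
volume tolerance TD50(v) = TD50 · v^(−n) (the standard LKB power law —
the notation "TD50(Vol_eff)" is interpreted this way and documented as an
interpretation); NTCP = Φ(t) = 0.5 + erf(t/√2)/2 via the platform erf.
DVHs are an input type with equal-volume sample weighting; no 3-D dose
grid exists in this engine, so DVHs are not computed from imaging.

Serial organs are flagged when the beam axis crosses them, reporting the
PDD-maximal depth in the traversed interval (the peak when straddled, the
entry when entirely past it, the exit when entirely before it). For
parallel organs, the trapezoidal area under the tumor-depth-vs-gantry-angle
curve is the irradiated-volume proxy; lower is better.

## Beam geometry

IEC-style convention, declared rather than assumed: x = patient left,
y = posterior, z = superior; the gantry rotates about z through the
isocenter; at 0° the source is anterior at isocenter + SAD·(0,−1,0) and
the beam travels +y; at 90° the source is on the patient's left. Beams are
isocentric and aimed at the tumor center; off-axis targets are projected
onto the ray with a logged warning. SSD is the first body-mesh hit along
the ray. Sweep reports keep the caller's raw angles so full-circle
profiles remain strictly increasing for the AUC.

Model-vs-reference comparison uses
100 · |model − reference| / reference — the reference (TPS) value as
denominator, which reproduces all three published percent differences at
one-decimal rounding and is documented as inferred, not stated.

## Collision detection

Deliberately conservative: every component's AABB is recomputed in the
world frame at each pose, so rotated parts get enlarged boxes and
near-misses inside the margin are flagged (false positives may look like
small gaps — that is the designed trade-off, not a bug). SAT for AABBs is
interval overlap on the three axes, touching faces counting as collision.
Each box is inflated by margin/2 (default margin 50 mm), so a pair is
flagged exactly when an axis-wise gap falls below the margin. Pairs
adjacent in the kinematic chain (arm–head, couch–patient) are excluded.
The BVH (median split on the longest centroid-extent axis) is an
acceleration only; its pair list is tested identical to all-pairs. The
machine model is schematic (gantry arm + head rotating about z, couch +
patient translating/yawing), not a vendor geometry.

## Synthetic phantom

All organs are spheres/ellipsoids so entry/exit points, chords and volumes
have closed forms usable as oracles. Default thorax: body 350×200×400 mm
ellipsoid (water), two lungs 100×80×200 mm (η 0.275), heart (η 1.05,
serial), 15 mm-radius tumor at the left-lung center. Dimensions are
clinically plausible artifact choices that keep chord lengths in the
useful range of the depth-dose curve; they are not patient measurements.
Cloud sampling is uniform per organ (fixed count per organ), perturbed by
isotropic Gaussian noise; outliers are placed 5–10× the noise scale
(≥ 5–10 mm) beyond the surface via normalized-space inflation, which
guarantees the clearance needed for the 2σ rule to find them. Organ
samples may spatially overlap for nested organs (body points can fall
inside a lung) — real CT labels are exclusive, so exact-label recovery is
demonstrated on disjoint-organ scenes.

What passing tests show — and do not show. The synthetic phantoms exercise
geometry, bookkeeping and the analytic identities exactly; they do not
contain CT noise, partial-volume effects, true anatomical shapes, scatter,
lateral electron transport or heterogeneous media beyond piecewise-uniform
η. The published comparison itself shows the correction-based model is
≈ 6 % off a clinical TPS for homogeneous sites and ≈ 14 % in lung; this
engine reproduces that model class, not a convolution/superposition or
Monte Carlo engine.

## Problem sizes used by the test suite and acceptance script

30 000-point clouds refined at 3 mm voxels (volume error ≈ 3 %),
subdivision-4 icospheres (5 120 faces, chord error < 0.2 %), 50-depth PDD
fits, 25-angle sweeps, 100-box collision scenes over 20–100 seeds. These
sizes were chosen so every oracle comparison is comfortably resolved;
errors shrink further at finer resolution (convergence is itself tested).
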