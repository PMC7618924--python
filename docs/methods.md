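# Methods

## Coordinate and unit conventions

All physical quantities are micrometres and minutes. Arrays are ordered
(z, y, x) with 0-based voxel indices; a voxel's coordinate is its centre,
`index × spacing`. Orientations are sign-free axes (unit vectors defined up
to sign); every angle between axes is folded to [0°, 90°].

## Synthetic blastocyst generator

The generator emulates the statistical structure of a chromatin-labelled
blastocyst movie, not its optics. Nuclei are solid ellipsoids with
per-nucleus log-normal size jitter around default semi-axes
(6.5, 4.5, 3.5) μm (volume ≈ 430 μm³, in the range of blastocyst-stage
nuclei). Outer (trophectoderm-like) nuclei sit exactly on a spherical
shell of baseline radius R₀ = 30 μm whose radius oscillates sinusoidally
(default ±6 % with a 24-frame period) to emulate expansion/collapse;
inner (ICM-like) nuclei random-walk inside 0.35 R. Per-frame centroid
displacement defaults to 1 μm/frame — the real displacement at a 15-min
cadence is not well characterised, so this is an explicit free parameter,
kept well below the ~3.5 μm short semi-axis so consecutive instances
overlap in a tracking-friendly way.

**Tangential bias.** A single parameter κ ∈ [0, 1] controls how nuclear
long axes and division axes align with the local tangent plane. An
isotropic axis v is split against the radial unit vector r̂ and its radial
component shrunk:

    v' ∝ (1 − κ)(v·r̂) r̂ + (v − (v·r̂) r̂)

κ = 0 leaves the isotropic axis distribution (mean axis-to-radial angle
1 rad ≈ 57.3°); κ = 1 projects exactly onto the tangent plane (90°); the
angle is monotone in κ for every draw. The default movie uses κ = 0.8.

**Divisions.** Scheduled divisions replace a parent by two daughters of
half its volume, placed symmetrically at ±0.8·a along the sampled division
axis at the division frame (a = parent long semi-axis). This guarantees
separable instances at birth. Optional micronuclei (default semi-axes
(1.6, 1.4, 1.2) μm, ≈ 11 μm³, well under the 30 μm³ pre-filter) are shed
at division and ride along daughter 1 at a fixed offset — the passive
inheritance scenario.

**Rendering.** Labels are the exact rasterization of the truth ellipsoids;
voxels claimed by two nuclei go to the nearer centroid (Euclidean), ties to
the lower id, which keeps every label star-convex about its centroid.
Intensity is the blurred indicator (anisotropic Gaussian, default σ =
(1.6, 0.8, 0.8) μm against a (2, 1, 1) μm grid) with Poisson noise at
photon scale 50 plus additive Gaussian noise (σ = 0.05), giving in-nucleus
SNR ≈ 10. Not emulated: refraction, depth-dependent attenuation, membrane
signal, mitotic chromosome morphology, photobleaching. Tests passing on
these movies therefore certify the geometry/linking machinery, not
robustness to real optical artefacts.

## Preprocessing

Dual-view fusion is a plain voxelwise mean (no registration by default; a
rigid shift can be applied upstream if needed). Resampling targets
0.381 μm lateral / 1.9 μm axial by default, with output shape
`round(shape × spacing / target)`; labels always go through order-0
(nearest) so label sets are preserved. Normalization maps the 1st and
99.8th intensity percentiles to [0, 1] per frame (robust to hot pixels;
per-movie normalization is available behind a flag). Gamma correction
(default γ = 0.8) is a monotone contrast stretch.

## Segmentation

The trained anisotropic star-convex network that motivates this geometry
is out of scope (training data and weights are not part of the package);
the pipeline accepts externally produced label volumes through the
standard readers, and ships a classical stand-in: anisotropic Gaussian
smoothing (σ = (1.0, 0.6, 0.6) μm), a global threshold, Euclidean distance
transform (physical sampling), seeds at distance maxima greedily thinned
to ≥ 6 μm separation in physical space (strongest first, index order as
tie-break), and a watershed on the inverted distance transform.

The default threshold is **half-max**: the midpoint between the robust
background level and the foreground plateau (estimated from an initial
Otsu split). For a blur-limited fluorescent body in *linear* intensity the
half-maximum contour recovers the true surface; Otsu, biased by the PSF
halo, systematically over-grows instances (~1.7× volume on the synthetic
renders). For this reason the pipeline segments the normalized pre-gamma
frame; Otsu and explicit thresholds remain available.

Star-convex encoding uses Fibonacci-sphere ray directions generated in a
space rescaled by the voxel spacing and renormalized (denser sampling
along better-resolved axes), 96 rays by default; the ray count of the
original network is not recoverable and is exposed as a parameter. Ray
distances are measured to the last in-label voxel along each ray
(marching at ¼ of the finest spacing). Decoding interpolates the radial
distance field with inverse-distance weights over the 4 nearest rays;
overlaps resolve by larger containment margin, ties by lower id. NMS is
greedy by descending score with polyhedron IoU estimated on a sampled
grid.

The pre-filter removes instances with voxel-count × voxel-volume strictly
below 30 μm³ ("smaller than" read as strict; no sub-voxel correction), is
idempotent and keeps surviving ids.

## Tracking (regularized GMMOT)

Each frame's instances become a Gaussian mixture: weight ∝ voxel volume
(normalized within the frame), mean = centroid, covariance = second
central moment of voxel coordinates with Sheppard's correction
(+ spacing²/12 per axis — voxel mass fills its box) and eigenvalues floored
at (0.5 μm)² for SPD safety. Pairwise costs are squared Bures–Wasserstein
distances scaled by a displacement penalty:

    c_ij = W₂²(i, j) · (1 + λ |m_i − m_j|²),   λ = 0.01 μm⁻²

The penalty inflates long-range moves superlinearly, suppressing mass
teleportation between distant nuclei. The exact functional form of the
regularization used in the original tool is unpublished; this is the
package's own choice, motivated by the same goal.

Balanced transport between the weight vectors is solved exactly by linear
programming (HiGHS) at ε = 0 — the default, exact and fast at blastocyst
densities (≤ ~50 components). Entropic smoothing (ε > 0) is fully
supported via log-domain Sinkhorn with ε-scaling (annealed from max cost,
warm-started potentials) and an exact-marginal rounding step; `"auto"`
selects ε = 0.05 × median matched-pair (row-minimum) cost. Entropic mode
is not the default because with Bures costs spanning ~1–10⁵ μm² per frame
pair, Sinkhorn at small ε needs impractically many iterations to reach the
10⁻⁶ marginal tolerance; a genuinely non-convergent solve (residual mass
> 1 %) raises with iteration diagnostics rather than returning silently.

Link readout: each source's daughters are the targets receiving ≥ 20 % of
its mass (1 → continuation, 2 → division, 0 → disappearance; > 2 → top-2
kept as a division and the rest flagged as residual, mirroring manual
curation of multipolar events). A target claimed by several sources goes
to the largest sender — merges are suppressed as biologically disallowed
here. Unclaimed targets are appearances. Gap closing across more than one
frame is out of scope.

The forest (in-degree ≤ 1, out-degree ≤ 2, acyclic) is exported as a
TrackMate-style XML subset (Spots with physical coordinates and
volume-equivalent-sphere radii, Edges, Tracks as connected components)
for manual curation; the bundled reader round-trips it exactly. The
package deliberately provides no curation GUI — the automated result plus
the export *is* the semi-automated contract.

## Morphometry

The best-fitting ellipsoid of an instance comes from the eigendecomposition
of its (Sheppard-corrected) voxel covariance: diameter `2√(5 λ_k)` along
eigenvector k — the exact moment inversion for a solid uniform ellipsoid —
orientation = leading eigenvector, anisotropy = d_max/d_min. Degenerate
instances (≤ 2 voxels, or rank-deficient) are flagged with anisotropy 1 and
floor covariance.

Embryo shape per frame: 3D convex hull of all nucleus voxel coordinates;
hull volume and centre are exact (tetrahedral decomposition); the embryo
ellipsoid is fitted to fixed-seed uniform samples of the hull *interior*
(vertex-based moments would be biased by vertex density). Average shell
thickness is the standard deviation of nucleus-centroid-to-embryo-centre
distances — 0 for a perfect single-layer shell.

Angles: α between nucleus and embryo long axes; β between a nucleus axis
and its radial direction (0° radial, 90° tangential); ϑ between the
inter-daughter axis at the daughters' first shared frame and the radial
direction at the parent. The reference frame for ϑ is the package's
choice; the daughters' first common frame is the least-ambiguous moment.

**Isotropy testing.** "Deviation from the uniform distribution" is read as
deviation from an *isotropic axis*: for an isotropic 3D axis the cosine of
its angle to any fixed direction is Uniform(0, 1), so the one-sample K-S
test is applied to u = cos(angle). A tangential-vs-radial claim is a claim
against isotropy, which motivates this null; the literal uniform-in-angle
null remains available behind a flag (`null="uniform-angle"`). Type-I
error is calibrated (rejection rate 0.048–0.053 at α = 0.05 over 1000
isotropic replicates of n = 100 in the shipped checks).

## Pipeline, determinism, problem sizes

One master seed fans out through `numpy.random.SeedSequence.spawn` into
per-module substreams, so adding a consumer never shifts another's
randomness; all seeds stay below 2³¹. Stages write `.done` markers keyed
by the config hash (SHA-256 of canonical JSON) and are skipped on
unchanged reruns; CSV outputs use fixed float formatting and are
byte-identical across identical runs. Unknown config keys are rejected.
CLI exit codes: 0 ok, 2 config error, 3 data error, 4 numerical failure.

Shipped checks run at deliberately desk-scale sizes — the default movie is
12 + 4 founders / 6 divisions / 40 frames on a (2, 1, 1) μm grid (~46 × 91
× 91 voxels), transport oracles use ≤ 5×5 mixtures, metric checks 10⁴
triples, K-S calibration 1000 × n = 100 — chosen so the whole suite
completes in minutes while still exercising every code path at the
geometry of a real blastocyst.

## Known limitations

* The classical segmenter is a stand-in: it assumes roughly convex,
  blur-limited blobs and will merge nuclei closer than the seed distance;
  it is not a replacement for the learned model on real data.
* Balanced transport assumes total nuclear volume is roughly conserved
  between frames; large segmentation dropouts appear as
  appearance/disappearance events rather than being gap-closed.
* Embryo orientation from hull-interior sampling carries Monte-Carlo
  error (fixed seed, 2·10⁴ samples ⇒ axis wobble ≪ 1° at blastocyst
  anisotropies).
* Mitotic-phase classification and mitotic-error calling (misalignment,
  lagging, slippage, multipolarity) are intentionally absent; only
  micronucleus-scale plumbing (size association, passive-inheritance
  tracking) is provided.
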