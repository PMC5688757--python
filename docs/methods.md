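# Methods

This note records the models, conventions, parameter choices and known
limitations behind `retinamech`. All positions are in micrometres, all
angles in degrees; orientations (column directions, ridge angles) are
undirected and compared with the 180°-periodic circular distance. In image
arrays the first axis is y (rows, downward), the second x (columns,
rightward); angles are measured from +x toward +y.

## The lattice model

The adult zebrafish cone mosaic is idealized as straight, single-cell-width
columns repeating the six-cone motif **R, B, R, G, U, G** with spacing *s*
between successive sites (default 5 µm, a typical centre-to-centre distance
between cone apical profiles). Successive Red cones in a column are thus
separated alternately by one Blue cone and by a Green–UV–Green triplet.
Adjacent columns are phase-shifted along the column axis by half a repeat
unit (3 sites), which produces rows of alternating UV and Blue cones
perpendicular to the columns and places each UV cone at the centre of a
ring of six Red cones.

Columns are separated by *f·s* with *f* exposed as
`column_spacing_factor`. The default is *f = √3*: it is the unique value
for which the six Red cones ringing a UV cone are equidistant from it (a
regular hexagon of circumradius 2*s*), so the ideal lattice satisfies the
hexagonality rule its own validator enforces. Red cones then form a
honeycomb — every interior Red has exactly 3 equidistant Red neighbours at
2*s*, and every interior UV a regular Red hexagon — which is the geometric
content of "hexagonally packed Red cones" for this motif; no inter-column
spacing makes each Red have six equidistant Red neighbours, because the
column rules fix the Red sublattice topology to a honeycomb.

Rods, when enabled, sit at the four corners of each UV cone: at the
diagonal midpoints between the UV site and its four off-column Red
neighbours, i.e. at offsets (±*s*/2, ±*f·s*/2) in column coordinates. This
puts them in the inter-column space, four per UV cone. Counting one repeat
unit then gives the predicted reporter ratios used throughout: 2 Red vs 4
non-Red cones (1:2) without rods, and 2 vs 8 (1:4) with them.
`expected_profile_ratio` derives these by counting a generated unit, never
from literals.

`validate_lattice` checks, within a positional tolerance: the alternating
separator rule per column (using the stored column indices and the
projection onto the column axis, so the check is rotation-invariant); four
rods per UV at the expected corner distance; and hexagonality (UV-centred
Red rings and Red honeycomb neighbours equidistant). Interior sites are
those at least half a repeat unit plus one ring from the ragged column
ends the phase shift creates.

## Synthetic imagery

`render_zstack` emulates a confocal stack of a flat-mounted retina. A 2D
en-face pattern per channel — *membrane* (bright on the Voronoi boundaries
between sites, emulating junctional ZO1), *soma* (Gaussian blobs of σ =
0.25·spacing at selected subtypes' sites, emulating a cytoplasmic
reporter), or *glial* (a smooth complement of the photoreceptor profiles,
thicker between columns because the inter-column gap is wider) — is
blurred laterally (psf_sigma, default 0.4 µm), placed at the OLM surface
depth with a Gaussian axial profile (psf_sigma_z, default 1.5 µm,
reflecting the poorer axial resolution of confocal imaging), and corrupted
with additive Gaussian noise clipped at zero. Default voxel spacing is
dz = 1.8 µm (the optical-section interval of the emulated acquisitions)
and dx = dy = 0.2 µm, though tests and pipelines typically render at
0.5 µm pixels to keep images small. Surfaces may be flat, tilted planes,
or spherical caps; a surface leaving the stack raises a geometry error.
The renderer deliberately omits real optics (no Airy PSF, no
photobleaching, no depth-dependent attenuation) and the RPE layer; passing
tests on these renders therefore validates the geometry and algebra of the
pipeline, not its robustness to real microscope artefacts.

`render_glial_band_image` renders the 2D glial distribution at the OLM:
straight bright bands of FWHM `band_width_px` centred midway between
adjacent columns, plus thin closed lamellae (FWHM `lamella_width_px`)
along the Voronoi boundaries of all profiles.

`simulate_ablation_recoil` deforms the photoreceptor positions around a
circular lesion by the affine map R(rotation)·P about the hole centre,
where P stretches by (λx, λy) across and along the columns. The recoil
approaches the full deformation exponentially, by the factor
f(t) = 1 − e^(−t/τ) with τ = 20 min by default — the emulated experiments
show strain increasing and saturating over tens of minutes, but no
functional form is implied by the data, so the exponential is a modelling
choice. Tracked centroids get i.i.d. Gaussian positional jitter; CONTROL
experiments apply identity plus the same jitter. The ground truth —
including the effective (M, b) at each timepoint — is stored with the
experiment, and recovery is always scored against that effective truth.

## OLM surface reconstruction and projection

Each pixel's z-profile is smoothed with a Gaussian kernel
(`z_kernel_sigma`, default 1.5 µm) and the surface depth taken as the
profile's argmax, refined to sub-voxel precision by a three-point
parabolic fit (exact for the log of a Gaussian peak, an excellent
approximation near it). Argmax was preferred over the intensity-weighted
centroid because it ignores basal background; the centroid variant remains
available behind `method="centroid"`. Confidence is the smoothed peak
prominence (peak minus the profile median) normalized to [0, 1]; pixels
below `confidence_floor` (default 0.1) and manually masked pixels (e.g.
radial glial fibers) are filled by linear interpolation from confident
neighbours, and the field is finally smoothed laterally
(`xy_smooth_sigma`, default 1 µm). The kernel widths and interpolation
scheme are free parameters of the method; the defaults recover planes and
spherical caps to well within one z-step in the rendered stacks.

Projection takes, per pixel, the max (default) or mean of the voxels
within ±`band_halfwidth` (default 2 µm) of the surface; the slice nearest
the surface is always included so a narrow band still projects one slice.
The tilt plane is a confidence-weighted least-squares plane through the
surface, and `correct_tilt` rotates tracked centroids so the plane normal
maps onto the optical axis (2D inputs are first lifted onto the plane).
No attempt is made to separate multiple bright surfaces (e.g. RPE vs
OLM); the caller chooses the channel.

## Profile segmentation and classification

Profiles are segmented by seeded watershed on the boundary projection
(boundaries bright). Seeds are an input, mirroring the manual seeding of
the emulated protocol; a local-minima auto-seeder exists for exploration
but is not part of any validated path. An optional field mask delimits
the analysed region — the pipelines use pixels within 0.9× the median
seed nearest-neighbour distance of any seed — so border profiles are not
inflated by empty image margins; an optional exclusion mask marks
irregular glial profiles, which are labeled EXCLUDED when they overlap it
by more than half their area (the criterion for "irregular" is left to
the user, as in the emulated protocol). Mean reporter intensity is
measured per profile mask, and profiles are split POSITIVE/NEGATIVE by
two-cluster k-means on the 1D intensities. Because 1D two-cluster k-means
reduces to a threshold, the default solver enumerates all sorted splits
and minimizes the within-cluster sum of squares exactly (deterministic,
globally optimal); scikit-learn k-means with 10 seeded restarts is
available behind `method="kmeans"`. Ties in intensity are broken by the
stable sort order; all-identical intensities are rejected as
unclassifiable.

## Ridge analysis

The ridge template is the even-order directional derivative of a Gaussian
taken across the candidate ridge, steered analytically from the order+1
Cartesian derivative basis images; per pixel the response is maximized
over 180 orientations at 1° steps. Default order 4 and width 8 px match
the thickness of the rendered inter-column bands; the Gaussian scale is
σ = width/(2√2) so the template's ridge response has FWHM ≈ width. Sampled
even-order derivative kernels leak a small DC response, which is
subtracted explicitly (kernel-sum × smoothed image) so constant images
score zero. Scores are defined only up to a positive scale, so every
threshold in the package is quantile-based — this keeps results
independent of renderer amplitude.

Refinement: non-maximum suppression across the local ridge direction
(bilinear samples at ±1 px), score thresholding at `score_quantile`
(default 0.9), removal of pixels with fewer than `min_neighbors` (2)
surviving 8-neighbours, splitting at junction pixels of degree > 2, and
8-connected component linking. Line pixels are ordered by projection onto
the component's principal axis and carry a doubled-angle circular mean
orientation.

The column direction θ_c comes from the image power spectrum with DC and
a small low-frequency disc (radius 3 bins) excluded: the peak spectral
direction is perpendicular to the columns, so θ_c is that angle + 90°.
Its angular resolution is limited by spectral-bin quantization at the
peak radius (~2° for the image sizes used). A spectrum whose peak is
below `contrast_floor` (50) times the median power is flagged
low-confidence (white noise triggers this; gratings exceed it by orders
of magnitude). Surviving lines deviating more than 30° from θ_c, or
shorter than 20 px, are discarded; re-running the angular filter with
θ_c + 90° is the built-in negative control and should retain almost
nothing on a banded image. Detection is single-scale by design.

## Strain mechanics

The affine fit minimizes Σ‖r_f − M r_0 − b‖² in closed form on
mean-centred coordinates (b from the centroids), which is the exact
normal-equations solution and well-conditioned; collinear point sets are
rejected. The polar decomposition uses P = (MᵀM)^½ via eigendecomposition
and U = M P⁻¹ (pseudo-inverse, flagged, if singular); tests cross-check
against the independent SVD construction. Principal strains are the
eigenvalues of P; the eigenvector circularly closer to the column
direction carries the y-strain (along columns, parallel to the margin),
the other the x-strain, with the deviation angle reported. An isotropic P
leaves the axes indeterminate (deviation NaN) but still returns the equal
strains.

The residual diagnostic is the RMS fit residual divided by the typical
neighbour distance, defined here as the median nearest-neighbour distance
of the pre-ablation points (RMS matches the least-squares objective; the
"typical distance" needed a concrete definition and the median
nearest-neighbour distance is robust and scale-equivariant). Group
statistics pool all post-ablation timepoints per group and compare
ablation vs control with Welch's unequal-variance t-test per axis
(delegated to scipy) and a two-sample Hotelling T² with unpooled
covariances, using Yao's moment-matched F approximation for the p-value —
the variant was an open choice, and the test suite arbitrates it against
a permutation oracle. Only strain ratios are estimated; no forces or
stresses, and no spatially varying (non-affine) deformation fields.

## Problem sizes and determinism

The validated configurations are desk-scale by choice: lattices of 3–5
columns × 4–5 repeat units (72–120 sites), images of roughly 70–350 px a
side, stacks of ~10 slices, 20 tracked points per recoil, 100 Monte-Carlo
seeds for recovery statistics, and 10⁵ permutations for the statistical
oracles. Every stochastic component takes an explicit seed and is
bit-reproducible given (parameters, seed). The reproduction script
(`scripts/acceptance.py`) reruns the full imaging pipeline at these sizes.

## Known limitations

* The lattice is perfectly periodic up to optional Gaussian jitter; no
  pre-column disorder gradient, no dorsal–ventral UV size difference, no
  cell-fate modelling.
* Renderers use Gaussian optics only; robustness to real PSFs, shading
  and bleaching is untested.
* The recoil time course is exponential by assumption; only its
  saturating, monotone character is meaningful.
* Hotelling's p-value is an F approximation; for very small groups trust
  the permutation comparison instead.
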