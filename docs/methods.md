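# Methods

## The measurement model

A bioerosion accretion replicate (BAR) is a block of cleaned, unbored
massive-*Porites* skeleton (nominally 5 × 2 × 1 cm) epoxied to a PVC base
and deployed on a reef. The pre-deployment micro-CT scan (voxel pitch
59.51 µm) records the original carbonate; the post-deployment scan
(64.23 µm) records that carbonate plus everything ~2 years of community
activity added or removed. Four functional-group signals are extracted,
each standardized to the block's initial surface area with the epoxied
base excluded:

| signal       | definition                                            | units      |
|--------------|-------------------------------------------------------|------------|
| accretion    | new carbonate outside the original block outline      | cm³ cm⁻²   |
| macroboring  | void space inside the remaining block (tunnels >100 µm) | cm³ cm⁻² |
| grazing      | loss of external block volume                          | cm³ cm⁻²   |
| microboring  | bulk density loss of non-bored, non-grazed carbonate   | g cm⁻²     |

Microboring (boreholes <100 µm across) cannot be resolved at these
pitches; it appears as a diffuse density decrease, measured as
(mean ρ_pre − mean ρ_post) × V_remaining after phantom-based densitometry
(linear regression of known density on mean attenuation, one curve per
scan session). Tunnels near 100–130 µm sit at the resolution limit of the
64.23 µm post scan and partially leak from the macroboring term into the
microboring term; the pipeline reproduces this behaviour rather than
correcting it, since the field measurement has the same property. The
microboring estimate is signed: an apparent density *gain* (secondary
precipitation, abiotic effects) is reported as negative, with a clamp
option.

Assumptions: the block is rigid (registration is Euler-rigid, no
deformation); the pre-scan block is organic-free and unbored (blocks are
NaOH-cleaned before the initial scan); density maps linearly to
attenuation over the relevant range; scan noise is additive and
unstructured (reconstruction artefacts such as rings or beam hardening
are assumed corrected upstream).

## Registration and partition

The post scan is aligned to the pre-scan frame by maximizing normalized
cross-correlation between lightly blurred attenuation volumes over an
Euler transform (SimpleITK, multi-resolution pyramid, full deterministic
metric sampling, geometric initialization with a moments fallback).
Correlation is invariant to affine intensity maps, so the two scan
sessions need no mutual intensity calibration; the skeleton's internal
density texture anchors the alignment. Because the surface itself changes
between scans (that change is the signal), a second pass re-registers
with all changed voxels — the first-pass accretion/macroboring/grazing
labels dilated by 3 voxels — excluded from the metric, removing their
pull on the alignment. On simulated pairs this recovers imposed offsets
to better than 0.2 voxel.

The *solid hull* (block plus internal voids) is built from the carbonate
mask by (1) morphological closing with a ball of physical radius 400 µm
(two exact Euclidean distance transforms; the array is padded so the
dilated band never touches the grid edge), (2) classifying each connected
closing addition by geodesic depth from the open exterior through
non-solid space — additions reaching deeper than 2× the closing radius
are sealed tunnel fills, shallow ones are corner fillets of wide surface
depressions and are discarded (grown back only along tunnel throats), and
(3) flood-filling enclosed cavities. Consequences to know about: tunnels
shorter than ~2× the closing radius (0.8 mm) are treated as surface
relief, and surface scars narrower than ~2× the closing radius are
bridged and counted as borings. 400 µm covers annelid-scale apertures
while staying well below the width of realistic grazing scars.

Thresholding uses a two-mode rule: background and carbonate modes are
estimated from the Otsu split, and the cut is placed 60% of the way from
background to carbonate. A midpoint cut systematically classifies
partial-volume voxels in concave corners (grazing-scar perimeters) as
solid; 0.6 trims them while staying clear of tunnel walls (by 0.7 the
cut visibly erodes tunnel interiors). Plain Otsu and fixed thresholds
remain available; Otsu falls back with a warning when the histogram is
effectively unimodal (between-class variance fraction < 0.75).

Resampling between pitches leaves sub-voxel partial-volume "films" along
block faces that a one-sided label (accretion counts only outward
excursions, grazed only inward) would accumulate as bias. The partition
therefore removes change-label components with no interior thicker than
`min_feature_voxels` (default 1): an erosion finds feature cores and the
raw label is kept only near surviving cores, so genuine features ≥ 3
voxels across keep their full shape while films vanish. Voxels freed
inside the pre hull return to `original_remaining`, keeping the
conservation identity |H_pre| = remaining + macroboring + grazed exact.

Mean densities for the microboring term are taken over the remaining
region eroded by 2 voxels (partial-volume boundary voxels would bias the
pre/post difference), while the volume multiplier uses the full region.

Surface areas are marching-cubes isosurface areas of the Gaussian-
smoothed mask (σ = 1.5 voxels; a raw binary level set overestimates
curved areas by ~10% through staircasing). Facets whose centroids lie on
the base plane are dropped to exclude the epoxied underside. CT metrics
are standardized to the *initial* (pre-scan) area; incubation rates to
the *final* (post-scan) area — two deliberately different denominators.

Coordinates are voxel-centred, 0-based, physical = origin + index·pitch;
volumes are voxel count × (pitch_µm·10⁻⁴)³ cm³.

## Incubation chemistry

Closed-chamber runs (0.640 l, light ~80 min, dark ~140 min) give
calcification by the alkalinity anomaly, G = −(ΔA_T/2)·m_sw/(SA·Δt),
with ΔA_T = final − initial after subtracting the mean of the paired
blank chambers at the same phase and pH level (the strictest reading of
the blank protocol). Seawater mass is chamber volume × 1.023 kg l⁻¹
(29 °C, S 35; configurable) — A_T is per kilogram while chambers are
measured in litres. O₂ fluxes are ΔO₂·1000·V/(SA·Δt) µg cm⁻² min⁻¹; dark
respiration is reported as positive consumption with the signed flux
retained. The 24-h mean weights light and dark rates 11 h : 13 h.

The carbonate-system solver works entirely on the total pH scale with
K₁/K₂ from Lueker et al. (2000), K_B Dickson (1990), K_W Millero (1995),
K₀ Weiss (1974), aragonite K_sp Mucci (1983), borate Uppström (1974) and
calcium Riley & Tongudai (1967); nutrient and fluoride alkalinity are
neglected (open-ocean surface conditions). pH is found by bracketed
root-solving of the alkalinity balance in [3, 12]; the test suite checks
it against an algebraically independent polynomial-root formulation of
the same equilibrium system and enforces the expected monotonicities.

## Statistics

Responses are regressed on pH with single-predictor GLMs: Gaussian with
identity link (ordinary least squares; verified against the
normal-equations closed form to 10⁻¹⁰) for responses spanning both signs,
Gamma with log link (IRLS; a numerically perfect fit whose deviance
reaches ~0 is accepted as converged) for strictly positive skewed
metrics. Which family applies to which response is a per-response
configuration with Gaussian default — the choice is data-dependent and
deliberately not hard-wired. Responses containing non-positive values are
shifted by −min(y) + 10⁻³·range(y) before a Gamma fit and predictions
back-shifted.

Site contrasts use the two-sample Wilcoxon rank-sum test (exact
enumeration when both groups have ≤8 untied values, normal approximation
otherwise; the reported W is the Mann–Whitney U of the first sample, as R
reports it) for the volumetric metrics and Welch's unequal-variance
t-test for microboring. All tests are two-sided and no multiple-testing
correction is applied. One published microboring contrast of this kind
prints t = −5.245, d.f. = 53.229 together with p = 0.133; those three
numbers are mutually inconsistent (that t at ~53 d.f. implies
p ≪ 0.001), so this implementation always computes p from (t, d.f.)
rather than matching any printed value.

The net accretion→dissolution switch point pools 24-h calcification
across sites and fits a Gaussian-identity GLM (the responses span both
signs, ruling out an unshifted Gamma; the crossing in the observed data
is visibly linear); the crossing is −intercept/slope, with a
case-resampling percentile bootstrap CI (≥1000 replicates,
seed-reproducible; the interval is widened to include the point estimate
in the rare replicate-skew case). If all responses share one sign the
crossing is reported as an error stating the sign, not extrapolated.

## The synthetic generator

`synthetic_data` fabricates the study's inputs with exact voxel-counted
truth recorded on the pre-scan grid before noise: a carbonate block
(default 5 × 2 × 1 cm, bulk density 1.4 g cm⁻³ — typical massive
*Porites*) with slab-shaped accretion patches on exposed faces (the
underside is epoxied, so accretion there is disallowed), capsule-shaped
tunnels entering from faces (annelid-like morphology; radius must exceed
50 µm, below which excavation is microboring by definition), slab grazing
scars, a uniform fractional density drop on remaining carbonate, a rigid
offset (applied before resampling to the post pitch; the post field of
view is padded so the offset never clips the block), trilinear
resampling, and additive Gaussian scanner noise (applied after
resampling — noise belongs to the scanner, not the block).

The block interior carries a smooth density texture (Gaussian random
field, σ = 5 voxels, sd 7 attenuation units ≈ 5% of the carbonate level,
clipped at ±2.5 sd) because real skeleton is far from uniform and that
structure is what anchors registration; the clip keeps excursions from
mimicking resolvable porosity, which the cleaned deployed cores by
premise do not have. What the generator does *not* emulate: real
pore-network microstructure, CT reconstruction artefacts (rings, beam
hardening, cupping), partial organic remains, irregular biological
morphologies (curved multi-branch tunnels, bite-shaped scars), or
spatially varying noise. Passing recovery tests therefore demonstrate
the pipeline's set algebra, registration and calibration under
controlled geometry — not robustness to every property of field scans.

Batch simulations (`make_batch_specs`) and the analysis/test runs use a
reduced block of ~1.2 × 0.6 × 0.36 cm at the true scan pitches
(59.51/64.23 µm), keeping every feature's size in voxels — the quantity
that controls partial-volume behaviour — realistic while grids stay at
~2 M voxels; offsets are up to 5 voxels translation and ±1.5° rotation
per axis. Incubation and pH-response generators default to rate scales
matching the published scatter (24-h calcification within roughly
±0.2 µmol cm⁻² h⁻¹, residual sd 0.08, crossing at pH 7.80, chamber pH
7.4–8.1).

## Known limitations

* The closing radius is a single scale separating "aperture" from
  "scar"; communities with large-aperture borers (clionaid sponges) or
  narrow grazing traces would need it retuned, and the two error modes
  (short tunnels dropped, narrow scars bridged) trade off against each
  other.
* Microboring inherits any secular scanner drift between sessions that
  phantom calibration fails to remove.
* The carbonate solver omits nutrient alkalinity; in reef pore waters or
  eutrophic settings the pH solve would bias accordingly.
* Registration assumes rigidity; a block that fractured or lost its base
  during deployment violates it.
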