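# Methods

## Data model and conventions

All volumes are rank-3 arrays in `(z, y, x)` order with 0-based indices; `z`
is the vertical tooth axis (cervical at low z, occlusal at high z), `x` the
buccal–palatal direction, `y` the contact–contact direction. Voxel pitch is
isotropic and carried in micrometres; anisotropic input is rejected rather
than silently resampled. Attenuation is stored as unsigned 16-bit, labels as
unsigned 8-bit with the fixed coding `0 = air, 1 = enamel, 2 = dentin,
3 = crack`. The pulp cavity is radiolucent and carries the *air* code — the
four-class scheme deliberately does not distinguish them, which is exactly
what makes crack/pulp separation the hard part of the classification.

Slab intervals are half-open; when the tooth's vertical extent is not
divisible by three, remainder slices go to the lower (cervical-first) slabs,
so an extent of 10 splits (4, 3, 3). This rule is arbitrary but fixed and
documented.

## Synthetic tooth phantoms

The phantom emulates a premolar crown in a desk-scale data-cube. Defaults
(all overridable in `PhantomSpec`):

| parameter | default | rationale |
|---|---|---|
| grid, pitch | 128³ voxels at 20 µm | desk-scale stand-in for ~2000³ at 5 µm scans; the analysis chain is resolution-agnostic |
| crown | half-ellipsoid, height 2.16 mm, semi-axes 1.15 / 0.95 mm (x / y) | unequal radii give the convex-buccal / flatter-contact asymmetry that sector detection needs |
| enamel thickness | 0.30 mm cervical → 0.60 mm cuspal, linear in z | the anatomical cervical-to-cusp gradient, scaled to the small crown; kept within the 0.3–3.0 mm validity band |
| pulp | ellipsoid, 0.35 of the crown radii, fully enclosed by dentin | root canals are outside the imaged crown |
| densities | enamel U(2.61, 2.77), dentin U(1.79, 2.12) g/cm³, one draw per phantom | measured tissue-density ranges; per-phantom draws give realistic scanner-to-scanner contrast variation |
| grey mapping | linear in density, mean enamel ≈ 60% of the 16-bit range | only the ordering enamel > dentin > (pulp ≈ crack ≈ air ≈ 0) matters downstream |
| noise | additive Gaussian, σ = 800 grey units (≈2% of range), clipped | plausible for long-exposure absorption scans; the source studies do not quantify their noise, so this is a fixed choice, not a calibration |
| artifacts | cylindrical void and occlusal ray pattern, off by default | lets artifact-robustness be tested explicitly |

**Crack network.** Primary cracks are planar slabs that all contain the
tooth axis — radial planes in two nearly perpendicular azimuth families
(±7° jitter), yielding the star topology. They span the full cross-section
and extend downward from just below the cusp over an *occlusal band* whose
depth is calibrated (log–log secant iteration, ≤12 evaluations) until the
labelled network occupies the requested `target_volume_fraction` of the
hard tissue (default 2%); if the band reaches the whole crown the slab
width grows instead, and an unreachable target raises rather than silently
under-delivering. Anchoring the band at the occlusal surface keeps the
network connected at any fraction (the planes always cross at the axis
above the pulp chamber) and mirrors where occlusal-load cracks actually
concentrate. Isolated cracks are small planar disks (radius 4–10 voxels)
with random orientation, biased toward the outer surface, widths drawn
log-uniformly from 0.3–30 µm.

**Partial volume.** A voxel is modelled as a unit interval along the crack
normal; crack occupancy is the overlap of that interval with the slab, so a
crack of width pitch/2 through a voxel centre dims it to exactly half the
host grey. A voxel is ground-truth *crack* only when occupancy ≥ ½ —
sub-voxel cracks dim tissue without being labelled, exactly the ambiguity a
real scan presents.

**Reproducibility.** Geometry is deterministic given the spec; crack
placement and densities/noise consume independent child RNG streams of the
master seed, so the crack-free twin of any phantom (`nocrack_spec`) has
bit-identical tissue geometry and rendering — this is what the fill-in
validation compares against. `PhantomTruth` carries the labels, the
crack-free labels, the plane normals, the connected-network mask, and its
realised volume fraction.

**What the phantom does not emulate:** beam hardening, ring/cone-beam
artifacts, detector blur, enamel rod microstructure and lamellae, curved or
branching cracks, roots and periodontium. Passing tests on phantoms
therefore demonstrates the correctness of the processing chain under the
stated image-formation model, not classifier performance on real scans.

## Slice segmentation

Slices perpendicular to a chosen axis are covered by overlapping tiles
(default 512 px / stride 256 at full scale; 64 px in the desk-scale
experiments), each tile classified per pixel, and the per-tile
class-probability maps averaged over overlaps before the argmax — averaging
is order-independent, and for any backend that is a pure per-pixel function
the tiling is provably lossless (a property test asserts it).

**Reference CNN.** A small fully-convolutional encoder–decoder in plain
numpy: two 3×3 convolutions at full resolution, 2× average pooling, a 3×3
and a dilated (rate-2) 3×3 convolution as multi-scale context, nearest
upsampling with a skip concatenation back to full resolution, a 3×3
decoder convolution, and a 1×1 head that also sees the raw input channels.
The input skip matters: class boundaries in CT are defined by the pixel's
own grey value, while the ~25 px receptive field of the deep features
supplies the context that separates a thin dark crack from the equally dark
pulp or background. Width 12 channels (~13k parameters). Training follows
the standard recipe — Adam, batch 5, categorical cross-entropy, random
contrast (±20%), flips, and k·90° rotations, all seeded — and is
bit-deterministic on one CPU. At this scale a from-scratch network needs a
larger learning rate than a fine-tuned pretrained backbone; the validation
configuration uses 1.5 × 10⁻³ cosine-annealed to zero over 25 epochs
(`TrainConfig` defaults remain 10⁻⁵/50 epochs/constant for the full-scale
recipe). Training tiles are drawn from four phantoms so the classifier sees
the realistic spread of tissue densities; validation tiles come from a
fifth phantom it never saw. This run reaches ≥ 99.5% held-out pixel
accuracy in about two minutes.

**Rule-based oracle.** A deterministic classifier used as an independent
cross-check. Two thresholds (derived by 3-class multi-Otsu on a 256-bin
histogram unless given) split air / dentin / enamel. Cracks are recovered
by local contrast: tissue is binary-closed with a disk (radius 3 px) so
surface-breaking cracks do not open the outline, holes are filled, and the
*greylevel closing* of the image estimates the host-tissue grey across any
thin dark structure; a pixel darker than half its host is a crack
candidate — the exact inverse of the partial-volume rendering rule, valid
in both enamel and dentin. Conversely, a pixel still at least half its
host's grey takes the host's class, which prevents partially dimmed enamel
from masquerading as dentin. Wide dark regions are excluded pixelwise:
candidates within 5 px of a dark core whose 2D inscribed radius exceeds
5 px (the pulp, artifact voids) are classed air, so thin crack arms stay
crack even where they meet the pulp rim.

## Consensus and fill-in

A voxel is crack iff ≥ 2 of the 3 per-axis labellings say crack (checked
against exhaustive enumeration of all 64 code triples). Remaining voxels
take the majority non-crack vote; ties fall to the z label, then y, then x
(z slices are the primary orientation; the order is arbitrary but fixed).
The degenerate off-mask all-crack triple, impossible under the vote itself,
maps to dentin.

Fill-in works per z-slice on the categorical map (nearest-label
reassignment under the dilated crack mask, 3×3 square at the default radius
1) rather than greyscale inpainting: it is well defined on categories,
exactly idempotent, and cannot fabricate tissue into air (masked air pixels
are untouched). A slice whose tissue is entirely masked raises. On default
phantoms ≥ 95% of filled voxels match the crack-free twin's labels; the
mismatches sit where cracks straddle the enamel–dentin junction.

## Geometry

*Resampling* is block-mean with an integer pitch ratio (non-integer ratios
raise; trailing partial blocks are cropped), conserving mean grey to
rounding — chosen over interpolation because it preserves thin-crack
contrast and is exactly testable. *Alignment* maps the tooth mask's largest
principal-moment axis to z and the second to x via the coordinate
covariance eigenvectors, with signs chosen nearest the identity; collinear
masks raise. *Sectors*: on the middle slice of each slab, the boundary
contour is periodically smoothed, its curvature computed and smoothed, and
the four convex-to-flat transitions located as the crossings of the
curvature through the mid-level between its 5th and 95th percentiles (a
circular majority filter removes threshold chatter). The two chords joining
opposite transitions split the slice into four sectors named by the
cardinal extreme they contain (+x palatal, −x buccal, +y contact right,
−y contact left), propagated through the slab. If the curvature is
near-constant (circular section) or the crossings are not exactly four,
the partition falls back to centroid-anchored ±45° quadrants and flags the
slab. Chords are computed once per slab — stabler than per-slice and the
reference figures draw them per slab.

## Morphometry

Connected components use 26-connectivity by default (thin oblique sheets
fragment under 6-connectivity), with deterministic ids ordered by
decreasing size then lexicographically smallest voxel, and are checked
against an independent flood-fill oracle. The default size filter drops
components under 27 voxels (one 3³ blob at working scale). Volume fractions
are taken against hard tissue + crack, excluding the pulp — the natural
reading of "volume of a tooth" for a 4-class labelling with no pulp class.

*Local width* is twice the Euclidean distance transform minus one voxel
(centre-to-boundary correction, exact for axis-aligned slabs), sampled on
the skeletonized medial surface and propagated to every mask voxel from its
nearest medial voxel; estimates at or below one pitch are reported as the
pitch and flagged sub-resolution. *Planarity* is (λ₂−λ₃)/λ₁ of the
component's coordinate covariance (≈1 for sheets, ≈0 for threads); the
sheet normal is the λ₃ eigenvector. *Orientation modes* come from the
structure tensor of the Gaussian-smoothed mask (σ = 2 voxels): per crack
voxel the local plane normal is the tensor's **largest**-eigenvalue
eigenvector — for a thin sheet the intensity varies fastest across it, so
the principal direction *is* the normal, while the smallest-eigenvalue
direction lies ambiguously in the plane. Normals are folded to a
hemisphere, binned on an 18 × 5° inclination × 36 × 10° azimuth grid
(648 bins), and the two strongest modes at least 25° apart are refined by
sign-aligned averaging of member normals within 15°, giving sub-degree mode
precision from a coarse histogram.

## Fracture mechanics

All formulas are evaluated in SI; fracture toughness is accepted in
MPa·√m and converted. The module implements σ_max = 2σ√(l_c/l_ρ),
σ_th = √(γE/a₀) with the E/2π approximation, σ_c = K_Ic/√(πl) for a linear
crack, the elliptical variant σ_c = (π/2)·K_Ic/√(πl) (the criterion
K_Ic = (2/π)σ_c√(πl) inverted as written), the Griffith form
σ_c = √(2γE/(πl)), bite pressure m·g/A (g = 9.81, with g = 10 for
order-of-magnitude figures), and the pressure/σ_c percentage. One numerical
wrinkle is worth flagging: for K_Ic = 1.24 MPa·√m and l = 2 µm the formula
gives σ_c ≈ 0.49 GPa, an order of magnitude below the 4.9 GPa figure often
quoted for this case; the module computes the formula as written, and the
canonical "bite is 0.2% of σ_c" ratio takes the quoted 4.9 GPa as an
explicit input (10⁷ Pa / 4.9 GPa = 0.204%). Surface energy γ and the
interplanar spacing a₀ have no established enamel values and remain user
inputs.

## Problem sizes and runtime

The validation experiments run on 128³ phantoms (≈2.1 M voxels): full
three-axis segmentation + voting + components takes ~2 s with the rule
backend; CNN training on 240 × 64² tiles takes ~2 minutes single-threaded;
the whole test suite runs in ~3 minutes. These sizes were chosen as the
smallest at which every structural feature (pulp, both plane families,
partial-volume cracks, 12 non-empty regions) is well resolved.

## Known limitations

- The rule-based oracle's crack rule assumes crack grey ≈ host·(1−occupancy);
  real scans add blur and beam hardening it does not model.
- Width estimates below one voxel are censored at the pitch; real 0.3–5 µm
  cracks at 10–20 µm voxels are all in this regime (they are detectable but
  not measurable, which is a physics limit, not a software one).
- Sector detection assumes a single convex-ish cross-section per slab;
  multi-rooted or heavily damaged teeth would hit the quadrant fallback.
- `align_axes` relies on a clear principal-moment gap; a crown as wide as it
  is tall can have near-degenerate moments, in which case alignment should
  be skipped (the pipeline's default).
- The CNN is a desk-scale reference model (~13k parameters), adequate for
  the phantom image model; it is not expected to transfer to real scans
  without retraining.
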