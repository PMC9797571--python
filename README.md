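# crackct

Micro-CT analysis of tooth microcracks: per-slice voxel classification,
three-axis consensus voting, and 3D crack-network morphometry, exercised end
to end on synthetic tooth phantoms with known ground truth.

## The problem

X-ray micro-computed tomography can image an extracted tooth at micrometre
resolution as a 16-bit attenuation data-cube in which enamel (bright), dentin
(darker), the pulp cavity (black), and microcracks (thin black sheets,
0.3–30 µm across) are all visible. Turning such a volume into a quantitative
description of the crack network takes a chain of steps: classify every voxel
into {air, enamel, dentin, crack}; do it three times on slices perpendicular
to x, y, and z, and call a voxel *crack* only when at least two of the three
slice classifiers agree; restore the crack-free tooth by filling the (dilated)
crack mask with the nearest surrounding tissue label; isolate connected crack
groups in 3D, filter the small ones, and measure what remains — volume
fraction of the tooth, local width (the local-thickness convention: twice the
distance transform on the medial surface), sheet-vs-thread shape (eigenvalue
planarity), and dominant crack-plane orientations (structure-tensor normals);
and report results per anatomical region, splitting the crown into three
horizontal slabs (cervical/middle/occlusal thirds) × four angular sectors
(buccal, contact right, palatal, contact left) — 12 slab-sectors.

`crackct` implements that whole chain for researchers in dental biomechanics
and hard-tissue imaging. Because raw tooth scans are rarely shareable, the
package includes a first-class phantom generator: a half-ellipsoid enamel
shell over a dentin core and pulp chamber, carved by a connected star-shaped
network of radial crack planes (two nearly perpendicular families) calibrated
to a target volume fraction, plus isolated near-surface cracks, rendered with
partial-volume physics (a crack thinner than a voxel dims the voxel in
proportion), Gaussian noise, and optional scan artifacts. Every stage is
validated against this known truth.

Slice classification is pluggable: a small fully-convolutional
encoder–decoder CNN (pure numpy, trained with Adam on categorical
cross-entropy with contrast/flip/rotation augmentation) and a deterministic
rule-based greylevel classifier that serves as an independent oracle. A
`fracture` module collects the closed-form fracture-mechanics estimates that
put measured crack sizes in mechanical context:

- stress concentration σ_max = 2σ√(l_c/l_ρ) at an elliptical flaw,
- theoretical strength σ_th = √(γE/a₀) ≈ E/2π,
- Irwin/Griffith critical stresses σ_c = K_Ic/√(πl) (elliptical: ×π/2;
  energy balance: √(2γE/πl)) with enamel's anisotropic toughness
  K_Ic⊥ = 1.24, K_Ic∥ = 0.70 MPa·√m,
- bite pressure and its ratio to σ_c.

## Worked example

```python
import numpy as np
from crackct.phantom import PhantomSpec, generate_phantom
from crackct.segmentation import rule_based_oracle, segment_axis
from crackct.consensus import vote_crack, resolve_noncrack
from crackct.morphometry import (connected_components, filter_by_size,
                                 largest_k, volume_fraction, orientation_modes,
                                 local_width, tooth_mask_from_labels)
from crackct.geometry import slab_sector_regions

spec = PhantomSpec(rng_seed=42)          # 128^3 cube, 20 um pitch, ~2% network
grey, truth = generate_phantom(spec)
backend = rule_based_oracle(grey)        # thresholds from the grey histogram
labels = {ax: segment_axis(grey, backend, ax) for ax in "xyz"}
crack = vote_crack(labels["x"], labels["y"], labels["z"])
final = resolve_noncrack(labels["x"], labels["y"], labels["z"], crack)

comps = filter_by_size(connected_components(final.data == 3), min_voxels=27)
tooth = tooth_mask_from_labels(final)
print(f"crack voxels voted: {int(crack.sum())}")
for c in largest_k(comps, 3):
    print(f"component {c.component_id}: {c.voxel_count} voxels, "
          f"{100 * volume_fraction(c, tooth):.2f}% of the tooth")
modes = orientation_modes(truth.network_mask)
print(f"main crack-plane families meet at {modes.inter_mode_angle_deg:.1f} deg")
width, subres = local_width(final.data == 3, spec.voxel_pitch_um)
print(f"median crack width: {np.nanmedian(width[final.data == 3]):.0f} um "
      f"({100 * subres[final.data == 3].mean():.0f}% at or below one voxel)")
print(f"slab-sector regions: {len(slab_sector_regions(tooth).region_counts())}")
```

prints

```
crack voxels voted: 10862
component 1: 10845 voxels, 1.88% of the tooth
main crack-plane families meet at 87.9 deg
median crack width: 20 um (85% at or below one voxel)
slab-sector regions: 12
```

The phantom was built with a connected network occupying 2% of the hard
tissue; the pipeline recovers a single dominant component at 1.88% (within
the method's few-percent bias from partial-volume crack edges). The two
radial plane families were placed nearly perpendicular, and the
structure-tensor orientation analysis returns 87.9°. Most crack voxels sit
at or below one voxel pitch in width, so their width estimates are flagged
as resolution-limited — the expected regime for real microcracks at this
voxel size.

The same chain is available from the shell:

```bash
crackct run --seed 42 --out runs/demo       # full pipeline + provenance JSON
crackct phantom --size 128 --seed 1 --out-grey g.tif --out-labels l.tif
crackct segment --volume g.tif --axis all --out seg.tif
crackct fracture --formula bite             # 1e7 Pa
```

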