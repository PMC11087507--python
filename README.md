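# orgcontact

Quantitative morphometry and contact-site analysis for instance-segmented
hepatocyte organelles in volume electron microscopy.

Liver FIB-SEM volumes at isotropic 8 nm voxel pitch resolve every
mitochondrion, the ER network, lipid droplets and nuclei of whole
hepatocytes. `orgcontact` turns such instance-segmented label volumes (and
2D TEM masks, and zonation line profiles) into the quantities that describe
organelle architecture and its remodeling:

- **3D morphometry** — per-mitochondrion volume V (µm³), surface area SA
  (µm²), Wadell sphericity ψ = π¹ᐟ³(6V)²ᐟ³/SA, and the mitochondrial
  complexity index **MCI² = SA³/(16π²V²)** (0.716 for a sphere, higher for
  branched/flattened shapes), plus size/boundary filtering and the bivariate
  (MCI², V) classification of large complex mitochondria.
- **ER–mitochondria contact mapping** — the single-voxel mitochondrial
  outer shell (object minus its one-step erosion) intersected with the
  partner mask dilated one voxel at a time. Exclusive distance bands at 8 nm
  pitch: 0–24 nm (3 dilations; tight smooth-ER contacts, MAMs) and 25–56 nm
  (7 dilations; rough ER sheet apposition), plus voxel-by-voxel distance
  profiles and ER-sheet-restricted and lipid-droplet variants.
- **Spatial statistics** — mitochondrion-to-nucleus distances with the
  binucleate midpoint rule, absolute (µm) and relative (per-cell scaled).
- **2D TEM analysis** — Euclidean distance maps from the mitochondrion
  perimeter, ER coverage in 0–24 / 25–80 nm bands, area/roundness/aspect
  ratio.
- **Zonation profiles** — central-vein→portal-vein intensity lines
  percentized, binned at 5%, summarized at the bin-10 (pericentral) and
  bin-90 (periportal) readouts.
- **Inference** — permutation tests (default n = 10⁵, pooling objects
  within condition groups, object- or cell-level relabeling) and percentile
  bootstrap confidence intervals.
- **Synthetic scenes** — a generator of label volumes with analytic ground
  truth (digital balls/ellipsoids/capsules, ER shells at exact city-block
  gaps, TEM discs/arcs, zonation ramps) so every stage is testable against
  brute-force oracles.

## Worked example

Generate a cell scene with one mitochondrion (digital ball, r = 8 voxels)
wrapped by an ER sheet at a 3-voxel gap, then quantify it:

```python
from orgcontact import synthetic, morphometry3d, contact3d

spec = synthetic.SceneSpec(
    shape=(48, 48, 48),
    mitochondria=[synthetic.MitoSpec("ball", center=(24, 24, 18), radius=8)],
    er_structures=[synthetic.ERSpec("wrapped_shell", attached_to=1, gap_voxels=3)],
)
mito, er, ld, nuc, manifest = synthetic.generate_scene(spec)

metrics = morphometry3d.instance_metrics(mito, sa_method="mesh")
print(metrics[["volume_um3", "sphericity", "mci2"]].round(4).to_string(index=False))
#  volume_um3  sphericity    mci2
#      0.0011      0.9901   0.738

contacts = contact3d.band_contact(mito, er)
print(contacts.to_string(index=False))
#  mito_id  shell_voxels  contact_voxels_0_24nm  fraction_0_24nm  contact_voxels_25_56nm  fraction_25_56nm
#        1           606                      0              0.0                     606               1.0

profile = contact3d.distance_profile(mito, er, max_nm=56)
print(profile.new_counts, profile.modal_step())
# [  0   0   0 606   0   0   0] 4
```

The ball is nearly spherical (ψ = 0.99, MCI² ≈ 0.74, close to the spherical
limit 9/(4π) ≈ 0.716). The ER sits 3 empty voxels away, so no shell voxel is
within 24 nm, the entire shell is contacted within 25–56 nm, and the
voxel-by-voxel profile first (and only) touches the shell at dilation step 4
= 32 nm — exactly the programmed gap + 1.

The same pipeline runs from the shell on real label volumes
(`orgcontact synth|morpho|contact|spatial|tem2d|zonation|stats|run`); see
`orgcontact --help`.

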