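# Methods

This note documents the models, conventions and numerical choices behind
`orgcontact`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Data model and conventions

Label volumes are 3D integer grids in `(z, y, x)` axis order, 0-based, with
0 = background and positive integers as object instances; each carries a
physical voxel size in nanometres per axis (default isotropic 8 nm, the
FIB-SEM pitch the pipeline was designed around). Supported containers are
multi-page TIFF / OME-TIFF (physical size honored from OME metadata; an
explicit argument overrides it with a warning) and HDF5 with a
`voxel_size_nm` or ImageJ-style `element_size_um` attribute. Label dtypes up
to 32 bits are accepted; larger values are rejected. Every table written by
the package gets a JSON sidecar with voxel size, software version and seed.

## 3D morphometry

Connected components use 26-connectivity by default ("full connectivity" in
x, y, z; 6 and 18 available) and are relabeled deterministically by
first-voxel raster order. Size filters remove instances below a voxel-count
threshold; the per-dataset proof-reading thresholds of the source
segmentations ship as named presets (`MIN_VOXEL_PRESETS`), with 0 (no
filtering) as the default. Filtering preserves surviving label ids so
objects stay traceable across stages; `relabel_sequential_scan_order` is
available when compact ids are needed.

Volume is voxel count × voxel volume. Two surface-area estimators:

- **mesh** (default): marching cubes at level 0.5 on the zero-padded binary
  mask, followed by Taubin smoothing (λ = 0.5, µ = −0.53, 50 iterations).
  The raw binary isosurface is a staircase that overestimates smooth
  surfaces by ≈ 9% (digital-ball sphericity plateaus near 0.92); Taubin's
  two-step filter removes the staircase with negligible shrinkage, bringing
  digital-ball SA within ~0.5% of 4πr² at r = 40 voxels while keeping
  ψ ≤ 1. Gaussian pre-smoothing of the mask was rejected: it biases SA low
  for small objects (pushing ψ above 1) and can delete 1-voxel-thick
  structures entirely.
- **voxel_face**: exposed voxel faces weighted by physical face area.
  Exactly additive and robust, but inflates SA of smooth bodies up to
  ~1.5×, deflating ψ and inflating MCI² accordingly. Always ≥ the mesh SA.

Sphericity uses Wadell's definition ψ = π¹ᐟ³(6V)²ᐟ³/SA (the standard form;
bounded by 1 with mesh SA). MCI² = SA³/(16π²V²); both are scale-invariant.
The bivariate "large complex" classifier counts instances with MCI² > 5 and
V > 3 µm³ by default. Because published ψ/MCI² values depend on the SA
estimator of the analysis software used, cross-study comparison may require
estimator calibration; both estimators are exposed for that reason.

## Contact quantification (3D)

The mitochondrial outer shell is the object minus its one-step erosion;
out-of-volume is background, so faces on the volume border are shell. The
partner mask (ER, ER sheets, LD) is dilated one voxel per iteration with a
face-connected (6-neighbor) cross, realizing discrete city-block distance:
k iterations reach exactly the voxels within distance k. Distance bands are
converted to iterations as ⌊hi_nm / pitch⌋ (24 nm → 3, 56 nm → 7,
80 nm → 10 at 8 nm pitch; non-multiples are floored with a warning). Band
contact voxels are dilated-partner ∩ shell minus voxels claimed by inner
bands, so 0–24 and 25–56 nm surfaces are disjoint by construction;
fractions divide by the per-instance shell size. The voxel-by-voxel profile
records newly contacted shell voxels per step, deleting claimed voxels so
each is attributed once; its cumulative count at step k equals the 0–(k ×
pitch) band total exactly.

Numerical/semantic choices:

- Dilation is masked to background + shell and never proceeds through
  mitochondrial interiors: contact is by exterior approach only, and the
  effective metric is the *geodesic* city-block distance around objects.
- Partner voxels lying on the shell itself count at distance 0 in the
  innermost band; partner voxels inside an interior (segmentation
  conflicts) are logged and contribute only through their shell overlap.
- A partner voxel may contribute to several mitochondria; accounting is per
  shell instance.
- Two structuring-element modes: `volume3d` (default, isotropic 3D cross)
  and `planewise_xy` (2D cross per z-slice), the latter reproducing
  strictly slice-wise morphology of commercial tools. Which of the two the
  original renderings used is not asserted; both are first-class.
- Lipid-droplet "contact prevalence" counts mitochondria with ≥ 1 shell
  voxel within the innermost band by default; the threshold (voxels or
  fraction) is a parameter because no canonical criterion exists.

## Spatial distribution

The nuclear reference is the nucleus centroid, or the midpoint of the two
nuclear centroids in binucleate cells (consistency across ploidy); 0 or > 2
nuclei per cell is an error. Mitochondrion positions are unweighted voxel
centroids. Absolute distances are Euclidean in µm; relative distances
divide by the per-cell maximum, giving [0, 1] with exactly one object at 1.
The 25 µm saturation seen in color-mapped renderings is a visualization
parameter and never applied to metric values.

## 2D TEM analysis

The 2D path deliberately uses the exact Euclidean distance transform (the
2D workflow is defined as a distance map, unlike the discrete dilation in
3D; the metric difference is intentional and documented). Band edges are
inclusive on the upper bound: 0–24 means d ≤ 24 nm, 25–80 means
24 < d ≤ 80 nm, matching the 3-/10-dilation semantics. Coverage is
reported per perimeter pixel (fraction of boundary pixels whose nearest ER
pixel falls in the band) — the default statistic — with the per-ER-pixel
distance distribution returned alongside, since either reading of
"perimeter coverage" is defensible. Shape metrics use second-moment fitted
ellipses: AR = major/minor, roundness = 4·area/(π·major²).

## Zonation profiles

Positions along a hand-drawn central-vein→portal-vein line are affinely
mapped to percent (0 = CV edge, 100 = PP edge; reverse-drawn profiles are
flagged and flipped), binned at width 5 into [k·w, (k+1)·w) with the last
bin closed, and averaged per bin. Bin labels are lower edges, so "bin 10" =
[10, 15) and "bin 90" = [90, 95); summaries at those two bins represent the
pericentral and periportal zones. A center-labeled alternative is switchable
(`cv_bin`/`pp_bin` arguments) since the labeling convention is not uniquely
determined by the binned-percent phrasing.

## Inference

Permutation tests pool per-object values within each condition group,
compute the observed statistic (default: difference of means, two-sided on
|T|; the direction-ambiguous phrasing of one-sided alternatives is exposed
by flag) and permute labels at the object level by default; cell-level
permutation is offered to respect within-cell correlation. The empirical
p-value uses the add-one correction p = (1 + #{|T*| ≥ |T|})/(n_perm + 1) —
a deliberate deviation from a literal proportion that avoids p = 0 and
keeps p ≥ 1/(n_perm+1). Default n_perm = 10⁵. Bootstrap CIs are percentile
intervals with linear interpolation; the default n_boot = 20 mirrors the
effect-size summaries this layer reproduces but is statistically coarse —
for calibrated coverage use n_boot ≥ 1000 (the coverage test runs at
n_boot = 2000). Histograms use half-open bins with the last bin closed.

## Synthetic scenes and what passing tests show

The generator emulates the geometry that drives every metric: digital
balls/ellipsoids/capsules and branched capsule unions (voxel included iff
its center is inside the continuous surface — the standard digitization
that makes brute-force oracles unambiguous); wrapped ER shells placed at
city-block distance gap+1 from their mitochondrion over a spherical-cap
coverage fraction, in the same metric as the contact dilation so band
assignment is exact by construction; parallel sheet stacks and curved
tubules; LD and nuclear balls; TEM discs and arcs at exact Euclidean gaps;
and zonation ramps with Gaussian noise. Analytic volume/SA are recorded
where the shape admits them (Thomsen's approximation, < 1.1% error, for
ellipsoid SA; none for capsule unions). Scene sizes in the test-suite and
acceptance runs are 32³–72³ voxels with mitochondria of 3–9 voxel radius —
deliberately small so 50-scene brute-force sweeps stay fast, while
exercising every code path at full fidelity.

Not emulated: EM texture and segmentation noise (beyond optional
clipping of ER at occupied voxels), anisotropic voxels in generated scenes,
the sheet/tubule classification that produces ER-sheet masks (consumed as
pre-made inputs), and realistic organelle densities of a hepatocyte
(thousands of mitochondria). Passing tests therefore demonstrate metric
correctness on known geometry, not robustness to segmentation error or
performance at whole-cell scale.

## Known limitations

- Whole-hepatocyte volumes (10⁹–10¹⁰ voxels) need chunked processing that
  this in-memory implementation does not provide.
- The contact metric is discrete city-block distance, intentionally
  faithful to iterated dilation; it is not a Euclidean membrane-to-membrane
  distance, and 3D vs 2D numbers are not directly comparable.
- Mesh SA below ~5 voxel radius is digitization-dominated; voxel-face SA is
  then the more predictable (if biased) choice.
- The pipeline consumes segmentations; it does not validate them beyond
  size/boundary filters.
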