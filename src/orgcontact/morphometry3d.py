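"""Per-instance 3D morphometry: volume, surface area, sphericity and MCI².

The mitochondrial complexity index used throughout is

    MCI² = SA³ / (16 π² V²)

with surface area SA in µm² and volume V in µm³. MCI² equals 9/(4π) ≈ 0.716
for a perfect sphere and grows with branching and flattening; it is invariant
under uniform rescaling. Sphericity is Wadell's

    ψ = π^(1/3) (6V)^(2/3) / SA,

1 for a sphere and < 1 otherwise.

Surface area is estimated either from a marching-cubes mesh (default; close
to the true continuous area for smooth bodies) or by counting exposed voxel
faces (simple and exactly additive, but it over-estimates the area of smooth
surfaces by up to ~1.5x, inflating MCI² and deflating ψ accordingly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from orgcontact.volume_io import LabelVolume

__all__ = [
    "label_components",
    "filter_instances",
    "instance_metrics",
    "mci2",
    "sphericity",
    "classify_complex",
    "MIN_VOXEL_PRESETS",
]

#: Named per-dataset minimum mitochondrion sizes (voxels) used during
#: proof-reading of the source segmentations; ER objects below 100,000 voxels
#: were discarded in every dataset.
MIN_VOXEL_PRESETS: dict[str, int] = {
    "lean_fed": 21696,
    "lean_fasted": 92243,
    "obese_fed": 50382,
    "obese_fasted": 80293,
    "obese_lacz": 50437,
    "obese_rrbp1": 50234,
    "er": 100_000,
}


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def relabel_sequential_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels 1..K by first-voxel raster (z, y, x) order."""
    flat = labels.ravel()
    first_idx = {}
    for pos in np.flatnonzero(flat):
        lab = flat[pos]
        if lab not in first_idx:
            first_idx[lab] = pos
    order = sorted(first_idx, key=first_idx.get)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.uint32)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels]


def label_components(binary: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Connected-component labeling of a binary mask.

    Components are maximal under the stated voxel connectivity (26 = "full
    connectivity in x, y, z", the convention used for object creation from
    the source segmentations) and are labeled 1..K deterministically by
    first-voxel raster order.
    """
    data = binary.data
    if data.max() > 1:
        raise ValueError("label_components expects a binary mask (values 0/1)")
    structure = _connectivity_structure(connectivity)
    labeled, _ = ndimage.label(data > 0, structure=structure)
    labeled = relabel_sequential_scan_order(labeled)
    return LabelVolume(labeled, binary.voxel_size_nm, name=binary.name)


def boundary_labels(labels: np.ndarray) -> set[int]:
    """Labels of objects touching any face of the volume."""
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    out: set[int] = set()
    for face in faces:
        out.update(np.unique(face).tolist())
    out.discard(0)
    return out


def filter_instances(
    labels: LabelVolume,
    min_voxels: int = 0,
    exclude_boundary: bool = False,
) -> LabelVolume:
    """Remove instances below a voxel-count threshold and, optionally, those
    touching the volume boundary. Surviving labels keep their original ids.

    The per-dataset thresholds applied during proof-reading of the source
    data are available in :data:`MIN_VOXEL_PRESETS`; the default is 0
    (no size filtering).
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be non-negative")
    data = labels.data
    out = data.copy()
    if min_voxels > 0:
        ids, counts = np.unique(data[data > 0], return_counts=True)
        small = ids[counts < min_voxels]
        if small.size:
            out[np.isin(out, small)] = 0
    if exclude_boundary:
        touching = boundary_labels(out)
        if touching:
            out[np.isin(out, list(touching))] = 0
    return LabelVolume(out, labels.voxel_size_nm, name=labels.name)


def mci2(SA: float, V: float) -> float:
    """Mitochondrial complexity index MCI² = SA³ / (16 π² V²).

    SA in µm², V in µm³; dimensionless and scale-invariant. 9/(4π) ≈ 0.7162
    for a sphere, 216/(16π²) ≈ 1.3678 for a cube.
    """
    SA = np.asarray(SA, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(SA <= 0) or np.any(V <= 0):
        raise ValueError("mci2 requires SA > 0 and V > 0")
    out = SA**3 / (16.0 * np.pi**2 * V**2)
    return float(out) if out.ndim == 0 else out


def sphericity(SA: float, V: float) -> float:
    """Wadell sphericity ψ = π^(1/3) (6V)^(2/3) / SA; 1 for a sphere."""
    SA = np.asarray(SA, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(SA <= 0) or np.any(V <= 0):
        raise ValueError("sphericity requires SA > 0 and V > 0")
    out = np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / SA
    return float(out) if out.ndim == 0 else out


def voxel_face_surface_area(mask: np.ndarray, voxel_size_nm) -> float:
    """Surface area (µm²) by counting exposed voxel faces.

    Counts, per axis, faces between foreground and background (volume edges
    count as exposed) weighted by the physical face area. Exactly additive
    over voxels but over-estimates smooth surfaces.
    """
    sz, sy, sx = (v * 1e-3 for v in voxel_size_nm)  # nm -> µm
    face_areas = (sy * sx, sz * sx, sz * sy)  # faces normal to z, y, x
    padded = np.pad(mask.astype(np.int8), 1)
    total = 0.0
    for axis, face_area in enumerate(face_areas):
        diff = np.abs(np.diff(padded, axis=axis))
        total += diff.sum() * face_area
    return float(total)


#: Taubin smoothing iterations applied to marching-cubes meshes. The raw
#: binary isosurface is a staircase that over-estimates smooth surfaces by
#: ~9%; Taubin's shrink-free lambda/mu filter removes the staircase while
#: preserving enclosed volume, bringing digital-ball surface area within
#: ~0.5% of 4*pi*r^2 by radius 40 voxels.
_TAUBIN_ITERATIONS = 50


def mesh_surface_area(mask: np.ndarray, voxel_size_nm) -> float:
    """Surface area (µm²) of the smoothed marching-cubes isosurface.

    Marching cubes at level 0.5 on the zero-padded binary mask, followed by
    Taubin mesh smoothing (lambda = 0.5, mu = -0.53) to suppress the voxel
    staircase without shrinking the object.
    """
    import trimesh

    spacing = tuple(v * 1e-3 for v in voxel_size_nm)  # nm -> µm
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    mesh = trimesh.Trimesh(verts, faces, process=False)
    trimesh.smoothing.filter_taubin(
        mesh, lamb=0.5, nu=0.53, iterations=_TAUBIN_ITERATIONS
    )
    return float(mesh.area)


def instance_metrics(
    labels: LabelVolume,
    sa_method: str = "mesh",
    cell_id=None,
) -> pd.DataFrame:
    """Per-instance morphometry table.

    One row per positive label with voxel count, volume V (µm³, voxel count
    times voxel volume), surface area SA (µm², by ``sa_method``: ``mesh`` for
    marching cubes or ``voxel_face`` for exposed-face counting), Wadell
    sphericity, MCI², centroid (z, y, x in µm) and a boundary-touch flag.
    """
    if sa_method not in ("mesh", "voxel_face"):
        raise ValueError(f"sa_method must be 'mesh' or 'voxel_face', got {sa_method!r}")
    data = labels.data
    voxel_um3 = labels.voxel_volume_um3
    scale_um = np.asarray(labels.voxel_size_nm) * 1e-3
    touching = boundary_labels(data)

    rows = []
    objects = ndimage.find_objects(data)
    for idx, slc in enumerate(objects):
        lab = idx + 1
        if slc is None:
            continue
        mask = data[slc] == lab
        n_vox = int(mask.sum())
        if n_vox == 0:
            continue
        V = n_vox * voxel_um3
        if sa_method == "mesh":
            SA = mesh_surface_area(mask, labels.voxel_size_nm)
        else:
            SA = voxel_face_surface_area(mask, labels.voxel_size_nm)
        zc, yc, xc = ndimage.center_of_mass(mask)
        offset = np.array([s.start for s in slc], dtype=float)
        centroid_um = (np.array([zc, yc, xc]) + offset) * scale_um
        rows.append(
            {
                "object_id": lab,
                "voxel_count": n_vox,
                "volume_um3": V,
                "surface_area_um2": SA,
                "sphericity": sphericity(SA, V),
                "mci2": mci2(SA, V),
                "centroid_z_um": centroid_um[0],
                "centroid_y_um": centroid_um[1],
                "centroid_x_um": centroid_um[2],
                "touches_boundary": lab in touching,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "voxel_count",
            "volume_um3",
            "surface_area_um2",
            "sphericity",
            "mci2",
            "centroid_z_um",
            "centroid_y_um",
            "centroid_x_um",
            "touches_boundary",
        ],
    )
    if cell_id is not None:
        table["cell_id"] = cell_id
    table.attrs["provenance"] = labels.name
    table.attrs["sa_method"] = sa_method
    return table


def classify_complex(
    table: pd.DataFrame, mci2_min: float = 5.0, volume_min_um3: float = 3.0
) -> float:
    """Fraction of mitochondria that are both complex and large.

    A mitochondrion qualifies when MCI² > ``mci2_min`` and V > ``volume_min_um3``
    (defaults 5 and 3 µm³, the bivariate gate separating the large branched
    population in the fasted liver from the compact fed-state population).
    """
    if len(table) == 0:
        raise ValueError("classify_complex requires a nonempty metrics table")
    hits = (table["mci2"] > mci2_min) & (table["volume_um3"] > volume_min_um3)
    return float(hits.mean())
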