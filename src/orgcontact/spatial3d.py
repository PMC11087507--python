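"""Mitochondrial spatial distribution relative to the nucleus.

Distances are measured from each mitochondrion's centroid (the unweighted
voxel centroid of its 3D geometry) to a per-cell nuclear reference point: the
nuclear centroid for mononucleate cells, or the midpoint between the two
nuclear centroids for binucleate hepatocytes. Absolute distances are in µm;
relative distances divide by the per-cell maximum so positioning can be
compared independently of cell size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from orgcontact.volume_io import LabelVolume

__all__ = ["NucleusReference", "nucleus_reference", "mito_nucleus_distances"]

#: Saturation distance (µm) used for absolute-distance colour maps in the
#: original renderings; a visualization parameter only, never applied to the
#: metric values.
COLORMAP_SATURATION_UM = 25.0


@dataclass(frozen=True)
class NucleusReference:
    """Reference point for nucleus-distance measurements, in µm (z, y, x)."""

    point_um: tuple[float, float, float]
    n_nuclei: int

    def __post_init__(self) -> None:
        if self.n_nuclei not in (1, 2):
            raise ValueError(f"n_nuclei must be 1 or 2, got {self.n_nuclei}")


def nucleus_reference(
    nuc_labels: LabelVolume, cell_mask: np.ndarray | None = None
) -> NucleusReference:
    """Nuclear reference point of one cell.

    With one nucleus the reference is its centroid; with two (binucleate
    hepatocytes) it is the midpoint between the two nuclear centroids, keeping
    the measurement consistent across ploidy. ``cell_mask`` optionally
    restricts the nucleus volume to one cell; 0 or more than 2 nuclei within
    the cell is an error.
    """
    data = nuc_labels.data
    if cell_mask is not None:
        data = np.where(cell_mask, data, 0)
    ids = np.unique(data)
    ids = ids[ids > 0]
    if len(ids) == 0 or len(ids) > 2:
        raise ValueError(f"expected 1 or 2 nuclei in cell, found {len(ids)}")
    scale_um = np.asarray(nuc_labels.voxel_size_nm) * 1e-3
    centroids = np.array(ndimage.center_of_mass(data > 0, data, ids)) * scale_um
    point = centroids.mean(axis=0)  # midpoint of the two centroids when n == 2
    return NucleusReference(point_um=tuple(float(v) for v in point), n_nuclei=len(ids))


def mito_nucleus_distances(
    metrics_table: pd.DataFrame, ref: NucleusReference
) -> pd.DataFrame:
    """Absolute and relative mitochondrion-to-nucleus distances.

    Euclidean distance from each centroid (``centroid_{z,y,x}_um`` columns of
    a morphometry table) to the reference point; ``relative`` divides by the
    per-cell maximum, so it lies in [0, 1] with exactly one mitochondrion at 1.
    """
    if len(metrics_table) == 0:
        raise ValueError("mito_nucleus_distances requires a nonempty metrics table")
    centroids = metrics_table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    absolute = np.linalg.norm(centroids - np.asarray(ref.point_um), axis=1)
    max_abs = absolute.max()
    relative = absolute / max_abs if max_abs > 0 else np.zeros_like(absolute)
    return pd.DataFrame(
        {
            "mito_id": metrics_table["object_id"].to_numpy(),
            "absolute_um": absolute,
            "relative": relative,
        }
    )
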