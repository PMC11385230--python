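"""Assign bipolar channels to labeled networks from an atlas volume.

Each channel carries the MNI coordinate of its contact-pair midpoint.  A
channel inside a labeled voxel gets that voxel's label at distance zero;
otherwise it gets the label of the nearest labeled voxel center within a
distance tolerance (10 mm by default, inclusive), measured as Euclidean
distance in world (mm) space.  Channels farther than the tolerance from every
label, and exact distance ties between two labels, remain unassigned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["assign_channels"]

UNASSIGNED = "unassigned"


def _as_volume(atlas):
    """Accept a nibabel image or a (data, affine) pair."""
    if isinstance(atlas, tuple):
        data, affine = atlas
        return np.asarray(data), np.asarray(affine, dtype=float)
    return np.asarray(atlas.dataobj), np.asarray(atlas.affine, dtype=float)


def assign_channels(
    midpoints: np.ndarray,
    atlas,
    labels: dict[int, str],
    tolerance_mm: float = 10.0,
    tie_eps: float = 1e-9,
) -> pd.DataFrame:
    """Label channel midpoints with the nearest atlas network within tolerance.

    Parameters
    ----------
    midpoints : (n, 3) array of MNI mm coordinates.
    atlas : nibabel image or ``(data, affine)`` with integer labels (0 = none).
    labels : mapping of label value -> network name.
    tolerance_mm : inclusive maximum midpoint-to-voxel-center distance.

    Returns
    -------
    DataFrame with columns ``label`` and ``distance_mm``.
    """
    pts = np.atleast_2d(np.asarray(midpoints, dtype=float))
    data, affine = _as_volume(atlas)
    inv = np.linalg.inv(affine)
    trees = {}
    for value, name in labels.items():
        ijk = np.argwhere(data == value)
        if len(ijk) == 0:
            continue
        world = ijk @ affine[:3, :3].T + affine[:3, 3]
        trees[name] = cKDTree(world)
    if not trees:
        raise ValueError("atlas contains no labeled voxels for the given lookup")

    out_label = []
    out_dist = []
    vox = (pts @ inv[:3, :3].T + inv[:3, 3])
    vox_idx = np.round(vox).astype(int)
    for i, pt in enumerate(pts):
        ijk = vox_idx[i]
        inside = np.all((ijk >= 0) & (ijk < data.shape))
        if inside:
            value = int(data[tuple(ijk)])
            if value in labels:
                out_label.append(labels[value])
                out_dist.append(0.0)
                continue
        dists = {name: float(tree.query(pt)[0]) for name, tree in trees.items()}
        best = min(dists, key=dists.get)
        d = dists[best]
        ties = [n for n, v in dists.items() if abs(v - d) <= tie_eps and n != best]
        if d > tolerance_mm:
            out_label.append(UNASSIGNED)
            out_dist.append(d)
        elif ties:
            warnings.warn(f"channel {i}: exact distance tie between {best!r} "
                          f"and {ties}; left unassigned")
            out_label.append(UNASSIGNED)
            out_dist.append(d)
        else:
            out_label.append(best)
            out_dist.append(d)
    return pd.DataFrame({"label": out_label, "distance_mm": out_dist})
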