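"""Retinal in-situ quantification: puncta per cell, GCL density,
colocalization.

One Laplacian-of-Gaussian blob detector serves two parameterizations:
cell-scale (marker or nuclei channel, e.g. slc17a6b-labelled RGCs or DAPI
nuclei in the ganglion cell layer) and punctum-scale (RNAscope probe
channel).  Each punctum is assigned to the nearest cell centroid within a
maximum distance; unassigned puncta are kept so that assigned + unassigned
always equals the total detected.  Density is cells per calibrated field
area; colocalization is the fraction of reference-channel cells with a
second-channel detection nearby under greedy one-to-one matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import blob_log

__all__ = [
    "DensityRecord",
    "detect_cells",
    "detect_puncta",
    "puncta_per_cell",
    "gcl_density",
    "colocalization_fraction",
]


@dataclass
class DensityRecord:
    region: str  # "central" | "peripheral"
    cells: int
    area_um2: float
    density_per_um2: float


def _merge_close(coords: np.ndarray, radii: np.ndarray, merge_dist: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Union-find merge of detections closer than their merge distance."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(float(merge_dist.max())):
        if np.hypot(*(coords[i] - coords[j])) < min(merge_dist[i],
                                                    merge_dist[j]):
            parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    out_c, out_r = [], []
    for r in np.unique(roots):
        sel = roots == r
        out_c.append(coords[sel].mean(axis=0))
        out_r.append(radii[sel].mean())
    return np.asarray(out_c), np.asarray(out_r)


def detect_cells(image: np.ndarray, *, min_radius_px: float = 4.0,
                 max_radius_px: float = 12.0, threshold: float = 0.1,
                 exclude_border: bool = True) -> pd.DataFrame:
    """LoG blob detection at cell scale; duplicate detections closer than
    one radius are merged.  Returns columns ``cell_id``, ``y``, ``x``,
    ``radius``.  Cells touching the field border are excluded by default."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    blobs = blob_log(img, min_sigma=min_radius_px / math.sqrt(2),
                     max_sigma=max_radius_px / math.sqrt(2),
                     num_sigma=8, threshold=threshold)
    if len(blobs) == 0:
        return pd.DataFrame(columns=["cell_id", "y", "x", "radius"])
    coords = blobs[:, :2]
    radii = blobs[:, 2] * math.sqrt(2)
    if len(coords) > 1:
        coords, radii = _merge_close(coords, radii, radii)
    if exclude_border:
        h, w = img.shape
        keep = ((coords[:, 0] >= radii) & (coords[:, 0] <= h - 1 - radii)
                & (coords[:, 1] >= radii) & (coords[:, 1] <= w - 1 - radii))
        coords, radii = coords[keep], radii[keep]
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords, radii = coords[order], radii[order]
    return pd.DataFrame({"cell_id": np.arange(len(coords)),
                         "y": coords[:, 0], "x": coords[:, 1],
                         "radius": radii})


def detect_puncta(image: np.ndarray, *, sigma_px: float = 1.5,
                  threshold: float = 0.05) -> pd.DataFrame:
    """Single-scale LoG spot detection; returns columns ``y``, ``x``."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    blobs = blob_log(img, min_sigma=sigma_px, max_sigma=sigma_px,
                     num_sigma=1, threshold=threshold)
    if len(blobs) == 0:
        return pd.DataFrame(columns=["y", "x"])
    order = np.lexsort((blobs[:, 1], blobs[:, 0]))
    return pd.DataFrame({"y": blobs[order, 0], "x": blobs[order, 1]})


def puncta_per_cell(cells: pd.DataFrame, puncta: pd.DataFrame,
                    max_dist_px: float) -> tuple[pd.DataFrame, int]:
    """Assign puncta to nearest cell centroids within ``max_dist_px``.

    Ties go to the lowest ``cell_id``.  Returns ``(table, n_unassigned)``
    where the table has one row per cell with its ``count``; conservation
    holds: ``table['count'].sum() + n_unassigned == len(puncta)``.
    """
    if cells.empty:
        return (pd.DataFrame(columns=["cell_id", "y", "x", "count"]),
                len(puncta))
    ccoords = cells[["y", "x"]].to_numpy(dtype=float)
    counts = np.zeros(len(cells), dtype=int)
    unassigned = 0
    if not puncta.empty:
        pcoords = puncta[["y", "x"]].to_numpy(dtype=float)
        d = np.sqrt(((pcoords[:, None, :] - ccoords[None, :, :]) ** 2)
                    .sum(axis=2))
        for pi in range(len(pcoords)):
            best = np.min(d[pi])
            if best <= max_dist_px:
                counts[int(np.argmin(d[pi]))] += 1  # argmin → lowest index
            else:
                unassigned += 1
    table = cells[["cell_id", "y", "x"]].copy()
    table["count"] = counts
    return table, unassigned


def gcl_density(nuclei_image: np.ndarray, region: str, *, px_per_um: float,
                **detect_kwargs) -> DensityRecord:
    """Nuclei count per calibrated field area in the ganglion cell layer."""
    if region not in ("central", "peripheral"):
        raise ValueError("region must be 'central' or 'peripheral'")
    if px_per_um <= 0:
        raise ValueError("calibration px_per_um must be positive")
    img = np.asarray(nuclei_image, dtype=float)
    area_um2 = img.shape[0] * img.shape[1] / px_per_um**2
    if area_um2 <= 0:
        raise ValueError("field area must be positive")
    cells = detect_cells(img, **detect_kwargs)
    n = len(cells)
    return DensityRecord(region=region, cells=n, area_um2=area_um2,
                         density_per_um2=n / area_um2)


def colocalization_fraction(detections_a: pd.DataFrame,
                            detections_b: pd.DataFrame,
                            match_dist_px: float) -> float:
    """Fraction of A-channel cells with a B-channel detection nearby.

    Matching is greedy one-to-one by increasing distance, so one B
    detection can certify at most one A cell.
    """
    if detections_a.empty:
        raise ValueError("no reference cells in channel A")
    if detections_b.empty:
        return 0.0
    a = detections_a[["y", "x"]].to_numpy(dtype=float)
    b = detections_b[["y", "x"]].to_numpy(dtype=float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    pairs = [(d[i, j], i, j) for i in range(len(a)) for j in range(len(b))
             if d[i, j] <= match_dist_px]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
    return len(used_a) / len(a)
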