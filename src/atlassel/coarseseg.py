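"""Atlas-free coarse tissue segmentation of a target image.

Atlas pre-selection needs a coarse tissue map of the target before any
atlas has been registered. This module supplies that map from the raw
intensity image alone: an Otsu + largest-component brain mask, a seeded
3-class k-means intensity clustering (CSF / gray matter / white matter,
ordered by mean intensity for T1-like contrast), and an interiority rule
that separates ventricular CSF from the surrounding CSF space. When a
precomputed coarse map already exists, callers should bypass this stage
and feed that map to the ranking step directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from sklearn.cluster import KMeans

from .volio import COARSE_SCHEME, IntensityVolume, LabelVolume

__all__ = ["CoarseSegResult", "quick_coarse_segment", "project_fine_to_coarse"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class CoarseSegResult:
    """Coarse tissue map plus the per-class mean intensities found."""

    coarse: LabelVolume
    class_means_found: dict[int, float]
    brain_mask_voxels: int


def quick_coarse_segment(
    img: IntensityVolume,
    k_classes: int = 3,
    seed: int = 0,
    contrast: str = "t1",
) -> CoarseSegResult:
    """Estimate the coarse tissue map of an intensity volume.

    Steps: (1) brain mask = largest 6-connected component above the Otsu
    threshold, morphologically closed; (2) seeded k-means (k=3) on in-mask
    intensities, classes assigned to CSF < GM < WM by ascending cluster mean
    (descending for ``contrast='t2'``); (3) CSF-class components that do not
    touch the mask boundary become ventricles (id 4), the rest the CSF
    space (id 1); (4) everything outside the mask is the remaining space
    (id 0). Skull-base and skin labels are not emitted: no head model is
    fitted at this stage. Deterministic for a fixed seed.
    """
    if k_classes != 3:
        raise ValueError("only k_classes=3 (CSF/GM/WM) is supported")
    if contrast not in ("t1", "t2"):
        raise ValueError(f"contrast must be 't1' or 't2', got {contrast!r}")
    values = img.values
    if values.min() == values.max():
        raise ValueError("fewer than k distinct intensity levels (constant image)")

    # Head/air cut. A plain two-class Otsu can land between CSF and GM when
    # air dominates the histogram, so prefer the lowest threshold of a
    # 4-class multi-Otsu (air | CSF | GM | WM) and fall back to binary Otsu
    # for low-diversity images.
    try:
        thr = float(threshold_multiotsu(values, classes=4)[0])
    except ValueError:
        thr = float(threshold_otsu(values))
    above = values > thr
    if not above.any():
        raise ValueError("empty brain mask (no voxels above Otsu threshold)")
    comps, n_comp = ndimage.label(above, structure=_STRUCT6)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == sizes.argmax()
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3, 3), dtype=bool))
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty brain mask")

    in_mask = values[mask]
    if np.unique(in_mask).size < k_classes:
        raise ValueError("fewer than k distinct intensity levels in brain mask")

    km = KMeans(n_clusters=k_classes, n_init=10, random_state=int(seed))
    assign = km.fit_predict(in_mask.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)          # ascending mean: CSF < GM < WM for T1
    if contrast == "t2":
        order = order[::-1]
    # cluster index -> coarse tissue id (1 CSF, 2 GM, 3 WM)
    tissue_of_cluster = np.empty(k_classes, dtype=np.int32)
    for tissue, cluster in enumerate(order, start=1):
        tissue_of_cluster[cluster] = tissue

    labels = np.zeros(img.grid.shape, dtype=np.int32)
    labels[mask] = tissue_of_cluster[assign]

    # Interior CSF components are ventricles.
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT6)
    csf = labels == 1
    csf_comps, n_csf = ndimage.label(csf, structure=_STRUCT6)
    if n_csf:
        touching = np.unique(csf_comps[boundary & csf])
        interior = np.setdiff1d(np.arange(1, n_csf + 1), touching)
        if interior.size:
            labels[np.isin(csf_comps, interior)] = 4

    means = {
        int(cid): float(values[labels == cid].mean())
        for cid in (0, 1, 2, 3, 4)
        if np.any(labels == cid)
    }
    table = {cid: COARSE_SCHEME[cid] for cid in np.unique(labels) if cid != 0}
    return CoarseSegResult(
        coarse=LabelVolume(img.grid, labels, table),
        class_means_found=means,
        brain_mask_voxels=n_mask,
    )


def project_fine_to_coarse(fine: LabelVolume, mapping: dict[int, int]) -> LabelVolume:
    """Voxelwise substitution of fine label ids by coarse tissue ids.

    Every nonzero fine id present in the volume must have a mapping entry;
    id 0 maps to 0 unless the mapping says otherwise.
    """
    present = [i for i in fine.present_ids() if i != 0]
    missing = [i for i in present if i not in mapping]
    if missing:
        raise KeyError(f"unmapped fine id(s): {missing}")
    lut_size = max(fine.present_ids(), default=0) + 1
    lut = np.zeros(lut_size, dtype=np.int32)
    for fid in present:
        lut[fid] = int(mapping[fid])
    if 0 in mapping:
        lut[0] = int(mapping[0])
    coarse = lut[fine.labels]
    table = {int(c): COARSE_SCHEME.get(int(c), f"label_{int(c)}")
             for c in np.unique(coarse) if c != 0}
    return LabelVolume(fine.grid, coarse, table)
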