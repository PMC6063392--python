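"""Target-atlas similarity measures for atlas ranking.

Three measures are provided:

* ``score_4l`` — mean Dice overlap of the four selection tissues (CSF
  space, gray matter, white matter, ventricles) between two coarse maps;
* ``score_lv`` — Dice overlap of the ventricle label alone;
* ``normalized_mi`` — intensity-histogram similarity
  ``NMI(A, B) = (H(A) + H(B)) / H(A, B)``, which lies in [1, 2] (2 for
  identical volumes, 1 for independent ones).

Dice(W_i, W_j) = 2 |W_i ∩ W_j| / (|W_i| + |W_j|). Entropies are Shannon
entropies in bits of equal-width intensity histograms; the NMI ratio is
independent of the logarithm base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volio import GridError, IntensityVolume, LabelVolume, SELECTION_IDS, VolumeGrid

__all__ = [
    "RegionMask",
    "SimilarityScore",
    "dice",
    "entropy",
    "normalized_mi",
    "score_4l",
    "score_lv",
]

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 64


@dataclass
class RegionMask:
    """Binary region of voxels on a grid (one structure's support)."""

    grid: VolumeGrid
    members: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.members, dtype=bool)
        if arr.shape != self.grid.shape:
            raise ValueError(f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        self.members = arr


@dataclass(frozen=True)
class SimilarityScore:
    atlas_id: str
    method: str
    value: float


def _as_bool(a) -> np.ndarray:
    if isinstance(a, RegionMask):
        return a.members
    return np.asarray(a, dtype=bool)


def dice(a, b) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|) of two region masks.

    Two empty masks agree that the structure is absent and score 1.0 (with
    a logged warning); one empty mask against a nonempty one scores 0.0.
    """
    if isinstance(a, RegionMask) and isinstance(b, RegionMask):
        a.grid.require_compatible(b.grid, "region masks")
    am, bm = _as_bool(a), _as_bool(b)
    if am.shape != bm.shape:
        raise GridError(f"mask shapes differ: {am.shape} vs {bm.shape}")
    na, nb = int(am.sum()), int(bm.sum())
    if na == 0 and nb == 0:
        log.warning("dice of two empty masks: returning 1.0 (structure absent in both)")
        return 1.0
    inter = int(np.count_nonzero(am & bm))
    return 2.0 * inter / (na + nb)


def _histogram_probs(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    return counts / counts.sum()


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy(img: IntensityVolume, mask=None, n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon entropy (bits) of the in-mask intensity histogram.

    The histogram has ``n_bins`` equal-width bins spanning the in-mask
    [min, max]; a constant region has zero entropy.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = img.values
    if mask is not None:
        m = _as_bool(mask)
        if not m.any():
            raise ValueError("empty mask")
        values = values[m]
    return _shannon(_histogram_probs(values.ravel(), n_bins))


def normalized_mi(
    a: IntensityVolume,
    b: IntensityVolume,
    n_bins: int = DEFAULT_N_BINS,
    mask=None,
) -> float:
    """Normalized mutual information (H(A)+H(B)) / H(A,B) in [1, 2].

    Marginal and joint histograms share the same per-volume equal-width
    bin edges, built over the full common grid by default (whole-head
    intensity information); pass ``mask`` to restrict to a region.
    Symmetric in its arguments.
    """
    a.grid.require_compatible(b.grid, "intensity volumes")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    va, vb = a.values.ravel(), b.values.ravel()
    if mask is not None:
        m = _as_bool(mask).ravel()
        if not m.any():
            raise ValueError("empty mask")
        va, vb = va[m], vb[m]
    if va.min() == va.max() or vb.min() == vb.max():
        raise ValueError("constant volume: joint entropy degenerate")
    edges_a = np.linspace(va.min(), va.max(), n_bins + 1)
    edges_b = np.linspace(vb.min(), vb.max(), n_bins + 1)
    joint, _, _ = np.histogram2d(va, vb, bins=[edges_a, edges_b])
    joint /= joint.sum()
    h_a = _shannon(joint.sum(axis=1))
    h_b = _shannon(joint.sum(axis=0))
    h_ab = _shannon(joint.ravel())
    return (h_a + h_b) / h_ab


def _check_coarse_pair(target: LabelVolume, atlas: LabelVolume) -> None:
    target.grid.require_compatible(atlas.grid, "coarse maps")
    target.require_coarse()
    atlas.require_coarse()


def score_4l(
    target_coarse: LabelVolume,
    atlas_coarse: LabelVolume,
    mode: str = "mean",
) -> float:
    """4L criterion: agreement of the four selection tissues.

    ``mode='mean'`` (default) averages the per-label Dice over CSF space,
    gray matter, white matter, and ventricles, with empty-empty labels
    contributing 1.0. ``mode='union'`` computes a single Dice on the union
    of the four labels treated as one region.
    """
    _check_coarse_pair(target_coarse, atlas_coarse)
    if mode == "union":
        ta = np.isin(target_coarse.labels, SELECTION_IDS)
        ab = np.isin(atlas_coarse.labels, SELECTION_IDS)
        return dice(ta, ab)
    if mode != "mean":
        raise ValueError(f"unknown 4L mode {mode!r}")
    values = [
        dice(target_coarse.mask(cid), atlas_coarse.mask(cid)) for cid in SELECTION_IDS
    ]
    return float(np.mean(values))


def score_lv(target_coarse: LabelVolume, atlas_coarse: LabelVolume) -> float:
    """LV criterion: Dice of the ventricle label alone."""
    _check_coarse_pair(target_coarse, atlas_coarse)
    return dice(target_coarse.mask(4), atlas_coarse.mask(4))
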