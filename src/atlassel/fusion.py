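"""Label fusion: combine selected atlases' fine label maps by voting.

All inputs live on one common grid (label propagation is the identity;
real-data use requires externally registered inputs). Each atlas casts one
vote per voxel — unit weight in majority mode, or a caller-supplied
non-negative weight (typically the pre-selection similarity score) in
weighted mode. Ties go to the lowest label id, which makes the result
independent of atlas order. The back-end is pluggable in principle; voting
is the only one shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volio import LabelVolume

__all__ = ["FusionConfig", "fuse_labels"]


@dataclass
class FusionConfig:
    """mode: 'majority' (unit votes) or 'weighted' (per-atlas weights)."""

    mode: str = "majority"
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("majority", "weighted"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")


def fuse_labels(
    atlas_fines: list[LabelVolume],
    cfg: FusionConfig | None = None,
    weights: list[float] | None = None,
) -> LabelVolume:
    """Voxelwise (weighted) plurality vote over the input label maps.

    ``weights`` aligns with ``atlas_fines``; required in weighted mode.
    The output label table is the union of the input tables.
    """
    if not atlas_fines:
        raise ValueError("empty atlas list")
    cfg = cfg or FusionConfig()
    grid = atlas_fines[0].grid
    for lv in atlas_fines[1:]:
        grid.require_compatible(lv.grid, "fused label maps")

    if cfg.mode == "weighted":
        if weights is None:
            raise ValueError("weighted mode requires per-atlas weights")
        w = np.asarray(weights, dtype=np.float64)
        if len(w) != len(atlas_fines):
            raise ValueError("weights length must match the number of atlases")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with at least one positive")
    else:
        w = np.ones(len(atlas_fines))

    # Compact the union of label ids, in ascending order so that argmax's
    # first-maximum rule implements the lowest-id tie-break.
    all_ids = np.unique(np.concatenate([lv.present_ids() for lv in atlas_fines]))
    lut = np.zeros(int(all_ids.max()) + 1, dtype=np.int32)
    lut[all_ids] = np.arange(all_ids.size)

    nvox = int(np.prod(grid.shape))
    n_codes = all_ids.size
    votes = np.zeros(nvox * n_codes, dtype=np.float64)
    base = np.arange(nvox, dtype=np.intp) * n_codes
    for lv, wi in zip(atlas_fines, w):
        codes = lut[lv.labels].ravel().astype(np.intp)
        votes += wi * np.bincount(base + codes, minlength=nvox * n_codes)
    fused_codes = votes.reshape(nvox, n_codes).argmax(axis=1)
    fused = all_ids[fused_codes].astype(np.int32).reshape(grid.shape)

    table: dict[int, str] = {}
    for lv in atlas_fines:
        table.update(lv.table)
    table = {i: n for i, n in table.items() if i in set(np.unique(fused)) and i != 0}
    return LabelVolume(grid, fused, table)
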