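"""Volume and atlas-library I/O.

Volumes are 3D NIfTI-1 images on a fixed voxel grid. The toolkit operates
strictly on a common grid: atlases and targets must already live in the
same space, and mixed grids are a hard error rather than being resampled.
All computations are voxel-count based; physical volumes are obtained by
multiplying counts with the spacing product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "IntensityVolume",
    "LabelVolume",
    "COARSE_SCHEME",
    "COARSE_IDS",
    "Atlas",
    "AtlasLibrary",
    "read_volume",
    "write_volume",
    "load_library",
    "GridError",
]


class GridError(ValueError):
    """Raised when two volumes do not share a compatible voxel grid."""


#: Fixed coarse whole-head tissue scheme: 7 labels covering the full field
#: of view. Id 0 is the remaining space (background) by convention.
COARSE_SCHEME: dict[int, str] = {
    0: "remaining_space",
    1: "csf_space",
    2: "gray_matter",
    3: "white_matter",
    4: "ventricles",
    5: "skull_base",
    6: "skin",
}

COARSE_IDS = frozenset(COARSE_SCHEME)

#: The four tissue classes used by the 4L selection criterion.
SELECTION_IDS = (1, 2, 3, 4)


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice: shape (voxels per axis), spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(not (s > 0) for s in self.spacing):
            raise ValueError(f"grid spacing must be a positive triple, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=1e-6)
            and np.allclose(self.origin, other.origin, rtol=0, atol=1e-6)
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.compatible_with(other):
            raise GridError(
                f"incompatible grids between {what}: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )


@dataclass
class IntensityVolume:
    """3D scalar field (arbitrary units) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite intensities present")


@dataclass
class LabelVolume:
    """3D non-negative integer field with a label table (id -> name).

    Id 0 is reserved for background / remaining space and need not appear
    in the table; every other id present in the array must.
    """

    grid: VolumeGrid
    labels: np.ndarray
    table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label array must be integer-typed")
        if arr.shape != self.grid.shape:
            raise ValueError(f"labels shape {arr.shape} != grid shape {self.grid.shape}")
        if arr.min(initial=0) < 0:
            raise ValueError("negative label ids present")
        self.labels = arr.astype(np.int32, copy=False)
        self.table = {int(k): str(v) for k, v in self.table.items()}
        present = set(self.present_ids()) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"label ids missing from table: {sorted(missing)}")

    def present_ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels)]

    def mask(self, label_id: int) -> np.ndarray:
        """Binary region mask for one label id."""
        return self.labels == int(label_id)

    def is_coarse(self) -> bool:
        return set(self.present_ids()) <= COARSE_IDS

    def require_coarse(self) -> None:
        extra = set(self.present_ids()) - COARSE_IDS
        if extra:
            raise ValueError(f"non-coarse ids present: {sorted(extra)}")


@dataclass
class Atlas:
    """One library member: intensity image + coarse tissue map + fine labels."""

    id: str
    intensity: IntensityVolume
    coarse: LabelVolume
    fine: LabelVolume
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.intensity.grid
        g.require_compatible(self.coarse.grid, f"atlas {self.id} intensity/coarse")
        g.require_compatible(self.fine.grid, f"atlas {self.id} intensity/fine")
        self.coarse.require_coarse()

    @property
    def grid(self) -> VolumeGrid:
        return self.intensity.grid


class AtlasLibrary:
    """Ordered collection of atlases with unique ids on one shared grid.

    Order is significant: it is the manifest row order and fixes
    deterministic tie-breaking downstream.
    """

    def __init__(self, atlases: list[Atlas]):
        if not atlases:
            raise ValueError("empty atlas library")
        ids = [a.id for a in atlases]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate id(s) in library: {sorted(dupes)}")
        self.grid = atlases[0].grid
        for a in atlases[1:]:
            self.grid.require_compatible(a.grid, f"library and atlas {a.id}")
        self._atlases: dict[str, Atlas] = {a.id: a for a in atlases}
        self.ids: list[str] = ids

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[Atlas]:
        return (self._atlases[i] for i in self.ids)

    def __getitem__(self, atlas_id: str) -> Atlas:
        return self._atlases[atlas_id]

    def __contains__(self, atlas_id: str) -> bool:
        return atlas_id in self._atlases


def _affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), origin)


def read_volume(path: str | Path, as_labels: bool = False) -> IntensityVolume | LabelVolume:
    """Read a NIfTI-1 volume as intensities or as an integer label map.

    In label mode, values within 1e-6 of an integer are rounded; anything
    else is an error. Intensity mode rejects non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    grid = _grid_from_img(img)
    if as_labels:
        if not np.all(np.isfinite(data)):
            raise ValueError(f"non-finite values in label volume {path}")
        rounded = np.rint(data)
        if np.abs(data - rounded).max(initial=0.0) > 1e-6:
            bad = float(data.flat[np.argmax(np.abs(data - rounded))])
            raise ValueError(f"non-integer label value {bad!r} in {path}")
        return LabelVolume(grid, rounded.astype(np.int32), _default_table(rounded))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite intensities in {path}")
    return IntensityVolume(grid, data)


def _default_table(labels: np.ndarray) -> dict[int, str]:
    return {int(i): f"label_{int(i)}" for i in np.unique(labels) if int(i) != 0}


def write_volume(vol: IntensityVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; round-trips through :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, _affine_from_grid(vol.grid))
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))
    return path


MANIFEST_COLUMNS = ("id", "intensity_path", "coarse_path", "fine_path")


def load_library(manifest: str | Path) -> AtlasLibrary:
    """Load an atlas library from a CSV manifest.

    Required columns: id, intensity_path, coarse_path, fine_path. Optional
    columns (age, group, ...) become per-atlas metadata. Relative paths are
    resolved against the manifest's directory. Member order equals row order.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate id(s) in manifest: {dupes}")
    root = manifest.parent
    meta_cols = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    atlases = []
    for row in df.itertuples(index=False):
        rd = row._asdict()

        def respath(key: str) -> Path:
            p = Path(rd[key])
            return p if p.is_absolute() else root / p

        intensity = read_volume(respath("intensity_path"), as_labels=False)
        coarse = read_volume(respath("coarse_path"), as_labels=True)
        coarse.table = {i: COARSE_SCHEME[i] for i in coarse.present_ids() if i != 0}
        fine = read_volume(respath("fine_path"), as_labels=True)
        meta = {c: rd[c] for c in meta_cols if not pd.isna(rd[c])}
        atlases.append(Atlas(str(rd["id"]), intensity, coarse, fine, meta))
    return AtlasLibrary(atlases)
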