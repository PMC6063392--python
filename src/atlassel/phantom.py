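"""Synthetic brain-like phantom libraries.

A phantom is a nested-shell head model on a regular voxel grid: a spherical
brain (cortical gray-matter rind over a white-matter core), lateral and
third ventricles as ellipsoids inside the white matter, small hippocampal
ellipsoids in the infero-lateral white matter, a surrounding CSF shell, a
dark skull gap, a skin shell, and a skull-base blob of brain-like intensity
below the head. Intensities follow a class-mean model (T1-like contrast,
CSF < GM < WM) modulated by a smooth multiplicative bias field plus
additive Gaussian noise.

A phantom *library* varies anatomy systematically: ventricle size is swept
evenly across a scale range (the dominant, selectable axis of variation,
emulating ventricular enlargement with age and atrophy), while cortical
thickness and the positions of the ventricles and hippocampi receive small
seeded jitters (idiosyncratic anatomy that no selection axis explains).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import (
    Atlas,
    AtlasLibrary,
    COARSE_SCHEME,
    IntensityVolume,
    LabelVolume,
    VolumeGrid,
)

__all__ = [
    "PhantomSpec",
    "LibrarySpec",
    "FINE_SCHEME",
    "FINE_TO_COARSE",
    "make_phantom",
    "make_library",
]

#: Fine-structure inventory of the phantom (a small proxy parcellation).
FINE_SCHEME: dict[int, str] = {
    10: "cortex_L",
    11: "cortex_R",
    20: "white_matter_L",
    21: "white_matter_R",
    30: "lateral_ventricle_L",
    31: "lateral_ventricle_R",
    32: "third_ventricle",
    40: "hippocampus_L",
    41: "hippocampus_R",
    50: "csf_shell",
    60: "skull_base",
    70: "skin",
}

#: Deterministic projection of fine structures onto the 7-label scheme.
FINE_TO_COARSE: dict[int, int] = {
    10: 2, 11: 2,          # cortex -> gray matter
    20: 3, 21: 3,          # white matter
    30: 4, 31: 4, 32: 4,   # ventricles
    40: 2, 41: 2,          # hippocampus -> gray matter
    50: 1,                 # surrounding CSF space
    60: 5,                 # skull-base tissues
    70: 6,                 # skin
}

#: Default tissue-class mean intensities (arbitrary units, T1-like).
DEFAULT_CLASS_MEANS: dict[int, float] = {
    0: 5.0,     # air / remaining space (noise floor)
    1: 35.0,    # CSF space
    2: 90.0,    # gray matter
    3: 140.0,   # white matter
    4: 35.0,    # ventricular CSF
    5: 70.0,    # skull-base soft tissue (brain-like)
    6: 120.0,   # skin / lipid
}

#: Dark gap between the CSF shell and the skin (skull bone, part of the
#: remaining space in the 7-label scheme). Keeps the head's bright tissues
#: in two separate connected components (brain+CSF vs skin).
SKULL_GAP_MM = 4.0

#: Hippocampus proxy geometry (mm): mirrored infero-lateral ellipsoids.
HIPPOCAMPUS_CENTER_MM = (12.0, -7.0, -7.0)
HIPPOCAMPUS_SEMIAXES_MM = (4.0, 6.0, 4.0)

#: Third-ventricle semiaxes as fractions of the lateral-ventricle semiaxes.
THIRD_VENTRICLE_FRACTION = (0.3, 0.8, 0.5)

#: Structures whose centers may be jittered per library member.
_JITTER_KEYS = ("lv_l", "lv_r", "v3", "hc_l", "hc_r")


class GeometryError(ValueError):
    """Raised when a phantom specification violates its geometric invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full geometric + intensity recipe for one phantom.

    All lengths in mm; the model is centered in the field of view.
    ``structure_offsets`` holds per-structure center displacements (mm) for
    the lateral ventricles, third ventricle, and hippocampi — the library
    generator fills these with seeded jitter.
    """

    grid: VolumeGrid = VolumeGrid((48, 56, 48), (2.0, 2.0, 2.0))
    brain_radius_mm: float = 30.0
    cortex_thickness_mm: float = 6.0
    csf_thickness_mm: float = 3.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (7.0, 13.0, 7.0)
    ventricle_offset_mm: tuple[float, float, float] = (8.0, 0.0, 2.0)
    skull_base_radius_mm: float = 5.0
    skin_thickness_mm: float = 2.0
    class_means: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    noise_sd: float = 2.5
    bias_amplitude: float = 0.05
    seed: int = 0
    structure_offsets: Mapping[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.brain_radius_mm <= 0 or self.cortex_thickness_mm <= 0:
            raise GeometryError("brain radius and cortex thickness must be positive")
        if self.cortex_thickness_mm >= self.brain_radius_mm:
            raise GeometryError("cortex thickness must be smaller than the brain radius")
        if self.csf_thickness_mm <= 0:
            raise GeometryError("csf thickness must be positive")
        if not (0.0 <= self.bias_amplitude <= 1.0):
            raise GeometryError("bias amplitude must lie in [0, 1]")
        if self.noise_sd < 0:
            raise GeometryError("noise sd must be non-negative")
        half = self._half_extents()
        if self.csf_outer_radius_mm >= min(half):
            raise GeometryError(
                f"csf outer radius {self.csf_outer_radius_mm} mm does not fit the "
                f"field of view (half-extents {half} mm)"
            )
        outer = self.csf_outer_radius_mm + SKULL_GAP_MM + self.skin_thickness_mm
        if self.skin_thickness_mm > 0 and outer >= min(half):
            raise GeometryError("skin shell does not fit the field of view")

    def _half_extents(self) -> tuple[float, float, float]:
        return tuple(
            (n - 1) / 2.0 * s for n, s in zip(self.grid.shape, self.grid.spacing)
        )

    @property
    def csf_outer_radius_mm(self) -> float:
        return self.brain_radius_mm + self.csf_thickness_mm

    @property
    def wm_radius_mm(self) -> float:
        return self.brain_radius_mm - self.cortex_thickness_mm

    def offsets(self) -> dict[str, np.ndarray]:
        base = {k: np.zeros(3) for k in _JITTER_KEYS}
        if self.structure_offsets:
            for k, v in self.structure_offsets.items():
                if k not in base:
                    raise GeometryError(f"unknown structure-offset key {k!r}")
                base[k] = np.asarray(v, dtype=float)
        return base


@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for a library of phantoms with controlled anatomical spread.

    Ventricle scale multipliers are evenly spaced (not sampled) across
    ``ventricle_scale_range`` so that selection-recovery experiments have a
    known unique answer; cortical thickness and structure centers receive
    seeded jitter (uniform within +/- cortex_jitter_mm, and Gaussian with
    sd structure_jitter_mm truncated at two sd, respectively).
    """

    n_atlases: int
    base: PhantomSpec = PhantomSpec()
    ventricle_scale_range: tuple[float, float] = (0.7, 1.3)
    cortex_jitter_mm: float = 1.0
    structure_jitter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be positive")
        lo, hi = self.ventricle_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("ventricle_scale_range must be a positive interval")
        if self.cortex_jitter_mm < 0 or self.structure_jitter_mm < 0:
            raise ValueError("jitter amplitudes must be non-negative")


def _coords_mm(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered physical coordinates of voxel centers, one array per axis."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(grid.shape, grid.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: np.ndarray,
    semiaxes: np.ndarray,
) -> np.ndarray:
    x, y, z = coords
    q = (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def _bias_field(grid: VolumeGrid, amplitude: float) -> np.ndarray:
    """Separable quadratic multiplicative field 1 + amplitude * q, q in [-1, 1]."""
    if amplitude == 0.0:
        return np.ones(grid.shape)
    x, y, z = _coords_mm(grid)
    half = [(n - 1) / 2.0 * s for n, s in zip(grid.shape, grid.spacing)]
    u, v, w = x / half[0], y / half[1], z / half[2]
    q = (u**2 + v**2 + w**2) * (2.0 / 3.0) - 1.0
    return 1.0 + amplitude * q


def make_phantom(
    spec: PhantomSpec,
    atlas_id: str = "phantom",
    ventricle_scale: float = 1.0,
    meta: dict | None = None,
) -> Atlas:
    """Build one phantom atlas (intensity + coarse + fine volumes).

    Identical specs (including the seed) produce bit-identical output.
    ``ventricle_scale`` multiplies the lateral- and third-ventricle
    semiaxes; the result must remain strictly interior to the white-matter
    core (at least one voxel of margin), otherwise a GeometryError is raised.
    """
    grid = spec.grid
    coords = _coords_mm(grid)
    x = coords[0]
    r = np.sqrt(coords[0] ** 2 + coords[1] ** 2 + coords[2] ** 2)
    fine = np.zeros(grid.shape, dtype=np.int32)

    # Outer shells first; inner structures overwrite.
    if spec.skin_thickness_mm > 0:
        skin_in = spec.csf_outer_radius_mm + SKULL_GAP_MM
        fine[(r > skin_in) & (r <= skin_in + spec.skin_thickness_mm)] = 70
    if spec.skull_base_radius_mm > 0:
        c = np.array([
            0.0,
            0.0,
            -(spec.csf_outer_radius_mm + SKULL_GAP_MM + spec.skull_base_radius_mm),
        ])
        blob = _ellipsoid_mask(coords, c, np.full(3, spec.skull_base_radius_mm))
        fine[blob] = 60

    fine[(r > spec.brain_radius_mm) & (r <= spec.csf_outer_radius_mm)] = 50
    brain = r <= spec.brain_radius_mm
    fine[brain & (x < 0)] = 10
    fine[brain & (x >= 0)] = 11
    wm = r <= spec.wm_radius_mm
    fine[wm & (x < 0)] = 20
    fine[wm & (x >= 0)] = 21

    offs = spec.offsets()
    semi = np.asarray(spec.ventricle_semiaxes_mm) * float(ventricle_scale)
    off = np.asarray(spec.ventricle_offset_mm)
    lv_r = _ellipsoid_mask(coords, np.array([off[0], off[1], off[2]]) + offs["lv_r"], semi)
    lv_l = _ellipsoid_mask(coords, np.array([-off[0], off[1], off[2]]) + offs["lv_l"], semi)
    v3 = _ellipsoid_mask(
        coords,
        np.array([0.0, off[1], off[2] - 0.3 * semi[2]]) + offs["v3"],
        semi * np.asarray(THIRD_VENTRICLE_FRACTION),
    )
    ventricle = lv_l | lv_r | v3

    # Invariant: ventricles strictly inside the white-matter core.
    wm_eroded = ndimage.binary_erosion(wm, structure=ndimage.generate_binary_structure(3, 1))
    if np.any(ventricle & ~wm_eroded):
        raise GeometryError(
            "ventricle ellipsoids are not strictly interior to the white matter "
            f"(scale {ventricle_scale}, offsets {spec.structure_offsets})"
        )
    fine[lv_l] = 30
    fine[lv_r & ~lv_l] = 31      # rare midline overlap stays left-labeled
    fine[v3 & ~lv_l & ~lv_r] = 32

    hc_semi = np.asarray(HIPPOCAMPUS_SEMIAXES_MM)
    hc = np.asarray(HIPPOCAMPUS_CENTER_MM)
    hc_l = _ellipsoid_mask(coords, np.array([-hc[0], hc[1], hc[2]]) + offs["hc_l"], hc_semi)
    hc_r = _ellipsoid_mask(coords, np.array([hc[0], hc[1], hc[2]]) + offs["hc_r"], hc_semi)
    # Hippocampi are carved out of remaining white matter only.
    fine[hc_l & np.isin(fine, (20, 21))] = 40
    fine[hc_r & np.isin(fine, (20, 21))] = 41

    coarse = np.zeros_like(fine)
    for fid, cid in FINE_TO_COARSE.items():
        coarse[fine == fid] = cid

    means = dict(DEFAULT_CLASS_MEANS)
    means.update({int(k): float(v) for k, v in spec.class_means.items()})
    intensity = np.zeros(grid.shape, dtype=np.float64)
    for cid, mu in means.items():
        intensity[coarse == cid] = mu
    intensity *= _bias_field(grid, spec.bias_amplitude)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity += rng.normal(0.0, spec.noise_sd, size=grid.shape)

    fine_table = {fid: FINE_SCHEME[fid] for fid in np.unique(fine) if fid != 0}
    coarse_table = {cid: COARSE_SCHEME[cid] for cid in np.unique(coarse) if cid != 0}
    md = {"ventricle_scale": float(ventricle_scale)}
    if meta:
        md.update(meta)
    return Atlas(
        id=atlas_id,
        intensity=IntensityVolume(grid, intensity),
        coarse=LabelVolume(grid, coarse, coarse_table),
        fine=LabelVolume(grid, fine, fine_table),
        meta=md,
    )


def make_library(lspec: LibrarySpec) -> tuple[AtlasLibrary, pd.DataFrame]:
    """Build a phantom library plus its per-atlas anatomical truth table.

    Ventricle scales are evenly spaced across ``ventricle_scale_range``
    (a single atlas sits at mid-range). The truth table reports the realized
    ventricle volume (recounted from the fine labels) and the jittered
    cortical thickness of every member.
    """
    n = lspec.n_atlases
    lo, hi = lspec.ventricle_scale_range
    scales = np.array([(lo + hi) / 2.0]) if n == 1 else np.linspace(lo, hi, n)

    rng = np.random.default_rng(lspec.seed)
    cortex_jit = rng.uniform(-lspec.cortex_jitter_mm, lspec.cortex_jitter_mm, size=n)
    struct_jit = rng.normal(0.0, lspec.structure_jitter_mm, size=(n, len(_JITTER_KEYS), 3))
    clip = 2.0 * lspec.structure_jitter_mm
    struct_jit = np.clip(struct_jit, -clip, clip)
    noise_seeds = rng.integers(0, 2**31, size=n)

    width = max(2, len(str(n)))
    atlases, rows = [], []
    for i in range(n):
        offsets = {
            k: tuple(struct_jit[i, j]) for j, k in enumerate(_JITTER_KEYS)
        }
        spec_i = replace(
            lspec.base,
            cortex_thickness_mm=lspec.base.cortex_thickness_mm + float(cortex_jit[i]),
            seed=int(noise_seeds[i]),
            structure_offsets=offsets,
        )
        aid = f"p{i + 1:0{width}d}"
        atlas = make_phantom(
            spec_i,
            atlas_id=aid,
            ventricle_scale=float(scales[i]),
            meta={"cortex_thickness_mm": spec_i.cortex_thickness_mm},
        )
        atlases.append(atlas)
        vent_voxels = int(np.count_nonzero(atlas.coarse.labels == 4))
        rows.append(
            {
                "id": aid,
                "ventricle_scale": float(scales[i]),
                "cortex_thickness_mm": spec_i.cortex_thickness_mm,
                "ventricle_voxels": vent_voxels,
                "ventricle_volume_mm3": vent_voxels * atlas.grid.voxel_volume_mm3,
            }
        )
    return AtlasLibrary(atlases), pd.DataFrame(rows)
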