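"""Atlas ranking and top-k subset selection.

The pre-selection principle: rank every atlas in the library by its
agreement with the target — coarse-label Dice (4L or LV) or normalized
mutual information of the intensity images — and keep the top-k for the
subsequent (expensive) segmentation. A seeded uniform random subset serves
as the benchmark baseline. If the target is itself a library member it is
excluded before ranking (leave-one-out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import DEFAULT_N_BINS, SimilarityScore, normalized_mi, score_4l, score_lv
from .volio import AtlasLibrary, IntensityVolume, LabelVolume

__all__ = ["Ranking", "rank_atlases", "select_top_k", "select_random", "METHODS"]

log = logging.getLogger(__name__)

METHODS = ("4L", "LV", "MI", "random")
DEFAULT_KS = (5, 10, 15, 20, 25)


@dataclass
class Ranking:
    """Ordered atlas ids (best first) with their similarity scores."""

    method: str
    order: list[str]
    scores: list[SimilarityScore] = field(default_factory=list)
    seed: int | None = None

    def score_of(self, atlas_id: str) -> float:
        for s in self.scores:
            if s.atlas_id == atlas_id:
                return s.value
        raise KeyError(atlas_id)


def _canonical_method(method: str) -> str:
    m = method.upper() if method.lower() != "random" else "random"
    if m not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return m


def rank_atlases(
    lib: AtlasLibrary,
    method: str,
    target_coarse: LabelVolume | None = None,
    target_intensity: IntensityVolume | None = None,
    target_id: str | None = None,
    n_bins: int = DEFAULT_N_BINS,
    exclude_target: bool = True,
) -> Ranking:
    """Score every library atlas against the target and sort, best first.

    4L and LV require ``target_coarse``; MI requires ``target_intensity``.
    Ties are broken by ascending atlas id so rankings are deterministic
    regardless of library order. If ``target_id`` names a library member
    and ``exclude_target`` is true, that member is dropped before ranking.
    """
    m = _canonical_method(method)
    if m == "random":
        raise ValueError("use select_random for the random baseline")
    if m in ("4L", "LV") and target_coarse is None:
        raise ValueError(f"method {m} requires a target coarse map")
    if m == "MI" and target_intensity is None:
        raise ValueError("method MI requires a target intensity volume")

    candidates = [a for a in lib if not (exclude_target and a.id == target_id)]
    if not candidates:
        raise ValueError("no candidate atlases after target exclusion")
    scores = []
    for atlas in candidates:
        if m == "4L":
            v = score_4l(target_coarse, atlas.coarse)
        elif m == "LV":
            v = score_lv(target_coarse, atlas.coarse)
        else:
            v = normalized_mi(target_intensity, atlas.intensity, n_bins=n_bins)
        scores.append(SimilarityScore(atlas.id, m, float(v)))
    scores.sort(key=lambda s: (-s.value, s.atlas_id))
    return Ranking(method=m, order=[s.atlas_id for s in scores], scores=scores)


def select_top_k(ranking: Ranking, k: int) -> list[str]:
    """First min(k, N) ids of the ranking; top-k is a prefix of top-(k+1)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(ranking.order):
        log.warning(
            "requested top-%d but only %d atlases ranked; returning all",
            k, len(ranking.order),
        )
    return ranking.order[:k]


def select_random(
    lib: AtlasLibrary,
    k: int,
    seed: int,
    exclude: str | None = None,
) -> list[str]:
    """Seeded uniform sample of k atlas ids without replacement."""
    pool = [i for i in lib.ids if i != exclude]
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} available atlases")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in picked]
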