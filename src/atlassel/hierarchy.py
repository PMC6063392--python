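"""Hierarchical aggregation of fine labels into named superstructures.

Fine structural units are grouped into nested superstructures at three
granularity levels: Level A (hemispheric tissue compartments), Level B
(lobes and major white-matter territories), and Level C (individual
nuclei, gyri, and ventricular parts). A hierarchy table maps each fine
label id to its superstructure name at each level (or to none, meaning
the id is outside that level's inventory); the mapping must be a tree —
each named Level-C structure lies in at most one Level-B structure, and
each Level-B in at most one Level-A.

The packaged evaluation ROI lists contain 63 names (4 at Level A, 26 at
Level B, 33 at Level C); the packaged phantom hierarchy table maps the
phantom's proxy structures into those lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .volio import LabelVolume

__all__ = [
    "HierarchyTable",
    "LevelROISet",
    "load_hierarchy",
    "phantom_hierarchy",
    "load_roi_sets",
    "LEVELS",
]

log = logging.getLogger(__name__)

LEVELS = ("A", "B", "C")
_NONE_TOKENS = {"", "none", "na", "nan", "-"}

#: Known spelling fix-ups applied on load (with a logged note).
_NAME_FIXES = {"Hippocampu_R": "Hippocampus_R"}


def _clean_name(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.lower() in _NONE_TOKENS:
        return None
    if s in _NAME_FIXES:
        log.info("normalizing structure name %r -> %r", s, _NAME_FIXES[s])
        s = _NAME_FIXES[s]
    return s


@dataclass
class HierarchyTable:
    """Rows of (fine_id, level_a, level_b, level_c); names or None."""

    rows: pd.DataFrame  # columns fine_id, level_a, level_b, level_c

    def __post_init__(self) -> None:
        df = self.rows.copy()
        required = ["fine_id", "level_a", "level_b", "level_c"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"hierarchy table missing column(s): {missing}")
        df["fine_id"] = df["fine_id"].astype(int)
        if df["fine_id"].duplicated().any():
            dupes = sorted(df.loc[df["fine_id"].duplicated(), "fine_id"].unique())
            raise ValueError(f"duplicate fine id(s) in hierarchy table: {dupes}")
        for col in ("level_a", "level_b", "level_c"):
            df[col] = df[col].map(_clean_name)
        self._validate_tree(df)
        self.rows = df.reset_index(drop=True)

    @staticmethod
    def _validate_tree(df: pd.DataFrame) -> None:
        for child, parent in (("level_c", "level_b"), ("level_b", "level_a")):
            named = df[df[child].notna()]
            parents = named.groupby(child)[parent].nunique(dropna=False)
            bad = parents[parents > 1]
            if not bad.empty:
                raise ValueError(
                    f"tree property violated: {child} structure(s) "
                    f"{list(bad.index)} map to multiple {parent} names"
                )

    def level_column(self, level: str) -> str:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
        return f"level_{level.lower()}"

    def level_names(self, level: str) -> list[str]:
        """Named superstructures at a level, in first-appearance table order."""
        col = self.level_column(level)
        seen: list[str] = []
        for name in self.rows[col]:
            if name is not None and name not in seen:
                seen.append(name)
        return seen

    def mapping(self, level: str) -> dict[int, str | None]:
        col = self.level_column(level)
        return dict(zip(self.rows["fine_id"], self.rows[col]))


def load_hierarchy(path: str | Path) -> HierarchyTable:
    """Load a hierarchy table from a TSV (fine_id, level_a, level_b, level_c)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return HierarchyTable(df)


def phantom_hierarchy() -> HierarchyTable:
    """The packaged hierarchy table for the phantom's proxy structures."""
    with resources.as_file(
        resources.files("atlassel") / "data" / "phantom_hierarchy.tsv"
    ) as p:
        return load_hierarchy(p)


@dataclass
class LevelROISet:
    level: str
    names: list[str]

    def __len__(self) -> int:
        return len(self.names)


def load_roi_sets(path: str | Path | None = None) -> dict[str, LevelROISet]:
    """Load the per-level evaluation ROI lists from a TSV (level, name).

    With no path, returns the packaged default lists (4 Level-A, 26
    Level-B, and 33 Level-C structure names, 63 in total).
    """
    if path is None:
        with resources.as_file(resources.files("atlassel") / "data" / "roi_sets.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, LevelROISet] = {lvl: LevelROISet(lvl, []) for lvl in LEVELS}
    if df.empty:
        return out
    for _, row in df.iterrows():
        lvl = str(row["level"]).strip().upper()
        if lvl not in LEVELS:
            raise ValueError(f"unknown level token {row['level']!r}")
        name = _clean_name(row["name"])
        if name is not None:
            out[lvl].names.append(name)
    return out


def aggregate_to_level(
    fine: LabelVolume, table: HierarchyTable, level: str
) -> LabelVolume:
    """Replace each fine id by an integer code for its level-name.

    Codes are assigned by first appearance in table order (1, 2, ...);
    fine ids whose level entry is none (and the background id 0) map to 0.
    Every nonzero fine id present in the volume must have a table row.
    """
    mapping = table.mapping(level)
    present = [i for i in fine.present_ids() if i != 0]
    missing = [i for i in present if i not in mapping]
    if missing:
        raise KeyError(f"fine id(s) missing from hierarchy table: {missing}")
    names = table.level_names(level)
    code_of = {name: i + 1 for i, name in enumerate(names)}
    lut = np.zeros(max(present, default=0) + 1, dtype=np.int32)
    for fid in present:
        name = mapping[fid]
        lut[fid] = code_of[name] if name is not None else 0
    agg = lut[fine.labels]
    out_table = {code_of[n]: n for n in names if code_of[n] in np.unique(agg)}
    return LabelVolume(fine.grid, agg, out_table)
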