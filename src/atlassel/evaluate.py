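"""Segmentation-accuracy metrics and the method x subset-size sweep.

Accuracy is measured per named superstructure as the Dice overlap between
the fused segmentation and the truth labels, after aggregating both to a
granularity level (A, B, or C). Summaries follow the study design around
atlas pre-selection: mean Dice per (method, k, level), the poor-outcome
ratio (fraction of structure Dice scores below 0.7 — a tail-sensitive
complement to means), and paired t tests between selection methods on
per-target mean Dice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coarseseg import quick_coarse_segment
from .fusion import FusionConfig, fuse_labels
from .hierarchy import HierarchyTable, LevelROISet, aggregate_to_level, load_roi_sets, phantom_hierarchy
from .preselect import DEFAULT_KS, METHODS, rank_atlases, select_random, select_top_k
from .similarity import dice
from .volio import Atlas, AtlasLibrary, LabelVolume

__all__ = [
    "SweepReport",
    "structure_dice",
    "poor_outcome_ratio",
    "paired_compare",
    "run_sweep",
    "plot_mean_dice",
    "POOR_DICE_THRESHOLD",
]

log = logging.getLogger(__name__)

#: Dice below this is a "poor outcome".
POOR_DICE_THRESHOLD = 0.7


def structure_dice(
    seg: LabelVolume,
    truth: LabelVolume,
    roi_set: LevelROISet,
    table: HierarchyTable,
) -> list[tuple[str, float | None]]:
    """Per-structure Dice at one granularity level.

    Both volumes are aggregated to the ROI set's level; each listed
    structure gets the Dice of its aggregated masks. Structures empty in
    the truth (including names absent from the hierarchy) are reported as
    None and are meant to be excluded from means.
    """
    seg.grid.require_compatible(truth.grid, "segmentation and truth")
    seg_lvl = aggregate_to_level(seg, table, roi_set.level)
    truth_lvl = aggregate_to_level(truth, table, roi_set.level)
    code_of = {n: i + 1 for i, n in enumerate(table.level_names(roi_set.level))}
    out: list[tuple[str, float | None]] = []
    for name in roi_set.names:
        code = code_of.get(name)
        if code is None:
            out.append((name, None))
            continue
        t_mask = truth_lvl.labels == code
        if not t_mask.any():
            log.warning("structure %r empty in truth; excluded from evaluation", name)
            out.append((name, None))
            continue
        out.append((name, dice(seg_lvl.labels == code, t_mask)))
    return out


def poor_outcome_ratio(dices, threshold: float = POOR_DICE_THRESHOLD) -> float:
    """Fraction of Dice values strictly below the threshold."""
    vals = [d for d in dices if d is not None]
    if not vals:
        raise ValueError("empty Dice list")
    return sum(d < threshold for d in vals) / len(vals)


def paired_compare(per_target_a, per_target_b) -> tuple[float, float]:
    """Paired-samples t test on per-target scores; returns (t, two-sided p).

    Identical samples give (0, 1); nonzero constant differences have zero
    variance and are flagged, with t = +/-inf and p = 0.
    """
    a = np.asarray(per_target_a, dtype=float)
    b = np.asarray(per_target_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        log.warning("zero-variance nonzero differences in paired t test")
        return float(np.inf * np.sign(d[0])), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class SweepReport:
    """Per-structure records plus the design's summary tables."""

    records: pd.DataFrame      # target_id, method, k, level, structure, dice
    summaries: pd.DataFrame    # method, k, level, mean_dice, n_structures
    poor_ratio: pd.DataFrame   # method, k, poor_ratio, n
    paired_stats: pd.DataFrame  # method_a, method_b, t, p

    def equals(self, other: "SweepReport") -> bool:
        return (
            self.records.equals(other.records)
            and self.summaries.equals(other.summaries)
            and self.poor_ratio.equals(other.poor_ratio)
            and self.paired_stats.equals(other.paired_stats)
        )


def _derived_seed(*key: int) -> int:
    return int(np.random.SeedSequence(tuple(key)).generate_state(1)[0] % (2**31))


def _propagate(
    fine: LabelVolume, jitter_mm: float, seed: int, t_idx: int, a_idx: int
) -> LabelVolume:
    """Apply the simulated residual-registration shift to one atlas map."""
    if jitter_mm <= 0:
        return fine
    rng = np.random.default_rng(_derived_seed(seed, 3, t_idx, a_idx))
    sd_vox = np.asarray(jitter_mm) / np.asarray(fine.grid.spacing)
    shift = np.clip(np.rint(rng.normal(0.0, sd_vox, size=3)), -2, 2).astype(int)
    if not shift.any():
        return fine
    shifted = np.zeros_like(fine.labels)
    src = [slice(max(0, -s), fine.grid.shape[i] - max(0, s)) for i, s in enumerate(shift)]
    dst = [slice(max(0, s), fine.grid.shape[i] - max(0, -s)) for i, s in enumerate(shift)]
    shifted[tuple(dst)] = fine.labels[tuple(src)]
    table = {i: fine.table[i] for i in np.unique(shifted) if i != 0}
    return LabelVolume(fine.grid, shifted, table)


def run_sweep(
    lib: AtlasLibrary,
    targets: list[Atlas],
    methods=METHODS,
    ks=DEFAULT_KS,
    cfg: FusionConfig | None = None,
    seed: int = 0,
    n_bins: int = 64,
    table: HierarchyTable | None = None,
    roi_sets: dict[str, LevelROISet] | None = None,
    threshold: float = POOR_DICE_THRESHOLD,
    levels=("A", "B", "C"),
    target_coarse: str = "estimate",
    propagation_jitter_mm: float = 2.0,
) -> SweepReport:
    """Full pre-selection experiment: rank, select, fuse, and score.

    For each target and method, atlas subsets of every size in ``ks`` are
    selected (leave-one-out: a target never enters its own pool), their
    fine label maps fused, and the result scored per structure against the
    target's truth labels at each level. ``target_coarse='estimate'`` runs
    the atlas-free coarse segmentation on the target image (the deployment
    path); ``'truth'`` uses the target's own coarse map. Subset sizes
    exceeding the pool saturate to the whole pool. Deterministic given the
    seed.

    ``propagation_jitter_mm`` emulates residual atlas-to-target
    registration error: each atlas's label map is shifted by a seeded
    random integer-voxel translation (Gaussian with this sd per axis,
    rounded, clipped at two voxels) drawn once per (target, atlas) pair
    before fusion. These independent per-atlas errors are what voting
    averages away as subsets grow; set 0 for identity propagation.
    """
    cfg = cfg or FusionConfig()
    table = table or phantom_hierarchy()
    roi_sets = roi_sets or load_roi_sets()
    if target_coarse not in ("estimate", "truth"):
        raise ValueError("target_coarse must be 'estimate' or 'truth'")

    rows = []
    for t_idx, target in enumerate(targets):
        if target_coarse == "estimate":
            coarse = quick_coarse_segment(
                target.intensity, seed=_derived_seed(seed, 1, t_idx)
            ).coarse
        else:
            coarse = target.coarse
        pool_n = len(lib) - (1 if target.id in lib else 0)
        propagated = {
            a.id: _propagate(a.fine, propagation_jitter_mm, seed, t_idx, i)
            for i, a in enumerate(lib)
            if a.id != target.id
        }

        for method in methods:
            ranking = None
            if method != "random":
                ranking = rank_atlases(
                    lib,
                    method,
                    target_coarse=coarse,
                    target_intensity=target.intensity,
                    target_id=target.id,
                    n_bins=n_bins,
                )
            for k in ks:
                k_eff = min(int(k), pool_n)
                if method == "random":
                    ids = select_random(
                        lib, k_eff, seed=_derived_seed(seed, 2, t_idx, int(k)),
                        exclude=target.id,
                    )
                    weights = None
                else:
                    ids = select_top_k(ranking, k_eff)
                    weights = [ranking.score_of(i) for i in ids]
                # The random baseline has no similarity scores: it always
                # fuses with unit votes, even under a weighted config.
                use_weighted = cfg.mode == "weighted" and weights is not None
                fused = fuse_labels(
                    [propagated[i] for i in ids],
                    cfg if use_weighted else FusionConfig(mode="majority"),
                    weights=weights if use_weighted else None,
                )
                for level in levels:
                    for structure, d in structure_dice(
                        fused, target.fine, roi_sets[level], table
                    ):
                        rows.append(
                            {
                                "target_id": target.id,
                                "method": method,
                                "k": int(k),
                                "level": level,
                                "structure": structure,
                                "dice": d,
                            }
                        )

    records = pd.DataFrame(rows)
    present = records.dropna(subset=["dice"])
    summaries = (
        present.groupby(["method", "k", "level"], as_index=False)
        .agg(mean_dice=("dice", "mean"), n_structures=("dice", "size"))
    )
    poor = (
        present.groupby(["method", "k"], as_index=False)
        .agg(
            poor_ratio=("dice", lambda s: float((s < threshold).mean())),
            n=("dice", "size"),
        )
    )
    per_target = (
        present.groupby(["method", "target_id"])["dice"].mean().unstack("target_id")
    )
    stats_rows = []
    if len(targets) >= 2:
        for ma, mb in itertools.combinations(list(methods), 2):
            t, p = paired_compare(per_target.loc[ma].values, per_target.loc[mb].values)
            stats_rows.append({"method_a": ma, "method_b": mb, "t": t, "p": p})
    paired_stats = pd.DataFrame(
        stats_rows, columns=["method_a", "method_b", "t", "p"]
    )
    return SweepReport(records, summaries, poor, paired_stats)


def plot_mean_dice(report: SweepReport, out_path, level: str = "C"):
    """Simple summary plot: mean Dice vs subset size, one line per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = report.summaries
    fig, ax = plt.subplots(figsize=(5, 4))
    for method, grp in summ[summ.level == level].groupby("method"):
        ax.plot(grp["k"], grp["mean_dice"], marker="o", label=method)
    ax.set_xlabel("number of selected atlases (k)")
    ax.set_ylabel(f"mean Level-{level} Dice")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
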