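"""From 4-D time series plus block events to labeled, normalized voxel patterns.

Pipeline order is fixed and matches the decoding analysis it feeds:
per-run z-scoring -> hemodynamic shift + within-block averaging ->
(optional stimulus-vs-fixation voxel selection) -> per-pattern mean-centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ExperimentDesign, SyntheticDataset

logger = logging.getLogger("cuefuse")


@dataclass
class RunTimeSeries:
    """One run's (voxel, volume) data."""

    data: np.ndarray
    run_id: int
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("RunTimeSeries.data must be 2-D (voxel, volume)")
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")


@dataclass
class PatternMatrix:
    """Block-averaged voxel patterns with their labels.

    ``signs`` are +1 (near) / -1 (far); ``voxel_ids`` index into the original
    voxel axis so selections stay traceable.
    """

    patterns: np.ndarray  # (n_blocks, n_voxels)
    conditions: np.ndarray  # (n_blocks,) str
    signs: np.ndarray  # (n_blocks,) +-1
    run_ids: np.ndarray  # (n_blocks,)
    voxel_ids: np.ndarray  # (n_voxels,)

    def __len__(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset_voxels(self, voxel_index: np.ndarray) -> "PatternMatrix":
        """Restrict to columns ``voxel_index`` (positions, not original ids)."""
        return replace(
            self,
            patterns=self.patterns[:, voxel_index],
            voxel_ids=self.voxel_ids[voxel_index],
        )

    def select(self, condition: str | None = None) -> "PatternMatrix":
        if condition is None:
            return self
        m = self.conditions == condition
        return replace(
            self,
            patterns=self.patterns[m],
            conditions=self.conditions[m],
            signs=self.signs[m],
            run_ids=self.run_ids[m],
        )


@dataclass
class VoxelSelection:
    """Result of the all-stimuli-vs-fixation t contrast."""

    t_values: np.ndarray
    selected: np.ndarray  # ordered voxel indices, descending t
    cap: int
    fallback_used: bool

    @property
    def empty(self) -> bool:
        return self.selected.size == 0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def zscore_per_run(ts: RunTimeSeries) -> RunTimeSeries:
    """Z-score each voxel's time course within the run.

    Zero-variance voxels are set to all-zero (with a logged warning) rather
    than dropped, keeping voxel indexing stable across runs.
    """
    mean = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "run %s: %d zero-variance voxel(s) set to 0", ts.run_id, int(flat.sum())
        )
    out = np.zeros_like(ts.data, dtype=float)
    np.divide(ts.data - mean, sd, out=out, where=sd != 0)
    return RunTimeSeries(data=out, run_id=ts.run_id, tr_s=ts.tr_s)


def extract_block_patterns(
    ts: RunTimeSeries, events: pd.DataFrame, design: ExperimentDesign
) -> PatternMatrix:
    """Average each block's volumes (after the hemodynamic shift) into one
    pattern per block.

    The window for a block with onset volume k is
    [k + shift, k + shift + block_volumes).
    """
    shift = design.hemodynamic_shift_volumes
    width = design.block_volumes
    n_vol = ts.data.shape[1]
    ev = events[events["run"] == ts.run_id]
    pats, conds, signs = [], [], []
    for _, row in ev.iterrows():
        start = int(row["onset_volume"]) + shift
        stop = start + width
        if stop > n_vol:
            raise ValueError(
                f"run {ts.run_id} block {row['block']}: shifted window "
                f"[{start}, {stop}) exceeds run length {n_vol}"
            )
        pats.append(ts.data[:, start:stop].mean(axis=1))
        conds.append(row["condition"])
        signs.append(+1 if row["sign"] == "near" else -1)
    return PatternMatrix(
        patterns=np.asarray(pats),
        conditions=np.asarray(conds, dtype=object),
        signs=np.asarray(signs, dtype=int),
        run_ids=np.full(len(pats), ts.run_id, dtype=int),
        voxel_ids=np.arange(ts.data.shape[0]),
    )


def extract_fixation_patterns(
    ts: RunTimeSeries, design: ExperimentDesign
) -> np.ndarray:
    """Patterns from the leading and trailing fixation intervals, shifted and
    averaged like stimulus blocks; the trailing window is truncated at the end
    of the run."""
    shift = design.hemodynamic_shift_volumes
    width = design.fixation_volumes
    n_vol = ts.data.shape[1]
    windows = []
    lead = (shift, min(shift + width, n_vol))
    trail_onset = design.block_onset_volume(design.blocks_per_run)
    trail = (trail_onset + shift, min(trail_onset + shift + width, n_vol))
    for start, stop in (lead, trail):
        if stop > start:
            windows.append(ts.data[:, start:stop].mean(axis=1))
    return np.asarray(windows)


def select_voxels(
    stimulus_patterns: np.ndarray, fixation_patterns: np.ndarray, cap: int = 150
) -> VoxelSelection:
    """Rank voxels by a two-sample pooled-variance t statistic of all-stimulus
    vs fixation responses and keep the top ``cap``.

    If fewer than ``cap`` voxels have t > 0, all and only the t > 0 voxels
    are kept (the small-ROI fallback); an empty fallback selection is flagged.
    """
    if stimulus_patterns.shape[0] < 2 or fixation_patterns.shape[0] < 2:
        raise ValueError("need >= 2 samples per class for the t contrast")
    t, _ = stats.ttest_ind(
        stimulus_patterns, fixation_patterns, axis=0, equal_var=True
    )
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    order = np.argsort(-t, kind="stable")
    n_pos = int((t > 0).sum())
    fallback = n_pos < cap
    if fallback:
        selected = order[:n_pos]
        if n_pos == 0:
            logger.warning("voxel selection: no voxel with t > 0")
    else:
        selected = order[:cap]
    return VoxelSelection(
        t_values=t, selected=selected, cap=cap, fallback_used=fallback
    )


def mean_center_patterns(pm: PatternMatrix) -> PatternMatrix:
    """Subtract each pattern's mean voxel amplitude so classification cannot
    ride on univariate baseline differences."""
    if len(pm) == 0:
        raise ValueError("empty pattern matrix")
    centered = pm.patterns - pm.patterns.mean(axis=1, keepdims=True)
    return replace(pm, patterns=centered)


# ---------------------------------------------------------------------------
# Convenience: full extraction pipeline
# ---------------------------------------------------------------------------

def dataset_to_patterns(
    ds: SyntheticDataset,
    cap: int | None = 150,
    mean_center: bool = True,
) -> PatternMatrix:
    """Run the full extraction pipeline on a synthetic dataset:
    z-score per run, shift + block-average, voxel selection against the
    fixation baseline (skipped when ``cap`` is None), mean-centering."""
    per_run, fix = [], []
    for run_id, data in enumerate(ds.runs):
        ts = zscore_per_run(RunTimeSeries(data, run_id, ds.design.tr_s))
        per_run.append(extract_block_patterns(ts, ds.events, ds.design))
        fix.append(extract_fixation_patterns(ts, ds.design))
    pm = PatternMatrix(
        patterns=np.concatenate([p.patterns for p in per_run]),
        conditions=np.concatenate([p.conditions for p in per_run]),
        signs=np.concatenate([p.signs for p in per_run]),
        run_ids=np.concatenate([p.run_ids for p in per_run]),
        voxel_ids=per_run[0].voxel_ids,
    )
    if cap is not None:
        sel = select_voxels(pm.patterns, np.concatenate(fix), cap=cap)
        if sel.empty:
            raise ValueError("voxel selection returned no voxels")
        pm = pm.subset_voxels(sel.selected)
    if mean_center:
        pm = mean_center_patterns(pm)
    return pm
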