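"""Moving-sphere decoding over a masked volume: per-center accuracy maps and
per-voxel integration / transfer index maps, with group-level aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decode import ClassifierConfig, FoldPlan, cross_cue_decode, cv_decode
from .fusion_stats import dprime, integration_index, transfer_index
from .patterns import PatternMatrix, mean_center_patterns

logger = logging.getLogger("cuefuse")


@dataclass(frozen=True)
class SphereOffsets:
    """Integer lattice offsets within a world-distance radius of the center."""

    radius_mm: float
    voxel_size_mm: tuple[float, float, float]
    offsets: np.ndarray  # (k, 3) int

    def __len__(self) -> int:
        return self.offsets.shape[0]


def build_sphere_offsets(
    radius_mm: float, voxel_size_mm: float | tuple[float, float, float] = 1.0
) -> SphereOffsets:
    """All and only lattice offsets (dx, dy, dz) whose world distance
    ||offset * voxel_size|| is <= radius; the center is always included."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if np.isscalar(voxel_size_mm):
        vs = (float(voxel_size_mm),) * 3
    else:
        vs = tuple(float(v) for v in voxel_size_mm)
    if any(v <= 0 for v in vs):
        raise ValueError("voxel sizes must be positive")
    bounds = [int(np.floor(radius_mm / v)) for v in vs]
    grids = np.meshgrid(*[np.arange(-b, b + 1) for b in bounds], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    if pts.size == 0:
        pts = np.zeros((1, 3), dtype=int)
    d2 = ((pts * np.asarray(vs)) ** 2).sum(axis=1)
    keep = pts[d2 <= radius_mm**2 + 1e-12]
    return SphereOffsets(
        radius_mm=radius_mm, voxel_size_mm=vs, offsets=keep.astype(int)
    )


@dataclass
class StatMap:
    """Per-voxel statistic defined inside a boolean mask; NaN outside."""

    volume: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def write(self, path) -> None:
        import nibabel as nib

        nib.Nifti1Image(self.volume.astype(np.float32), self.affine).to_filename(
            str(path)
        )


def _empty_map(mask: np.ndarray, affine: np.ndarray) -> StatMap:
    vol = np.full(mask.shape, np.nan)
    return StatMap(volume=vol, mask=mask, affine=affine)


def searchlight_map(
    pm: PatternMatrix,
    voxel_coords: np.ndarray,
    mask: np.ndarray,
    plan: FoldPlan,
    sphere: SphereOffsets,
    conditions: tuple[str, ...] = ("disparity", "motion", "congruent"),
    min_voxels: int = 10,
    config: ClassifierConfig = ClassifierConfig(),
    affine: np.ndarray | None = None,
    compute_integration: bool = True,
    compute_transfer: bool = False,
) -> dict[str, StatMap]:
    """Decode inside a sphere centered at every in-mask voxel.

    ``pm`` holds the already z-scored, block-averaged patterns of all in-mask
    voxels; ``voxel_coords`` (n_voxels, 3) maps pattern columns to grid
    positions.  Per center, the in-mask sphere voxels are mean-centered and
    decoded with the same cross-validation contract as the ROI analysis (no
    voxel-count cap beyond the sphere itself).  Centers with fewer than
    ``min_voxels`` in-mask voxels get a NaN sentinel.

    Returns accuracy maps per condition plus, when the three relevant
    conditions are present, a per-voxel integration-index map and (optionally)
    a direction-averaged cross-cue accuracy and transfer-index map.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    if affine is None:
        affine = np.eye(4)
    voxel_coords = np.asarray(voxel_coords, dtype=int)
    col_of = -np.ones(mask.shape, dtype=int)
    col_of[tuple(voxel_coords.T)] = np.arange(voxel_coords.shape[0])

    maps = {c: _empty_map(mask, affine) for c in conditions}
    want_phi = compute_integration and {"disparity", "motion", "congruent"} <= set(
        conditions
    )
    if want_phi:
        maps["integration_index"] = _empty_map(mask, affine)
    if compute_transfer:
        maps["cross_cue"] = _empty_map(mask, affine)
        if want_phi or {"disparity", "motion"} <= set(conditions):
            maps["transfer_index"] = _empty_map(mask, affine)

    centers = np.argwhere(mask)
    shape = np.asarray(mask.shape)
    for center in centers:
        pos = center + sphere.offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        pos = pos[ok]
        in_mask = mask[tuple(pos.T)]
        cols = col_of[tuple(pos[in_mask].T)]
        cols = cols[cols >= 0]
        if cols.size < min_voxels:
            continue
        local = mean_center_patterns(pm.subset_voxels(cols))
        acc: dict[str, float] = {}
        dp: dict[str, float] = {}
        for cond in conditions:
            res = cv_decode(local, cond, plan, config=config)
            acc[cond] = res.accuracy
            dp[cond] = float(
                dprime(res.accuracy, clamp_n=max(res.n_test_patterns, 1))
            )
            maps[cond].volume[tuple(center)] = res.accuracy
        if want_phi:
            try:
                phi = integration_index(dp["congruent"], dp["disparity"], dp["motion"])
            except ZeroDivisionError:
                phi = np.nan
            maps["integration_index"].volume[tuple(center)] = phi
        if compute_transfer:
            cross = cross_cue_decode(local, "disparity", "motion", plan, config=config)
            res = cross.mean
            maps["cross_cue"].volume[tuple(center)] = res.accuracy
            if "transfer_index" in maps:
                d_t = float(dprime(res.accuracy, clamp_n=max(res.n_test_patterns, 1)))
                try:
                    t = transfer_index(d_t, dp["disparity"], dp["motion"])
                except ZeroDivisionError:
                    t = np.nan
                maps["transfer_index"].volume[tuple(center)] = t
    return maps


def group_map(
    subject_maps: list[StatMap], chance: float = 0.5
) -> StatMap:
    """Per-voxel one-sample t of subject statistics against ``chance``
    (0.5 for accuracy maps, 0 for index maps).

    Voxels where every subject equals ``chance`` get t = 0; voxels undefined
    (NaN) in any subject stay NaN.
    """
    if len(subject_maps) < 2:
        raise ValueError("group map needs >= 2 subjects")
    shapes = {m.volume.shape for m in subject_maps}
    if len(shapes) > 1:
        raise ValueError(f"subject maps on different grids: {sorted(shapes)}")
    stack = np.stack([m.volume for m in subject_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - chance) / se
    t = np.where((se == 0) & (mean == chance), 0.0, t)
    t = np.where(np.isnan(stack).any(axis=0), np.nan, t)
    mask = subject_maps[0].mask
    return StatMap(volume=t, mask=mask, affine=subject_maps[0].affine)
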