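"""ROI/level quantification, BOLD effect size, reliability, null rates.

The cross-sectional atlas splits the cord into right/left x
ventral/dorsal quadrants around the cord center row and column (both
excluded, leaving a one-voxel gap) plus a medioventral (MV) sector: an
inverse-pyramid wedge over the anterior midline separating the sulcal
vein territory from the ventral horns. Rostrocaudally, slices carry
neurological-level labels (L3-S2). Activity statistics, the percentage
BOLD effect size extracted from the denoised GLM reconstruction, Dice
split-half reliability and the task-free false-positive rate live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlockParadigm, MOTION, REST
from .glm import RunStats
from .inference import fwe_permutation_test
from .phantom import PhantomGeometry

__all__ = [
    "RoiAtlas",
    "build_atlas",
    "two_landmark_align",
    "activity_stats",
    "effect_size",
    "dice",
    "split_half",
    "false_positive_rate",
]

SECTORS = ("RV", "RD", "LV", "LD", "MV")
LEVELS = ("L3", "L4", "L5", "S1", "S2")


@dataclass
class RoiAtlas:
    """Sector labels per voxel plus per-slice neurological levels."""

    sector_of_voxel: np.ndarray  # int codes, 0 = none, 1..5 = SECTORS order
    level_of_slice: dict
    center_row: int
    center_col: int

    def sector_mask(self, name: str) -> np.ndarray:
        return self.sector_of_voxel == SECTORS.index(name) + 1

    def level_mask(self, levels) -> np.ndarray:
        levels = {levels} if isinstance(levels, str) else set(levels)
        nz = self.sector_of_voxel.shape[2]
        keep = np.array(
            [self.level_of_slice.get(z) in levels for z in range(nz)]
        )
        out = np.zeros_like(self.sector_of_voxel, dtype=bool)
        out[:, :, keep] = True
        return out


def build_atlas(
    geom: PhantomGeometry,
    mv_halfwidth_base_mm: float = 1.5,
    mv_depth_mm: float = 2.5,
) -> RoiAtlas:
    """Sector atlas on the phantom grid.

    Quadrants split at the cord center row (left-right) and column
    (anterior-posterior); voxels on either center line belong to no
    quadrant. The MV wedge is an inverse pyramid (apex toward the cord
    center, widening anteriorly) of depth ``mv_depth_mm`` and base
    half-width ``mv_halfwidth_base_mm``, carved out of the ventral
    sectors; its exact vertices are free parameters of the atlas.
    """
    cx, cy = geom.config.center
    ci, cj = int(round(cx)), int(round(cy))
    nx, ny, nz = geom.grid_shape
    dx, dy, _ = geom.voxel_size_mm
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    code = np.zeros(geom.grid_shape, dtype=np.int8)
    cord = geom.cord_mask
    right = ii < ci
    left = ii > ci
    ventral = jj < cj
    dorsal = jj > cj
    gap = (ii == ci) | (jj == cj)
    for name, sel in (("RV", right & ventral), ("RD", right & dorsal),
                      ("LV", left & ventral), ("LD", left & dorsal)):
        code[cord & (sel & ~gap)[:, :, None]] = SECTORS.index(name) + 1

    # medioventral inverse pyramid: per slice, from the anterior cord edge
    # inward, half-width shrinking linearly from base to apex
    xm = (ii - cx) * dx
    for z in range(nz):
        cord_z = cord[:, :, z]
        if not cord_z.any():
            continue
        j_front = np.flatnonzero(cord_z.any(axis=0)).min()
        depth_vox = mv_depth_mm / dy
        # the wedge never reaches the center line (stays strictly anterior)
        j_stop = min(int(np.ceil(j_front + depth_vox)), ny, int(np.ceil(cy)))
        for j in range(j_front, j_stop):
            frac = 1.0 - (j - j_front) / max(depth_vox, 1e-9)  # 1 at base
            hw = mv_halfwidth_base_mm * frac
            sel = cord_z[:, j] & (np.abs(xm[:, j]) <= hw)
            code[sel, j, z] = SECTORS.index("MV") + 1

    return RoiAtlas(
        sector_of_voxel=code,
        level_of_slice=dict(geom.level_of_slice),
        center_row=ci,
        center_col=cj,
    )


def two_landmark_align(
    subject_lse: float,
    subject_tip: float,
    template_lse: float,
    template_tip: float,
):
    """1-D slice mapping sending (tip, LSE) onto the template landmarks.

    Returns a monotone piecewise-linear function subject-slice ->
    template-slice (a single affine map through both landmark pairs,
    extrapolated linearly). Raises on coincident landmarks.
    """
    if subject_tip >= subject_lse or template_tip >= template_lse:
        raise ValueError("tip must lie caudal to (below) the LSE landmark")
    slope = (template_lse - template_tip) / (subject_lse - subject_tip)

    def mapping(z):
        return template_tip + (np.asarray(z, dtype=float) - subject_tip) * slope

    return mapping


def activity_stats(
    tmap: np.ndarray,
    p_fwe: np.ndarray,
    atlas: RoiAtlas,
    thresholds=(0.05, 0.01, 0.001),
    levels=LEVELS,
) -> pd.DataFrame:
    """Mean t and suprathreshold voxel ratio per sector and per level.

    Sectors are evaluated over the pooled L3-S2 slab, levels over the
    whole cross-section, at each FWE threshold. Empty regions yield NaN.
    """
    rows = []
    slab = atlas.level_mask(levels)
    for name in SECTORS:
        region = atlas.sector_mask(name) & slab
        rows.append(("sector", name, region))
    cord = atlas.sector_of_voxel > 0
    for lv in levels:
        rows.append(("level", lv, cord & atlas.level_mask(lv)))

    records = []
    for kind, name, region in rows:
        nvox = int(region.sum())
        rec = {"kind": kind, "name": name, "n_voxels": nvox}
        if nvox:
            vals = tmap[region]
            rec["mean_t"] = float(np.nanmean(vals))
            for a in thresholds:
                rec[f"ratio_p{a}"] = float(np.mean(p_fwe[region] < a))
        else:
            rec["mean_t"] = np.nan
            for a in thresholds:
                rec[f"ratio_p{a}"] = np.nan
        records.append(rec)
    return pd.DataFrame(records)


def effect_size(
    stats: RunStats,
    roi_mask: np.ndarray,
    paradigm: BlockParadigm,
    tr_ms: float,
    n_transient: int = 3,
) -> tuple[float, dict]:
    """Percentage BOLD signal difference between motion and rest blocks.

    The denoised series is rebuilt as beta1 * c1(t) + mean + residuals
    (c1 the canonical task regressor as fitted), averaged within the ROI,
    split into blocks by volume start time, with the first
    ``n_transient`` volumes of every block dropped to skip hemodynamic
    transients. Returns 100 * (mean_motion - mean_rest) / mean_rest and
    the block-mean traces.
    """
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    n = stats.residuals.shape[3]
    c1 = stats.task_regressors[:, 0]
    denoised = (
        stats.beta1[..., None] * c1[None, None, None, :]
        + stats.mean_image[..., None]
        + stats.residuals
    )
    series = denoised[roi_mask].mean(axis=0)  # (n,)

    times = np.arange(n) * tr_ms / 1000.0
    in_paradigm = times < paradigm.total_duration_s
    block = paradigm.block_index(times)
    # index of each volume within its block
    first_of_block = np.concatenate([[0], np.flatnonzero(np.diff(block)) + 1])
    within = np.arange(n) - first_of_block[np.searchsorted(
        first_of_block, np.arange(n), side="right") - 1]
    keep = in_paradigm & (within >= n_transient)

    cond = np.array([paradigm.condition_of_block[b] for b in block])
    motion_sel = keep & (cond == MOTION)
    rest_sel = keep & (cond == REST)
    if not motion_sel.any() or not rest_sel.any():
        raise ValueError("no retained volumes in one of the block types")
    mean_motion = float(series[motion_sel].mean())
    mean_rest = float(series[rest_sel].mean())
    pct = 100.0 * (mean_motion - mean_rest) / mean_rest
    traces = {
        "motion_mean": mean_motion,
        "rest_mean": mean_rest,
        "series": series,
        "kept": keep,
    }
    return pct, traces


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B|/(|A|+|B|) of two binary maps; 0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def split_half(
    run1_copes: np.ndarray,
    run2_copes: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds=(0.05, 0.01, 0.001),
    **test_kwargs,
) -> dict:
    """Split-half reliability: independent group inference per run half,
    Dice between the thresholded maps at each FWE threshold."""
    g1 = fwe_permutation_test(run1_copes, mask, thresholds=thresholds,
                              **test_kwargs)
    g2 = fwe_permutation_test(run2_copes, mask, thresholds=thresholds,
                              **test_kwargs)
    out = {a: dice(g1.thresholded[a], g2.thresholded[a]) for a in thresholds}
    out["group1"] = g1
    out["group2"] = g2
    return out


def false_positive_rate(
    zmap: np.ndarray,
    cord_mask: np.ndarray,
    z_threshold: float = 2.3263,
) -> float:
    """Fraction of cord voxels with z above threshold (task-free runs
    analyzed with the full task model; nominal rate 1 % at z = 2.3263)."""
    vals = zmap[cord_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return 0.0
    return float(np.mean(vals > z_threshold))
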