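"""Block paradigm and acquisition arithmetic.

Everything in this module is deterministic bookkeeping around the
block-design motor task and the gradient-echo EPI acquisition: the
alternating rest/motion schedule, volume counts from run duration and TR,
the Ernst flip angle, the 3-kernel hemodynamic response basis, task
regressors sampled on the volume grid, and discrete-cosine high-pass
filtering.

Conventions
-----------
* Times are seconds unless the name says ``_ms``.
* Volume ``k`` is timestamped at ``k * TR`` (start of the slice stack);
  no slice-timing correction is applied anywhere in the package.
* The canonical HRF kernel is scaled so that the response to a single
  reference block (default 15 s) peaks at 1, making the first regressor's
  coefficient interpretable as the plateau signal change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlockParadigm",
    "HrfBasis",
    "make_block_paradigm",
    "make_hrf_basis",
    "volumes_for_run",
    "ernst_angle",
    "ernst_angle_rounded",
    "build_task_regressors",
    "boxcar_regressor",
    "highpass",
    "dct_highpass_basis",
]

REST = "rest"
MOTION = "motion"


@dataclass(frozen=True)
class BlockParadigm:
    """Alternating rest/motion block schedule, starting with rest."""

    block_duration_s: float
    condition_of_block: tuple[str, ...]

    @property
    def n_blocks(self) -> int:
        return len(self.condition_of_block)

    @property
    def n_motion_blocks(self) -> int:
        return sum(c == MOTION for c in self.condition_of_block)

    @property
    def total_duration_s(self) -> float:
        return self.block_duration_s * self.n_blocks

    def block_index(self, t: float | np.ndarray) -> np.ndarray:
        """Block containing time ``t`` (a volume belongs to the block its
        start time falls in)."""
        idx = np.floor(np.asarray(t, dtype=float) / self.block_duration_s)
        return np.clip(idx, 0, self.n_blocks - 1).astype(int)

    def boxcar(self, t: float | np.ndarray) -> np.ndarray:
        """Task indicator x(t): 1 during motion blocks, 0 during rest."""
        t = np.asarray(t, dtype=float)
        cond = np.asarray([c == MOTION for c in self.condition_of_block])
        out = np.where(
            (t >= 0) & (t < self.total_duration_s), cond[self.block_index(t)], 0
        )
        return out.astype(float)

    def events(self) -> pd.DataFrame:
        """Paradigm as an (onset, duration, condition) event table."""
        onsets = np.arange(self.n_blocks) * self.block_duration_s
        return pd.DataFrame(
            {
                "onset_s": onsets,
                "duration_s": self.block_duration_s,
                "condition": list(self.condition_of_block),
            }
        )


def make_block_paradigm(block_s: float = 15.0, n_blocks: int = 40) -> BlockParadigm:
    """Alternating rest/motion paradigm, first block rest.

    The study paradigm is 40 blocks of 15 s (20 motion, 20 rest; 600 s).
    """
    if block_s <= 0:
        raise ValueError("block duration must be positive")
    if n_blocks % 2 != 0:
        raise ValueError("n_blocks must be even for an alternating paradigm")
    conditions = tuple(REST if i % 2 == 0 else MOTION for i in range(n_blocks))
    return BlockParadigm(float(block_s), conditions)


def volumes_for_run(duration_s: float, tr_ms: float) -> int:
    """Smallest volume count N with N*TR >= run duration.

    Dummy volumes discarded by the scanner are excluded. Reproduces the
    per-sequence task (600 s) and rest (360 s) volume counts.
    """
    if duration_s <= 0 or tr_ms <= 0:
        raise ValueError("duration and TR must be positive")
    # guard against float noise on exact divisions
    return int(math.ceil(duration_s * 1000.0 / tr_ms - 1e-9))


def ernst_angle(tr_ms: float, t1_ms: float = 994.0) -> float:
    """Ernst angle acos(exp(-TR/T1)) in degrees (max spoiled GRE signal)."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    return math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))


def ernst_angle_rounded(tr_ms: float, t1_ms: float = 994.0) -> int:
    return int(round(ernst_angle(tr_ms, t1_ms)))


# ---------------------------------------------------------------------------
# Hemodynamic response basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HrfBasis:
    """Three-kernel HRF basis on a fine time grid.

    Kernel 0 is the canonical double-gamma response; kernels 1 and 2 are
    its temporal- and dispersion-derivative companions, spanning latency
    and width departures from the canonical shape. All three share the
    canonical kernel's block-response normalization.
    """

    dt: float
    kernels: np.ndarray  # (3, nt)

    @property
    def n_basis(self) -> int:
        return self.kernels.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.kernels.shape[1]) * self.dt


def _double_gamma(t: np.ndarray, peak: float, under: float, ratio: float,
                  disp: float = 1.0) -> np.ndarray:
    g1 = sps.gamma.pdf(t, peak / disp, scale=disp)
    g2 = sps.gamma.pdf(t, under / disp, scale=disp)
    return g1 - g2 / ratio


def make_hrf_basis(
    dt: float = 0.05,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 6.0,
    ref_block_s: float = 15.0,
) -> HrfBasis:
    """Canonical double-gamma + temporal and dispersion derivatives.

    The canonical kernel is scaled so the convolution of one
    ``ref_block_s`` boxcar block with it peaks at exactly 1.
    """
    t = np.arange(0.0, duration_s, dt)
    canon = _double_gamma(t, peak_delay, undershoot_delay, undershoot_ratio)
    # temporal derivative: shift sensitivity
    shift = 0.5
    tder = (canon - _double_gamma(t - shift, peak_delay, undershoot_delay,
                                  undershoot_ratio)) / shift
    # dispersion derivative: width sensitivity
    ddisp = 0.01
    dder = (canon - _double_gamma(t, peak_delay, undershoot_delay,
                                  undershoot_ratio, disp=1.0 + ddisp)) / ddisp

    block = np.ones(int(round(ref_block_s / dt)))
    scale = np.max(np.convolve(block, canon) * dt)
    kernels = np.vstack([canon, tder, dder]) / scale
    return HrfBasis(dt=float(dt), kernels=kernels)


def build_task_regressors(
    paradigm: BlockParadigm,
    basis: HrfBasis,
    tr_ms: float,
    n_volumes: int,
) -> np.ndarray:
    """Convolve the task boxcar with each basis kernel, sample at k*TR.

    Returns an (n_volumes, 3) array. Column 0 (canonical response) is the
    regressor whose coefficient defines the task>rest contrast and feeds
    the effect-size reconstruction.
    """
    tr_s = tr_ms / 1000.0
    if basis.dt >= tr_s:
        raise ValueError("basis must be sampled finer than TR")
    if n_volumes * tr_ms + 1e-6 < paradigm.total_duration_s * 1000.0:
        raise ValueError(
            f"{n_volumes} volumes at TR {tr_ms} ms do not cover the "
            f"{paradigm.total_duration_s}-s paradigm"
        )
    fine_t = np.arange(0.0, n_volumes * tr_s + basis.dt, basis.dt)
    x = paradigm.boxcar(fine_t)
    cols = np.empty((n_volumes, basis.n_basis))
    vol_idx = np.round(np.arange(n_volumes) * tr_s / basis.dt).astype(int)
    for j in range(basis.n_basis):
        conv = np.convolve(x, basis.kernels[j])[: fine_t.size] * basis.dt
        cols[:, j] = conv[vol_idx]
    return cols


def boxcar_regressor(paradigm: BlockParadigm, tr_ms: float, n_volumes: int
                     ) -> np.ndarray:
    """Unconvolved task regressor: the boxcar sampled at volume times.

    Used by the physics-validation mode, where the phantom's response is
    itself a boxcar and hemodynamic modelling is deliberately bypassed so
    closed-form signal checks are exact. Returns an (n_volumes, 1) array.
    """
    if n_volumes * tr_ms + 1e-6 < paradigm.total_duration_s * 1000.0:
        raise ValueError("volume count does not cover the paradigm")
    t = np.arange(n_volumes) * tr_ms / 1000.0
    return paradigm.boxcar(t)[:, None]


# ---------------------------------------------------------------------------
# High-pass filtering
# ---------------------------------------------------------------------------


def dct_highpass_basis(n_volumes: int, tr_ms: float, cutoff_s: float = 100.0
                       ) -> np.ndarray:
    """Orthonormal DCT-II vectors with period longer than ``cutoff_s``.

    Component k (k >= 1) has period 2*N*TR/k; components with period above
    the cutoff are the ones the high-pass removes. The constant (k = 0)
    term is excluded so filtering preserves the mean.
    """
    tr_s = tr_ms / 1000.0
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    n_k = int(math.floor(2.0 * n_volumes * tr_s / cutoff_s))
    n_k = min(n_k, n_volumes - 1)
    t = np.arange(n_volumes)
    basis = np.array(
        [np.cos(np.pi * k * (t + 0.5) / n_volumes) for k in range(1, n_k + 1)]
    ).T if n_k > 0 else np.empty((n_volumes, 0))
    if basis.size:
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass(series: np.ndarray, tr_ms: float, cutoff_s: float = 100.0
             ) -> np.ndarray:
    """Remove slow DCT components (period > cutoff) along axis 0; the mean
    is preserved. Applied identically to data and design columns."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 volumes to filter")
    basis = dct_highpass_basis(series.shape[0], tr_ms, cutoff_s)
    if basis.shape[1] == 0:
        return series.copy()
    flat = series.reshape(series.shape[0], -1)
    filtered = flat - basis @ (basis.T @ flat)
    return filtered.reshape(series.shape)
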