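"""Run-level prewhitened voxel-wise GLM and subject-level fixed effects.

Per slice the design is [3 task basis columns | slice nuisance block],
high-pass filtered identically with the data, then demeaned (the constant
is carried implicitly by the stored mean image, which the effect-size
reconstruction needs). Temporal autocorrelation is handled by voxel-wise
AR(1) prewhitening (one Cochrane-Orcutt pass: estimate rho from OLS
residuals, transform data and design, refit). The task>rest contrast is
the coefficient of the first (canonical-response) column: beta1 = COPE.
z-maps come from the two-sided quantile transform of t through the
normal. Subject-level combination is inverse-variance fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import highpass

__all__ = ["RunStats", "SubjectStats", "fit_run_glm", "fixed_effects",
           "t_to_z"]


@dataclass
class RunStats:
    """Voxel-wise run-level fit results on the full grid."""

    beta1: np.ndarray     # COPE: canonical task-regressor coefficient
    varcope: np.ndarray
    tmap: np.ndarray
    zmap: np.ndarray
    dof: np.ndarray       # per slice effective dof
    residuals: np.ndarray  # (nx, ny, nz, n), filtered-data residuals
    mean_image: np.ndarray
    task_regressors: np.ndarray  # (n, 3) filtered + demeaned, as fitted
    rho: np.ndarray       # fitted AR(1) coefficient per voxel


def t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Gaussianize t at the given dof (two-sided quantile transform)."""
    dof = max(float(dof), 1.0)
    t = np.asarray(t, dtype=float)
    # sign-symmetric mapping through the survival function, stable in the tails
    p = sps.t.sf(np.abs(t), dof)
    z = sps.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.sign(t) * z


def _ar1_coeff(resid: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation per column of an (n, nvox) residual array,
    with the standard small-sample bias correction rho + (1 + 3 rho)/n."""
    n = resid.shape[0]
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 1e-30, num / np.maximum(den, 1e-300), 0.0)
    rho = rho + (1.0 + 3.0 * rho) / n
    return np.clip(rho, -0.95, 0.95)


def fit_run_glm(
    data: np.ndarray,
    task_regressors: np.ndarray,
    nuisance=None,
    tr_ms: float = 1400.0,
    highpass_cutoff_s: float = 100.0,
    prewhiten: bool = True,
    mask: np.ndarray | None = None,
) -> RunStats:
    """Fit the voxel-wise GLM slice by slice.

    ``nuisance`` is a NuisanceSet (per-slice blocks) or None. Outlier
    volumes are handled through their spike columns rather than deletion,
    so every run keeps a common time axis. Raises if any slice design is
    rank deficient after filtering.
    """
    data = np.asarray(data, dtype=float)
    nx, ny, nz, n = data.shape
    task = np.asarray(task_regressors, dtype=float)
    if task.shape[0] != n:
        raise ValueError("task regressor length does not match volume count")
    n_task = task.shape[1]

    mean_image = data.mean(axis=3)
    beta1 = np.zeros((nx, ny, nz))
    varcope = np.zeros((nx, ny, nz))
    tmap = np.zeros((nx, ny, nz))
    zmap = np.full((nx, ny, nz), np.nan)
    rho_map = np.zeros((nx, ny, nz))
    residuals = np.zeros((nx, ny, nz, n))
    dof = np.zeros(nz)

    task_f = highpass(task, tr_ms, highpass_cutoff_s)
    task_f = task_f - task_f.mean(axis=0)

    for z in range(nz):
        block = None
        if nuisance is not None:
            block = nuisance.blocks[z]
            if block.shape[0] != n:
                raise ValueError("nuisance block length mismatch")
        if block is not None and block.size:
            block_f = highpass(block, tr_ms, highpass_cutoff_s)
            # spike columns stay one-hot; only smooth regressors are demeaned
            spike_like = (np.abs(block) > 0).sum(axis=0) == 1
            block_f[:, ~spike_like] -= block_f[:, ~spike_like].mean(axis=0)
            x = np.hstack([task_f, block_f])
        else:
            x = task_f
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            raise ValueError(
                f"rank-deficient design on slice {z}: rank {rank} < "
                f"{x.shape[1]} columns"
            )

        if mask is not None:
            sel2d = mask[:, :, z]
            if not sel2d.any():
                dof[z] = n - rank
                continue
        else:
            sel2d = np.ones((nx, ny), dtype=bool)
        y = data[:, :, z, :][sel2d].T  # (n, nvox)
        y = highpass(y, tr_ms, highpass_cutoff_s)
        y_mean = y.mean(axis=0)
        yc = y - y_mean

        pinv = np.linalg.pinv(x)
        beta = pinv @ yc
        resid = yc - x @ beta
        dof_z = n - rank - _n_filter_dims(n, tr_ms, highpass_cutoff_s) - 1
        dof_z = max(dof_z, 1)

        if prewhiten:
            rho = _ar1_coeff(resid)
            # voxel-wise Cochrane-Orcutt transform of data and design
            yw = yc[1:] - rho[None, :] * yc[:-1]
            scale0 = np.sqrt(1.0 - rho**2)
            yw = np.vstack([yc[:1] * scale0[None, :], yw])
            nvox = yc.shape[1]
            p = x.shape[1]
            xw = np.empty((nvox, n, p))
            xw[:, 1:, :] = x[None, 1:, :] - rho[:, None, None] * x[None, :-1, :]
            xw[:, 0, :] = scale0[:, None] * x[None, 0, :]
            xtx = np.einsum("vnp,vnq->vpq", xw, xw)
            xty = np.einsum("vnp,nv->vp", xw, yw)
            beta_w = np.linalg.solve(xtx, xty[..., None])[..., 0]  # (nvox, p)
            resid_w = yw - np.einsum("vnp,vp->nv", xw, beta_w)
            sigma2 = np.sum(resid_w**2, axis=0) / dof_z
            xtx_inv = np.linalg.inv(xtx)
            var_b1 = sigma2 * xtx_inv[:, 0, 0]
            b1 = beta_w[:, 0]
            resid_out = yc - np.einsum("np,vp->nv", x, beta_w)
        else:
            rho = np.zeros(yc.shape[1])
            sigma2 = np.sum(resid**2, axis=0) / dof_z
            xtx_inv = np.linalg.inv(x.T @ x)
            var_b1 = sigma2 * xtx_inv[0, 0]
            b1 = beta[0]
            resid_out = resid

        with np.errstate(invalid="ignore", divide="ignore"):
            tvals = np.where(var_b1 > 1e-300, b1 / np.sqrt(var_b1), 0.0)
        zvals = t_to_z(tvals, dof_z)
        zvals = np.where(var_b1 > 1e-300, zvals, np.nan)

        beta1[:, :, z][sel2d] = b1
        varcope[:, :, z][sel2d] = var_b1
        tmap[:, :, z][sel2d] = tvals
        zmap[:, :, z][sel2d] = zvals
        rho_map[:, :, z][sel2d] = rho
        residuals[:, :, z, :][sel2d] = resid_out.T
        dof[z] = dof_z

    return RunStats(
        beta1=beta1, varcope=varcope, tmap=tmap, zmap=zmap, dof=dof,
        residuals=residuals, mean_image=mean_image,
        task_regressors=task_f[:, :n_task], rho=rho_map,
    )


def _n_filter_dims(n: int, tr_ms: float, cutoff_s: float) -> int:
    from .design import dct_highpass_basis

    return dct_highpass_basis(n, tr_ms, cutoff_s).shape[1]


@dataclass
class SubjectStats:
    cope: np.ndarray
    varcope: np.ndarray
    zmap: np.ndarray
    valid: np.ndarray  # voxels with positive varcope in every run


def fixed_effects(run_stats: list[RunStats]) -> SubjectStats:
    """Inverse-variance fixed-effects combination of run-level COPEs.

    cope = sum(c_i/v_i) / sum(1/v_i), varcope = 1 / sum(1/v_i). Voxels
    with non-positive varcope in any run are masked. With equal run
    variances this reduces to the arithmetic mean of the run copes.
    """
    if not run_stats:
        raise ValueError("need at least one run")
    copes = np.stack([r.beta1 for r in run_stats])
    varcopes = np.stack([r.varcope for r in run_stats])
    valid = np.all(varcopes > 1e-300, axis=0)
    w = np.zeros_like(varcopes)
    w[:, valid] = 1.0 / varcopes[:, valid]
    wsum = w.sum(axis=0)
    cope = np.zeros_like(wsum)
    var = np.full_like(wsum, np.nan)
    cope[valid] = (w * copes).sum(axis=0)[valid] / wsum[valid]
    var[valid] = 1.0 / wsum[valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        zmap = np.where(valid, cope / np.sqrt(var), np.nan)
    return SubjectStats(cope=cope, varcope=var, zmap=zmap, valid=valid)
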