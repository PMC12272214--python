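"""End-to-end orchestration of the run / subject / group analysis.

Thin glue over the library modules so the analysis scripts, the tests and
the acceptance checks all exercise the same code path:

run level      motion correction (volume- then slice-wise) -> DVARS
               outliers -> smoothing -> slice-wise aCompCor -> prewhitened
               GLM with the 3-basis task design
subject level  inverse-variance fixed effects over task runs
group level    sign-flip max-TFCE permutation test on subject COPEs
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import design, glm, inference, nuisance, preprocess
from .phantom import EpiRun, PhantomGeometry

__all__ = ["RunLevelOptions", "process_task_run", "subject_level",
           "group_level", "eroded_csf"]


@dataclass
class RunLevelOptions:
    do_moco: bool = True
    moco_dof: int = 3           # 6 available; translations dominate here
    do_slice_moco: bool = True
    slice_lambda: float = 1.0
    do_smooth: bool = True
    smooth_fwhm_mm: tuple = (1.0, 1.0, 5.0)
    do_acompcor: bool = True
    n_components: int = 5
    prewhiten: bool = True
    highpass_cutoff_s: float = 100.0
    fit_mask: np.ndarray | None = None  # restrict the voxel fit (speed)
    task_model: str = "hrf"  # "hrf": 3-basis design; "boxcar": physics mode
    hrf_basis: design.HrfBasis = field(default_factory=design.make_hrf_basis)


def eroded_csf(geom: PhantomGeometry) -> np.ndarray:
    """CSF noise ROI: the true CSF mask eroded by one voxel in-plane,
    excluding the CSF-cord interface."""
    out = np.zeros_like(geom.csf_mask)
    footprint = ndimage.generate_binary_structure(2, 1)
    for z in range(geom.csf_mask.shape[2]):
        out[:, :, z] = ndimage.binary_erosion(geom.csf_mask[:, :, z],
                                              footprint)
    return out


@dataclass
class RunLevelResult:
    stats: glm.RunStats
    motion_volume: preprocess.MotionEstimate | None
    motion_slice: preprocess.MotionEstimate | None
    outliers: preprocess.OutlierReport
    keep: bool


def process_task_run(
    run: EpiRun,
    geom: PhantomGeometry,
    options: RunLevelOptions | None = None,
) -> RunLevelResult:
    """Full run-level analysis of one task run."""
    if run.paradigm is None:
        raise ValueError("task run must carry a paradigm")
    opt = options or RunLevelOptions()
    data = np.asarray(run.data, dtype=float)
    vs = run.voxel_size_mm

    est_vol = est_slice = None
    if opt.do_moco:
        centerline = preprocess.cord_centerline(geom.cord_mask)
        cyl = preprocess.cylindrical_mask(centerline, geom.grid_shape, vs,
                                          radius_mm=20.0)
        est_vol, data = preprocess.moco_volume(data, vs, mask=cyl,
                                               dof=opt.moco_dof)
        if opt.do_slice_moco:
            est_slice, data = preprocess.moco_slice(data, cyl, vs,
                                                    lam=opt.slice_lambda)

    d = preprocess.dvars(data, geom.cord_mask)
    report = preprocess.flag_outliers(d, n_volumes=data.shape[3])
    keep = preprocess.exclude_run(report)

    if opt.do_smooth:
        data = preprocess.smooth(data, vs, opt.smooth_fwhm_mm)

    nuis = None
    if opt.do_acompcor:
        comps = nuisance.acompcor(data, eroded_csf(geom),
                                  n_components=opt.n_components)
        slice_motion = est_slice.slice_params if est_slice is not None else None
        nuis = nuisance.assemble_nuisance(
            comps, slice_motion, report.outlier_volumes,
            n_volumes=data.shape[3],
        )

    if opt.task_model == "boxcar":
        task = design.boxcar_regressor(run.paradigm, run.seq.tr_ms,
                                       data.shape[3])
    else:
        task = design.build_task_regressors(
            run.paradigm, opt.hrf_basis, run.seq.tr_ms, data.shape[3]
        )
    stats = glm.fit_run_glm(
        data, task, nuisance=nuis, tr_ms=run.seq.tr_ms,
        highpass_cutoff_s=opt.highpass_cutoff_s, prewhiten=opt.prewhiten,
        mask=opt.fit_mask,
    )
    return RunLevelResult(stats=stats, motion_volume=est_vol,
                          motion_slice=est_slice, outliers=report, keep=keep)


def subject_level(run_results) -> glm.SubjectStats:
    """Fixed-effects combination of the retained task runs of one subject."""
    stats = [r.stats for r in run_results if r.keep]
    if not stats:
        raise ValueError("all runs of this subject were excluded")
    return glm.fixed_effects(stats)


def group_level(
    subject_copes: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 5.0),
    **kwargs,
) -> inference.GroupResult:
    return inference.fwe_permutation_test(
        subject_copes, mask, voxel_size_mm=voxel_size_mm, **kwargs
    )
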