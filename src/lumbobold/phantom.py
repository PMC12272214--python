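"""Synthetic lumbosacral spinal-cord EPI phantom.

Generates 4D gradient-echo EPI sessions with known ground truth: a tapered
cord cylinder with a butterfly-shaped gray-matter core and a CSF ring,
four sequence presets differing in TE/TR/flip angle/partial Fourier, a
block-design task response injected as a reduction of R2* in the
right-ventral gray matter, an optional medioventral "large-vein"
compartment whose effective dR2* falls off as 1/TE, respiratory noise
shared between CSF and cord, signal drift, rigid and slice-wise motion,
spike volumes, and thermal noise.

Axis conventions (fixed throughout the package)
-----------------------------------------------
* axis 0 (``i``/x): right -> left (low index = subject's right)
* axis 1 (``j``/y): anterior -> posterior (low index = ventral); the EPI
  phase-encode direction, so partial-Fourier smoothing acts along it
* axis 2 (``z``): caudal -> rostral (slice 0 is the most caudal)

Steady-state signal model (spoiled GRE)::

    S = S0 * sin(FA) (1 - e)/(1 - cos(FA) e) * exp(-TE * R2*(t)),
    e = exp(-TR/T1),   R2*(t) = 1/T2* - dR2* x(t)

with TE, TR, T1, T2* in ms, dR2* converted from 1/s, and x(t) in [0, 1]
the task response (boxcar or HRF-convolved boxcar) sampled at volume
start times. Task engagement lowers R2*, raising the signal by the factor
exp(TE * dR2* * x) — at TE 42 ms and dR2* 0.1377 /s a plateau change of
exp(0.042 * 0.1377) - 1 = +0.580 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import design as _design
from .design import BlockParadigm, make_block_paradigm, make_hrf_basis

__all__ = [
    "GeometryConfig",
    "PhantomGeometry",
    "SequenceSpec",
    "TissueParams",
    "ActivationSpec",
    "NoiseSpec",
    "EpiRun",
    "PhantomTruth",
    "SessionConfig",
    "SEQUENCES",
    "build_geometry",
    "right_ventral_target",
    "simulate_run",
    "simulate_session",
    "steady_state_factor",
]

LEVELS = ("L3", "L4", "L5", "S1", "S2")


# ---------------------------------------------------------------------------
# Sequence presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceSpec:
    """One EPI sequence variant (TE/TR/FA/partial Fourier/volume counts)."""

    name: str
    te_ms: float
    tr_ms: float
    fa_deg: float
    partial_fourier: float  # 6/8, 7/8 or 1.0
    n_volumes_task: int
    n_volumes_rest: int

    def __post_init__(self):
        if self.te_ms <= 0 or self.tr_ms <= 0:
            raise ValueError("TE and TR must be positive")
        if not 0 < self.fa_deg <= 90:
            raise ValueError("flip angle must be in (0, 90] degrees")


def _preset(name: str, te: float, tr: float, pf: float) -> SequenceSpec:
    return SequenceSpec(
        name=name,
        te_ms=te,
        tr_ms=tr,
        fa_deg=_design.ernst_angle_rounded(tr),
        partial_fourier=pf,
        n_volumes_task=_design.volumes_for_run(600.0, tr),
        n_volumes_rest=_design.volumes_for_run(360.0, tr),
    )


#: The four shipped acquisition variants. Flip angles are Ernst angles for
#: T1 = 994 ms; volume counts follow from the 600-s task / 360-s rest runs.
SEQUENCES: dict[str, SequenceSpec] = {
    "OVS20": _preset("OVS20", 20.0, 1460.0, 6 / 8),
    "iFOV28": _preset("iFOV28", 28.0, 1190.0, 6 / 8),
    "iFOV35": _preset("iFOV35", 35.0, 1290.0, 7 / 8),
    "iFOV42": _preset("iFOV42", 42.0, 1400.0, 1.0),
}


def steady_state_factor(fa_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Spoiled steady-state factor sin(FA)(1-e)/(1-cos(FA)e), e=exp(-TR/T1)."""
    e = math.exp(-tr_ms / t1_ms)
    fa = math.radians(fa_deg)
    return math.sin(fa) * (1.0 - e) / (1.0 - math.cos(fa) * e)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryConfig:
    grid_shape: tuple[int, int, int] = (48, 48, 15)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    center: tuple[float, float] = (24.0, 24.0)  # voxel coords of cord axis
    cord_radius_mm: float = 4.0     # at the LSE landmark slice
    tip_radius_mm: float = 1.6      # conus taper endpoint
    top_radius_mm: float = 3.4      # most rostral slice
    lse_slice_index: int = 9
    tip_slice_index: int = 1
    csf_gap_mm: float = 0.5
    csf_thickness_mm: float = 3.0
    vein_halfwidth_mm: float = 0.6
    vein_depth_mm: float = 2.0


@dataclass(frozen=True)
class PhantomGeometry:
    """Tissue masks and landmarks of the synthetic cord."""

    config: GeometryConfig
    cord_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    vein_mask: np.ndarray
    lse_slice_index: int
    tip_slice_index: int
    level_of_slice: dict[int, str | None]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.config.grid_shape

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.config.voxel_size_mm

    def slices_of_levels(self, levels) -> list[int]:
        return [z for z, lv in self.level_of_slice.items() if lv in set(levels)]


def _radius_profile(cfg: GeometryConfig) -> np.ndarray:
    nz = cfg.grid_shape[2]
    r = np.zeros(nz)
    tip, lse = cfg.tip_slice_index, cfg.lse_slice_index
    for z in range(tip, lse + 1):
        f = (z - tip) / max(lse - tip, 1)
        r[z] = cfg.tip_radius_mm + f * (cfg.cord_radius_mm - cfg.tip_radius_mm)
    for z in range(lse + 1, nz):
        f = (z - lse) / max(nz - 1 - lse, 1)
        r[z] = cfg.cord_radius_mm + f * (cfg.top_radius_mm - cfg.cord_radius_mm)
    return r


def build_geometry(config: GeometryConfig | None = None) -> PhantomGeometry:
    """Deterministic cord/GM/WM/CSF/vein masks from a geometry config.

    The cord is a circular cylinder whose radius tapers caudally to the
    conus tip and is maximal at the LSE landmark slice. Gray matter is a
    butterfly (four horn disks plus a central commissure) scaled with the
    local cord radius; CSF is an annulus separated from the cord by a gap;
    the vein compartment sits on the anterior midline inside the cord.
    """
    cfg = config or GeometryConfig()
    nx, ny, nz = cfg.grid_shape
    dx, dy, _ = cfg.voxel_size_mm
    cx, cy = cfg.center
    outer = cfg.cord_radius_mm + cfg.csf_gap_mm + cfg.csf_thickness_mm
    if outer >= min(cx * dx, cy * dy, (nx - 1 - cx) * dx, (ny - 1 - cy) * dy):
        raise ValueError("cord + CSF ring does not fit inside the grid")
    if cfg.tip_radius_mm <= 0 or cfg.cord_radius_mm < max(
        cfg.tip_radius_mm, cfg.top_radius_mm
    ):
        raise ValueError("radii must taper away from the LSE slice")

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xm = (ii - cx) * dx  # mm, + = left
    ym = (jj - cy) * dy  # mm, + = posterior/dorsal
    dist = np.hypot(xm, ym)

    radii = _radius_profile(cfg)
    cord = np.zeros(cfg.grid_shape, dtype=bool)
    gm = np.zeros_like(cord)
    csf = np.zeros_like(cord)
    vein = np.zeros_like(cord)

    for z in range(nz):
        r = radii[z]
        if r <= 0:
            continue
        cord_z = dist <= r
        cord[:, :, z] = cord_z
        csf[:, :, z] = (dist > r + cfg.csf_gap_mm) & (
            dist <= r + cfg.csf_gap_mm + cfg.csf_thickness_mm
        )
        s = r / cfg.cord_radius_mm
        gm_z = np.zeros_like(cord_z)
        # ventral (anterior, -y) and dorsal (+y) horn disks + commissure
        for hx, hy, hr in (
            (1.6, -1.0, 1.4), (-1.6, -1.0, 1.4),
            (1.1, 1.6, 1.1), (-1.1, 1.6, 1.1),
        ):
            gm_z |= np.hypot(xm - hx * s, ym - hy * s) <= hr * s
        gm_z |= (np.abs(xm) <= 0.6 * s) & (np.abs(ym) <= 1.4 * s)
        gm[:, :, z] = gm_z & cord_z
        vein[:, :, z] = (
            cord_z
            & (np.abs(xm) <= cfg.vein_halfwidth_mm)
            & (ym <= min(-(r - cfg.vein_depth_mm), -0.5))
        )

    wm = cord & ~gm
    areas = cord.sum(axis=(0, 1))
    if areas[cfg.lse_slice_index] < areas.max():
        raise ValueError("cord area is not maximal at the LSE slice")

    level_of_slice: dict[int, str | None] = {z: None for z in range(nz)}
    cord_slices = list(range(cfg.tip_slice_index, nz))
    # rostral slices -> L3, caudal -> S2
    groups = np.array_split(cord_slices[::-1], len(LEVELS))
    for label, grp in zip(LEVELS, groups):
        for z in grp:
            level_of_slice[int(z)] = label

    return PhantomGeometry(
        config=cfg,
        cord_mask=cord,
        gm_mask=gm,
        wm_mask=wm,
        csf_mask=csf,
        vein_mask=vein,
        lse_slice_index=cfg.lse_slice_index,
        tip_slice_index=cfg.tip_slice_index,
        level_of_slice=level_of_slice,
    )


# ---------------------------------------------------------------------------
# Tissue / activation / noise specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Proton-density-weighted baseline signal and relaxation times.

    The gray-matter T2* default (41.3 ms) is a cervical-cord literature
    value; no lumbosacral measurement exists, so it is an assumption of
    the phantom. T1 = 994 ms matches the value used for the Ernst-angle
    calculation.
    """

    s0: dict = field(
        default_factory=lambda: {
            "gm": 1000.0, "wm": 880.0, "csf": 1300.0, "background": 30.0
        }
    )
    t2star_ms: dict = field(
        default_factory=lambda: {
            "gm": 41.3, "wm": 38.0, "csf": 120.0, "background": 25.0
        }
    )
    t1_ms: float = 994.0

    def __post_init__(self):
        if any(v <= 0 for v in self.s0.values()) or self.t1_ms <= 0:
            raise ValueError("signal and relaxation parameters must be positive")
        if self.t2star_ms["csf"] <= self.t2star_ms["gm"]:
            raise ValueError("CSF T2* must exceed gray-matter T2*")


@dataclass(frozen=True)
class ActivationSpec:
    """Task-related dR2* injection.

    ``delta_r2star`` (1/s) is subtracted from R2* in ``target_mask``
    scaled by the response x(t). The vein compartment receives an
    effective dR2*_vein(TE) = 1000 * vein_k / TE^2 (1/s, TE in ms), so
    the resulting fractional plateau contrast is approximately
    vein_k / TE_ms — stronger at shorter TE, emulating the large-vein
    drainage effect. vein_k = 0 disables the compartment.
    """

    target_mask: np.ndarray
    delta_r2star: float  # 1/s
    vein_k: float = 0.0  # (1/s) * ms -> dR2*_vein = vein_k / TE_ms
    response_model: str = "hrf"  # "hrf" | "boxcar"

    def __post_init__(self):
        if self.delta_r2star < 0 or self.vein_k < 0:
            raise ValueError("activation amplitudes must be non-negative")
        if self.response_model not in ("hrf", "boxcar"):
            raise ValueError("response_model must be 'hrf' or 'boxcar'")


def right_ventral_target(geom: PhantomGeometry,
                         levels=("L3", "L4", "L5", "S1", "S2")) -> np.ndarray:
    """Default activation site: right-ventral gray matter on L3-S2 slabs."""
    cx, cy = geom.config.center
    nx, ny, nz = geom.grid_shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    quadrant = (ii < cx) & (jj < cy)  # right (low i) and ventral (low j)
    mask = geom.gm_mask & quadrant[:, :, None]
    keep = np.zeros(nz, dtype=bool)
    keep[geom.slices_of_levels(levels)] = True
    return mask & keep[None, None, :]


@dataclass(frozen=True)
class NoiseSpec:
    """Artifact model of one run.

    Respiratory noise is an amplitude-modulated sinusoid (default
    0.25 Hz) with a slow random-walk phase jitter; its amplitude grows
    rostrally (slices closer to the lungs). A fraction
    ``csf_shared_fraction`` of the cord's respiratory component is common
    with the CSF, which is what makes CSF-derived aCompCor regressors
    effective. Rigid motion is a per-volume 6-parameter trajectory;
    ``slice_shift_rostral_mm`` adds a respiration-locked per-slice
    y-translation ramp (zero caudally, maximal rostrally). Spike volumes
    are multiplicative intensity bursts.
    """

    thermal_sd: float = 30.0
    resp_freq_hz: float = 0.25
    resp_amp_caudal: float = 2.0   # signal units, most caudal slice
    resp_amp_rostral: float = 6.0  # signal units, most rostral slice
    resp_phase_jitter: float = 0.15  # rad, per-volume random-walk step
    cord_resp_gain: float = 0.5    # cord amplitude relative to CSF
    csf_shared_fraction: float = 0.7
    drift_per_minute: float = 0.002  # fractional signal drift
    motion_volume: np.ndarray | None = None  # (n, 6): tx ty tz mm, rx ry rz deg
    slice_shift_rostral_mm: float = 0.0
    spike_volumes: tuple[int, ...] = ()
    spike_factor: float = 1.3
    seed: int = 0

    def __post_init__(self):
        for name in ("thermal_sd", "resp_amp_caudal", "resp_amp_rostral",
                     "cord_resp_gain", "slice_shift_rostral_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.csf_shared_fraction <= 1:
            raise ValueError("csf_shared_fraction must lie in [0, 1]")


#: Noise-free specification, used by the closed-form physics checks.
QUIET = NoiseSpec(
    thermal_sd=0.0, resp_amp_caudal=0.0, resp_amp_rostral=0.0,
    drift_per_minute=0.0, slice_shift_rostral_mm=0.0,
)


# ---------------------------------------------------------------------------
# Run containers
# ---------------------------------------------------------------------------


@dataclass
class EpiRun:
    """One 4D EPI time series plus acquisition metadata."""

    data: np.ndarray  # (nx, ny, nz, n_volumes) float32
    seq: SequenceSpec
    paradigm: BlockParadigm | None
    voxel_size_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.seq.tr_ms / 1000.0


@dataclass
class PhantomTruth:
    """Ground-truth record of every injected parameter of a simulated run."""

    geometry: PhantomGeometry
    seq: SequenceSpec
    tissue: TissueParams
    activation: ActivationSpec | None
    noise: NoiseSpec
    response: np.ndarray          # x(t) at volume times
    motion_volume: np.ndarray     # (n, 6) applied rigid parameters
    slice_dy_mm: np.ndarray       # (n, nz) applied slice-wise y-shifts
    seed: int


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_PF_FWHM_VOX = ((6 / 8, 1.5), (7 / 8, 1.2))


def _pf_sigma(partial_fourier: float) -> float:
    for pf, fwhm in _PF_FWHM_VOX:
        if abs(partial_fourier - pf) < 1e-9:
            return fwhm / 2.3548
    return 0.0


def _tissue_maps(geom: PhantomGeometry, tissue: TissueParams):
    shape = geom.grid_shape
    s0 = np.full(shape, tissue.s0["background"])
    t2 = np.full(shape, tissue.t2star_ms["background"])
    for name, mask in (("csf", geom.csf_mask), ("wm", geom.wm_mask),
                       ("gm", geom.gm_mask)):
        s0[mask] = tissue.s0[name]
        t2[mask] = tissue.t2star_ms[name]
    return s0, t2


def _response_series(activation, paradigm, seq, times_s):
    if paradigm is None:
        return np.zeros(times_s.size)
    if activation is not None and activation.response_model == "hrf":
        # canonical response, unit plateau; transient dips below zero
        # mirror the post-stimulus undershoot
        basis = make_hrf_basis()
        cols = _design.build_task_regressors(
            paradigm, basis, seq.tr_ms, times_s.size
        )
        return cols[:, 0]
    return paradigm.boxcar(times_s)


def _apply_rigid_volume(vol, params, voxel_size):
    """Apply a rigid transform (mm translations, deg rotations) to one volume."""
    tx, ty, tz, rx, ry, rz = params
    if not np.any(np.asarray(params)):
        return vol
    vs = np.asarray(voxel_size, dtype=float)
    if not (rx or ry or rz):
        return ndimage.shift(vol, np.array([tx, ty, tz]) / vs, order=1,
                             mode="nearest")
    ax, ay, az = np.radians([rx, ry, rz])
    rxm = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                    [0, np.sin(ax), np.cos(ax)]])
    rym = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                    [-np.sin(ay), 0, np.cos(ay)]])
    rzm = np.array([[np.cos(az), -np.sin(az), 0],
                    [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    rot = rzm @ rym @ rxm
    center = (np.array(vol.shape) - 1) / 2.0 * vs
    # output voxel o -> input voxel: undo translation, rotate back about center
    m = np.diag(1.0 / vs) @ rot.T @ np.diag(vs)
    offset = np.diag(1.0 / vs) @ (
        rot.T @ (-center - np.array([tx, ty, tz])) + center
    )
    return ndimage.affine_transform(vol, m, offset=offset, order=1,
                                    mode="nearest")


def simulate_run(
    geom: PhantomGeometry,
    seq: SequenceSpec,
    tissue: TissueParams | None = None,
    activation: ActivationSpec | None = None,
    noise: NoiseSpec | None = None,
    paradigm: BlockParadigm | None = None,
    n_volumes: int | None = None,
) -> tuple[EpiRun, PhantomTruth]:
    """Simulate one EPI run. Identical seeds give bitwise-identical output.

    A task run passes a paradigm (volume count must cover its duration);
    a rest run passes ``paradigm=None``. All randomness flows from
    ``noise.seed`` through a single SeedSequence split into named streams
    (respiration, thermal, spare), so individual artifact components can
    be toggled without perturbing the others.
    """
    tissue = tissue or TissueParams()
    noise = noise or NoiseSpec()
    if n_volumes is None:
        n_volumes = seq.n_volumes_task if paradigm is not None else seq.n_volumes_rest
    if paradigm is not None and n_volumes * seq.tr_ms + 1e-6 < (
        paradigm.total_duration_s * 1000.0
    ):
        raise ValueError("volume count does not cover the paradigm duration")
    if any(v < 0 or v >= n_volumes for v in noise.spike_volumes):
        raise ValueError("spike volume indices out of range")

    nx, ny, nz = geom.grid_shape
    tr_s = seq.tr_ms / 1000.0
    times = np.arange(n_volumes) * tr_s
    x = _response_series(activation, paradigm, seq, times)

    s0, t2 = _tissue_maps(geom, tissue)
    r2s_ms = 1.0 / t2  # 1/ms
    delta_ms = np.zeros(geom.grid_shape)
    if activation is not None:
        if np.any(activation.target_mask & ~geom.cord_mask):
            raise ValueError("activation target must lie inside the cord")
        delta_ms[activation.target_mask] += activation.delta_r2star / 1000.0
        if activation.vein_k > 0:
            delta_ms[geom.vein_mask] += activation.vein_k / seq.te_ms**2
    if np.any(delta_ms * x.max() >= r2s_ms):
        raise ValueError("activation would drive R2* negative")

    e_ss = steady_state_factor(seq.fa_deg, seq.tr_ms, tissue.t1_ms)
    base = s0 * e_ss * np.exp(-seq.te_ms * r2s_ms)

    data = np.repeat(base[:, :, :, None], n_volumes, axis=3)
    active = delta_ms > 0
    if np.any(active) and np.any(x):
        data[active] *= np.exp(np.outer(delta_ms[active] * seq.te_ms, x))

    ss = np.random.SeedSequence(noise.seed)
    rng_resp, rng_thermal, _rng_spare = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    # respiratory component: shared + tissue-specific sinusoids
    if noise.resp_amp_caudal > 0 or noise.resp_amp_rostral > 0:
        def resp_wave():
            # independently phase-jittered sinusoid per component, so the
            # common and tissue-specific parts decorrelate over the run
            jitter = np.cumsum(
                rng_resp.normal(0.0, noise.resp_phase_jitter, n_volumes)
            )
            phase = 2 * np.pi * noise.resp_freq_hz * times + jitter
            return np.sin(phase + rng_resp.uniform(0, 2 * np.pi))

        common, own_csf, own_cord = resp_wave(), resp_wave(), resp_wave()
        s = noise.csf_shared_fraction
        amp_z = np.linspace(noise.resp_amp_caudal, noise.resp_amp_rostral, nz)
        csf_t = s * common + (1 - s) * own_csf
        cord_t = noise.cord_resp_gain * (s * common + (1 - s) * own_cord)
        resp = (
            geom.csf_mask[..., None] * csf_t[None, None, None, :]
            + geom.cord_mask[..., None] * cord_t[None, None, None, :]
        ) * amp_z[None, None, :, None]
        data += resp

    if noise.drift_per_minute:
        data *= 1.0 + noise.drift_per_minute * (times / 60.0)

    # motion: per-volume rigid + respiration-locked slice-wise y ramp
    motion = (
        np.zeros((n_volumes, 6))
        if noise.motion_volume is None
        else np.asarray(noise.motion_volume, dtype=float)
    )
    if motion.shape != (n_volumes, 6):
        raise ValueError("motion_volume must have shape (n_volumes, 6)")
    slice_dy = np.zeros((n_volumes, nz))
    if noise.slice_shift_rostral_mm > 0:
        mod = np.sin(2 * np.pi * noise.resp_freq_hz * times
                     + rng_resp.uniform(0, 2 * np.pi))
        ramp = np.linspace(0.0, noise.slice_shift_rostral_mm, nz)
        slice_dy = np.outer(mod, ramp)
    dy_vox = slice_dy / geom.voxel_size_mm[1]
    for t in range(n_volumes):
        vol = data[..., t]
        if np.any(motion[t]):
            vol = _apply_rigid_volume(vol, motion[t], geom.voxel_size_mm)
        if np.any(slice_dy[t]):
            vol = vol.copy() if vol is data[..., t] else vol
            for z in range(nz):
                if dy_vox[t, z]:
                    vol[:, :, z] = ndimage.shift(
                        vol[:, :, z], (0.0, dy_vox[t, z]), order=1,
                        mode="nearest",
                    )
        data[..., t] = vol

    sigma_pf = _pf_sigma(seq.partial_fourier)
    if sigma_pf > 0:
        data = ndimage.gaussian_filter1d(data, sigma_pf, axis=1, mode="nearest")

    if noise.thermal_sd > 0:
        data += rng_thermal.normal(0.0, noise.thermal_sd, data.shape)

    for k in noise.spike_volumes:
        data[..., k] *= noise.spike_factor

    run = EpiRun(
        data=data.astype(np.float32),
        seq=seq,
        paradigm=paradigm,
        voxel_size_mm=geom.voxel_size_mm,
        meta={"seed": noise.seed, "kind": "task" if paradigm is not None else "rest"},
    )
    truth = PhantomTruth(
        geometry=geom,
        seq=seq,
        tissue=tissue,
        activation=activation,
        noise=noise,
        response=x,
        motion_volume=motion,
        slice_dy_mm=slice_dy,
        seed=noise.seed,
    )
    return run, truth


# ---------------------------------------------------------------------------
# Session layout: per sequence, one rest run followed by two task runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    sequences: tuple[str, ...] = ("OVS20", "iFOV28", "iFOV35", "iFOV42")
    delta_r2star: float = 0.1377  # 1/s, calibrated to +0.580 % at TE 42 ms
    vein_k: float = 0.0
    response_model: str = "hrf"
    control: bool = False  # task-free subject: task runs carry zero activation
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    n_task_runs: int = 2
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    paradigm_block_s: float = 15.0
    paradigm_n_blocks: int = 40


def simulate_session(config: SessionConfig | None = None
                     ) -> dict[str, list[tuple[EpiRun, PhantomTruth]]]:
    """Simulate one subject's session: per sequence 1 rest + task runs.

    In control mode the task runs are acquired and analyzed with the task
    paradigm but carry zero activation (dR2* = 0), mirroring participants
    instructed not to move. Run seeds are spawned from the session seed.
    """
    cfg = config or SessionConfig()
    geom = build_geometry(cfg.geometry)
    paradigm = make_block_paradigm(cfg.paradigm_block_s, cfg.paradigm_n_blocks)
    target = right_ventral_target(geom)
    ss = np.random.SeedSequence(cfg.seed)
    out: dict[str, list[tuple[EpiRun, PhantomTruth]]] = {}
    for name in cfg.sequences:
        seq = SEQUENCES[name]
        runs = []
        n_task = _design.volumes_for_run(paradigm.total_duration_s, seq.tr_ms)
        n_rest = max(_design.volumes_for_run(
            paradigm.total_duration_s * 0.6, seq.tr_ms), 10)
        for kind in ["rest"] + ["task"] * cfg.n_task_runs:
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            noise = replace(cfg.noise, seed=child_seed)
            if kind == "task":
                act = ActivationSpec(
                    target_mask=target,
                    delta_r2star=0.0 if cfg.control else cfg.delta_r2star,
                    vein_k=cfg.vein_k,
                    response_model=cfg.response_model,
                )
                run, truth = simulate_run(
                    geom, seq, activation=act, noise=noise,
                    paradigm=paradigm, n_volumes=n_task,
                )
            else:
                run, truth = simulate_run(
                    geom, seq, noise=noise, paradigm=None, n_volumes=n_rest,
                )
            run.meta["sequence"] = name
            runs.append((run, truth))
        out[name] = runs
    return out
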