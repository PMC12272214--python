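"""Slice-wise aCompCor components and nuisance regressor assembly.

aCompCor extracts principal components of the CSF time series per slice,
under the assumptions that CSF carries no signal of interest and that its
physiological noise shares structure with the cord tissue. The retained
components (default 5 per slice, ordered by explained variance) join the
two slice-wise motion regressors and one indicator column per outlier
volume to form the per-slice nuisance block of the run-level GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["SliceComponents", "NuisanceSet", "acompcor", "assemble_nuisance"]


@dataclass
class SliceComponents:
    """Principal-component time courses of one slice's CSF region."""

    components: np.ndarray  # (n_volumes, k), unit variance, zero mean
    explained_variance: np.ndarray  # (k,), fractions, non-increasing


def acompcor(
    data: np.ndarray,
    csf_mask: np.ndarray,
    n_components: int = 5,
) -> list[SliceComponents]:
    """Per-slice principal components of the CSF voxel time series.

    Voxel series are demeaned and variance-normalized before the
    decomposition (zero-variance voxels are dropped). Slices whose CSF
    region has fewer voxels than requested components yield fewer
    components; empty slices yield zero components (logged).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[3]
    out: list[SliceComponents] = []
    for z in range(data.shape[2]):
        m = csf_mask[:, :, z]
        if not m.any():
            log.warning("aCompCor: empty CSF region on slice %d", z)
            out.append(SliceComponents(np.zeros((n, 0)), np.zeros(0)))
            continue
        series = data[:, :, z, :][m].T  # (n, nvox)
        series = series - series.mean(axis=0)
        sd = series.std(axis=0)
        keep = sd > 1e-12
        series = series[:, keep] / sd[keep]
        if series.shape[1] == 0:
            out.append(SliceComponents(np.zeros((n, 0)), np.zeros(0)))
            continue
        k = min(n_components, series.shape[1], n - 1)
        if k < n_components:
            log.info("aCompCor: slice %d yields only %d components", z, k)
        u, s, _ = np.linalg.svd(series, full_matrices=False)
        comps = u[:, :k]
        comps = comps / comps.std(axis=0, ddof=0)
        evr = (s**2 / np.sum(s**2))[:k]
        out.append(SliceComponents(comps, evr))
    return out


@dataclass
class NuisanceSet:
    """Per-slice nuisance design blocks: 5 PCs + 2 motion + spike columns."""

    blocks: list[np.ndarray]  # per slice, (n_volumes, p_z)
    labels: list[list[str]]
    outlier_volumes: tuple[int, ...]


def _drop_collinear(x: np.ndarray, labels: list[str], tol: float = 1e-8
                    ) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.linalg.norm(col) < tol:
            log.warning("dropping null nuisance column %s", labels[j])
            continue
        if keep:
            q, _ = np.linalg.qr(x[:, keep])
            resid = col - q @ (q.T @ col)
        else:
            resid = col
        if np.linalg.norm(resid) < tol * max(np.linalg.norm(col), 1.0):
            log.warning("dropping collinear nuisance column %s", labels[j])
            continue
        keep.append(j)
    return x[:, keep], [labels[j] for j in keep]


def assemble_nuisance(
    components: list[SliceComponents],
    slice_motion: np.ndarray | None,
    outlier_volumes=(),
    n_volumes: int | None = None,
) -> NuisanceSet:
    """Assemble the per-slice nuisance block.

    ``slice_motion`` is the (n, nz, 2) slice-wise (dx, dy) estimate from
    motion correction (None for zero motion). PC and motion columns are
    demeaned; spike columns are one-hot indicators of outlier volumes.
    Collinear or null columns are dropped with a warning.
    """
    nz = len(components)
    if n_volumes is None:
        n_volumes = next(
            (c.components.shape[0] for c in components if c.components.size), None
        )
        if n_volumes is None and slice_motion is not None:
            n_volumes = slice_motion.shape[0]
        if n_volumes is None:
            raise ValueError("cannot infer volume count")
    if slice_motion is not None and slice_motion.shape[0] != n_volumes:
        raise ValueError("motion and component volume counts disagree")

    spikes = np.zeros((n_volumes, len(outlier_volumes)))
    for j, v in enumerate(sorted(outlier_volumes)):
        spikes[v, j] = 1.0

    blocks, labels = [], []
    for z in range(nz):
        comp = components[z].components
        if comp.shape[0] not in (0, n_volumes) and comp.size:
            raise ValueError("component volume count disagrees")
        cols = [comp - comp.mean(axis=0)] if comp.size else []
        names = [f"csf_pc{i + 1}" for i in range(comp.shape[1])]
        if slice_motion is not None:
            mot = slice_motion[:, z, :] - slice_motion[:, z, :].mean(axis=0)
            cols.append(mot)
            names += ["motion_dx", "motion_dy"]
        if spikes.shape[1]:
            cols.append(spikes)
            names += [f"spike_{v}" for v in sorted(outlier_volumes)]
        x = np.hstack(cols) if cols else np.zeros((n_volumes, 0))
        x, names = _drop_collinear(x, names)
        blocks.append(x)
        labels.append(names)
    return NuisanceSet(blocks=blocks, labels=labels,
                       outlier_volumes=tuple(sorted(outlier_volumes)))
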