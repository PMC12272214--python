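"""NIfTI-1 and sidecar I/O for simulated runs, masks and truth tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import make_block_paradigm
from .phantom import SEQUENCES, EpiRun, PhantomGeometry, PhantomTruth, SequenceSpec

__all__ = [
    "save_run",
    "load_run",
    "save_mask",
    "load_mask",
    "save_map",
    "truth_table",
    "save_geometry",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_run(run: EpiRun, path) -> Path:
    """Write a 4D run as NIfTI plus a JSON sidecar with the acquisition
    metadata (sequence name, TE, TR, FA, block schedule, seed)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32),
                          _affine(run.voxel_size_mm))
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.seq.tr_ms / 1000.0,))
    nib.save(img, path)
    sidecar = {
        "sequence": run.seq.name,
        "te_ms": run.seq.te_ms,
        "tr_ms": run.seq.tr_ms,
        "fa_deg": run.seq.fa_deg,
        "partial_fourier": run.seq.partial_fourier,
        "n_volumes": run.n_volumes,
        "meta": {k: v for k, v in run.meta.items()
                 if isinstance(v, (str, int, float, bool))},
    }
    if run.paradigm is not None:
        sidecar["paradigm"] = {
            "block_duration_s": run.paradigm.block_duration_s,
            "n_blocks": run.paradigm.n_blocks,
        }
    side_path = path.with_name(path.name.split(".")[0] + ".json")
    side_path.write_text(json.dumps(sidecar, indent=1))
    return path


def load_run(path) -> EpiRun:
    path = Path(path)
    img = nib.load(path)
    side_path = path.with_name(path.name.split(".")[0] + ".json")
    sidecar = json.loads(side_path.read_text())
    name = sidecar["sequence"]
    seq = SEQUENCES.get(name) or SequenceSpec(
        name=name, te_ms=sidecar["te_ms"], tr_ms=sidecar["tr_ms"],
        fa_deg=sidecar["fa_deg"],
        partial_fourier=sidecar.get("partial_fourier", 1.0),
        n_volumes_task=sidecar["n_volumes"], n_volumes_rest=sidecar["n_volumes"],
    )
    paradigm = None
    if "paradigm" in sidecar:
        p = sidecar["paradigm"]
        paradigm = make_block_paradigm(p["block_duration_s"], p["n_blocks"])
    zooms = img.header.get_zooms()
    return EpiRun(
        data=np.asarray(img.dataobj, dtype=np.float32),
        seq=seq,
        paradigm=paradigm,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        meta=sidecar.get("meta", {}),
    )


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0


def save_map(data: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def save_geometry(geom: PhantomGeometry, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    vs = geom.voxel_size_mm
    for name in ("cord_mask", "gm_mask", "wm_mask", "csf_mask", "vein_mask"):
        paths[name] = save_mask(getattr(geom, name), vs,
                                out_dir / f"{name}.nii.gz")
    return paths


def truth_table(truth: PhantomTruth) -> pd.DataFrame:
    """Injected ground-truth parameters of one run as a flat table."""
    act = truth.activation
    rows = {
        "sequence": truth.seq.name,
        "te_ms": truth.seq.te_ms,
        "tr_ms": truth.seq.tr_ms,
        "fa_deg": truth.seq.fa_deg,
        "delta_r2star": act.delta_r2star if act else 0.0,
        "vein_k": act.vein_k if act else 0.0,
        "response_model": act.response_model if act else "none",
        "thermal_sd": truth.noise.thermal_sd,
        "resp_freq_hz": truth.noise.resp_freq_hz,
        "csf_shared_fraction": truth.noise.csf_shared_fraction,
        "n_target_voxels": int(act.target_mask.sum()) if act else 0,
        "seed": truth.seed,
    }
    return pd.DataFrame([rows])
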