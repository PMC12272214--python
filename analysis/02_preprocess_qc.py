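"""Motion-correct the simulated session and tabulate quality metrics.

Reads the runs written by 01_simulate_session.py, applies the two-step
motion correction, computes DVARS outlier reports, the run-exclusion
decision, and rest-run tSNR per slice (keyed by distance from the LSE
landmark). Tables land under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lumbobold as lb
from lumbobold import io, preprocess

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    img_dir = ROOT / "scratch" / "session"
    if not img_dir.exists():
        raise SystemExit("run analysis/01_simulate_session.py first")
    geom = lb.build_geometry(lb.GeometryConfig(
        grid_shape=(32, 32, 10), center=(16.0, 16.0),
        lse_slice_index=6, tip_slice_index=1))
    line = preprocess.cord_centerline(geom.cord_mask)
    cyl = preprocess.cylindrical_mask(line, geom.grid_shape,
                                     geom.voxel_size_mm, 20.0)

    qc_rows, tsnr_rows = [], []
    for path in sorted(img_dir.glob("*.nii.gz")):
        if "masks" in str(path):
            continue
        run = io.load_run(path)
        est, data = preprocess.moco_volume(run.data, run.voxel_size_mm,
                                           mask=cyl, dof=3)
        d = preprocess.dvars(data, geom.cord_mask)
        report = preprocess.flag_outliers(d, data.shape[3])
        qc_rows.append({
            "run": path.name.split(".")[0],
            "n_volumes": data.shape[3],
            "max_abs_translation_mm": float(
                np.max(np.abs(est.volume_params[:, :3]))),
            "n_outliers": len(report.outlier_volumes),
            "outlier_rate": report.outlier_rate,
            "kept": preprocess.exclude_run(report),
        })
        if "rest" in path.name:
            _, per_slice = preprocess.tsnr(data, geom.cord_mask)
            for z, v in enumerate(per_slice):
                if np.isfinite(v):
                    tsnr_rows.append({
                        "run": path.name.split(".")[0],
                        "slice": z,
                        "dist_from_lse_mm": (z - geom.lse_slice_index)
                        * geom.voxel_size_mm[2],
                        "tsnr": v,
                    })

    out = ROOT / "results"
    pd.DataFrame(qc_rows).to_csv(out / "qc_outliers.csv", index=False)
    pd.DataFrame(tsnr_rows).to_csv(out / "qc_tsnr_per_slice.csv", index=False)
    print(pd.DataFrame(qc_rows).to_string(index=False))
    rest = pd.DataFrame(tsnr_rows)
    if len(rest):
        print("\nrest-run tSNR by sequence (cord mean):")
        rest["sequence"] = rest["run"].str.split("_").str[1]
        print(rest.groupby("sequence")["tsnr"].mean().round(2).to_string())


if __name__ == "__main__":
    main()
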