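"""Simulate one subject's scan session and write it to disk.

Generates the phantom geometry and, per sequence preset, one rest run and
two task runs (20-block desk-scale paradigm), then writes NIfTI volumes
and JSON sidecars under scratch/session/ and the ground-truth parameter
table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

import lumbobold as lb
from lumbobold import io

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    out_img = ROOT / "scratch" / "session"
    out_img.mkdir(parents=True, exist_ok=True)
    out_tab = ROOT / "results"
    out_tab.mkdir(exist_ok=True)

    cfg = lb.SessionConfig(
        geometry=lb.GeometryConfig(grid_shape=(32, 32, 10),
                                   center=(16.0, 16.0),
                                   lse_slice_index=6, tip_slice_index=1),
        paradigm_n_blocks=20, seed=seed, vein_k=0.2,
    )
    session = lb.simulate_session(cfg)
    geom = lb.build_geometry(cfg.geometry)
    io.save_geometry(geom, out_img / "masks")

    rows = []
    for seq_name, runs in session.items():
        for idx, (run, truth) in enumerate(runs):
            kind = run.meta["kind"]
            stem = f"sub-01_{seq_name}_{kind}{idx}"
            io.save_run(run, out_img / f"{stem}.nii.gz")
            t = io.truth_table(truth)
            t.insert(0, "run", stem)
            rows.append(t)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out_tab / "session_truth.csv", index=False)
    print(f"wrote {len(rows)} runs to {out_img}")
    print(f"ground-truth table: {out_tab / 'session_truth.csv'}")
    print(table[["run", "te_ms", "tr_ms", "delta_r2star", "seed"]]
          .to_string(index=False))


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    main(seed)
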