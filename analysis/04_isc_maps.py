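#!/usr/bin/env python
"""Voxel-wise inter-subject correlation maps per condition.

For every voxel and condition: leave-one-out correlations r_j, their mean
R, a phase-randomization null of R (independent surrogates per subject and
voxel), one-sided p-values, and a Benjamini-Hochberg mask at q* = 0.05.

Reads results/preprocessed/, writes R/p/mask NIfTIs and a per-condition
summary to results/isc/.
"""

import argparse
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from trwmap import io as tio
from trwmap.pipeline import isc_condition_maps


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results/preprocessed"))
    ap.add_argument("--out", type=Path, default=Path("results/isc"))
    ap.add_argument("--n-perm", type=int, default=500)
    ap.add_argument("--q", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    manifest = tio.read_manifest(args.in_dir / "manifest.tsv")
    conditions = sorted(manifest["condition"].unique())
    first = nib.load(str(args.in_dir / manifest.iloc[0]["path"]))
    grid = first.shape[:3]
    vs = float(first.header.get_zooms()[0])

    data = {
        cond: tio.load_condition(manifest, cond, args.in_dir) for cond in conditions
    }
    maps = isc_condition_maps(data, n_perm=args.n_perm, seed=args.seed, q_star=args.q)

    rows = []
    for cond, m in maps.items():
        tio.write_map(args.out / f"R_{cond}.nii.gz", m.R.reshape(grid), voxel_size=vs)
        tio.write_map(args.out / f"p_{cond}.nii.gz", m.p.reshape(grid), voxel_size=vs)
        tio.write_map(
            args.out / f"mask_{cond}.nii.gz",
            m.mask.reshape(grid).astype(np.int16), voxel_size=vs,
        )
        rows.append(
            {"condition": cond, "n_significant": int(m.mask.sum()),
             "frac_significant": round(float(m.mask.mean()), 4),
             "median_R_sig": round(float(np.median(m.R[m.mask])), 3) if m.mask.any() else None,
             "p_threshold": m.p_threshold, "n_perm": m.n_perm}
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "isc_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"wrote ISC maps to {args.out}")


if __name__ == "__main__":
    main()
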