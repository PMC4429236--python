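#!/usr/bin/env python
"""Figures: TRW label map slices and per-ROI condition-reliability bars.

Reads results/trw/ and results/roi/, writes PNGs to results/figures/.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd

from trwmap.cohort import CONDITIONS


def plot_trw_slices(trw_dir: Path, out: Path) -> None:
    img = nib.load(str(trw_dir / "trw_labels.nii.gz"))
    labels = np.asanyarray(img.dataobj)
    legend = json.loads((trw_dir / "trw_legend.json").read_text())
    n_labels = len(legend)
    z_slices = np.linspace(1, labels.shape[2] - 2, 4, dtype=int)
    fig, axes = plt.subplots(1, len(z_slices), figsize=(3 * len(z_slices), 3.2))
    cmap = plt.get_cmap("viridis", n_labels)
    for ax, z in zip(axes, z_slices):
        im = ax.imshow(labels[:, :, z].T, cmap=cmap, vmin=-0.5, vmax=n_labels - 0.5,
                       origin="lower", interpolation="nearest")
        ax.set_title(f"z = {z}")
        ax.set_xticks([]), ax.set_yticks([])
    cbar = fig.colorbar(im, ax=axes, ticks=range(n_labels), shrink=0.85)
    cbar.ax.set_yticklabels([legend[str(i)] for i in range(n_labels)])
    fig.suptitle("TRW labels: shortest condition with reliable response")
    fig.savefig(out / "trw_map.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_roi_profiles(roi_dir: Path, out: Path) -> None:
    table = pd.read_csv(roi_dir / "profiles.tsv", sep="\t")
    rois = list(dict.fromkeys(table["roi"]))
    fig, axes = plt.subplots(1, len(rois), figsize=(2.6 * len(rois), 3.2), sharey=True)
    for ax, roi in zip(np.atleast_1d(axes), rois):
        sub = table[table["roi"] == roi].set_index("condition").loc[list(CONDITIONS)]
        x = np.arange(len(CONDITIONS))
        ax.bar(x, sub["mean_R"], yerr=sub["se"], color="steelblue", capsize=2)
        for xi, (cond, row) in zip(x, sub.iterrows()):
            p = row["p_vs_intact"]
            if pd.notna(p) and p < 0.05:
                ax.text(xi, max(row["mean_R"], 0) + 0.04, "*", ha="center")
        ax.set_xticks(x)
        ax.set_xticklabels([c[:4] for c in CONDITIONS], rotation=45)
        ax.set_title(roi)
        ax.axhline(0, color="k", lw=0.5)
    np.atleast_1d(axes)[0].set_ylabel("inter-subject correlation (R)")
    fig.suptitle("Condition reliability by ROI (* p<0.05 vs intact, paired one-tailed)")
    fig.tight_layout()
    fig.savefig(out / "roi_profiles.png", dpi=120)
    plt.close(fig)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trw-dir", type=Path, default=Path("results/trw"))
    ap.add_argument("--roi-dir", type=Path, default=Path("results/roi"))
    ap.add_argument("--out", type=Path, default=Path("results/figures"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    plot_trw_slices(args.trw_dir, args.out)
    plot_roi_profiles(args.roi_dir, args.out)
    print(f"wrote trw_map.png and roi_profiles.png to {args.out}")


if __name__ == "__main__":
    main()
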