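"""NIfTI and manifest I/O.

Cohorts are stored one NIfTI-1 file per subject x condition
(``sub-<i>_cond-<name>.nii.gz``) with the TR in ``pixdim[4]``, plus a
manifest TSV (columns subject, condition, path) listing the runs. Statistic
maps (R, p, masks, TRW labels) are written as 3-D NIfTI volumes; truth/TRW
label maps carry a JSON legend sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import TruthMap, TRUTH_LABELS
from .preprocess import BoldRun


def _affine(voxel_size) -> np.ndarray:
    if np.isscalar(voxel_size):
        voxel_size = (voxel_size,) * 3
    return np.diag(list(voxel_size) + [1.0])


def write_bold(path, run: BoldRun) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.voxel_size))
    img.header["pixdim"][4] = run.tr
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    meta = {
        "subject": run.subject,
        "condition": run.condition,
        "tr": run.tr,
        "history": list(run.history),
    }
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))


def read_bold(path, tr: float | None = None, subject: str = "", condition: str = "") -> BoldRun:
    """Load a 4-D NIfTI; TR from pixdim[4] unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    hdr_tr = float(img.header["pixdim"][4])
    use_tr = tr if tr is not None else hdr_tr
    if use_tr <= 0:
        raise ValueError(f"no usable TR in header of {path}; pass tr= explicitly")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BoldRun(data=data, tr=use_tr, voxel_size=voxel_size, subject=subject, condition=condition)


def write_cohort(out_dir, cohort: dict, tr: float, voxel_size=3.0) -> pd.DataFrame:
    """Write per-subject, per-condition runs plus a manifest TSV.

    ``cohort`` maps condition -> array (n_subjects, x, y, z, t).
    Returns the manifest DataFrame (also saved as manifest.tsv).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cond, data in cohort.items():
        for j in range(data.shape[0]):
            name = f"sub-{j:02d}_cond-{cond}.nii.gz"
            run = BoldRun(
                data=data[j], tr=tr,
                voxel_size=(voxel_size,) * 3 if np.isscalar(voxel_size) else voxel_size,
                subject=f"sub-{j:02d}", condition=cond,
            )
            write_bold(out / name, run)
            rows.append({"subject": f"sub-{j:02d}", "condition": cond, "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "condition", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def load_condition(manifest: pd.DataFrame, condition: str, base_dir, tr: float | None = None) -> np.ndarray:
    """Stack one condition's runs into (n_subjects, n_voxels, n_t)."""
    base = Path(base_dir)
    sel = manifest[manifest["condition"] == condition].sort_values("subject")
    if sel.empty:
        raise ValueError(f"no runs for condition {condition!r}")
    runs = [
        read_bold(base / r.path, tr=tr, subject=r.subject, condition=condition)
        for r in sel.itertuples()
    ]
    return np.stack([r.timecourses() for r in runs])


def write_map(path, values: np.ndarray, voxel_size=3.0) -> None:
    """Write a 3-D statistic map (float) or mask/labels (int) as NIfTI."""
    arr = np.asarray(values)
    dtype = np.int16 if arr.dtype.kind in "biu" else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), _affine(voxel_size))
    nib.save(img, str(path))


def write_truth(path, truth: TruthMap) -> None:
    write_map(path, truth.data, voxel_size=truth.voxel_size)
    Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_legend.json").write_text(
        truth.legend_json()
    )


def read_truth(path, legend_path=None) -> TruthMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.int16)
    voxel_size = float(img.header.get_zooms()[0])
    if legend_path is not None:
        legend_map = json.loads(Path(legend_path).read_text())
        legend = tuple(legend_map[str(i)] for i in range(len(legend_map)))
    else:
        legend = TRUTH_LABELS
    return TruthMap(data=data, voxel_size=voxel_size, legend=legend)
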