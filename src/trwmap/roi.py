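"""ROI-level analyses: envelope extraction, A1+ definition, axis ROIs, profiles.

The early-auditory region (A1+) is defined functionally as the voxels whose
time courses track the stimulus audio envelope. A timescale gradient is then
examined by laying a sequence of ROIs along an axis across the reliability
map and computing, for each ROI, the per-condition inter-subject correlation
profile with paired-test annotations against the intact condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .cohort import hrf_double_gamma
from .audio import AudioTrack
from .isc import loo_isc_stack, paired_ttest_onetailed


@dataclass(frozen=True)
class Envelope:
    """Audio amplitude envelope resampled to the BOLD sampling rate."""

    values: np.ndarray
    tr: float
    band_hz: tuple
    source_rate: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < -1e-9):
            raise ValueError("envelope must be non-negative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))


def extract_envelope(
    track: AudioTrack,
    band: tuple = (4.0, 4000.0),
    tr: float = 1.5,
    filter_order: int = 4,
) -> Envelope:
    """Band-limited Hilbert envelope downsampled to the BOLD rate.

    Zero-phase Butterworth bandpass between ``band`` Hz, analytic-signal
    magnitude via the Hilbert transform, then anti-aliased FIR polyphase
    resampling (``scipy.signal.resample_poly``) down to 1/tr Hz.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band must satisfy 0 < low < high")
    if track.sample_rate <= 2 * hi:
        raise ValueError(
            f"sample rate {track.sample_rate} too low for band upper edge {hi} Hz"
        )
    nyq = track.sample_rate / 2
    sos = signal.butter(filter_order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, track.samples)
    env = np.abs(signal.hilbert(x))
    # resample from sample_rate to 1/tr: rational factor up/down
    frac = Fraction(1 / tr / track.sample_rate).limit_denominator(10**6)
    y = signal.resample_poly(env, frac.numerator, frac.denominator)
    n_out = int(np.floor(track.duration / tr + 1e-9))
    y = y[:n_out]
    return Envelope(
        values=np.maximum(y, 0.0), tr=tr, band_hz=(lo, hi), source_rate=track.sample_rate
    )


def hrf_convolve_envelope(env: Envelope) -> np.ndarray:
    """Envelope convolved with the canonical HRF (same length, z-scored)."""
    kern = hrf_double_gamma(env.tr)
    v = np.convolve(env.values - env.values.mean(), kern)[: env.values.size]
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v


def define_a1(
    data: np.ndarray,
    env: Envelope,
    k: int = 50,
    hrf: bool = True,
    crop_initial_trs: int = 0,
) -> tuple:
    """Select the k voxels most correlated with the stimulus envelope.

    Parameters
    ----------
    data : ndarray (n_subjects, n_voxels, n_timepoints)
        Preprocessed cohort for one condition; the cohort-average time
        course is correlated with the (optionally HRF-convolved) envelope.
    env : Envelope
        Must match the run length — align (crop) it to the preprocessed
        series before calling.
    k : int
        ROI size in voxels.
    hrf : bool
        Convolve the envelope with the canonical HRF before correlating
        (compensates the hemodynamic lag).
    crop_initial_trs : int
        Drop this many leading envelope samples after HRF convolution, to
        align a full-stimulus envelope with runs whose initial volumes were
        cropped during preprocessing.

    Returns
    -------
    (roi_indices, correlations) : flat voxel indices of the top-k voxels in
    descending envelope correlation, and the full per-voxel correlations.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("data must be (n_subjects, n_voxels, n_timepoints)")
    n_vox, n_t = x.shape[1], x.shape[2]
    ref = hrf_convolve_envelope(env) if hrf else np.asarray(env.values, dtype=float)
    if crop_initial_trs:
        ref = ref[crop_initial_trs:]
    if ref.size != n_t:
        raise ValueError(f"envelope length {ref.size} != run length {n_t}")
    if k > n_vox:
        raise ValueError(f"k={k} exceeds voxel count {n_vox}")
    mean_tc = x.mean(axis=0)  # (V, T)
    mc = mean_tc - mean_tc.mean(axis=-1, keepdims=True)
    rc = ref - ref.mean()
    num = mc @ rc
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (np.linalg.norm(mc, axis=-1) * np.linalg.norm(rc))
    order = np.argsort(np.nan_to_num(corr, nan=-np.inf))[::-1]
    return order[:k].copy(), corr


@dataclass(frozen=True)
class RoiAxis:
    """Ordered, disjoint voxel ROIs laid out along a spatial axis."""

    rois: tuple            # tuple of (n_i, 3) int arrays of voxel coords
    start: tuple
    end: tuple
    empty_bins: tuple = ()

    def __post_init__(self) -> None:
        seen = set()
        proj_prev = None
        direction = np.asarray(self.end, float) - np.asarray(self.start, float)
        for coords in self.rois:
            coords = np.asarray(coords)
            if coords.size == 0:
                raise ValueError("ROIs must be nonempty")
            for c in map(tuple, coords):
                if c in seen:
                    raise ValueError(f"voxel {c} appears in more than one ROI")
                seen.add(c)
            proj = float(
                (coords.mean(axis=0) - np.asarray(self.start, float)) @ direction
            )
            if proj_prev is not None and proj <= proj_prev:
                raise ValueError("ROI centroid projections must increase along the axis")
            proj_prev = proj


def define_axis_rois(
    mask: np.ndarray,
    start: tuple,
    end: tuple,
    n_rois: int = 5,
) -> RoiAxis:
    """Partition a mask into ROIs by projection onto the start->end line.

    Mask voxels are orthogonally projected onto the line through ``start``
    and ``end`` (voxel coordinates); the projection range is split into
    ``n_rois`` equal-length bins and each bin's voxels form one ROI. Bins
    that receive no voxels are dropped and reported in ``empty_bins``.
    """
    start_a = np.asarray(start, dtype=float)
    end_a = np.asarray(end, dtype=float)
    if np.allclose(start_a, end_a):
        raise ValueError("start and end must differ")
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if coords.size == 0:
        raise ValueError("mask is empty")
    direction = end_a - start_a
    t = (coords - start_a) @ direction / (direction @ direction)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        # all voxels project to one point: single ROI
        return RoiAxis(rois=(coords,), start=tuple(start), end=tuple(end))
    edges = np.linspace(lo, hi, n_rois + 1)
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_rois - 1)
    rois, empty = [], []
    for b in range(n_rois):
        sel = coords[bin_idx == b]
        if sel.size:
            rois.append(sel)
        else:
            empty.append(b)
    return RoiAxis(rois=tuple(rois), start=tuple(start), end=tuple(end), empty_bins=tuple(empty))


def roi_profile(cohort_data: dict, roi: np.ndarray, intact: str = "intact") -> dict:
    """Per-condition ISC profile of one ROI.

    For each condition, every subject's ROI time course is the mean over ROI
    voxels; leave-one-out correlations r_j are computed on those ROI time
    courses, and summarized as mean R with standard error sd(r_j)/sqrt(N).
    Each scrambled condition is annotated with a one-tailed paired t-test of
    intact r_j > condition r_j (when the intact condition is present).

    Parameters
    ----------
    cohort_data : dict
        Condition name -> (n_subjects, n_voxels, n_timepoints) array.
    roi : array of flat voxel indices (or (n, 1)+ coordinate rows already
        flattened by the caller).

    Returns
    -------
    dict : condition -> {"R", "se", "r_j", "t_vs_intact", "p_vs_intact"}
    """
    roi = np.asarray(roi).ravel()
    if roi.size == 0:
        raise ValueError("ROI is empty")
    r_by_cond = {}
    for cond, data in cohort_data.items():
        x = np.asarray(data, dtype=np.float64)
        if x.shape[0] < 2:
            raise ValueError("leave-one-out ISC needs at least 2 subjects")
        tc = x[:, roi, :].mean(axis=1)  # (N, T)
        r, _ = loo_isc_stack(tc[:, None, :])
        r_by_cond[cond] = r[:, 0]

    out = {}
    r_intact = r_by_cond.get(intact)
    for cond, r in r_by_cond.items():
        n = r.size
        entry = {
            "R": float(np.nanmean(r)),
            "se": float(np.nanstd(r, ddof=1) / np.sqrt(n)),
            "r_j": r,
            "t_vs_intact": None,
            "p_vs_intact": None,
        }
        if r_intact is not None and cond != intact:
            t, p = paired_ttest_onetailed(r_intact, r)
            entry["t_vs_intact"] = t
            entry["p_vs_intact"] = p
        out[cond] = entry
    return out


def coords_to_flat(coords: np.ndarray, shape: tuple) -> np.ndarray:
    """Convert (n, 3) voxel coordinates to flat C-order indices."""
    coords = np.asarray(coords)
    return np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), shape)
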