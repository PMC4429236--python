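"""End-to-end synthetic TRW-mapping experiment.

Glues the stages together the way the analysis scripts use them: build the
stimulus and its scrambled conditions, simulate a cohort with known TRW
structure, preprocess, run voxel-wise ISC with phase-randomization nulls and
FDR thresholding, classify TRW labels, and score against ground truth.

Spatial smoothing defaults to off here: the synthetic generator has no
spatially correlated noise, and the ground-truth labels change at voxel
scale, so a 6 mm kernel would only blur the designed boundaries. The
smoothing stage itself is exercised by its own unit tests and available via
``fwhm_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioTrack
from .cohort import (
    CONDITIONS,
    CohortSpec,
    TruthMap,
    gen_cohort_bold,
    gen_truth_map,
)
from .isc import fdr_threshold, isc_pvalue, loo_isc_stack, null_distribution
from .preprocess import BoldRun, PreprocessConfig, preprocess_run
from .roi import Envelope, coords_to_flat, define_a1, extract_envelope, roi_profile
from .scramble import reverse, scramble_track
from .segmentation import SegmentationSpec, gen_segmentation
from .synth_audio import gen_audio
from .trw import TrwMap, classify_trw, score_against_truth, trw_summary


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def build_stimuli(
    seed: int = 0,
    sample_rate: int = 11025,
    total_duration: float = 255.0,
    level_params: dict | None = None,
    compress: bool = False,
) -> tuple:
    """Segmentation spec plus all five stimulus conditions.

    Returns ``(spec, tracks)`` where tracks maps condition name to
    AudioTrack: intact, backward (time-reversed), and one scramble per
    segmentation level.
    """
    ss = _seedseq(seed)
    seg_seed, audio_seed, *scramble_seeds = ss.spawn(2 + len(CONDITIONS))
    spec = gen_segmentation(total_duration, level_params, seed=seg_seed)
    intact = gen_audio(spec, sample_rate=sample_rate, seed=audio_seed)
    tracks = {"intact": intact, "backward": reverse(intact)}
    for level, sub in zip(spec.levels, scramble_seeds):
        tracks[level] = scramble_track(
            intact, spec, level, seed=sub, compress=compress
        )
    return spec, tracks


def condition_envelopes(tracks: dict, tr: float, n_trs: int, band=(4.0, 4000.0)) -> dict:
    """Audio envelope per condition at the BOLD rate, padded to n_trs.

    Scrambled tracks are slightly shorter than the intact one (crossfade
    overlap), so envelopes are edge-padded with their final value to a
    common length.
    """
    envs = {}
    for cond, track in tracks.items():
        env = extract_envelope(track, band=band, tr=tr)
        v = env.values
        if v.size < n_trs:
            v = np.concatenate([v, np.full(n_trs - v.size, v[-1])])
        envs[cond] = Envelope(
            values=v[:n_trs], tr=tr, band_hz=env.band_hz, source_rate=env.source_rate
        )
    return envs


@dataclass
class Experiment:
    """Everything generated for one synthetic cohort run."""

    spec: SegmentationSpec
    tracks: dict
    envelopes: dict
    truth: TruthMap
    cohort_spec: CohortSpec
    cohort: dict = field(repr=False)


def simulate_experiment(
    seed: int = 0,
    n_subjects: int = 15,
    alpha: float = 1.0,
    sigma: float = 1.0,
    grid: tuple = (12, 12, 12),
    layout: str = "slabs_x",
    hrf_enabled: bool = True,
    envelope_locked: bool = True,
    sample_rate: int = 11025,
    conditions: tuple = CONDITIONS,
    stimuli: tuple | None = None,
) -> Experiment:
    """Simulate stimuli plus a cohort with ground-truth TRW structure.

    With ``envelope_locked`` the shared latent of short-TRW ("backward"
    truth level) voxels in each condition is that condition's audio
    envelope, so an A1-like region genuinely tracks the stimulus envelope;
    all other latents are random smooth time courses. Pass ``stimuli`` as a
    prebuilt ``(spec, tracks)`` pair (e.g. loaded from disk) to lock the
    cohort to existing audio instead of freshly generated stimuli.
    """
    ss = _seedseq(seed)
    stim_seed, truth_seed, cohort_seed = ss.spawn(3)
    if stimuli is not None:
        spec, tracks = stimuli
    else:
        spec, tracks = build_stimuli(seed=stim_seed, sample_rate=sample_rate)
    truth = gen_truth_map(shape=grid, layout=layout, seed=truth_seed)
    cs = CohortSpec(
        n_subjects=n_subjects,
        conditions=conditions,
        alpha=alpha,
        sigma=sigma,
        hrf_enabled=hrf_enabled,
        seed=cohort_seed,
    )
    envs = condition_envelopes(tracks, tr=cs.tr, n_trs=cs.n_stim_trs)
    shared = (
        {(cond, "backward"): envs[cond].values for cond in conditions}
        if envelope_locked
        else None
    )
    cohort = gen_cohort_bold(truth, cs, shared_latents=shared)
    return Experiment(
        spec=spec, tracks=tracks, envelopes=envs, truth=truth,
        cohort_spec=cs, cohort=cohort,
    )


def preprocess_cohort(
    cohort: dict,
    tr: float,
    voxel_size: float = 3.0,
    cutoff_hz: float = 0.01,
    fwhm_mm: float = 0.0,
    crop_trs: int = 15,
) -> dict:
    """Preprocess every run; returns condition -> (n_subjects, n_voxels, n_t)."""
    cfg = PreprocessConfig(cutoff_hz=cutoff_hz, fwhm_mm=fwhm_mm, crop_trs=crop_trs)
    out = {}
    for cond, data in cohort.items():
        runs = []
        for j in range(data.shape[0]):
            run = BoldRun(
                data=data[j], tr=tr, voxel_size=(voxel_size,) * 3,
                subject=f"sub-{j:02d}", condition=cond,
            )
            runs.append(preprocess_run(run, cfg).timecourses())
        out[cond] = np.stack(runs)
    return out


@dataclass
class IscMaps:
    """Voxel-wise ISC results for one condition."""

    condition: str
    r: np.ndarray          # (n_subjects, n_voxels)
    R: np.ndarray          # (n_voxels,)
    p: np.ndarray          # (n_voxels,)
    mask: np.ndarray       # (n_voxels,) bool
    p_threshold: float | None
    n_perm: int


def isc_condition_maps(
    preprocessed: dict,
    n_perm: int = 500,
    seed: int = 0,
    q_star: float = 0.05,
    by_correction: bool = False,
) -> dict:
    """Observed R, phase-randomization p-values, and FDR masks per condition."""
    ss = _seedseq(seed)
    subs = ss.spawn(len(preprocessed))
    out = {}
    for (cond, data), sub in zip(sorted(preprocessed.items()), subs):
        r, R = loo_isc_stack(data)
        null = null_distribution(data, n_perm=n_perm, seed=np.random.default_rng(sub).integers(2**31))
        p = isc_pvalue(R, null)
        fdr = fdr_threshold(p, q_star=q_star, by_correction=by_correction)
        out[cond] = IscMaps(
            condition=cond, r=r, R=R, p=p, mask=fdr.mask,
            p_threshold=fdr.p_threshold, n_perm=n_perm,
        )
    return out


def truth_level_rois(truth: TruthMap) -> dict:
    """Flat voxel indices per ground-truth label (nonempty labels only)."""
    flat = truth.data.ravel()
    return {
        name: np.flatnonzero(flat == code)
        for code, name in enumerate(truth.legend)
        if np.any(flat == code)
    }


@dataclass
class PipelineResult:
    experiment: Experiment
    preprocessed: dict = field(repr=False)
    maps: dict
    trw: TrwMap
    summary: dict
    score: dict
    a1_indices: np.ndarray
    a1_correlations: np.ndarray = field(repr=False)
    profiles: dict


def run_full(
    seed: int = 0,
    n_subjects: int = 15,
    alpha: float = 1.0,
    sigma: float = 1.0,
    n_perm: int = 500,
    grid: tuple = (12, 12, 12),
    q_star: float = 0.05,
    fwhm_mm: float = 0.0,
    k_a1: int = 50,
) -> PipelineResult:
    """Full synthetic experiment: simulate, preprocess, ISC, classify, score.

    ROI profiles are computed for an A1-like ROI (ground-truth short-TRW
    voxels) and a long-TRW ROI (union of phrase/section/intact truth
    voxels), reproducing the timescale-gradient comparison.
    """
    ss = _seedseq(seed)
    sim_seed, isc_seed = ss.spawn(2)
    exp = simulate_experiment(
        seed=sim_seed,
        n_subjects=n_subjects, alpha=alpha, sigma=sigma, grid=grid,
    )
    cs = exp.cohort_spec
    pre = preprocess_cohort(exp.cohort, tr=cs.tr, fwhm_mm=fwhm_mm)
    maps = isc_condition_maps(
        pre, n_perm=n_perm,
        seed=np.random.default_rng(isc_seed).integers(2**31), q_star=q_star,
    )
    masks = {c: m.mask.reshape(grid) for c, m in maps.items()}
    trw = classify_trw(masks, hierarchy=CONDITIONS)
    summary = trw_summary(trw)
    score = score_against_truth(trw, exp.truth)

    crop_stim_trs = 15 - cs.n_silence_trs  # stimulus TRs lost to cropping
    a1_idx, a1_corr = define_a1(
        pre["intact"], exp.envelopes["intact"], k=k_a1, hrf=cs.hrf_enabled,
        crop_initial_trs=crop_stim_trs,
    )
    level_rois = truth_level_rois(exp.truth)
    long_trw = np.concatenate(
        [level_rois[k] for k in ("phrase", "section", "intact") if k in level_rois]
    )
    profiles = {
        "a1_like": roi_profile(pre, level_rois.get("backward", a1_idx)),
        "a1_envelope": roi_profile(pre, a1_idx),
        "long_trw": roi_profile(pre, long_trw),
    }
    return PipelineResult(
        experiment=exp, preprocessed=pre, maps=maps, trw=trw,
        summary=summary, score=score,
        a1_indices=a1_idx, a1_correlations=a1_corr, profiles=profiles,
    )
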