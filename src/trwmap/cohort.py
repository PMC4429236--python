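"""Synthetic subject cohorts with known temporal-receptive-window structure.

The temporal receptive window (TRW) of a voxel is the span of preceding
stimulus time that shapes its response. In the scrambling paradigm a voxel
with a short TRW responds the same way to each local event regardless of the
surrounding temporal coherence, so its response is reproducible across
subjects (stimulus-locked) under every condition; a voxel with a long TRW is
stimulus-locked only when enough coherent structure survives the scrambling.

The generative model here makes that operational definition literal. Each
voxel carries a ground-truth level L in the condition hierarchy
backward < measure < phrase < section < intact (plus "none"). For condition
c the voxel's stimulus-period signal is

    alpha * latent + sigma * noise

where the latent time course is *shared across subjects* iff
coherence(c) >= L, and subject-specific otherwise. Latents are smooth
(Gaussian-filtered white noise, 3 s FWHM) and optionally convolved with a
canonical double-gamma HRF; each run is preceded by a silence lead-in
containing noise only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gamma as gamma_dist

#: condition hierarchy, ordered by increasing temporal coherence
CONDITIONS = ("backward", "measure", "phrase", "section", "intact")

#: rank of each condition in the coherence order
COHERENCE = {name: rank for rank, name in enumerate(CONDITIONS)}

#: ground-truth voxel labels: hierarchy levels plus "none" (never stimulus-locked)
TRUTH_LABELS = CONDITIONS + ("none",)

#: experiment timing defaults: 3 s silence lead-in, 4 min 15 s stimulus, TR 1.5 s
DEFAULT_SILENCE_S = 3.0
DEFAULT_STIMULUS_S = 255.0
DEFAULT_TR = 1.5

_GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def run_volume_count(
    silence_s: float = DEFAULT_SILENCE_S,
    stimulus_s: float = DEFAULT_STIMULUS_S,
    tr: float = DEFAULT_TR,
) -> int:
    """Number of volumes acquired in one run: floor((silence + stimulus) / TR).

    With the defaults (3 s + 255 s at TR = 1.5 s) this is 172.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    return int(np.floor((silence_s + stimulus_s) / tr + 1e-9))


def hrf_double_gamma(
    tr: float,
    duration_s: float = 32.0,
    peak_s: float = 5.0,
    undershoot_s: float = 15.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (unit dispersion) with modes at
    ``peak_s`` and ``undershoot_s``; the undershoot is scaled by 1/ratio.
    The kernel is normalized to unit peak.
    """
    t = np.arange(0.0, duration_s, tr)
    h = gamma_dist.pdf(t, a=peak_s + 1.0) - gamma_dist.pdf(t, a=undershoot_s + 1.0) / ratio
    return h / np.max(np.abs(h))


@dataclass(frozen=True)
class TruthMap:
    """Per-voxel ground-truth TRW labels on a 3-D grid.

    ``data`` holds integer codes indexing ``legend`` (default
    :data:`TRUTH_LABELS`); ``voxel_size`` is isotropic mm.
    """

    data: np.ndarray
    voxel_size: float = 3.0
    legend: tuple = TRUTH_LABELS

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.int16)
        if data.min() < 0 or data.max() >= len(self.legend):
            raise ValueError("label codes outside legend range")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    def labels_flat(self) -> np.ndarray:
        """Labels as a flat array of strings (C order)."""
        return np.array(self.legend, dtype=object)[self.data.ravel()]

    def counts(self) -> dict:
        return {
            name: int(np.sum(self.data == code)) for code, name in enumerate(self.legend)
        }

    def legend_json(self) -> str:
        return json.dumps({code: name for code, name in enumerate(self.legend)})


def gen_truth_map(
    shape: tuple = (12, 12, 12),
    voxel_size: float = 3.0,
    layout: str = "slabs_x",
    seed: int = 0,
) -> TruthMap:
    """Generate a ground-truth TRW map.

    layout="slabs_x" tiles the x axis with contiguous slabs in hierarchy
    order (backward nearest x=0, then measure ... intact, then none),
    emulating the posterior-to-anterior timescale gradient on a toy grid.
    layout="random" assigns labels i.i.d. uniformly.
    """
    n_labels = len(TRUTH_LABELS)
    if layout == "slabs_x":
        edges = np.linspace(0, shape[0], n_labels + 1)
        codes_x = np.searchsorted(edges, np.arange(shape[0]), side="right") - 1
        codes_x = np.clip(codes_x, 0, n_labels - 1)
        data = np.broadcast_to(
            codes_x[:, None, None], shape
        ).copy()
    elif layout == "random":
        rng = np.random.default_rng(seed)
        data = rng.integers(0, n_labels, size=shape)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return TruthMap(data=data, voxel_size=voxel_size)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    alpha is the stimulus-locked signal amplitude, sigma the subject noise
    sd (both unitless, relative scale only); latent_fwhm_s sets the temporal
    smoothness of the latent time courses.
    """

    n_subjects: int = 15
    conditions: tuple = CONDITIONS
    alpha: float = 1.0
    sigma: float = 1.0
    tr: float = DEFAULT_TR
    silence_s: float = DEFAULT_SILENCE_S
    stimulus_s: float = DEFAULT_STIMULUS_S
    hrf_enabled: bool = False
    latent_fwhm_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @property
    def n_stim_trs(self) -> int:
        return int(np.floor(self.stimulus_s / self.tr + 1e-9))

    @property
    def n_silence_trs(self) -> int:
        return run_volume_count(self.silence_s, self.stimulus_s, self.tr) - self.n_stim_trs

    @property
    def n_trs(self) -> int:
        return run_volume_count(self.silence_s, self.stimulus_s, self.tr)


def _smooth_latent(rng: np.random.Generator, n_t: int, tr: float, fwhm_s: float) -> np.ndarray:
    """Z-scored Gaussian-filtered white noise of length n_t."""
    x = rng.standard_normal(n_t)
    sigma_trs = fwhm_s / _GAUSS_FWHM_TO_SIGMA / tr
    if sigma_trs > 0:
        x = gaussian_filter1d(x, sigma_trs, mode="wrap")
    return (x - x.mean()) / x.std()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def gen_cohort_bold(
    truth: TruthMap,
    cohort: CohortSpec,
    shared_latents: dict | None = None,
) -> dict:
    """Simulate per-subject, per-condition BOLD runs.

    Parameters
    ----------
    truth : TruthMap
        Ground-truth TRW level per voxel.
    cohort : CohortSpec
        Cohort size, signal/noise amplitudes, timing, HRF flag, seed.
    shared_latents : dict, optional
        Override ``{(condition, level): series}`` supplying the shared latent
        time course (length ``n_stim_trs``; z-scored internally) for specific
        condition/level cells — e.g. to make short-TRW voxels track the audio
        envelope. Cells not listed get random smooth latents.

    Returns
    -------
    dict
        Mapping condition name to array of shape
        ``(n_subjects, *grid_shape, n_trs)``. Runs start with a noise-only
        silence lead-in followed by the stimulus period.
    """
    rng = np.random.default_rng(cohort.seed)
    n_t = cohort.n_stim_trs
    n_sil = cohort.n_silence_trs
    grid = truth.shape
    flat_codes = truth.data.ravel()
    n_vox = flat_codes.size
    kern = hrf_double_gamma(cohort.tr) if cohort.hrf_enabled else None

    def finalize(latent: np.ndarray) -> np.ndarray:
        if kern is not None:
            latent = np.convolve(latent, kern)[:n_t]
        return _zscore(latent)

    out = {}
    levels_present = sorted({int(c) for c in flat_codes})
    for cond in cohort.conditions:
        rank = COHERENCE[cond]
        # one shared latent per truth level, one private latent per subject x level
        shared = {}
        private = {}
        for code in levels_present:
            label = TRUTH_LABELS[code]
            if shared_latents is not None and (cond, label) in shared_latents:
                base = np.asarray(shared_latents[(cond, label)], dtype=float)
                if base.size != n_t:
                    raise ValueError(
                        f"shared latent for {(cond, label)} has length {base.size}, "
                        f"expected {n_t}"
                    )
                shared[code] = finalize(base.copy())
            else:
                shared[code] = finalize(_smooth_latent(rng, n_t, cohort.tr, cohort.latent_fwhm_s))
            private[code] = np.stack(
                [
                    finalize(_smooth_latent(rng, n_t, cohort.tr, cohort.latent_fwhm_s))
                    for _ in range(cohort.n_subjects)
                ]
            )

        data = np.empty((cohort.n_subjects, n_vox, n_sil + n_t))
        for code in levels_present:
            vox = np.flatnonzero(flat_codes == code)
            label = TRUTH_LABELS[code]
            locked = label != "none" and rank >= COHERENCE[label]
            for j in range(cohort.n_subjects):
                latent = shared[code] if locked else private[code][j]
                data[j, vox, n_sil:] = cohort.alpha * latent
        data[:, :, :n_sil] = 0.0
        data += cohort.sigma * rng.standard_normal(data.shape)
        out[cond] = data.reshape((cohort.n_subjects, *grid, n_sil + n_t))
    return out
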