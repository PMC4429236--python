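"""Inter-subject correlation statistics.

Reliability of a voxel's response to a naturalistic stimulus is measured by
leave-one-out inter-subject correlation (ISC): for each subject j, the
Pearson correlation r_j between that subject's time course and the average
time course of the remaining subjects, summarized as the plain average
R = (1/N) * sum_j r_j.

Significance is assessed nonparametrically. Phase randomization builds
surrogate time courses with the same power spectrum but random Fourier
phases; recomputing R after independently phase-randomizing every subject's
series yields a voxel-wise null distribution with expected value 0. The
observed R is compared against this null with an add-one permutation
p-value, and voxel-wise p-values are thresholded by the
Benjamini–Hochberg step-up rule (optionally with the Benjamini–Yekutieli
dependence correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# leave-one-out ISC


def _loo_r_stack(x: np.ndarray) -> np.ndarray:
    """Leave-one-out correlations for a (N, ..., T) stack.

    Returns r of shape (N, ...): Pearson correlation of each subject's
    series with the sum of the remaining subjects' series (equal, up to the
    irrelevant 1/(N-1) scale and mean offset, to their average). Zero
    variance on either side yields NaN.
    """
    xm = x - x.mean(axis=-1, keepdims=True)
    s = xm.sum(axis=0, keepdims=True)
    loo = s - xm
    num = np.sum(xm * loo, axis=-1)
    den = np.sqrt(np.sum(xm * xm, axis=-1) * np.sum(loo * loo, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def loo_isc(timecourses) -> tuple:
    """Leave-one-out ISC for one voxel.

    Parameters
    ----------
    timecourses : sequence of 1-D arrays
        One series per subject, equal lengths >= 3, at least 2 subjects.

    Returns
    -------
    (r_j, R) : ndarray of shape (N,), float
        Per-subject correlations (NaN where a series or the others' average
        has zero variance — those are excluded from R with a warning) and
        their plain average.
    """
    x = np.asarray(timecourses, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_timepoints) array")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    r = _loo_r_stack(x)
    if np.any(np.isnan(r)):
        warnings.warn(
            f"{int(np.isnan(r).sum())} subject(s) with undefined correlation "
            "(zero variance) excluded from R",
            RuntimeWarning,
            stacklevel=2,
        )
    R = float(np.nanmean(r)) if np.any(np.isfinite(r)) else float("nan")
    return r, R


def loo_isc_stack(data: np.ndarray) -> tuple:
    """Vectorized leave-one-out ISC over many voxels.

    data has shape (n_subjects, n_voxels, n_timepoints); returns
    (r of shape (N, V), R of shape (V,)), with NaN-exclusion as in loo_isc.
    """
    r = _loo_r_stack(np.asarray(data, dtype=np.float64))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.nanmean(r, axis=0)
    return r, R


# ---------------------------------------------------------------------------
# phase randomization and the null distribution


def _random_phase_factors(rng: np.random.Generator, shape_bins: tuple, n_t: int) -> np.ndarray:
    """Unit-modulus factors for rfft bins: DC (and Nyquist if n_t even) stay real."""
    factors = np.exp(2j * np.pi * rng.random(shape_bins))
    factors[..., 0] = 1.0
    if n_t % 2 == 0:
        factors[..., -1] = 1.0
    return factors


def phase_randomize(series: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Phase-randomized surrogate of a real series.

    FFT, uniform random phase added to each positive-frequency component
    (DC, and the Nyquist bin for even lengths, stay real), inverse FFT. The
    power spectrum — hence variance and autocorrelation — is preserved.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.shape[-1] < 4:
        raise ValueError("need at least 4 time points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.fft.rfft(x, axis=-1)
    f *= _random_phase_factors(rng, f.shape, x.shape[-1])
    return np.fft.irfft(f, n=x.shape[-1], axis=-1)


def _spectral_loo_R(g: np.ndarray, w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Mean leave-one-out correlation from positive-frequency rfft bins.

    g : (N, V, B) complex rfft coefficients, DC bin already dropped.
    w : (B,) Parseval weights (2 per bin, 1 for an even-length Nyquist bin).
    a : (N, V) precomputed weighted power sum_k w_k |g_jk|^2, which equals
        T * ||x_j - mean(x_j)||^2 and is invariant to phase randomization.

    Dropping the DC bin makes every inner product a demeaned time-domain
    inner product (Parseval), so this reproduces loo_isc_stack exactly up
    to rounding.
    """
    s = g.sum(axis=0)
    sw = s.conj() * w
    cross = np.einsum("nvk,vk->nv", g, sw).real
    s_norm = np.einsum("vk,vk->v", s, sw).real
    num = cross - a
    den_sq = a * (s_norm[None, :] - 2.0 * cross + a)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(den_sq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(r, axis=0)


def _parseval_weights(n_t: int) -> np.ndarray:
    """Weights for rfft bins 1..B so sum_k w_k |F_k|^2 = T * var * T (Parseval)."""
    n_bins = n_t // 2
    w = np.full(n_bins, 2.0, dtype=np.float32)
    if n_t % 2 == 0:
        w[-1] = 1.0
    return w


def null_distribution(
    data: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    dtype=np.float32,
    n_jobs: int = 1,
) -> np.ndarray:
    """Voxel-wise null distribution of R under phase randomization.

    Every subject's series at every voxel is independently phase-randomized,
    R is recomputed, and the process repeats ``n_perm`` times. The
    computation runs on the rfft coefficients directly: phase randomization
    multiplies the positive-frequency bins by unit-modulus factors, and all
    correlation sums follow from Parseval's identity with the DC bin
    dropped (equivalent to demeaning). This is algebraically identical to
    inverting the FFT and correlating in the time domain.

    Parameters
    ----------
    data : ndarray (n_subjects, n_voxels, n_timepoints)
    n_perm : int
        Number of surrogate replicates (5000 for production maps; a few
        hundred suffice for calibration experiments).
    seed : int
        Each replicate draws its phases from its own spawned child of the
        seed sequence, so results do not depend on worker count.
    dtype : numpy dtype
        Working precision; single precision by default (null R values are
        Monte-Carlo quantities and this loop dominates pipeline run time).
    n_jobs : int
        Replicates are embarrassingly parallel; >1 uses joblib threads.

    Returns
    -------
    ndarray (n_perm, n_voxels) of null R values (float64).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, None, :]
    n_sub, n_vox, n_t = x.shape
    if n_t < 4:
        raise ValueError("need at least 4 time points")
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    f0 = np.fft.rfft(x, axis=-1)[..., 1:].astype(ctype)  # drop DC: demeaned
    w = _parseval_weights(n_t).astype(dtype)
    a = np.einsum("nvk,k->nv", (f0.real**2 + f0.imag**2).astype(dtype), w)
    nyquist_real = n_t % 2 == 0

    children = np.random.SeedSequence(seed).spawn(n_perm)

    def one(child) -> np.ndarray:
        rng = np.random.default_rng(child)
        theta = (2.0 * np.pi) * rng.random(f0.shape, dtype=np.float32)
        theta = theta.astype(dtype, copy=False)
        factors = np.cos(theta) + 1j * np.sin(theta)
        if nyquist_real:
            factors[..., -1] = 1.0
        return _spectral_loo_R(f0 * factors, w, a)

    if n_jobs == 1:
        return np.stack([one(c) for c in children])
    from joblib import Parallel, delayed

    rows = Parallel(n_jobs=n_jobs, prefer="threads")(delayed(one)(c) for c in children)
    return np.stack(rows)


def isc_pvalue(r_obs, null_samples) -> np.ndarray | float:
    """One-sided (upper) add-one permutation p-value.

    p = (1 + #{null >= R_obs}) / (1 + n_perm); never exactly zero.
    Accepts a scalar R with a 1-D null, or a (V,) R with a (n_perm, V) null.
    """
    null = np.asarray(null_samples, dtype=np.float64)
    if null.size == 0:
        raise ValueError("null sample is empty")
    scalar = np.ndim(r_obs) == 0
    r = np.atleast_1d(np.asarray(r_obs, dtype=np.float64))
    if null.ndim == 1:
        null = null[:, None]
    n_perm = null.shape[0]
    p = (1.0 + np.sum(null >= r[None, :], axis=0)) / (1.0 + n_perm)
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# FDR


@dataclass(frozen=True)
class FdrDecision:
    """Outcome of the step-up FDR rule at level q_star over N p-values."""

    sorted_p: np.ndarray
    k: int                      # maximal rank passing the rule; 0 if none
    p_threshold: float | None   # p_(k), None if nothing passes
    q_star: float
    n_tests: int
    by_correction: bool
    mask: np.ndarray            # in input order; p <= p_threshold


def fdr_threshold(pvalues, q_star: float = 0.05, by_correction: bool = False) -> FdrDecision:
    """Benjamini–Hochberg step-up threshold on sorted p-values.

    Sorts p ascending and finds the maximum rank k (1-based) with
    p_(k) < (k / N) * q. By default q = q_star; with ``by_correction`` the
    Benjamini–Yekutieli divisor is applied, q = q_star / sum_{i=1..N} 1/i,
    which is valid under arbitrary dependence. The significance mask keeps
    every p at or below p_(k); if no rank passes, the mask is empty and the
    threshold undefined.
    """
    p = np.asarray(pvalues, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    q = q_star / np.sum(1.0 / np.arange(1, n + 1)) if by_correction else q_star
    order = np.argsort(p, kind="stable")
    sp = p[order]
    ranks = np.arange(1, n + 1)
    passing = np.flatnonzero(sp < ranks / n * q)  # strict inequality, as stated
    if passing.size == 0:
        return FdrDecision(
            sorted_p=sp, k=0, p_threshold=None, q_star=q_star,
            n_tests=n, by_correction=by_correction,
            mask=np.zeros(n, dtype=bool),
        )
    k = int(passing[-1]) + 1
    p_thr = float(sp[k - 1])
    return FdrDecision(
        sorted_p=sp, k=k, p_threshold=p_thr, q_star=q_star,
        n_tests=n, by_correction=by_correction,
        mask=p <= p_thr,
    )


# ---------------------------------------------------------------------------
# t-tests and covariate regression


def paired_ttest_onetailed(x, y) -> tuple:
    """One-tailed paired t-test of H1: mean(x) > mean(y).

    Returns (t, p); (NaN, NaN) when the paired differences have zero
    variance (degenerate case).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 0.5
        return float("nan"), float("nan")
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def twosample_ttest_onetailed(group1, group2, fisher_z: bool = False) -> tuple:
    """One-tailed Welch two-sample t-test of H1: mean(group1) > mean(group2).

    Intended for comparing per-subject correlation coefficients between two
    groups or regions; set ``fisher_z`` to compare arctanh-transformed
    values instead of raw r.
    """
    a = np.asarray(group1, dtype=np.float64)
    b = np.asarray(group2, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if fisher_z:
        a, b = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12)), np.arctanh(
            np.clip(b, -1 + 1e-12, 1 - 1e-12)
        )
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 0.5
        return float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def covariate_regression(isc_values, covariate) -> tuple:
    """OLS of per-subject ISC coefficients on a per-subject covariate.

    Used e.g. to test whether self-reported stimulus familiarity predicts a
    subject's reliability. Returns (slope, R^2).
    """
    r = np.asarray(isc_values, dtype=np.float64)
    c = np.asarray(covariate, dtype=np.float64)
    if r.size != c.size or r.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(c.std(), 0.0):
        raise ValueError("covariate has zero variance")
    res = stats.linregress(c, r)
    return float(res.slope), float(res.rvalue**2)
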