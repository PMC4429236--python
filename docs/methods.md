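# Methods

## The paradigm in brief

A naturalistic auditory stimulus is presented intact, time-reversed, and
scrambled at each level of a nested structural segmentation. Response
reliability per voxel and condition is measured as leave-one-out
inter-subject correlation (ISC); a voxel's temporal-receptive-window (TRW)
label is the lowest-coherence condition in which its ISC is significant.
Because no real cohort ships with this package, a synthetic-data generator
produces cohorts with known TRW structure so that every downstream stage is
testable and its recovery quantifiable.

## Stimulus model

**Segmentation** (`segmentation.gen_segmentation`). Segment durations are
drawn from a gamma distribution matched to the requested mean/sd per level
(defaults: measures 1.29 ± 0.12 s, phrases 6.32 ± 1.91 s, sections
38.28 ± 12.46 s over a 255 s timeline — values typical of a four-minute
orchestral excerpt). The finest level uses a fixed count
`round(total/mean)` with durations rescaled to tile the timeline exactly;
coarser levels place cumulative gamma targets and snap each to the nearest
finer boundary. Nesting is therefore exact by construction, and realized
per-level means stay within 15% of the targets.

**Audio** (`synth_audio.gen_audio`). One sine tone per measure with 20 ms
linear ramps; per-section base pitch with a random walk, and a loudness
profile that is a product of section, phrase, and measure factors — so the
amplitude envelope carries structure at every level. This is a schematic
stand-in, not music: it gives a waveform whose envelope and boundaries are
known exactly.

**Scrambling** (`scramble`). Orders are rejection-sampled uniformly from
permutations in which no segment is immediately followed by its original
successor (for n = 2 the only valid order is (1, 0)). Crossfades are 10 ms
overlap-add with linear complementary fades (equal-power optional): overlap
was chosen over insertion because it removes clicks without adding
material, at the cost of shortening the output by (n−1)·10 ms. The
compressor applies the static law `out = T + (in − T)/ratio` above
threshold (defaults −20 dBFS, 4:1, attack 10 ms, release 100 ms, optional
RMS-matched makeup). Its level detector is an instantaneous-peak follower
with release-rate decay; a symmetric one-pole follower at a 10 ms attack
under-reads a 440 Hz tone's peak by several dB and would break the static
law on steady tones.

## Cohort generative model

Each voxel on the grid (default 12×12×12 at 3 mm, labels laid out as slabs
along x) carries one ground-truth label from
{backward, measure, phrase, section, intact, none}. For condition c and a
voxel with label L, the stimulus-period signal is

    y = α · latent + σ · noise,

where the latent is **shared across subjects** iff coherence(c) ≥
coherence(L), and subject-specific otherwise (label "none" is never
shared). Latents are Gaussian-filtered white noise (3 s FWHM in time, so
HRF convolution and high-pass filtering leave usable signal), optionally
convolved with a canonical double-gamma HRF (peak 5 s, undershoot 15 s,
ratio 6). Runs start with a 3 s silence lead-in of pure noise; with the
default TR of 1.5 s a run is 172 volumes (2 silence + 170 stimulus).

Short-TRW ("backward"-label) voxels can be **envelope-locked**: their
shared latent in each condition is that condition's audio envelope, so an
A1-like region genuinely tracks the stimulus and the envelope-based A1+
definition has a real target.

α and σ are free calibrations (the amplitude of stimulus-locked signal
relative to noise in real data is unknown); the default α/σ = 1 with n = 15
subjects gives per-voxel ISC around 0.5 at locked voxels — comfortably
detectable but far from ceiling. The generator does **not** model anatomy,
spatially correlated or physiological noise, motion, or inter-subject
variability in HRF shape: passing recovery tests demonstrates the
statistical machinery is correct under the stated model, not that real
cortical maps would be recovered at these rates.

## Preprocessing

Per voxel: linear detrend, then a zero-phase (forward–backward) 2nd-order
Butterworth high-pass at 0.01 Hz — the filter family is a stand-in (only
the cutoff is canonical) and is exposed in the config. The output is
re-demeaned because boundary transients of zero-phase filtering leave small
offsets. Filtering precedes cropping so warm-up artifacts fall in the 15
discarded volumes. Note that zero-phase filtering is not strictly
idempotent: a second pass re-attenuates content near the cutoff and
re-excites boundary transients that decay on the ~1/cutoff timescale; away
from boundaries and the stop band a second pass is a <0.1% perturbation.

Spatial smoothing is volume-wise Gaussian, σ = FWHM/(2√(2 ln 2)) converted
to voxel units, nearest-edge padding. In the synthetic pipeline smoothing
defaults to **off**: the generator has no spatially correlated noise to
suppress, and ground-truth labels change at voxel scale, so a 6 mm kernel
would only blur designed boundaries. The stage itself is fully implemented
and unit-tested, and `fwhm_mm` re-enables it.

## ISC statistics

- `R` averages raw r_j (no Fisher z); z-averaging is available behind a
  flag. Zero-variance series yield an undefined r_j, which is excluded from
  R with a warning rather than propagating NaNs.
- The null phase-randomizes every subject's series at every voxel
  independently per replicate and recomputes R; nulls are strictly
  voxel-wise. For speed the computation stays in the frequency domain:
  dropping the DC bin makes every Parseval inner product a demeaned
  time-domain inner product, so null R values are algebraically identical
  to inverting the FFT and correlating (covered by an exactness test).
  Replicates run in single precision by default — null R values are
  Monte-Carlo quantities, and this loop dominates run time. Each replicate
  draws phases from its own spawned seed-sequence child, so results are
  independent of worker count (`n_jobs` uses joblib threads).
- p-values use the add-one estimator `(1 + #{null ≥ R}) / (1 + n_perm)`,
  one-sided (positive reliability is the implied direction), never zero.
- FDR keeps the strict inequality `p_k < (k/N) q*`. The default is the
  plain step-up rule; `by_correction=True` divides q* by `Σ_{i≤N} 1/i`
  (valid under arbitrary dependence).
- Group comparisons: one-tailed paired t (intact vs scrambled, per ROI) and
  one-tailed Welch two-sample t on raw correlation coefficients (optional
  Fisher z flag). The familiarity control regresses per-subject r_j on a
  covariate by OLS and reports slope and R².

Production maps use 5000 replicates; calibration experiments and the test
suite use 500 (and 12³ voxels), which keeps the full recovery pipeline
under two minutes while leaving the Monte-Carlo error on tail p-values
(~1/501) far below the FDR thresholds involved.

## TRW classification

The shortest-significant rule is applied literally even to non-nested
significance patterns (e.g. significant for measures and sections but not
phrases): the voxel is labeled by its shortest significant condition and a
violation flag is set, exposing rather than hiding such voxels (in the
default synthetic run they are <1% of the grid). Scoring against truth
reports exact-label accuracy, adjacent-label accuracy (±1 hierarchy step;
"none" matches only itself), and the full confusion matrix.

## ROI analyses

The audio envelope is extracted by zero-phase Butterworth bandpass
(4–4000 Hz), Hilbert analytic magnitude, then anti-aliased polyphase FIR
resampling to the BOLD rate. The anti-aliasing filter at ~0.3 Hz cutoff
necessarily has a support of several TRs, so envelope values within a few
samples of the run edges are distorted — tests and alignments use interior
samples. A1+ is the top-k (default 50) voxels by correlation between the
HRF-convolved envelope and the cohort-average time course; HRF convolution
is on by default because without lag compensation the correlation is
physiologically misaligned. Axis ROIs are built by orthogonal projection of
mask voxels onto a start→end line, with the projection range cut into
equal-length bins (a stated substitute for manual cubic partitioning, which
is not algorithmically recoverable). ROI-level r_j is computed on the
ROI-mean time course rather than averaging voxel-wise r — stabler for small
ROIs; a one-voxel ROI reduces exactly to the voxel's loo ISC.

## Determinism and degenerate inputs

All randomness flows through `numpy.random.SeedSequence` spawning: the same
seed reproduces stimuli, cohorts, and null distributions bit-exactly.
Sorting ties in FDR use stable argsort; `argsort` ties in A1+ selection
resolve by voxel index. Errors are raised for: infeasible segmentation
parameters, crossfades longer than the shortest segment, compression ratio
< 1, series too short to filter (<32 samples), cropping an entire run,
fewer than 2 subjects, empty ROIs or masks, constant covariates, and
mismatched grids.

## Known limitations

- The synthetic cohort shares one latent per (condition, truth level), so
  voxels of the same level are spatially correlated by construction;
  FDR-control experiments use α = 0 cohorts, which are free of this.
- Scrambled stimuli are slightly shorter than the intact one (crossfade
  overlap); envelopes are edge-padded to the common TR grid.
- Slice-time and motion correction, anatomical normalization, and surface
  projection are intentionally out of scope; config flags are reserved.
- At 1 s segment durations the crossfade joint density alone costs >1% of
  total energy; the energy-preservation bound (≤1%) is meaningful only at
  the default segment scales.
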