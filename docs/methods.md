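# Methods

## Scientific setting

In primate V1, most superficial-layer neurons respond to both eyes but with
graded eye preferences, summarized by the ocular dominance index
ODI = (R_i − R_c)/(R_i + R_c), where R_c and R_i are the peak responses to
contralateral and ipsilateral stimulation (−1 fully contralateral, +1 fully
ipsilateral). Under monocular stimulation, neurons preferring the stimulated
eye respond much more strongly than balanced (binocular) neurons; under
binocular stimulation the differences largely vanish. `binocombine`
implements the analysis chain that quantifies this: synthetic two-photon
data with known ground truth, cell-body segmentation from stimulus-evoked
differential images, tuning and ocular-dominance characterization, and the
divisive interocular-suppression + binocular-summation model that accounts
for the flattening.

## The combination model

With eye weights w_c = (ODI + 1)/2 and w_i = 1 − w_c:

    R_c = w_c^{m_c} · k        R_i = w_i^{m_i} · k                (monocular)
    R_b = (w_i^{m_i} k)/w_i^b + (w_c^{m_c} k)/w_c^b              (binocular)

`k` is a divisive gain constant shared by the two monocular curves, `m_c`
and `m_i` are monocular nonlinearity exponents (negative, near −1, in the
empirical regime), and `b` is the interocular suppression exponent: each
eye's drive is divided by the *other-eye weight* raised to b before the two
suppressed signals are summed. Stimulus contrasts (0.9 in the emulated
protocol) are carried in the fit record but drop out of the simplified
equations, since responses saturate near full contrast. When the other eye
is unstimulated the suppression factor is 1 and R_b reduces *exactly* to
R_c + R_i; this identity is enforced to machine precision in the tests. No
functional form is assumed for intermediate contrasts — only the two
endpoint cases (no suppression at zero contrast; a fitted constant b at the
experimental contrast) are implemented.

Fitting follows the population procedure: per-neuron responses are divided
by the field-of-view median binocular response, neurons are sorted by ODI
into 60 equal-count bins (ties broken by id; the first `remainder` bins get
one extra member; even-sized medians are the mean of the middle pair), and
bin medians are fit by bounded least squares on the sum of squared
residuals — first both monocular curves jointly with shared k, then the
binocular curve with b as the only free parameter, (k, m_c, m_i) frozen.
Bounds: k ∈ (0, 100], m ∈ [−5, 5], b ∈ [−5, 5]; five multi-starts from a
fixed seed. Goodness of fit uses q = 1 − RMS(residual)/mean(data); q = 1
iff residuals vanish and q is scale invariant. (q is sometimes described
as ranging 0–1; mathematically it is only bounded above by 1, and the code
reports whatever the data give.)

The eye weights are clipped to [ε, 1 − ε] with ε = 10⁻³: w^m diverges at
|ODI| = 1 for negative m, and no measured population reaches the
endpoints, so medians, coefficient-of-variation summaries, and simulated
curves are interpreted over the data-supported ODI range.

## Synthetic data generator

The generator's defaults reproduce the emulated protocol: 12 orientations
(0°–165°, 15° steps), 6 spatial frequencies (0.25–8 cpd, octave steps), 3
Gabor sizes per SF given as envelope σ in wavelength units (0.42/0.64/0.85λ
at ≤1 cpd, 0.64/0.85/1.06λ at ≥2 cpd; σ in degrees = σ_λ/SF), 2 opposite
drift directions, 12 trials per condition (6 per direction), three eye
conditions, 0.9 contrast, 2 cps drift, 8 frames/s, 1000 ms stimulus,
1500 ms ISI. That is 216 conditions per monocular eye.

Each synthetic neuron carries a true ODI, shared model parameters
(defaults k = 1, m_c = m_i = −1, b = −0.9 — the regime in which measured
ODI equals generative ODI and the binocular curve is nearly flat), a
preferred orientation and SF drawn from the design grid, an orientation
half-width at half-height from U[15°, 40°], a mild size preference, and a
trialwise additive Gaussian noise scale (default SD 0.05 in ΔF/F units —
the emulated experiment reports no trial variability, so this is a chosen,
not fitted, value). The expected response is separable: the model's
eye-condition factor times a base-2 Gaussian orientation profile (1 at the
peak, 1/2 at ±σ), a difference-of-Gaussians SF profile (σ₂ = σ₁/3,
a₂ = a₁/2, normalized to 1 at the preferred SF), and a size-index Gaussian.
A configurable fraction (default 5%) of neurons is direction selective,
with the non-preferred direction attenuated by 60%.

The default ODI distribution is a binocular-heavy mixture — 50% uniform on
[−0.5, 0.5] plus 25% on each flank — with flank support capped at |ODI| ≤
0.97: measured ODI distributions concentrate strictly inside (−1, 1), and
the divisive model diverges at the endpoints, so planting neurons at
|ODI| = 1 would produce physically meaningless responses.

Movies render each cell as a soft-edged (logistic, width 0.6 px) disk whose
brightness follows baseline × (1 + response × kernel), with a
double-exponential calcium kernel (50 ms rise, 500 ms decay) sampled at
frame centers and normalized so its mean over post-onset frames 5–8 equals
1 — the ΔF/F read window returns the planted response directly. Each trial
occupies ISI + stimulus frames with the onset after the ISI (≥4 baseline
frames before, ≥9 frames after). The kernel has decayed to <1% of its peak
by the end of the ISI, but its tail still contributes a small bias to the
next trial's pooled baseline; the tests account for this with a
kernel-trace oracle rather than pretending the carryover away. Optional
rigid motion applies per-frame integer translations (recorded as ground
truth); sensor noise is additive Gaussian. What the movies do *not*
emulate: optics/PSF blur, neuropil contamination, eye movements, photon
(shot) noise, or bleaching — so segmentation/recovery results on synthetic
movies bound what the code does, not how real tissue behaves.

## Segmentation

Motion correction maximizes normalized cross-correlation between each
frame and a reference (mean of the first 20 frames) over integer shifts
bounded by `max_shift` (default 10 px), implemented by sliding the
reference's central crop over the frame (`skimage.feature.match_template`);
out-of-frame pixels are filled with the frame median. With a blurred
average reference, all frames share at most a constant 1-px bias —
harmless, since a common offset cancels in differential images.

Differential images: per trial, F = mean of post-onset frames 6–9
(1-based), F0 = mean of the 4 pre-onset frames; ΔF = F − F0 averaged over
the condition's repeats, and the two drift-direction images of each
orientation are averaged, giving the 216-image sequence ordered by SF,
size, orientation.

Sequential screening per image: pixels of already-accepted ROIs are set to
the current image mean (progressively lowering the image SD so weak cells
surface); a difference-of-Gaussians band-pass filter (kernel FWHM 2 px and
10 px, i.e. σ = size/2.355 — the "filter size" reading is explicit in the
config); threshold at mean + 3 SD of the filtered image; 8-connected
components with >25 px become candidates after hole filling (the band-pass
dips at the center of large somata, but the ROI is the whole cell body).
Overlap with the most-overlapping existing ROI decides the candidate's
fate by fractions of its own area: <1/4 new, 1/4–3/4 discarded, >3/4
merged. The sweep runs twice, pass-1 ROIs counting as existing in pass 2.
The roundness filter 4πA/P² > 0.9 is applied once at the end. The printed
source formula for roundness is garbled; 4πA/P² is the only dimensionless
reading that is 1 for a disk and penalizes elongation, and the exponent is
exposed in the config. Perimeter uses the calibrated chain-code estimator
(`skimage.measure.perimeter`, 4-neighborhood), which is nearly unbiased
for rasterized disks down to cell-body sizes (~0.95–0.99 roundness at
radii 3–6 px) while thin neuropil-like lines score far below 0.9; the
marching-squares contour length is available as an alternative but
systematically overestimates digital disk perimeters (disk roundness
~0.8–0.87, which would reject genuine somata at the 0.9 screen).

## Tuning analysis

ΔF/F uses post-onset frames 5–8 (1-based) — deliberately different from
the screening window 6–9, matching the two stages' separate definitions —
with the baseline F0 pooled over all 12 trials of a condition to reduce
baseline noise; F0 ≤ 0 flags the neuron invalid. A condition's scalar
response averages the 11 strongest of 12 trials (the weakest, often
negative, trial is dropped — read as the rank-weakest per condition);
direction-selective neurons (Friedman p < 0.05 across the two directions,
blocked by condition × trial) instead use the 6 preferred-direction trials.

Per monocular eye, the best (SF, size, orientation) is the grid argmax
(ties to the lowest design-order index). Tuned neurons pass a Friedman
test (α = 0.01, blocks = trials) across the 12 orientations or 6 SFs in at
least one monocular condition *and* achieve R² > 0.5 in the corresponding
trial-level fit. The Friedman statistic is computed in-house (mid-ranks,
Conover's tie-robust χ² form, k−1 df) because the two-treatment direction
screen is outside scipy's supported range; it is cross-checked against
scipy for k ≥ 3.

Orientation fits use R(θ) = a₁·2^(−(d(θ,θ₀)/σ)²) + b with circular
distance modulo 180°; the base-2 form makes σ literally the half-width at
half-height, the only reading consistent with the model's description. SF
fits use the five-parameter difference of Gaussians with the baseline
initialized at the minimum mean response. Both are bounded least squares
(a₁ ≥ 0, σ_ori ∈ [5°, 90°], σ₁,σ₂ > 0) on trial-level points with analytic
Jacobians, five fixed-seed multi-starts (stopping early once R² > 0.995),
and R² computed over trial-level points; total non-convergence reports
R² = −∞ and the neuron is not tuned. Each eye's peak response is the
orientation-fit peak a₁ + b at that eye's own best condition (falling back
to the DoG-curve peak if the orientation fit fails), and
ODI = (R_i − R_c)/(R_i + R_c); a non-positive peak sum excludes the neuron.

## Pipeline

`run_pipeline` executes simulate → (segment, movie runs only) → tune →
model from one `RunConfig` (single seed; every threshold at its analysis
default: sd_k = 3, area_min = 25, roundness_min = 0.9, α_Friedman = 0.01,
α_direction = 0.05, R²_min = 0.5, 60 bins, ε = 10⁻³), writes plain-text
intermediates (CSV tables, TIFF images, JSON reports, a YAML copy of the
config) into the output directory, and records the filter cascade
(simulated → ROIs → tuned → binned). Re-running a completed directory
without `force` is a no-op.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`numpy.random.default_rng`
/ `SeedSequence`); multi-start jitter uses module-level fixed seeds so
repeated fits are identical. The test suite and acceptance script use
scaled problem sizes chosen to exercise every code path at stable
statistics: 60-bin fits on 300-neuron populations (20 seeds for recovery
medians), 120-neuron tuning-recovery and null-specificity populations,
300-neuron full-pipeline qualitative runs, and 32-cell rendered movies on a
160×160 field with a 4-orientation single-SF design (preferred orientations
spread across the design, as in real populations — a single shared
preference makes every cell light up in one differential image and defeats
the sequential SD-reduction trick).

## Known limitations

- Exact full-loop parameter recovery holds in the m = −1 regime, where the
  ODI recomputed from fitted peaks equals the generative ODI. For m ≠ −1
  the measured ODI is a monotone distortion of the generative one and the
  binned curve leaves the model family; the fits then describe, as with
  real data, the response-vs-measured-ODI relation.
- Bin medians of a convex response curve are biased off the curve when bin
  occupancy is even (median = midpoint of a chord); with odd per-bin counts
  and monotone curves the median commutes exactly. Recovery tests use
  odd-occupancy configurations where exactness matters.
- The movie generator's carryover bias (kernel tail into the next baseline)
  is real but small at realistic response amplitudes; it is measured, not
  corrected.
- The roundness screen's absolute values are estimator-dependent; the
  chain-code estimator and exponent are configuration, and the same
  estimator is used in the tests that justify the 0.9 threshold.
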