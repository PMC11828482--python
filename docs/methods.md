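# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `azquant`. All quantities below are computed by the test
suite or the analysis drivers; nothing here is asserted that the code does
not itself measure.

## 1. Synthetic data model

Every generator is seeded through a `numpy.random.SeedSequence`; per-object
child streams are spawned from the top-level seed, so enlarging a
simulation (adding an AZ, a sweep) leaves previously generated objects
bit-identical, and identical (config, seed) pairs reproduce outputs exactly.

### 1.1 Photoconversion / bleaching traces and movies

Each tagged channel carries one photoconvertible fluorophore following a
four-state chain stepped per frame:

    unconverted → bright ⇄ dark → (bright) → bleached

Conversion becomes possible at the UV onset frame with per-frame
probability `conversion_rate`; a bright fluorophore bleaches with
`bleach_rate` or blinks off with `blink_off_rate`; a dark fluorophore
returns with `blink_on_rate`. Bleaching proceeds from the bright state
only — photobleaching requires excitation, and dark-state molecules are
protected. State dwell times are sampled as geometric variates (competing
risks for leaving the bright state), which is equivalent to per-frame
Bernoulli stepping but faster.

Defaults (20 Hz, 2500 frames, UV onset at frame 250, 71 nm pixels):

| parameter | default | rationale |
| --- | --- | --- |
| conversion_rate | 0.35 /frame | ~95% of tags converted within 8 frames, so the early peak reflects the full complement before appreciable bleaching |
| bleach_rate | 0.001 /frame | mean bright lifetime 50 s: bleaching completes near the end of a 2500-frame movie, leaving isolated single-molecule events in the second half — the regime the unitary estimator reads |
| blink_off_rate | 0.003 /frame | a handful of reversible dark events per trace |
| blink_on_rate | 0.1 /frame | dark dwells of ~10 frames, long enough to segment |
| noise_sd | 10 a.u. (trace) | trace SNR 10 at unitary 100 a.u. |

The actual blinking kinetics of mEOS-class tags in vivo are not published
for this preparation; these are free parameters of the simulation, chosen
once for self-consistency with the counting procedure and exposed in the
config. The steady-state dark fraction at these rates is ~3%, which is the
main source of the small negative bias of the peak (see §2.4).

Movies render each AZ as a unit-sum Gaussian spot (σ = 1.3 px) on a
constant background with additive Gaussian read noise (Poisson shot noise
optional), plus rigid per-frame drift. Trace-level simulation applies the
noise directly to the summed ROI trace.

### 1.2 Synapse stacks

Boutons are smoothed ellipsoids (the HRP membrane channel). Each AZ is a
central cac cluster ringed by four brp puncta at `ring_radius` (106 nm
default) in one optical section, with a random ring orientation. Two cac
channels carry the two isoform tags; each AZ draws a content class from
`content_fractions` ({both: 0.95, B_only: 0.05} default) and per-channel
intensities with 15% lognormal-like jitter, at a 2:1 B:A default ratio.
Spots are analytic Gaussians deposited with their configured integrated
intensity; additive Gaussian noise is *not* clipped at zero — the channels
emulate background-subtracted data, and clipping would skew the background
mean above its median, which matters for the MAD-based presence calls.

Two sampling regimes are used throughout: STED-like (voxels 191.69 × 24.44
× 24.44 nm, PSF σ 150/30/30 nm) for ring geometry, and confocal-like
(300 × 80 × 80 nm, σ 350/130/130 nm) for colocalization, intensity ratios,
and content classification. The split is physical: at STED resolution the
brp ring mask contains essentially no cac intensity (the cluster sits
106 nm from the puncta with a 30 nm PSF), so mask-based intensity and
content measurements are only defined at confocal resolution, where the
blurred cluster fills the scaffold footprint.

Coordinates follow one convention everywhere: (z, y, x) order, 0-based
voxel indices, intensity centered on voxel centers, physical position =
index × voxel size in nm.

### 1.3 TEVC sweeps

EPSCs are biexponential kernels (rise 1 ms, decay 6 ms, unit peak) scaled
negative (inward). Per-stimulus amplitudes follow a depression recursion

    d₁ = 1,  d_{k+1} = p + (d_k − p)·exp(−Δt_k/τ)

with plateau fraction p (0.8 default) and time constant τ (5 s default);
for uniform trains this telescopes to the closed-form single exponential
the fitting stage assumes. Two-stimulus protocols can override the second
amplitude with an explicit paired-pulse ratio. Protocols at 0.1 Hz (single
evoked EPSCs) should set `depression_plateau = 1.0`, which reduces the
recursion to constant amplitudes (full recovery between stimuli).
Miniature EPSCs arrive as a Poisson process (2 Hz, 0.8 nA, CV 0.25) using
the same kernel; overlapping kernels sum linearly. Sampling is 50 kHz with
additive Gaussian current noise.

## 2. Channel counting

### 2.1 Drift correction

Each frame is registered to the temporal-median image by phase
cross-correlation with subpixel refinement. A frame's estimate is kept
only if the shifted frame correlates with the reference (r ≥ 0.2);
structureless frames — pure noise before photoconversion, fully bleached
tails — inherit the temporally nearest reliable shift. With no reliable
frame at all the correction is skipped with a warning.

### 2.2 ROI traces

The readout is a 5 × 5 px sum centered on the AZ, minus a per-frame local
background (mean over the square annulus between the 5 px and 9 px windows,
scaled to the ROI area). The original procedure says only "after
background subtraction"; the annulus estimator is this package's choice and
is configurable.

### 2.3 Step detection

Piecewise-constant fitting by exact penalized least-squares segmentation:
minimize the within-segment sum of squared deviations plus a penalty per
change point, over *all* segmentations, by the optimal-partitioning
dynamic program (O(n²), exact — verified against brute-force enumeration
and an independent k-constrained DP in the tests). The default penalty is
2·σ̂²·log n with σ̂ from the median absolute deviation of first differences
(divided by √2 for the difference). Ties are broken toward fewer change
points. A trace best fit by one segment yields zero steps — not an error.

### 2.4 Unitary intensity and the count

Step amplitudes whose post-step segment starts in the second half of the
illumination sequence are collected (both polarities: bleaching down-steps
and blink-on up-steps). Two reliability filters apply: amplitudes below 4
robust trace sigmas are discarded (spurious noise steps would otherwise
form a low mode and inflate counts catastrophically), and steps flanked by
a segment shorter than 5 frames are dropped (their levels are too
uncertain; short dark dwells otherwise contribute attenuated amplitudes
that bias the unitary low — this filter measurably reduced both MAE and
bias against generator truth). Because amplitudes fall on an
integer-multiple ladder (1u, 2u, …), the distribution is clustered by 1-D
k-means with k ∈ {1, 2, 3} chosen by mean silhouette (threshold 0.5); the
unitary intensity is the median of the smallest mode.

The peak is the maximum fitted segment level in the window from UV onset
to 25% of the post-onset frames ("shortly after starting the
photoconversion" — the window is this package's operationalization and is
configurable). The count is peak/unitary, un-rounded; cohort means are
fractional by construction.

Known bias: at trace SNR 10 the recovered counts run ~3–5% high (MAE ≈
0.35 channels over counts 4–16), dominated by slight unitary
underestimation from residual attenuated amplitudes, partly offset by the
~3% dark-state deficit of the peak. Both effects are visible in the
acceptance output (e.g. a cohort generated at a true mean of 10.8 recovers
≈ 11.1–11.4).

QC: traces with no late single-molecule events, no signal, or a peak
segment spanning the UV onset are flagged and excluded from aggregation
(excluded counts are reported); animals with fewer than 30 passing AZs are
flagged, mirroring the cohort inclusion rule.

## 3. Colocalization

All statistics use masked voxels only; the mask (Otsu on the smoothed HRP
channel, small components removed) is applied before the regression and
before thresholding. The Costes scan uses orthogonal (total least squares)
regression, matching the original formulation, and descends through the
unique observed intensities of channel a; the first pair whose
below-both-thresholds correlation is ≤ 0 wins (undefined correlations —
fewer than 2 voxels or zero variance — are skipped). If no crossing exists
(e.g. perfectly proportional channels) the minimum intensities are
returned with a `no Costes crossing` flag. Manders M1/M2 are computed with
the Costes thresholds by default; passing `thresholds=None` gives the
unthresholded co-occurrence variant (the original study's choice between
the two is not recorded; both are available).

## 4. Puncta geometry and content

Detection: Gaussian pre-smoothing (0.5/1/1 voxels), 3-D local maxima with
a 3-voxel minimum separation, threshold = median + k·MAD of masked
smoothed intensities (k = 6 for detection; a 1% dynamic-range floor guards
noiseless images whose MAD is zero). Centers are refined by the
threshold-subtracted intensity-weighted centroid of the in-plane 5 × 5
neighbourhood.

Distances: per cac punctum, the in-plane Euclidean distance to the nearest
brp punctum with the identical plane index ("within the same optical
sections" — no z-interpolation); cac puncta without a same-plane partner
are excluded and counted. On noiseless 24.44 nm stacks the recovered
median is ~4 nm below the generated 106 nm radius: centroid errors of a
fraction of a voxel, taken through a minimum over four candidate puncta,
bias the minimum slightly low — an inherent property of nearest-neighbour
readouts at this sampling, well inside the half-voxel acceptance band.

Masked intensity: the brp mask is built as in §3, optionally dilated
isotropically; AZs are connected components, with components closer than
2 voxels merged (label the gap-dilated mask, restrict labels to the
original mask). Per-AZ and global mean intensities are returned;
normalization divides by the control-group mean (idempotent by
construction).

Content calls: a channel is "present" at an AZ when its per-AZ mean
exceeds the background median + 3·MAD, background sampled inside the HRP
mask but outside the AZ components. The criterion the original analysis
used for an AZ "containing" a tag is unrecorded; k = 3 is configurable and
this choice is the main free parameter of the content fractions.

## 5. TEVC metrics

Filtering: zero-phase Gaussian smoothing with σ_t = √(ln 2)/(2π f_c), which
gives |H(f_c)| = 2^(−1/2) (−3.01 dB) exactly; DC gain is 1 by kernel
normalization. The filter contract (attenuation, DC gain, zero phase) is
asserted in the tests.

EPSC measures: baseline = mean over 5 ms ending 0.5 ms before the
stimulus; amplitude = baseline minus the most negative sample in a 20 ms
response window (positive magnitude); half-width by linear interpolation
at the half-amplitude crossings; charge = ∫(baseline − I)dt with only
below-baseline samples contributing (configurable). Amplitudes below 3
pre-stimulus SDs are flagged `no event`. The response and baseline windows
are not recorded in the original procedure; the defaults here are logged
with every run.

Paired pulses: both averaging schemes are reported (mean of per-sweep
ratios; ratio of mean amplitudes); they coincide exactly when first
amplitudes are equal, and the ratio-of-means scheme has the smaller
Jensen bias under noise (asserted in tests). Below ~25 ms IPI the second
EPSC rides on the first's decay and local-baseline amplitudes understate
the true ratio — the same summation that motivates measuring bursts by
charge from the pre-train baseline rather than by per-stimulus peaks.

Depression: A(t) = plateau + (A₀ − plateau)·e^(−t/τ) fit per animal by
bounded least squares, initialized from the data (A₀ = first amplitude,
plateau = mean of the last 20%, τ = time to the halfway point). Constant
trains return plateau = A₀ with τ flagged unidentifiable. At 1 Hz × 60
points with 5% multiplicative noise the per-seed τ spread is ~19% (an
intrinsic identifiability limit of a three-parameter exponential read from
a 20% depression depth); the seed-averaged τ recovers within ~5%.

Mean quantal content divides the mean evoked amplitude by the mean mEPSC
amplitude. mEPSC *detection* is deliberately out of scope — the module
ingests event-amplitude lists (from the generator's truth or any external
detector).

## 6. Pipeline and reproducibility

A single declarative config (YAML) with defaults filled and unknown keys
rejected (with a nearest-key suggestion) drives `simulate → count → coloc
→ puncta → ephys`. Every run writes a resolved-config echo, per-stage
record counts that reconcile (input = passed + excluded), and all
randomness derives from the one seed: rerunning with the same seed
reproduces every CSV byte-for-byte (asserted end-to-end).

## 7. Problem sizes

The validation studies run at desk scale: 300 traces × 2500 frames for
counting recovery, 3 animals × 30 AZs per condition for the two-genotype
ratio, 8–10 stacks of 8 AZs for geometry/content, 50-trace fixtures for
the segmentation oracle, 100 seeds for depression recovery. These sizes
give comfortable statistical margins for the stated tolerances while
keeping the full suite around a minute of CPU.

## 8. What passing tests do and do not show

The generators emulate the *structure* of the real data — staircase
bleaching with blinking, ringed puncta with PSF blur, kernel-summating
EPSC trains — not optical or biophysical realism: no vectorial PSF or
TIRF evanescent-field depth, no STED depletion physics, no Poisson-limited
photon statistics by default, no series-resistance or space-clamp errors,
and AZ rings are always planar within one section. Passing recovery tests
therefore demonstrates that the estimators are correct and well-behaved
under the stated noise models, not that real-data systematic errors
(out-of-focus light, antibody penetration gradients, muscle clamp quality)
are absent. The deposited raw data of the original study remain the only
ground for those questions.
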