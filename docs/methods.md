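# Methods

## Signal model and fitting

Each pixel of a relaxometry series is modelled as a monoexponential decay

    S(t) = S0 · exp(−t / T),

with `t` the spin-lock time (TSL; T = T1rho) or echo time (TE; T = T2) in
milliseconds. The default acquisition grids are TSL = 20/40/60/80 ms and
TE = 13/26/39/52/65/78/91 ms.

Fitting is two-stage. A log-linear least-squares fit on the positive
samples initializes (S0, T); a damped Gauss-Newton (Levenberg-Marquardt)
refinement then minimizes the unweighted residual sum of squares of the
monoexponential itself. The bulk fitter solves the 2×2 normal equations in
closed form for all pixels simultaneously, so whole-ROI maps cost
milliseconds. Convergence: relative cost change ≤ 1e−12 or a step below
1e−10 relative, at most 60 iterations. A noiseless decay is recovered
exactly (the log-linear pass is already exact; refinement terminates with a
zero step), and the estimate is scale-invariant: scaling the signal by c
scales S0 by c and leaves T untouched.

A fit is declared invalid — and stored with the zero-sentinel T = 0, the
convention used throughout for "excluded pixel" — when fewer than 2 samples
are positive, the refinement fails, the fitted T falls outside (0, 2000]
ms, or S0 ≤ 0. The 2000 ms cap marks runaway fits: with a maximum
weighting time of 80–91 ms, longer times are not distinguishable from a
flat signal. `exclude_invalid` re-applies the sentinel rule idempotently;
all downstream statistics use only valid pixels.

The model deliberately has no Rician noise-floor term. Magnitude-MRI noise
makes the plain monoexponential fit slightly biased upward; at the study's
SNR of 50 the simulated bias of the zone mean is below 1% (the test suite
bounds it at 2% with 10,000 pixels), and the simulator is the instrument
for quantifying — not correcting — this bias.

## Registration

Frames of a series are rigidly coregistered to the first frame, per slice,
in 2D. The similarity metric is normalized cross-correlation, chosen
because frames at different weighting times differ in contrast scale and
NCC is invariant to affine intensity changes. The optimizer is
deterministic: an exhaustive coarse grid over integer shifts (±4 px) and
1°-step rotations (±4° by default), followed by Nelder-Mead refinement to
1e−3 px/deg. Each candidate rotation is resampled once and integer shifts
are evaluated by array slicing, so the coarse stage is cheap. The metric is
restricted to an interior margin (search extent plus the rotation sweep at
the corners) so that out-of-field zeros introduced by warping cannot
corrupt the correlation; a dilated ROI mask further restricts it when
available. Resampling is bilinear; out-of-field pixels are zeroed and
tracked in a validity footprint. Simulated motion within ±4 px / ±5° is
recovered well within 0.25 px / 0.5° at SNR ≥ 30, and registration is
idempotent to within the same tolerance.

## Zonal partition

*Horizontal*: the superficial zone is the first layer of ROI pixels along
the meniscal surface — every ROI pixel with at least one of its 8
neighbors outside the ROI, equivalently ROI minus its 3×3 erosion; the deep
zone is the remainder. 8-connectivity is the default because a "layer
along the surface" naturally includes diagonal surface contact; a config
switch provides 4-connectivity, since either convention is defensible. The
two zones partition the ROI exactly; a one-pixel-thick ROI yields an empty
deep zone, which is flagged rather than an error.

*Vertical* (anterior/posterior horns only; the meniscal body is excluded by
contract): each pixel's normalized position between the free (inner) edge
and the periphery is

    u = d_free / (d_free + d_periphery),

where both distances are geodesic within the ROI (8-connected shortest
paths with Euclidean step weights, computed with a minimum-cost-path
search). Zones are the thirds white (u < 1/3), red-white (1/3 ≤ u < 2/3)
and red (u ≥ 2/3); ties at the cuts go to the outer zone by the half-open
rule. Geodesic thirds were chosen over equal-area or angular sweeps because
they generalize a manual free-edge-to-periphery division to arbitrary
crescent shapes and reduce exactly to equal-width thirds on a rectangle.
Superficial-layer pixels participate in the vertical zones. Edge
identification (`infer_edges`) splits the ROI boundary at the median
distance from the joint center: nearer pixels are free-edge candidates,
farther ones periphery. A boundary whose distance spread is below 2 px
(e.g. a circular ROI) is degenerate and must be given explicit edges.

## Zonal statistics

Zone summaries are mean ± SD of valid pixels (SD with n−1 denominator, 0
for a single pixel). Zones are compared with the two-sided Mann-Whitney U
test: the exact null distribution when the pooled sample is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
corrections (backed by `scipy.stats.mannwhitneyu`; the test suite checks
both paths against exhaustive and Monte-Carlo permutation oracles).
Significance is starred at p < 0.05 / < 0.001 / < 0.0001 and no
multiple-testing correction is applied.

Two pooling modes exist for group comparisons in the pipeline. The default
treats the subject as the statistical unit (per-subject zone means, one
value per subject per zone), the defensible choice given spatial
correlation among pixels; `stats.pooling: pixels` pools pixels directly,
reproducing spreadsheet-style pixelwise analysis. Pixel pooling inflates
the effective sample size — this is a known limitation of pixelwise
testing, reported here as a mode, not corrected.

## Observer agreement

ICC model: ICC(2,1) — two-way random effects, absolute agreement, single
measures — from the ANOVA mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

This is the standard model for different observers rating the same
subjects; it is validated against an independent implementation
(`pingouin.intraclass_corr`, type ICC(A,1)) to 1e−8. Interpretation bands
follow Fleiss: applied as icc < 0.40 poor, < 0.60 fair, ≤ 0.74 good, else
excellent, so the printed band edges (0.40–0.59, 0.60–0.74) are honoured
and no value falls between bands. A constant ratings matrix has no subject
variance; the ICC is then reported as undefined rather than forced to a
number. Bland-Altman agreement reports the bias (mean of first-minus-second
differences) with 1.96·SD limits of agreement (SD with n−1 denominator).
Inter-observer tables compare observer R1 vs R2 (first sessions);
intra-observer tables compare R1's two sessions.

## Synthetic phantom

The phantom emulates a sagittal multi-TSL/TE study of both menisci. Each
meniscus is an annular sector ("crescent") on a 128×128 grid (inner/outer
radii 13/23 px, 240° arc, 3 slices by default, one crescent per side), with
the arc split into equal angular thirds for the anterior horn, body and
posterior horn. Ground-truth relaxation times are assigned per zone using
the same partition functions the analysis applies, so the truth is
recoverable by construction. S0 = 500 everywhere; noise is Rician with
sigma = 10 (SNR 50): each pixel intensity is sqrt((ν+g1)² + g2²) with
g1, g2 ~ N(0, σ), which has the Rayleigh background mean σ√(π/2) and
high-SNR mean ≈ √(ν²+σ²) checked in the tests.

Default zone truths are the reference zonal means the simulator is built to
reproduce: the medial-meniscus horizontal values 84.3/76.0 ms (b-FFE
T1rho), 96.5/91.7 ms (SPGR T1rho) and 80.4/74.4 ms (T2), and the vertical
horn values including 88.4/77.1 ms (medial posterior horn, b-FFE),
104.9/96.8 ms (SPGR) and 104.6/84.2 ms (lateral anterior horn, T2).
Lateral-side horizontal values and the remaining horn cells, for which no
reference numbers exist, were fixed once at plausible values inside the
reported overall ranges (b-FFE 72–97 ms, SPGR 81–105 ms, T2 60–105 ms)
preserving the superficial > deep and white > red orderings where those
were reported (and the reversed white < red ordering for the lateral
posterior horn on T2). Red-white values are midpoints. Which zoning family
(horizontal or vertical) drives a segment's per-pixel truth is selectable
per segment (`truth_basis`); horizontal is the default since it covers all
six segments.

Optional features: per-frame rigid motion drawn uniformly within
configurable ranges (default 0 — motion is injected explicitly in
registration tests rather than blurring every fixture); a forced-invalid
fraction that zeroes pixels across all frames to exercise the exclusion
rule; and observer jitter, which toggles each boundary pixel with a given
probability (default 0.02), locally eroding or dilating with equal
probability and rejecting removals that would disconnect the mask. All
randomness flows from the single spec seed through named substreams
(geometry, noise, motion, jitter, invalid); a fixed seed yields
byte-identical studies.

In the cohort pipeline, subjects differ by a deterministic per-subject
outer-radius perturbation (±1.5 px) and a single multiplicative factor
(uniform 0.92–1.08) applied to all zonal truths. The factor supplies the
between-subject variance that agreement statistics require while keeping
cohort means centred on the reference values.

What the phantom does *not* model: partial-volume averaging at tissue
boundaries, anatomically realistic meniscus shape, B0/B1 field effects,
coil sensitivity, slice-to-slice anatomy change, and spatially correlated
noise. Passing tests therefore demonstrate correctness of the algorithms
under the stated generative model, not clinical accuracy on real knees.

## Pipeline and problem sizes

`run_study` simulates a cohort (default 5 subjects, 3 slices), registers
each series to its first frame (enabled by default), fits parameter maps
over the union of all observers' masks per side, computes both zonings per
observer, and emits the zonal summary/comparison tables, the ICC and
Bland-Altman agreement tables, and a manifest with the seed, config hash
and the pixel-accounting identity n_superficial + n_deep = n_valid +
n_excluded per segment, asserted at run time. Identical config and seed
produce byte-identical CSVs (numbers written at 6 significant digits).

The validation suite runs at desk scale: 2,000 pixels per zonal-recovery
target, 10,000 pixels for the bias bound, 1,000 random masks and 100
random crescents for the partition oracles, 100,000 permutation draws for
the Mann-Whitney approximation check, and cohorts of 2–6 subjects for the
pipeline and agreement simulations. These sizes keep the full suite under
a minute while leaving every estimate's Monte-Carlo error far below the
tolerance it is tested against.
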