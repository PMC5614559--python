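# Methods

This note documents the models behind `boutonmap`, the parameters that
matter, the numerical choices made where the design was open, and what the
synthetic benchmarks do and do not demonstrate.

## Units and conventions

- Best frequencies (BFs) are carried internally in **octaves re 1 kHz**,
  `log2(f / 1 kHz)`; conversion to/from Hz happens only at I/O boundaries.
  ΔBF and co-tuning are then plain subtraction and standard deviation.
- Images are indexed (row, col) = (y, x); shifts and drift are (dy, dx) in
  pixels. The default pixel size is 90/512 ≈ 0.176 µm/px (a 512 px frame
  spanning a ~90 µm field).
- Sample statistics use the n−1 denominator throughout.

## Synthetic forward model

The generator renders a tone-mapping session from a fully specified scene,
so the generative parameters serve as ground truth for every downstream
stage.

**Stimuli.** A `StimulusGrid` is log-spaced in frequency (constant ratio
`2^step`) crossed with arithmetic levels; the canonical protocol is 25
frequencies × 4 levels = 100 conditions. A `StimulusSchedule` is a seeded
uniform permutation of the condition multiset (each condition exactly
`repeats` times), constant inter-onset interval, partitioned into equal
consecutive blocks.

**Tuning.** Each bouton responds to a tone with amplitude
`A · exp(−(x − BF)² / 2σ²) · g(level)` where `x` is the tone's octave
value, σ is the tuning width in octaves, and `g` is a monotone level gain —
by default a linear ramp from 0.5 at the lowest level to 1.0 at the highest
(measured FRAs show level dependence but no canonical functional form, so
the simplest monotone choice is used).

**Calcium kernel.** Transients follow a difference of exponentials
`k(t) ∝ exp(−t/τ_d) − exp(−t/τ_r)`, unit peak, with defaults τ_r = 70 ms
and τ_d = 0.4 s. τ_d was chosen so that the transient has essentially
decayed (k < 5% of peak) by the next tone onset 1.5 s later, emulating an
indicator whose signal returns to baseline between stimuli at the 0.66 Hz
presentation rate; with τ_d = 0.6 s the residual at 1.5 s would still be
~12% of peak.

**Rendering.** Boutons are isotropic Gaussian blobs (σ_px = radius/2,
truncated at 3σ — no optical PSF model). Frame t is
`baseline + Σ_b brightness_b · blob_b(center + drift_t) · (1 + trace_b(t))`
where the trace is the schedule-driven amplitude train convolved with the
kernel; trial-to-trial reliability is a multiplicative Gaussian jitter on
the trial amplitude (SD 0.2 by default — measured bouton reliability is not
well constrained, so it is an explicit parameter). Noise is Gaussian with
variance `floor + gain·signal` (Poisson-like mean–variance scaling, the
simplest model exposing an SNR knob). Drift is a boxcar-smoothed random
walk rescaled to a configurable peak excursion (default ±2 px per session
in the pipeline, ±3 px in the registration benchmark), applied by shifting
blob centers — sized to exercise registration without tearing the field.

What the generator does **not** emulate: neuropil contamination, axial
(z) motion, bleaching, optical sectioning, correlated noise between
neighboring boutons, and multi-bouton axonal identity. Passing benchmarks
therefore demonstrates the correctness and calibration of the chain under
its stated model, not robustness to every artifact of real recordings.

## Registration

Each frame is aligned to the pixelwise mean of the first 50 frames (which
50 is not critical; configurable, with an optional per-block template
reset) by Fourier-upsampled phase cross-correlation (`scikit-image`),
default upsample 20 (0.05 px resolution — finer is slower with no benefit
at the benchmark noise levels). Frames are translated by the negated
estimated shift with spline interpolation and edge replication; an exactly
zero estimate passes the frame through untouched. Only whole-frame rigid
translation is corrected. The drift benchmark compares recovered shifts to
the injected trajectory after removing the mean drift of the template
frames, which the template absorbs by construction.

## ROI detection

The chain mirrors classical patch-based bouton segmentation with every
unstated constant made explicit:

- patches 8×8 px, stride 4 (50% overlap);
- HOG: 2×2 cells of 4×4 px, 9 unsigned orientation bins, L2 block norm —
  the smallest standard layout that fits an 8×8 patch (36 features);
  patches are min–max normalized first, so features are gain-invariant;
- the mean image (and, identically, the training patches) are pre-smoothed
  with a Gaussian of σ = 0.8 px: HOG on raw shot noise is unreliable at
  single-bouton scale;
- classifier: linear SVM, hinge loss, C = 1. Manual annotation is replaced
  by programmatic labels from the generator (blob patches vs background /
  axon-shaft patches);
- a brightness gate at 5 robust SDs (1.4826·MAD) above the image median is
  applied to patches and to final masks. HOG is intensity-blind by design,
  so without this gate structured noise passes the SVM; the gate is
  relative to image statistics and preserves gain invariance;
- seed: strongest circular-Hough circle (radii 1–4 px, matching ~1–2 µm
  boutons at 0.176 µm/px) on the Canny edges of the patch, then the
  brightest pixel inside that circle; fallback to the patch argmax when no
  circle is found;
- region growing: 8-connected flood fill from the seed, inclusion at
  `background + 0.5·(seed − background)` with the patch median as
  background. Growth runs in a window expanded by patch_size/2 around the
  patch so a bouton straddling a patch border produces one complete mask
  rather than clipped fragments;
- erosion by a 2×2 square to separate touching boutons; masks below 2 px
  or above 40 px (leakage) are dropped;
- recombination: union-find merge of masks with IoU > 0.5 *or* overlap
  covering > 0.8 of the smaller mask (the containment clause absorbs
  clipped duplicates of one bouton detected from neighboring patches).

Detection is scored by greedy one-to-one matching of ROI centroids to
generative centers within 2 px.

## Signal extraction and tuning

ΔF/F baseline F0 is the 20th percentile of the raw ROI trace, computed per
recording block (robust to evoked transients; the per-block choice matches
a workflow that corrects drift between blocks). The high-pass is a
2nd-order Butterworth at 0.03 Hz applied forward–backward (zero phase).
Single-trial responses average ΔF/F over the half-open window
[onset, onset+15) frames — the onset frame is included; the
electrophysiology variant of the analysis only changes the window length.

The responsiveness gate is a classical fixed-effects one-way ANOVA across
the 100 conditions at p < 0.001, per ROI, with no correction across ROIs.
Degenerate inputs (zero variance everywhere) are defined as p = 1; zero
within-group variance with unequal means as p = 0. Monte-Carlo calibration
with 10⁴ i.i.d. Gaussian null boutons under the full 900-trial protocol
reproduces the nominal inclusion rate.

The FRA is smoothed across frequency (never across level) with a 3-point
running average, shrinking to the 2 available points at the edges. The BF
is the argmax of the level-averaged smoothed curve; ties break to the
lowest frequency, and a perfectly flat curve has no BF (flagged). This
order of operations — smooth, then level-average, then argmax — is fixed.
Gaussian tuning fits are least-squares with an offset term on the linear
response vs log2-frequency axis (center constrained to the grid span ±1
octave, σ ∈ [0.1, 6] octaves); non-convergence yields a flagged fit.

## Population statistics

- **Co-tuning** = sample SD of a region's BF distribution (octaves).
- **Distance–ΔBF**: Spearman rank correlation over all unordered in-plane
  pairs; the equal-BF exclusion removes exactly the ΔBF = 0 pairs; binned
  means use 10 µm bins.
- **Normalized BF distributions**: per region, subtract the median BF,
  histogram on a common octave grid as fractions, average with equal
  region weight.
- **Axis sweep**: Pearson correlation between BF and the scalar projection
  of position onto axes at 1° spacing over 360°; the reported direction is
  the strongest *positive* correlation (the profile is antisymmetric under
  180° flips), ties to the smallest angle. Pearson is used because the
  target is a linear spatial gradient. Exact angle recovery in the
  noiseless case requires isotropic position scatter; with a finite random
  sample the peak shifts by the sample anisotropy (well inside the ±10°
  benchmark band at n = 300).
- **Paired comparisons**: Shapiro–Wilk on the pairwise differences routes
  to the two-sided Wilcoxon signed-rank test (non-normal, p < 0.05) or the
  paired t-test; the branch can also be forced explicitly, which matters
  when a small all-positive sample happens to look normal but the exact
  signed-rank tail is wanted. Effect size r = z/√N with N = number of
  pairs by default (the convention is exposed as a parameter since both
  pair- and observation-count readings appear in the literature); z is the
  normal approximation of the signed-rank statistic, while the t branch
  reports the bounded r = √(t²/(t²+df)) and defines z = r·√N for
  consistency. All-zero differences give p = 1, r = 0.

## Pipeline and reproducibility

The YAML configuration is validated against the full default tree: unknown
keys are rejected by name, and cross-field constraints (response window ≤
stimulus interval, high-pass cutoff < Nyquist) are enforced before any
stage runs. One global seed fans out to per-stage seeds through a fixed
`SeedSequence` derivation, so stages are independently reproducible; the
manifest records a sha256 per output file and identical configurations
reproduce identical bytes.

## Problem sizes

The package's standard synthetic session uses a 120×120 px field with 25
boutons, the full 100-condition grid with 3 repeats (interval 45 frames at
30 Hz; ~13.5k frames) — large enough that every stage runs exactly as it
would on a full-size session while keeping a complete end-to-end run near
half a minute. Schedule-level checks use the full 9-repeat, 900-trial
protocol. The detection benchmark uses 50 boutons at SNR 5 on a 256×256
field; gate calibration uses 10⁴ null boutons; estimator checks use 10⁴
draws (co-tuning), 100 replicates (axis sweep) and 50 replicates of 36
region pairs (layer contrast).

## Known limitations

- Bouton identity across z-planes and sessions is out of scope; each run
  analyzes one plane.
- The SVM is trained on generator-labeled patches; applying the detector to
  real data would require retraining on annotated patches from that data.
- No neuropil subtraction or spike inference; ΔF/F is the analysis unit.
- The Gaussian tuning fit assumes a single peak; multi-peaked FRAs are
  summarized only by their argmax BF.
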