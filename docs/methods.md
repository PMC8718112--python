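# Methods

This note documents the models and procedures implemented in
`receptorquant`, the parameters that matter, the numerical conventions, and
what the synthetic validation does and does not establish.

## Image model and segmentation

A measurement unit is one neuron imaged as a two-channel Z-stack
(`TwoChannelStack`): a cytoplasmic GFP fill used only for geometry, and a
membrane-label channel (Alexa594) carrying the quantified signal. Arrays
follow `(slice, row, col)`, 0-based, intensities as float64 regardless of
on-disk bit depth. Defaults describe the acquisitions the package was
built around: 512 × 512 px planes at 0.08 µm/px and ten optical slices at
0.5 µm spacing. Channel identity is declared by the caller — acquisition
metadata conventions vary too much for wavelength auto-detection to be
trustworthy.

Segmentation is deliberately minimal, mirroring the macro-style analysis
it replaces: per-slice Gaussian smoothing (σ = 1 px, reflect boundary so
membrane-adjacent pixels are not darkened), moment-preserving
thresholding, hole filling, and retention of the largest 8-connected
component. The cleanup steps guard against labeled processes of
neighbouring cells entering the field; they are not an instance
segmenter. A `min_area_px` floor (default 64 px) turns a speckle-only
foreground into an explicit segmentation failure rather than a nonsense
contour.

### Moment-preserving threshold

The threshold preserves the first three sample moments m₁, m₂, m₃ of the
intensity distribution in the bilevel image. The two representative
levels are the roots of z² + c₁z + c₀ = 0 with

    c₀ = (m₁m₃ − m₂²) / (m₂ − m₁²),   c₁ = (m₁m₂ − m₃) / (m₂ − m₁²),

i.e. the two-point Gauss-quadrature nodes of the histogram (real and
distinct whenever the variance is positive), and the ideal background
fraction is p₀ = (z₁ − m₁)/(z₁ − z₀). Implementation choices:

* moments are computed on raw pixel values, not a fixed 256-bin
  histogram, which makes the partition exactly equivariant under positive
  affine intensity changes;
* the achievable cut (pixels strictly above are foreground) is selected
  from the two cumulative-fraction neighbours of p₀ by minimizing the
  third-moment residual of the bilevel image whose first two moments are
  matched exactly — this reproduces a global brute-force candidate search
  on every histogram family we test;
* a constant plane raises `DegenerateHistogramError`: no threshold exists.

## Membrane line and F-memb

The membrane line is the set of mask pixels with any 8-neighbour
background, ordered into a ring by arc-length position along the
subpixel 0.5-level iso-contour of the mask (single closed curve for a
hole-free component; orientation fixed clockwise by signed area). The
ring is cut at a seeded random position — kept for fidelity to the
original macro, where the break converts a closed selection into a line —
and the break provably cannot affect a mean; tests assert this. The line
sits on the foreground side of the edge because the membrane label
surrounds the GFP fill; `side="inner"` shifts it one pixel inward, and
both options are within one pixel (~0.08 µm) of the true edge, which is
below the optical resolution of the data this models.

F-memb pools per-slice line means with equal slice weights (a mean of
means, not pixel-weighted) over the first `n_slices_analyzed` slices
(default ten). Slices can be excluded manually via the config — the
analysis this reproduces excluded slices with truncated masks along
dendritic branching planes by eye, and no automated criterion for that
judgement is attempted; per-slice means are reported so the practice can
be audited.

## Cytoplasm region and F/F0

The cytoplasm is the cell mask eroded by `erosion_px` (default 8 px
≈ 0.6 µm) with a Euclidean disk structuring element, giving an isotropic
exclusion band for the membrane plus its optical blur. Erosion that
empties the mask (cell thinner than twice the band) is an explicit
`DegenerateGeometryError`. The region includes the nucleus — the GFP
fill does not distinguish it, and no nuclear exclusion is applied.

Compartment fractions are formed as memb = F-memb/(F-memb + F-cyt) with
cyt = 1 − memb computed as the complement, so the two sum to 1 exactly in
floating point. F/F0 divides each fraction after treatment by the same
fraction before; the quotient of fractions is invariant under any uniform
multiplicative intensity change of either acquisition, which is the point
of using fractions — acquisition gain drift between the two time points
cancels. Before/after pairing is by `cell_id` only; region means are
robust to the small drift this tolerates, and no registration is
performed. Background subtraction is off by default (raw means), with a
config flag for sensitivity analyses.

## Spike metrics

Inputs are spike times with epoch annotations; raw traces are supported
through a detector (MAD-based noise SD, amplitude threshold in SD units,
extremum-sample timing, refractory suppression, optional 0.5-ms boxcar
pre-smoothing). A hard amplitude threshold on noisy data has an
irreducible false-positive rate set by the Gaussian tail — about 0.4
events/s at 4 SD and effectively zero at 5 SD for 10-kHz traces — so
long recordings should be detected at 5 SD or above; tests that assert
exact recovery use trace lengths where the tail bound predicts well under
one false crossing.

Metrics use fixed windows after agonist onset: the maximal effect in
[60, 120] s ("1–2 min") and the late effect in [270, 300] s standing in
for "at 5 min". The published definitions give the anchors but not the
window widths; both windows are configurable. Inhibition is clamped to
[0, 100] — rebound excitation above baseline reports 0% and is flagged
rather than reported negative. Desensitization is the raw difference of
the two inhibition percentages, not rescaled by the maximal inhibition;
the raw-difference reading is consistent with the magnitudes this package
is meant to reproduce (e.g. near-complete inhibition with ~32%
desensitization for a µ-agonist), and a normalized variant is available
behind `normalize_desensitization=True`. A zero baseline rate raises:
only cells with steady baseline firing are analyzable, matching the
standard inclusion rule for spontaneously active neurons.

## Binding fit

Per-well normalization: background (no-primary wells) is averaged per
wavelength and subtracted, then ratio = (s₇₈₄ − bg₇₈₄)/(s₆₅₈ − bg₆₅₈).
Wells whose denominator is non-positive after subtraction are flagged and
excluded, never silently dropped. Normalization happens per well and
replicates are averaged afterwards (the alternative order — average then
normalize — differs only at second order in the noise).

The default fit is sequential: the nonspecific slope comes from the
blocked wells by through-origin least squares, then (Bmax, Kd) are fit to
the total curve with the slope held fixed; `shared=True` fits all three
parameters jointly to the stacked data. Ordinary least squares on ratios,
unweighted — no weighting scheme is part of the assay definition. The
initial guess comes from the linearization y·Kd − L·Bmax = −y·L, which is
the exact solution for noise-free data, so clean inversions recover the
generating parameters at the optimizer's fixed point (relative error
~1e-9 or better). Kd estimates outside (0, 10 × max concentration) emit a
warning: the design cannot support them. The fitted "Kd" of a covalent
labeling reaction is an apparent half-maximal labeling concentration
under the fixed incubation protocol, not an equilibrium constant.

## Synthetic phantoms and what passing tests mean

The generators default to the study conditions: 512 × 512 px at
0.08 µm/px, ten slices, a convex soma (disk/ellipse/star-convex blob) of
radius ~120 px (≈ 19 µm diameter) with a 2-px rim at 170 AU over a 20-AU
cytoplasm and 10-AU background, additive Gaussian image noise (SD 5 AU),
an optional Gaussian PSF (σ = 1 px) applied before noise; spontaneous
firing at 1.5 Hz with 120 s baseline and 300 s agonist application; and
six-concentration plates (0–100 nM) in triplicate with duplicate blocked
wells and multiplicative noise. Internalization moves a stated fraction
of the summed rim signal into cytoplasmic puncta placed fully inside the
measured region, conserving total intensity.

Each generator emits a ground-truth record sufficient to compute every
downstream expectation in closed form. For images the record carries the
noiseless-field means over the true geometry (so blurred phantoms are
compared at the discretization actually generated); rim-intensity
recovery claims are made on sharp, noise-free phantoms where the nominal
value is the truth. For spike trains the rate model is baseline → full
programmed suppression held for 120 s (agonists reach and hold maximal
effect through the 1–2 min window) → exponential recovery (τ = 90 s)
toward a plateau solved from the target late-window inhibition; window
averages of the rate integrate in closed form. Target pairs where the
desensitization exceeds what full recovery can reach inside 5 min clamp
at full recovery, and the record reports the attainable analytic values.
Recovery of the programmed grid is assessed on per-condition means over
~22 seeds each (≈ 200 runs): single-run estimates are Poisson-limited to
several points of spread at these epoch lengths, so the meaningful claim
is absence of bias, not per-run exactness.

The phantoms do **not** emulate dendritic arbors, branch-plane truncation
artifacts, photon-counting (Poisson) image statistics, bursting or
rhythmic spike structure, or plate position effects. Passing tests
demonstrate that the measurement geometry and arithmetic are correct and
unbiased under the stated models — not robustness to every property of
real tissue.

## Numerical conventions and degenerate inputs

* 8-connectivity throughout; pixels strictly above threshold are
  foreground; bins are half-open [k·b, (k+1)·b).
* All randomness (phantom noise, spike thinning, ring breaks) flows from
  explicit integer seeds; identical seeds reproduce outputs bit-for-bit.
* Degenerate inputs fail loudly with typed errors: odd page counts,
  missing pixel size, constant planes, empty foregrounds, multi-component
  or hollow masks for contouring, over-eroded cells, zero baseline rates,
  too-few binding concentrations.
* Batch runners log per-cell failures and continue; warnings are carried
  in the run manifest, never swallowed.

## Known limitations

No image registration between before/after acquisitions; no photobleach
correction or deconvolution; no multi-cell instance segmentation or
dendrite tracing; no spike sorting (one unit per recording assumed); no
kinetic labeling model behind the saturation fit; group statistics stop
at mean/SD/SEM/n, with inferential testing left to dedicated statistics
environments.
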