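# receptorquant

Quantification pipelines for opioid-receptor surface expression,
agonist-induced internalization, firing inhibition and saturation binding —
the measurement side of ligand-directed fluorescent labeling experiments on
live neurons (e.g. striatal cholinergic interneurons labeled with a
fluorophore-conjugated naltrexamine reagent).

The package is aimed at imaging and electrophysiology labs that need the
bespoke arithmetic of these assays as tested, scriptable code rather than a
stack of spreadsheet formulas and one-off macros.

## What it computes

**Membrane fluorescence (F-memb).** A two-channel Z-stack carries a
cytoplasmic GFP fill and a membrane label (Alexa594). Each GFP slice is
Gaussian-smoothed (σ = 1 px) and binarized by *moment-preserving
thresholding*: the cut whose two representative gray levels z₀, z₁ and
mixing fraction p₀ preserve the first three sample moments of the intensity
histogram (the levels are the two-point Gauss-quadrature nodes of the
histogram). The mask edge becomes a one-pixel line, and

> F-memb = mean over slices of ( mean Alexa594 intensity along the line ).

**Internalization (F/F0).** The cytoplasm is the mask eroded inward by
8 px (≈ 0.6 µm at 0.08 µm/px, Euclidean disk element); its mean intensity,
pooled over slices, is F-cyt. With fractions

> memb = F-memb / (F-memb + F-cyt),  cyt = F-cyt / (F-memb + F-cyt),

an agonist's effect on one cell is F/F0, each fraction after treatment
divided by the same fraction before. Fractions cancel uniform gain drift
between acquisitions; cytoplasmic F/F0 > 1 indicates internalization.

**Firing inhibition and desensitization.** From spike times with a
baseline epoch and an agonist epoch,

> inhibition (%) = 100 × (1 − r₁₋₂ₘᵢₙ / r_baseline),
> desensitization (%) = inhibition₁₋₂ₘᵢₙ − inhibition₅ₘᵢₙ,

both clamped to [0, 100]; cells without steady baseline firing are
excluded. Spike detection from raw 10-kHz traces uses a MAD-based noise
estimate with an amplitude threshold and refractory suppression.

**Saturation binding (apparent Kd).** Two-wavelength plate readouts are
background-subtracted and normalized (784 nm / 658 nm); blocked wells give
the nonspecific component. The total curve is fit as

> total(L) = Bmax·L / (Kd + L) + ns·L

by least squares (nonspecific slope from blocked wells, or a joint fit).
Because labeling is covalent, Kd is an apparent labeling coefficient.

Every pipeline has a synthetic phantom generator
(`receptorquant.synthetic`) that emits closed-form ground truth, so all of
the above is validated end to end without external data.

## Worked example

Segment four phantom cells (two control, two with a receptor-selective
blocker reducing membrane label), pool F-memb per group, and fit a binding
plate generated at Kd = 7.1 nM with 3% noise:

```python
from receptorquant import AnalysisConfig
from receptorquant.binding_fit import OneSiteBindingModel
from receptorquant.reporting import run_membrane_quant
from receptorquant.synthetic import CellPhantomParams, make_binding_plate, make_cell_stack

stacks = []
for i, (cond, memb) in enumerate(
    [("control", 170.7), ("control", 165.0), ("blocker", 115.5), ("blocker", 118.0)]
):
    params = CellPhantomParams(
        membrane_intensity=memb, cell_id=f"cell{i}", condition=cond,
        psf_sigma_px=0.0, noise_sd=0.0, rng_seed=i,
    )
    stacks.append(make_cell_stack(params)[0])

per_cell, summary, manifest = run_membrane_quant(
    stacks, AnalysisConfig(), control_condition="control"
)
print(summary.to_string(index=False))

plate, _ = make_binding_plate(kd_nM=7.1, noise_frac=0.03, rng_seed=0)
model = OneSiteBindingModel().fit_plate(plate)
print(f"Kd = {model.kd_nM_:.2f} nM, Bmax = {model.bmax_:.3f}")
```

prints

```
condition   mean      std  n  sem  percent_of_control
  blocker 116.75 1.767767  2 1.25                  70
  control 167.85 4.030509  2 2.85                 100
Kd = 6.95 nM, Bmax = 1.003
```

The group means equal the programmed membrane intensities (noise-free
phantoms recover the rim exactly), the blocker group sits at 70% of
control, and the fitted Kd lands within a few percent of the generating
7.1 nM.

A `receptorquant` command-line tool wraps the same pipelines
(`membrane`, `endocytosis`, `spikes`, `binding`, `simulate`); see
`receptorquant --help`.

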