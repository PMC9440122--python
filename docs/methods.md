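# Methods

This note documents the models, defaults and numerical choices behind
`repliquant`, and what the synthetic-data generator does and does not
emulate.

## Segmentation

Nuclear masks are built on the DNA counterstain of a maximum Z-projection.
The threshold is the *maximum* of the triangle threshold (computed on a
256-bin histogram) and a fixed floor of 3000 AU on the 16-bit scale; the
heterochromatin threshold within each nucleus is likewise
`max(triangle(within-nucleus intensities), 7000)`. Reading the two stated
conditions as an intersection makes both bind: on dim images the floor
dominates, on bright ones the data-driven triangle does, and the
composition is symmetric to the order of the two steps. The
heterochromatin triangle is restricted to within-nucleus intensities so the
(large) extracellular background cannot dominate the histogram. Holes are
filled and components below 500 px discarded (≈ the smallest plausible
nucleus at 0.12 µm/px); both are configurable. Touching nuclei are not
split — the analysis targets well-separated cells. The nucleoplasm is
defined as the exact set difference `nuclear \ heterochromatin`, so the
three masks always form a partition, on degenerate inputs included.

## Relative accumulation

The readout is the ratio of the averaged mean protein intensity over three
radius-4 px circular ROIs on PCNA-marked heterochromatin to the averaged
mean over three same-sized nucleoplasmic ROIs (average-of-means, not pooled
pixels). ROI placement was originally manual; for testability the
automatic mode is deterministic: foci ROIs sit on the three brightest local
maxima of the Gaussian-smoothed (σ = radius/2) PCNA channel inside the
heterochromatin mask with a minimum separation of twice the ROI radius, and
nucleoplasm centers are drawn uniformly (seeded) from the nucleoplasm
eroded by the ROI radius. Smoothing before peak-finding keeps maxima near
focus centers rather than on noise spikes at focus edges. A manual mode
accepts hand-picked centers unchanged. No background subtraction is
applied inside the ratio (available as an explicit normalization step
elsewhere); the ratio is invariant to any positive rescaling of the protein
channel.

## Modification levels and grouping

Sum nuclear immunostain intensity is divided by the mean intensity of
below-background cells, then by the sum nuclear DAPI intensity
(compensating cell-cycle DNA-content differences). Expression bins are
half-open `[lo, hi)` — the published bin notation is ambiguous at shared
endpoints, and half-open intervals make the grouping a partition of
[0, ∞); values above the top bin are labeled `high` with an out-of-range
flag. Defaults: GFP background < 50 AU with bins 50–100/100–500/500–1000;
mCherry background < 100 AU with bins 100–500/500–1000/1000–5000.

## FRAP

Double normalization divides the background-corrected bleached-ROI signal
by the background-corrected reference ROI, each scaled by its pre-bleach
mean. Any multiplicative acquisition-bleaching decay shared by the two
nuclear ROIs cancels exactly; the simulator therefore applies its
acquisition-bleaching decay to both ROI1 and ROI2, which is the physical
situation (imaging bleaches all fluorophores alike).

Recovery is fit with the two-component saturating form
`N(t) = I_E − A1·e^(−k1 t) − A2·e^(−k2 t)`, bounds `I_E ∈ (0, 1.5]`,
amplitudes/rates ≥ 0, by trust-region least squares with a deterministic
multi-start (rate seeds log-spaced over 10⁻³–10 s⁻¹, amplitudes from curve
geometry). On effectively mono-exponential data the second component is
unidentifiable — a near-zero rate trades off against the plateau and can
pin `I_E` at its bound while inflating `t½` — so a single-term fit is run
alongside and the reported model is selected by BIC; a genuine second
component lowers the residual enough to win. `t½` solves
`N(t) = (N(0⁺) + I_E)/2` on the fitted model by Brent bisection
(`ln 2 / k1` exactly when `A2 = 0`), robust to noise because it never
touches raw data. Curves with total amplitude below 10⁻⁶ are flagged as
non-recovering with undefined `t½`.

## Colocalization

Pearson `r` over all in-mask pixels (all voxels for stacks), with no
automatic thresholding — an optional intensity floor is exposed as a flag.
Zero variance in either channel raises an explicit error rather than
returning NaN. Line profiles use bilinear interpolation at unit spacing,
averaged over an odd perpendicular width.

## Compaction profiling

In-nucleus DNA intensities are partitioned into K = 7 classes by 1-D
k-means with centers initialized at the (k + 0.5)/K quantiles, making the
result deterministic; classes are relabeled by ascending center so class 1
is the least compact. Each nucleus is clustered independently (no
cross-nucleus normalization), matching per-nucleus intensity scales.
K-means on 1-D data with quantile initialization is a standard intensity
classifier; it is an approximation of compaction, not a biophysical model.
Group comparisons report per-class mean fraction differences with a seeded
bootstrap 95% CI over cells.

## GluMS-PCR

Band densities come from a rectangle around each lane: the row-wise summed
profile minus a linear baseline through its endpoints, integrated and
floored at zero. The inference model is a survival-fraction
reconstruction of the assay's cleavage rules (HpaII cleaves only unmodified
CCGG; MspI cleaves unmodified, 5mC and 5hmC but not 5ghmC):
`hmc = max(Dg − Dm, 0)/D0`, `modified = Dh/D0`,
`mc = max(modified − hmc, 0)`, all clipped to [0, 1] with explicit flags.
It assumes a single CCGG site per amplicon; multi-site amplicons would
convolve survival probabilities and are out of scope.

## Bisulfite / TAB calling

Clones are globally aligned to the untreated reference with free end gaps
(match +1, mismatch −1, gap −2) and an asymmetric substitution matrix
scoring clone-T-opposite-reference-C as a match, avoiding biased gap
placement on converted strands. Alignment identity is measured against the
full reference length, so a fragment aligning only a short stretch cannot
pass; the default rejection threshold is 80%. Per-clone conversion QC uses
non-CpG cytosines (all unmodified in mammalian contexts): clones below 95%
conversion are flagged and excluded from site estimates, the standard
QUMA-like default. Site-level percent C carries a Wilson 95% CI. The
BS−TAB difference estimates 5mC per site, floored at 0 with a clip flag
since independent sampling noise can drive it negative.

## Synthetic-data generator

The generator defines the test conditions for every stage.

* **Nuclei** (256×256 px): elliptical nucleus (semi-axes 70×90 px),
  background 500 AU, euchromatin 5000 AU, six non-overlapping chromocenters
  of radius 5–9 px at 20 000 AU. Late-S PCNA foci are the chromocenter
  footprints dilated by 1 px at 12 000 AU; early-S patterns place 60 puncta
  of radius 1–2 px in the nucleoplasm. The protein channel is 3000 AU
  inside the nucleus and `fold × 3000` inside foci, so the noiseless
  enrichment equals the requested fold exactly. Noise is Poisson on the
  photon-scaled signal (gain 10 AU/photon) plus Gaussian read noise
  (σ = 50 AU), clipped to [0, 65535] — the standard sCMOS/CCD
  approximation. Not emulated: PSF blur, uneven illumination, nucleoli,
  touching nuclei, autofluorescence; passing tests therefore demonstrate
  correctness of the measurement logic, not robustness to those real-image
  features.
* **FRAP**: 10 pre-bleach + 100 post-bleach frames at 0.25 s, plateau 0.9,
  bleach depth 0.2, shared mono-exponential acquisition-bleaching decay,
  relative Gaussian noise.
* **Gels**: Gaussian-profile bands whose integrated background-subtracted
  density equals the requested value exactly before noise; digest panels
  are generated directly from (5mC, 5hmC) fractions via the cleavage rules.
* **Clones**: a fixed 150-bp synthetic amplicon with 8 CpGs (not from any
  genome); per-CpG states drawn from (p_mC, p_hmC), emission per chemistry
  with conversion, protection and oxidation efficiencies as separate knobs.

Every generator is byte-deterministic given its spec and seed; one seed
enters each stochastic operation.

## Problem sizes

The validation suite uses 50 nuclei per enrichment fold, 20 noisy nuclei
for mask recovery, 100 random nuclei for invariants, 100 FRAP replicates,
200 clones per chemistry and 100 clone-set replicates for CI coverage —
sizes at which Monte-Carlo error is far below the tolerances being checked
while the whole run stays around a minute.

## Known limitations

* The compaction classifier approximates the published seven-class analysis
  whose exact classifier is not specified; results are comparable across
  groups processed identically but not numerically interchangeable with
  other tools.
* GluMS quantitation assumes complete digestion and glucosylation and a
  single CCGG site.
* Stage (early/late S) is an input label, not inferred from PCNA texture.
* No watershed splitting of touching nuclei and no 3-D segmentation;
  stacks are max-projected for masking.
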