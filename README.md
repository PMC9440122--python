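# repliquant

Quantitative analysis of replication-coupled protein recruitment to
pericentric heterochromatin, for cell biologists working with multi-channel
fluorescence microscopy, FRAP, and locus-level DNA-modification assays.

During late S phase, mouse pericentric heterochromatin (DAPI-dense
chromocenters) is replicated, and PCNA forms large foci on these domains.
`repliquant` measures how strongly a protein of interest accumulates at
these replication foci, how mobile it is (FRAP), how it colocalizes with
chromatin marks, how chromatin compaction shifts, and how locus-level
5-methylcytosine (5mC) and 5-hydroxymethylcytosine (5hmC) are distributed —
together with a synthetic-data generator that provides exact ground truth
for every stage.

## What it computes

* **Segmentation** — nuclear mask from the DNA counterstain (triangle
  threshold combined with a fixed floor of 3000 AU on the 16-bit scale),
  chromocenter mask within each nucleus (triangle ∨ 7000 AU floor), and the
  nucleoplasm as their exact set difference.
* **Relative accumulation** — mean protein intensity in three 4-px circular
  ROIs on the brightest PCNA foci divided by the mean in three same-sized
  nucleoplasmic ROIs:
  `R = ⟨I_protein | PCNA foci⟩ / ⟨I_protein | nucleoplasm⟩`.
* **Modification levels** — sum nuclear immunostain intensity normalized by
  the mean of below-background cells and by the sum nuclear DAPI intensity,
  with GFP/mCherry expression grouping (background/low/mid/high bins) and
  5hmC:5mC ratios.
* **Colocalization** — Pearson `r` over all in-mask pixels/voxels, plus
  bilinear line profiles.
* **FRAP** — double normalization
  `N(t) = [R2_pre/(roi2−roi3)]·[(roi1−roi3)/R1_pre]` and a bi-exponential
  recovery fit `N(t) = I_E − A1·e^(−k1 t) − A2·e^(−k2 t)` with half-time
  `t½` solved on the fitted model (`ln 2 / k1` in the mono-exponential
  limit).
* **Compaction profiling** — seven DNA-intensity classes per nucleus by
  seeded 1-D k-means; class fractions quantify de/condensation.
* **GluMS-PCR** — band densitometry and inversion of the cleavage rules
  (HpaII cuts only unmodified C; MspI cuts C/5mC/5hmC but not
  glucosylated 5hmC) into locus-level 5mC and 5hmC fractions.
* **BS/TAB-seq** — bisulfite-aware clone alignment, per-CpG C/T calling
  with conversion-efficiency QC, Wilson 95% CIs, and the per-site 5mC/5hmC
  split (BS reads 5mC+5hmC as C; TAB reads only protected 5hmC as C).

## Worked example

```python
import repliquant as rq
from repliquant import simulate as sim

# a late-S nucleus with a known 3-fold protein enrichment at foci
spec = sim.NucleusSpec(accumulation_fold=3.0, rng_seed=7)
img, truth = sim.generate_nucleus(spec)

masks = rq.segment(img)                       # 1 nucleus found
res = rq.relative_accumulation(img, masks, seed=7)
print(res.mean_in_foci)                       # 8985.0
print(res.mean_in_nucleoplasm)                # 2994.3
print(res.relative_accumulation)              # 3.001  (truth: 3.0)

fit = rq.fit_trace(sim.generate_frap_trace(
    sim.FrapSpec(k1=0.2, noise_sd=0.005, rng_seed=7)))
print(fit.t_half)                             # 3.474 s (ln2/0.2 = 3.466 s)
```

The estimated enrichment (3.001) recovers the simulated 3-fold accumulation
of the protein at PCNA-marked chromocenters; the fitted FRAP half-time
matches the closed-form `ln 2 / k1` of the generating mono-exponential
within noise.

A command-line interface mirrors the library:

```
repliquant simulate --what nuclei --fold 3 --seed 1 --out sim/
repliquant segment --in sim/nucleus_000.tif --channels dna=0 --out masks/
repliquant accumulate --in sim/nucleus_000.tif --seed 1 --out acc.csv
repliquant frap --traces traces.csv --n-prebleach 10 --out fits.csv
```

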