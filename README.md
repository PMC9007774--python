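# lcmri

Quantification of the locus coeruleus (LC) from LC-sensitive brainstem MRI.

The LC is a small bilateral noradrenergic nucleus beneath the floor of the
fourth ventricle that appears hyperintense on neuromelanin-sensitive
sequences, and its imaging biomarkers — a contrast ratio (LC_CR) against a
ventral-pons reference and a supra-threshold voxel count (LC_VOX) — are
widely used proxies for LC integrity in aging and neurodegeneration.
`lcmri` implements the two standard post-acquisition quantification routes
side by side, the metrics for comparing an LC segmentation against a
published consensus mask, and the statistics used to assess inter-method
agreement, together with a synthetic brainstem cohort generator with known
ground truth so that every stage is verifiable end to end.

## What it computes

**Native space (NS).** Within an LC search ROI propagated across contiguous
axial slices, the intensity threshold is the lowest value among the 10
spatially interconnected voxels of maximum intensity (26-connectivity,
greedy growth from the global maximum). Supra-threshold voxels outside a
deterministic anatomical-plausibility mask are vetoed and the threshold is
recomputed until the selection stabilizes. Then, with both LC sides
combined,

    LC_CR-NS = mean(LC voxels) / mean(reference ROIs),   LC_VOX-NS = |selection|.

**Template space (TS).** Pre-aligned scans are averaged into a brainstem
template; the LC mask is every template voxel above

    threshold = μ_ROI + 4·σ_ROI

(statistics pooled over two bilateral 8.5 mm × 8.5 mm ventral-pons reference
squares across the slice span, population σ), intersected with the
plausibility mask and split left/right at the midline. Per subject and side,

    LC_CR-TS = [max(LC) − max(Ref)] / max(Ref)

and LC_VOX-TS counts mask voxels whose subject intensity exceeds the
subject's own μ+4σ reference threshold. A group probabilistic map reports
the per-voxel fraction of subjects with supra-threshold signal.

**Mask compatibility.** For a study mask A against a reference mask B on a
shared grid: sensitivity = |A∩B|/|B|, specificity = |A∩B|/|A|, accuracy =
their mean (percentages printed to one decimal, round-half-even).

**Agreement statistics.** Shapiro–Wilk checks, Z-standardization, the six
NS–TS Pearson correlations (LC_CR and LC_VOX × combined/left/right), paired
t-tests for left-vs-right differences (including the reference-intensity
negative control), and Benjamini–Hochberg FDR adjustment per family.

## Worked example

```python
from lcmri import (SimulationConfig, generate_cohort, build_template,
                   create_lc_mask, extract_subject, run_native)

cfg = SimulationConfig(n_subjects=20, seed=3)       # true contrast 1.30 L / 1.25 R
volumes, truth, roispec = generate_cohort(cfg)
mask = create_lc_mask(build_template(volumes), roispec, truth.plausibility)
print(mask.count(), mask.count("left"), mask.count("right"))
res = extract_subject(volumes[0], mask, roispec)
print(res.lc_cr["left"], res.lc_vox["left"])
```

Running `python examples/03_template_space.py` (the same computation with
narration) prints:

```
template reference stats: mu=100.00 sigma=0.449 -> threshold 101.80
LC mask: 300 voxels (left 152, right 148)
  left      LC_CR-TS = 0.307   LC_VOX-TS =  88   (true contrast 1.402)
  right     LC_CR-TS = 0.058   LC_VOX-TS =  12   (true contrast 1.122)
  combined  LC_CR-TS = 0.300   LC_VOX-TS = 100   (true contrast 1.402)
probabilistic map: 156 voxels carry LC signal in >10% of subjects
```

The μ+4σ mask recovers the simulated tubes (300 of 306 true voxels at this
noise level, spanning 17 axial slices), and the per-side contrast ratios
track each subject's own jittered true contrast — this first subject drew an
unusually asymmetric pair. The remaining examples cover cohort simulation
(`01`), the native-space route (`02`), mask overlap (`04`, printing
sensitivity/specificity/accuracy percentages) and the full agreement report
(`05`). A thin CLI mirrors the library: `lcmri simulate`, `lcmri ns-run`,
`lcmri ts-build-template`, `lcmri ts-make-mask`, `lcmri ts-extract`,
`lcmri compare-masks`, `lcmri stats-report`, `lcmri run-all`.

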