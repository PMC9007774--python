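"""Template-space pipeline: group template, μ+4σ LC mask, per-subject extraction.

Aligned scans are averaged into a brainstem template; voxels exceeding
μ_ROI + 4σ_ROI (statistics pooled over both ventral-pons reference squares)
and surviving the anatomical-plausibility veto form the LC mask, split into
left and right by the midline. Each subject is then quantified inside that
mask: LC_CR-TS = [max(LC) − max(Ref)]/max(Ref) per side, and LC_VOX-TS
counts mask voxels above the subject's own μ+4σ threshold.
"""

import numpy as np

from lcmri import (
    SimulationConfig, generate_cohort, build_template, roi_stats,
    create_lc_mask, extract_subject, probabilistic_map,
)

cfg = SimulationConfig(n_subjects=20, seed=3)
volumes, truth, roispec = generate_cohort(cfg)

template = build_template(volumes)
stats = roi_stats(template, roispec)
print(f"template reference stats: mu={stats.mu:.2f} sigma={stats.sigma:.3f} "
      f"-> threshold {stats.threshold:.2f}")

mask = create_lc_mask(template, roispec, truth.plausibility)
print(f"LC mask: {mask.count()} voxels (left {mask.count('left')}, right {mask.count('right')})")

res = extract_subject(volumes[0], mask, roispec)
true_c = truth.contrasts[truth.contrasts.subject_id == "sub-001"].set_index("side")["true_contrast"]
for side in ("left", "right", "combined"):
    print(f"  {side:9s} LC_CR-TS = {res.lc_cr[side]:.3f}   LC_VOX-TS = {res.lc_vox[side]:3d}"
          f"   (true contrast {true_c[side]:.3f})")
# Per-side values track each subject's own jittered contrast; the max-based
# ratio runs a little below (true contrast - 1) because the reference
# maximum over ~5000 pons voxels sits a few noise-SDs above its mean.

supra = [v.like((v.data > extract_subject(v, mask, roispec).subject_threshold) & mask.mask)
         for v in volumes]
frac, thresh, peaks = probabilistic_map(supra, min_probability=0.10)
print(f"probabilistic map: {int(thresh.sum())} voxels carry LC signal in >10% of subjects")
print(f"per-slice/side peak table: {len(peaks)} rows, fractions up to {peaks['fraction'].max():.2f}")
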