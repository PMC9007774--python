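"""Inter-method agreement and side-difference statistics over a full cohort.

Runs both quantification routes on a 53-subject synthetic cohort and feeds
the wide results table to the statistics stage: six NS–TS Pearson
correlations, paired t-tests for left-vs-right differences (including the
reference-intensity negative control), Shapiro–Wilk normality checks, and
Benjamini–Hochberg FDR adjustment per family.
"""

from lcmri import (
    SimulationConfig, generate_cohort, build_template, create_lc_mask,
    extract_subject, run_native, cohort_results_table, agreement_pipeline,
)

cfg = SimulationConfig(n_subjects=53, seed=1)
volumes, truth, roispec = generate_cohort(cfg)
mask = create_lc_mask(build_template(volumes), roispec, truth.plausibility)

ids = [f"sub-{i + 1:03d}" for i in range(len(volumes))]
ns = [run_native(v, roispec, truth.plausibility) for v in volumes]
ts = [extract_subject(v, mask, roispec) for v in volumes]
table = cohort_results_table(ns, ts, ids)

report = agreement_pipeline(table)
print(report.comparisons.to_string(index=False,
                                   float_format=lambda x: f"{x:.4f}"))
print()
print("The injected left>right contrast asymmetry shows as a positive paired t")
print("for both TS biomarkers while the reference-ROI control stays near zero.")
print("The contrast-ratio correlations are strongly positive because both")
print("methods observe the same per-subject contrast; the voxel-count pairings")
print("are noisier at this cohort size since the NS count tracks only the")
print("bright core above the connected-maximum threshold.")
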