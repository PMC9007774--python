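"""Inter-method agreement and side-difference statistics over a cohort table.

The cohort table is wide, one row per subject, carrying the native-space
(lc_cr_ns, lc_vox_ns) and template-space (lc_cr_ts_* / lc_vox_ts_* for
combined, left, right) biomarkers plus the per-side reference intensities.
The analysis mirrors the usual agreement workflow for paired quantification
methods: Shapiro–Wilk normality checks, Z-standardization, the six NS–TS
Pearson correlations (CR and VOX × combined/left/right), paired t-tests for
left-vs-right differences (TS CR, TS VOX, and reference intensities as a
negative control), and Benjamini–Hochberg FDR adjustment — correlations and
paired tests adjusted as separate families. Tests are two-sided at α=0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AgreementReport",
    "z_standardize",
    "pearson_agreement",
    "paired_t",
    "fdr_adjust",
    "agreement_pipeline",
]

CORRELATION_PAIRS = [
    ("lc_cr_ns", "lc_cr_ts_combined"),
    ("lc_cr_ns", "lc_cr_ts_left"),
    ("lc_cr_ns", "lc_cr_ts_right"),
    ("lc_vox_ns", "lc_vox_ts_combined"),
    ("lc_vox_ns", "lc_vox_ts_left"),
    ("lc_vox_ns", "lc_vox_ts_right"),
]
PAIRED_PAIRS = [
    ("lc_cr_ts_left", "lc_cr_ts_right"),
    ("lc_vox_ts_left", "lc_vox_ts_right"),
    ("ref_left", "ref_right"),
]


def z_standardize(values) -> np.ndarray:
    """Center and scale to sample SD 1 (divisor N−1). Constant input errors."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)] if np.isnan(v).any() else v
    if v.size < 2:
        raise ValueError("z-standardization needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z-standardization undefined for a constant vector")
    return (np.asarray(values, dtype=float) - v.mean()) / sd


def pearson_agreement(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p (t transform, n−2 df) on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(left, right) -> tuple[float, int, float]:
    """Paired-sample t-test; returns (t, df=n−1, two-sided p)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(left) | np.isnan(right))
    left, right = left[ok], right[ok]
    n = left.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    d = left - right
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            # no difference anywhere: t = 0/0 resolved as "no effect"
            return 0.0, n - 1, 1.0
        raise ValueError("paired t-test undefined: zero variance of differences")
    res = sps.ttest_rel(left, right)
    return float(res.statistic), n - 1, float(res.pvalue)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AgreementReport:
    """Tabulated comparisons plus per-variable normality checks."""

    comparisons: pd.DataFrame           # name, kind, statistic, df, p_raw, p_fdr
    normality: pd.DataFrame             # variable, shapiro_w, p
    n_subjects: int = 0

    def to_csv(self, path) -> None:
        self.comparisons.to_csv(path, index=False)


def _shapiro_rows(table: pd.DataFrame, columns) -> pd.DataFrame:
    rows = []
    for col in columns:
        v = table[col].dropna().to_numpy(dtype=float)
        if v.size >= 3 and v.std() > 0:
            w, p = sps.shapiro(v)
        else:
            w, p = np.nan, np.nan
        rows.append((col, float(w), float(p)))
    return pd.DataFrame(rows, columns=["variable", "shapiro_w", "p"])


def agreement_pipeline(table: pd.DataFrame) -> AgreementReport:
    """Full statistics stage over a wide cohort table.

    Requires the NS and TS biomarker columns; the reference-intensity paired
    test is included when ``ref_left``/``ref_right`` are present. Variables
    are Z-standardized before the parametric tests (which leaves r and t
    unchanged up to affine equivariance); the normality-check outcome is
    recorded rather than acted on, matching the agreement-analysis
    convention this pipeline reproduces.
    """
    required = sorted({c for pair in CORRELATION_PAIRS for c in pair}
                      | {"lc_cr_ts_left", "lc_cr_ts_right", "lc_vox_ts_left", "lc_vox_ts_right"})
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    have_ref = {"ref_left", "ref_right"} <= set(table.columns)
    paired_pairs = PAIRED_PAIRS if have_ref else PAIRED_PAIRS[:2]
    analyzed = required + (["ref_left", "ref_right"] if have_ref else [])
    complete = table[required].dropna()
    if len(complete) < 3:
        raise ValueError(f"need at least 3 complete rows, have {len(complete)}")

    normality = _shapiro_rows(table, analyzed)
    z = {col: z_standardize(table[col].to_numpy(dtype=float)) for col in analyzed}

    rows = []
    for a, b in CORRELATION_PAIRS:
        r, p = pearson_agreement(z[a], z[b])
        n = int((~(np.isnan(z[a]) | np.isnan(z[b]))).sum())
        rows.append((f"{a} vs {b}", "pearson", r, n - 2, p))
    for a, b in paired_pairs:
        # paired differences on the raw scale: side gaps are the quantity of interest
        t, df, p = paired_t(table[a].to_numpy(dtype=float), table[b].to_numpy(dtype=float))
        rows.append((f"{a} vs {b}", "paired_t", t, df, p))
    report = pd.DataFrame(rows, columns=["comparison", "kind", "statistic", "df", "p_raw"])
    report["p_fdr"] = np.nan
    for kind in ("pearson", "paired_t"):
        sel = report["kind"] == kind
        if sel.any():
            report.loc[sel, "p_fdr"] = fdr_adjust(report.loc[sel, "p_raw"].to_numpy())
    return AgreementReport(comparisons=report, normality=normality, n_subjects=len(table))
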