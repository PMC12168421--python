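"""Categorical classification of per-taxon circadian rhythms.

Two contrasts are supported.  Under the feeding-restriction contrast
(daytime-restricted DF vs nighttime-restricted NF) taxa rhythmic in both
groups are *feeding-time responsive* (FTR) when the circular peak-time shift
between regimes lies within 12 +/- 3 h (the feeding windows are 12 h apart),
and *multi-factor responsive* (MFR) otherwise; taxa rhythmic in neither group
are ARRHYTHMIC, and taxa rhythmic in exactly one group get an explicit
RHYTHMIC_UNCLASSIFIED label.  Under the transplantation contrast (48 h vs
7 days after rumen fluid transplantation) taxa are classified as having
consistent (CCR), inconsistent (InCCR), gained (GCR) or lost (LCR) circadian
rhythms, or NEVER_RHYTHMIC.  Window endpoints [9, 15] h are inclusive; CCR
requires all three pattern-parameter tests (mesor, amplitude, peak) to be
non-significant.

No multiple-testing correction is applied by default (raw p < alpha
thresholds); Benjamini-Hochberg adjustment of the rhythmicity p-values can be
switched on in :func:`classify_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import CosinorFit, RhythmComparison, circular_peak_diff, compare_rhythms, fit_cosinor
from .errors import ConsistencyError

__all__ = [
    "FEEDING_CONTRAST",
    "RFT_CONTRAST",
    "TaxonRhythmClass",
    "ClassSummary",
    "classify_feeding_response",
    "classify_rft_response",
    "classify_table",
    "summarize_classes",
]

FEEDING_CONTRAST = "DF_vs_NF"
RFT_CONTRAST = "RFT2d_vs_RFT7d"

FEEDING_LABELS = ("FTR", "MFR", "RHYTHMIC_UNCLASSIFIED", "ARRHYTHMIC")
RFT_LABELS = ("CCR", "InCCR", "GCR", "LCR", "NEVER_RHYTHMIC")


@dataclass
class TaxonRhythmClass:
    """One taxon's label under one contrast, with the underlying evidence."""

    taxon_id: str
    contrast: str
    label: str
    fit_a: CosinorFit | None = None
    fit_b: CosinorFit | None = None
    comparison: RhythmComparison | None = None


@dataclass
class ClassSummary:
    """Per-label taxon counts and summed mean relative abundance (percent)."""

    counts: dict[str, int]
    abundance_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(self.counts)
        return pd.DataFrame(
            {
                "label": labels,
                "n_taxa": [self.counts[k] for k in labels],
                "mean_abundance_pct": [self.abundance_pct[k] for k in labels],
            }
        )


def classify_feeding_response(
    fit_df: CosinorFit,
    fit_nf: CosinorFit,
    alpha: float = 0.05,
    window: tuple[float, float] = (9.0, 15.0),
) -> str:
    """FTR/MFR/RHYTHMIC_UNCLASSIFIED/ARRHYTHMIC label for one taxon.

    ``window`` holds the inclusive bounds on the absolute circular peak shift
    (hours) that counts as feeding-time responsive.
    """
    a_rhythmic = fit_df.rhythm_p < alpha
    b_rhythmic = fit_nf.rhythm_p < alpha
    if not a_rhythmic and not b_rhythmic:
        return "ARRHYTHMIC"
    if a_rhythmic != b_rhythmic:
        return "RHYTHMIC_UNCLASSIFIED"
    shift = abs(circular_peak_diff(fit_df.peak_time, fit_nf.peak_time, fit_df.period))
    return "FTR" if window[0] <= shift <= window[1] else "MFR"


def classify_rft_response(
    fit_2d: CosinorFit,
    fit_7d: CosinorFit,
    comparison: RhythmComparison,
    alpha: float = 0.05,
) -> str:
    """CCR/InCCR/GCR/LCR/NEVER_RHYTHMIC label for one taxon."""
    r2 = fit_2d.rhythm_p < alpha
    r7 = fit_7d.rhythm_p < alpha
    if not r2 and r7:
        return "GCR"
    if r2 and not r7:
        return "LCR"
    if not r2 and not r7:
        return "NEVER_RHYTHMIC"
    p_min = min(comparison.p_mesor, comparison.p_amplitude, comparison.p_peak)
    return "CCR" if p_min >= alpha else "InCCR"


def classify_table(
    table_a: pd.DataFrame,
    times_a,
    table_b: pd.DataFrame,
    times_b,
    contrast: str,
    alpha: float = 0.05,
    window: tuple[float, float] = (9.0, 15.0),
    period: float = 24.0,
    bh_correct: bool = False,
) -> tuple[list[TaxonRhythmClass], pd.DataFrame]:
    """Classify every shared column (taxon/feature) of two samples-by-features tables.

    ``table_a``/``table_b`` are the two groups' series (rows = samples, columns
    = features); ``times_a``/``times_b`` the matching sampling hours.  Returns
    the labels plus a tidy frame with the per-taxon evidence columns
    (p_a, p_b, peak_a, peak_b, d_peak, p_mesor, p_amplitude, p_peak).

    With ``bh_correct`` the two groups' rhythmicity p-values are
    Benjamini-Hochberg adjusted across taxa (within each group) before
    thresholding; off by default.
    """
    if contrast not in (FEEDING_CONTRAST, RFT_CONTRAST):
        raise ConsistencyError(f"unknown contrast {contrast!r}")
    taxa = [c for c in table_a.columns if c in set(table_b.columns)]
    if not taxa:
        raise ConsistencyError("the two tables share no feature columns")
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)

    fits_a = {tx: fit_cosinor(table_a[tx].to_numpy(), times_a, period) for tx in taxa}
    fits_b = {tx: fit_cosinor(table_b[tx].to_numpy(), times_b, period) for tx in taxa}

    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        for fits in (fits_a, fits_b):
            raw = np.array([fits[tx].rhythm_p for tx in taxa])
            adj = multipletests(raw, method="fdr_bh")[1]
            for tx, p in zip(taxa, adj):
                fits[tx].rhythm_p = float(p)

    results: list[TaxonRhythmClass] = []
    rows = []
    for tx in taxa:
        fa, fb = fits_a[tx], fits_b[tx]
        comparison = None
        if contrast == FEEDING_CONTRAST:
            label = classify_feeding_response(fa, fb, alpha=alpha, window=window)
        else:
            if fa.rhythm_p < alpha and fb.rhythm_p < alpha:
                comparison = compare_rhythms(
                    table_a[tx].to_numpy(), times_a, table_b[tx].to_numpy(), times_b, period
                )
            else:
                comparison = None
            if comparison is None:
                # GCR/LCR/NEVER_RHYTHMIC need no parameter comparison.
                dummy = RhythmComparison(fa, fb, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
                label = classify_rft_response(fa, fb, dummy, alpha=alpha)
            else:
                label = classify_rft_response(fa, fb, comparison, alpha=alpha)
        results.append(
            TaxonRhythmClass(
                taxon_id=tx, contrast=contrast, label=label, fit_a=fa, fit_b=fb, comparison=comparison
            )
        )
        rows.append(
            {
                "taxon_id": tx,
                "contrast": contrast,
                "label": label,
                "p_a": fa.rhythm_p,
                "p_b": fb.rhythm_p,
                "peak_a": fa.peak_time,
                "peak_b": fb.peak_time,
                "d_peak": circular_peak_diff(fb.peak_time, fa.peak_time, period),
                "p_mesor": comparison.p_mesor if comparison else np.nan,
                "p_amplitude": comparison.p_amplitude if comparison else np.nan,
                "p_peak": comparison.p_peak if comparison else np.nan,
            }
        )
    return results, pd.DataFrame(rows)


def summarize_classes(labels: list[TaxonRhythmClass], table: pd.DataFrame) -> ClassSummary:
    """Per-label taxon counts and summed mean relative abundance, in percent.

    ``table`` holds the relative abundances (fractions) of the samples the
    contrast was computed on; every labeled taxon must be present.
    """
    counts: dict[str, int] = {}
    pct: dict[str, float] = {}
    mean_ab = table.mean(axis=0)
    for rec in labels:
        if rec.taxon_id not in table.columns:
            raise ConsistencyError(f"labeled taxon {rec.taxon_id!r} missing from the table")
        counts[rec.label] = counts.get(rec.label, 0) + 1
        pct[rec.label] = pct.get(rec.label, 0.0) + float(mean_ab[rec.taxon_id]) * 100.0
    return ClassSummary(counts=counts, abundance_pct=pct)
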