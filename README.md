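# rumenrhythm

Circadian rhythm analysis for rumen microbiome time series.

Rumen microbial communities oscillate over the daily feeding cycle: the
abundances of many bacterial genera, archaeal species and protozoal genera
rise and fall with a ~24-h period, and so do total microbial load, volatile
fatty acid (VFA) concentrations, pH and ammonia.  `rumenrhythm` is a tested,
reusable implementation of the analysis toolchain used to characterize these
oscillations in cattle feeding-regime and rumen-fluid-transplantation
studies, for microbiome researchers who have taxon abundance tables sampled
around the clock and want to ask: *which taxa are rhythmic, what drives
their rhythm, and how do their interactions change through the day?*

## What it computes

**Cosinor rhythmometry.**  Each series is fit to the fixed-period cosinor
model

```
y(t) = M + A·cos(2π(t − φ)/24) + ε(t)
```

with mesor `M` (rhythm-adjusted mean), amplitude `A` (half the
peak-to-trough swing) and peak time `φ` (hours).  The model is linear in
`(M, β, γ)` with `A = √(β² + γ²)` and `φ = (24/2π)·atan2(γ, β)`, so fitting
is ordinary least squares; rhythmicity is the 2-df F-test of `β = γ = 0`.
Repeated-measures designs (several cows) get a per-cow random intercept
estimated by REML.  Two groups are compared through a joint model with
group-by-harmonic interactions; differences in mesor, amplitude and peak
time are tested by Wald statistics on the `(M, A, φ)` scale via the delta
method.

**Rhythm classification.**  Between daytime- and nighttime-restricted
feeding, taxa rhythmic in both groups whose circular peak shift lies within
12 ± 3 h are *feeding-time responsive* (FTR); rhythmic taxa outside that
window are *multi-factor responsive* (MFR).  Between 48 h and 7 days after
rumen fluid transplantation, taxa show *consistent* (CCR), *inconsistent*
(InCCR), *gained* (GCR) or *lost* (LCR) circadian rhythms.  Summaries report
per-class taxon counts and summed mean relative abundance.

**Quantification.**  qPCR standard-curve copies per ng,
`(N_L·A·10⁻⁹)/(660·n)`; total copies per mL, `(M_Q·C·V_D)/(S·V)`; estimated
absolute abundance (relative abundance × total copies); Shannon and Chao1
alpha diversity.

**Fermentation.**  VFA molar percentages of total VFA, the
acetate/propionate ratio, and the estimated methane statistic
`ECH4 = 2·Acetate% − Propionate% + 2·Butyrate% − Valerate%`.

**Network ecology.**  SparCC correlations on compositional abundance tables
(log-ratio variances with a sparse basis assumption and iterative exclusion
of strong pairs), null-bootstrap significance, `|r| > 0.3 & p < 0.05`
networks, greedy-modularity modules, within-module connectivity (Zi) and
participation (Pi) node roles, Levins' niche breadth `B_j = 1/Σ P_ij²`, and
Bray–Curtis/Mantel community concordance.

**Synthetic studies.**  A seeded generator produces complete studies (cows ×
time points × groups, abundance tables with compositional closure, qPCR
loads, fermentation series) with known per-taxon rhythm parameters and class
labels, so the entire pipeline is testable against ground truth.

## Worked example

```python
import numpy as np
from rumenrhythm import fit_cosinor, compare_rhythms, ech4

t = np.arange(0.0, 48.0, 6.0)        # every 6 h over two days: 8 samples
rng = np.random.default_rng(0)
day = 10 + 3 * np.cos(2 * np.pi * (t - 14) / 24) + rng.normal(0, 0.5, 8)

fit = fit_cosinor(day, t)
print(f"mesor={fit.mesor:.3f} amplitude={fit.amplitude:.3f} "
      f"peak_time={fit.peak_time:.2f} rhythm_p={fit.rhythm_p:.4f}")
# mesor=10.176 amplitude=3.307 peak_time=13.93 rhythm_p=0.0000

night = 10 + 3 * np.cos(2 * np.pi * (t - 2) / 24) \
        + np.random.default_rng(1).normal(0, 0.5, 8)
cmp = compare_rhythms(day, t, night, t)
print(f"d_peak={cmp.d_peak:.2f} p_peak={cmp.p_peak:.2e} p_amplitude={cmp.p_amplitude:.2f}")
# d_peak=-11.79 p_peak=0.00e+00 p_amplitude=0.91

print(ech4(65, 20, 12, 3))           # 131.0 mol CH4 per 100 mol TVFA
```

The first fit recovers the planted rhythm (true mesor 10, amplitude 3, peak
14:00) from 8 noisy samples.  The comparison detects the 12-h peak shift
between the two feeding schedules (`d_peak` ≈ ±12 h — the circular
difference is reported in (−12, 12] — with a vanishing `p_peak`) while the
amplitudes do not differ (`p_amplitude` = 0.91); a shift inside 12 ± 3 h
classifies the taxon as feeding-time responsive.

The full pipeline runs from one config (simulate → fit → classify →
quantify → ferment → network):

```sh
rumenrhythm run --outdir out --seed 1
```

writing `classification.tsv`, `class_summary.tsv`, `eaa_*.tsv`,
`fermentation_stats.tsv`, `network_nodes.tsv`/`network_edges.tsv` and a
`manifest.json`; the same seed reproduces byte-identical outputs.

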