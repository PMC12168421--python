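# Methods

## The cosinor model

All rhythm analysis rests on the single-component cosinor regression

    y(t) = M + A·cos(2π(t − φ)/P) + ε(t),    P = 24 h fixed,

linearized as `y = M + β·cos(ωt) + γ·sin(ωt)` with `ω = 2π/P`,
`A = √(β²+γ²)`, `φ = atan2(γ, β)/ω mod P`.  The period is never estimated:
the sampling designs this package targets (4 clock times × 2 days) cannot
resolve period, and the scientific question is about the 24-h feeding
cycle.  Multi-harmonic fits, period scanning (Lomb–Scargle) and
autocorrelated-error models are deliberately out of scope.

**Rhythmicity test.**  The 2-degree-of-freedom F-test of `β = γ = 0`
against the intercept-only model.  Degenerate inputs are resolved by
convention: a constant series has `rhythm_p = 1` (no evidence of rhythm,
avoiding 0/0 in the F statistic); a nonconstant series fit with zero
residual variance has `rhythm_p = 0` and carries a `degenerate` flag.

**Two recorded days are pooled** as repeated 24-h cycles (`t mod 24` enters
the harmonics); whether to pool or average days is a genuinely open design
choice, and pooling keeps all within-day replication in the residual.

**Mixed model.**  `fit_cosinor_mixed` adds a Gaussian per-subject (per-cow)
random intercept, estimated by REML through statsmodels' `MixedLM`.  The
model is deliberately the smallest consistent with the downstream use — no
random amplitude or phase — which keeps REML to two variance components.
Three degenerate paths are defined: one subject falls back to OLS with a
warning; an exact (zero-residual) fit reads parameters off the saturated
dummy regression; a boundary REML solution (`τ² ≤ 0`, e.g. identical
subjects) degrades to OLS with `subject_var = 0`.

**Group comparison.**  `compare_rhythms` fits one joint model with a group
indicator interacting with the intercept and both harmonics (OLS, or REML
when subject ids are given).  Differences are reported on the
interpretable `(M, A, φ)` scale with delta-method Wald tests:

* mesor: the interaction intercept directly;
* amplitude: gradient `(β/A, γ/A)` per group;
* peak: gradient `(−γ/A², β/A²)` per group, difference wrapped into
  (−12, 12] hours.

Near-zero amplitude makes the phase unidentifiable; when either group's
amplitude-to-SE ratio is below 2 the peak test returns `p_peak = 1` with a
`phase_unidentifiable` flag rather than a meaningless number.  When a joint
fit is exact (zero residual), a zero difference yields p = 1 and a nonzero
difference p = 0.  These Wald/delta-method tests are a documented,
reproducible construction — no claim of bit-compatibility with any
particular mixed-cosinor package is made.

## Rhythm classes

Feeding-restriction contrast (daytime- vs nighttime-restricted feeding), at
significance level α = 0.05 on raw p-values:

| both rhythmic? | circular peak shift | label |
|---|---|---|
| neither | — | ARRHYTHMIC |
| exactly one | — | RHYTHMIC_UNCLASSIFIED |
| both | within [9, 15] h | FTR |
| both | outside [9, 15] h | MFR |

The window endpoints are **inclusive** (a "12 ± 3 h" band stated without
openness), and shifts are circular differences mapped into (−12, 12], with
the −12 boundary mapped to +12 so an exact half-cycle shift always counts
as 12 h.  Taxa rhythmic in exactly one group get an explicit
RHYTHMIC_UNCLASSIFIED label instead of being silently dropped.

Transplantation contrast (48 h vs 7 days after transplantation): GCR when
rhythm appears only at 7 days, LCR when it disappears, NEVER_RHYTHMIC when
absent in both; otherwise CCR when **all three** pattern-parameter tests
(mesor, amplitude, peak) are non-significant, InCCR when any is
significant.  Mesor, amplitude and peak are used because they are the three
reported pattern parameters.

No multiple-testing correction is applied by default (raw p < α
thresholds); Benjamini–Hochberg adjustment of the rhythmicity p-values is
available via `classify_table(..., bh_correct=True)`.

Class summaries report, per label, the taxon count and the summed mean
relative abundance across the contrast's samples in percent of reads.  The
classification rules are generic over any feature table (e.g. predicted
pathway abundances), not just taxa.

## Quantification

* Standard-curve copy number per ng: `(N_L · A · 10⁻⁹)/(660 · n)` with
  Avogadro's number `N_L = 6.02×10²³`, molecular weight `A` (g/mol),
  amplicon length `n` (bp).  Plasmid standards are treated in copies/µl
  (a standard stated in "mol/µl" is dimensionally implausible).
* Total copies per mL rumen fluid: `(M_Q · C · V_D)/(S · V)`.
* Estimated absolute abundance: relative abundance × total copies; applied
  table-wide the row sums conserve the per-sample totals exactly.
* Shannon `H = −Σ pᵢ log₂ pᵢ` — **base 2 by default** (QIIME-compatible) and
  configurable, since the base is a convention, not a measurement.
* Chao1 `S_obs + F1²/(2F2)`, switching to the bias-corrected
  `S_obs + F1(F1−1)/(2(F2+1))` when no doubletons exist (F2 = 0); delegated
  to scikit-bio.  Amplification-efficiency modeling and Cq conversion are
  out of scope; a seeded rarefaction utility is provided but diversity
  operates on whatever counts it is given.

## Fermentation

Molar percentages divide each VFA by total VFA **including the iso-acids in
the denominator** (the percentage base is total VFA without exclusions);
`ECH4 = 2·Acetate% − Propionate% + 2·Butyrate% − Valerate%` is the
stoichiometric molar CH₄ yield per mole of VFA produced and is therefore
invariant to iso-acid changes and linear in the shares.

## Networks

**SparCC.**  For compositions `x` (fractions per sample), the log-ratio
variances `T_ij = var(log(x_i/x_j))` relate to basis variances `ω` under a
sparsity assumption via `Σ_{j≠i} T_ij = (D−1)ω_i + Σ_{j≠i} ω_j`;
correlations are `r_ij = (ω_i + ω_j − T_ij)/(2√(ω_i ω_j))`, clipped to
[−1, 1].  Pairs with the largest `|r|` above 0.1 are iteratively removed
from the linear system (up to 10 rounds, never leaving a taxon with fewer
than two equations) and the system re-solved — this is what lets a strongly
coupled pair be estimated correctly at small D.  Hyperparameters (20 inner
iterations, exclusion threshold 0.1, 10 rounds, pseudocount 1e-6) follow
the published defaults of the algorithm.  One deliberate dialect: because
the pipeline's inputs are relative abundances, the original Dirichlet
resampling of counts is replaced by a fixed pseudocount, which makes the
estimate deterministic and collapses the inner iterations to a single pass
(the parameter is kept for interface parity).  Zero-variance taxa are
flagged and dropped.

**Significance.**  The bootstrap builds a *null* distribution: each taxon's
samples are resampled with replacement independently, preserving marginals
while destroying cross-taxon coupling;
`p = (1 + #{|r*| ≥ |r_obs|})/(n_boot + 1)` (floor `1/(n_boot+1)`, default
100 bootstraps).  Joint row resampling would preserve the very coupling
being tested and cannot produce small p for real correlations, so
independent per-taxon resampling is the package's construction of
"bootstrap significance".

**Graphs.**  Edges require `|r| > 0.3` **and** `p < 0.05`, both strict;
isolated nodes are retained.  Node features: degree, weighted degree
(Σ|r|), unweighted betweenness with endpoints excluded, and closeness
computed within each connected component as `(n_comp − 1)/Σ distances`
(0 for isolates).  Modules come from deterministic greedy modularity
maximization on `|r|` weights (the algorithm choice is open; greedy CNM is
chosen for determinism), with modularity Q reported for the returned
partition.  Zi is the within-module degree z-score (0 when the module SD is
0); `Pi = 1 − Σ_s (k_is/k_i)²` (0 for isolates); roles use strict
thresholds — network hub (Zi > 2.5, Pi > 0.62), module hub (Zi > 2.5),
connector (Pi > 0.62), else peripheral — so boundary values fall on the
peripheral side.

**Niche breadth.**  Samples are grouped into N communities (by default the
after-feeding stratum); `P_ij` is taxon j's community-i share of its own
total, so `B_j = 1/Σ P_ij²` ranges from 1 (specialist) to N (uniform
generalist).

**Mantel.**  Bray–Curtis distances (`Σ|x−y|/Σ(x+y)`) and Spearman rank
correlation of off-diagonal entries by default (both configurable — the
choice of metric and correlation is open);
`p = (1 + #{|r*| ≥ |r|})/(permutations + 1)` under simultaneous row/column
permutations of one matrix.  The permutation loop is implemented in-package
so one master seed can drive it; scikit-bio's Mantel serves as an
independent cross-check in the test suite.

Whether networks should be built from relative or estimated absolute
abundance is open; relative abundance is the default input.  Networks are
built per group on the union of kingdoms.

## Synthetic data generator

The generator emulates the target study design: 12 cows, clock times
{02:00, 08:00, 14:00, 20:00}, 2 days (8 samples per cow per regime), five
groups (ALF/DF/NF/RFT2d/RFT7d).  Rhythms are imposed on **latent
log-abundance** — cosinor signal + per-cow Gaussian intercept (SD 0.3) +
i.i.d. Gaussian noise — and relative abundances are obtained by
softmax-style closure per sample.  Generating on the latent scale and then
closing makes compositional distortion an explicit, testable phenomenon:
closure of one dominant rhythmic taxon induces apparent anti-phase rhythms
in others, exactly as with real relative-abundance data.

Because of that distortion, *taxa that are arrhythmic on the latent scale
are genuinely (if weakly) rhythmic in relative abundance, even at zero
noise*.  Ground truth is defined on the latent scale, so truth-recovery
tests (including the acceptance checks) classify the retained latent
tables; the pipeline applied to closed tables measures the combined effect
of the statistics **and** closure distortion, which is informative but is
not a label-recovery check.  Consequently, passing recovery tests shows the
estimator chain is correct, not that closure effects are negligible in real
relative-abundance data — they are not, and the default pipeline
demonstrates this.

Generator defaults, chosen once as field-realistic: mesor ~ N(0, 1) on the
log scale (≈10-fold abundance spread between typical taxa), amplitude ~
U(0.75, 1.25) for rhythmic taxa (≈e²-fold peak-to-trough swings, matching
strongly rhythmic genera), observation noise SD 0.25 (a quarter of a
typical amplitude), cow-intercept SD 0.3.  Class semantics: FTR peaks shift
exactly +12 h between DF and NF; MFR shifts draw ±U(3, 6) h (outside the
12 ± 3 window); GCR is arrhythmic at RFT2d and rhythmic at RFT7d, LCR the
reverse; CCR keeps identical parameters; InCCR doubles the amplitude and
shifts the peak 6 h at RFT7d.  Per-cow heterogeneity is intercept-only (no
cow-specific phase), matching the mixed-model structure assumed downstream.
The within-taxon noise model (Gaussian on the log scale) is a modeling
choice the source studies do not constrain.

Total qPCR load is itself a cosinor on the log10 scale (evening peak 20:00,
amplitude 0.15 log10 units, noise 0.05) with kingdom-typical mesors (10.5 /
8.5 / 5.5 log10 copies/mL for bacteria/archaea/protozoa).  Fermentation
variables are positive cosinor series with VFA peaks at 17:00–19:00 and
pH/NH₃-N peaks about 12 h opposed (shifted 12 h in the NF group); total VFA
is always the sum of the six acids.  What the generator does **not**
emulate: sequencing (no reads or ASVs, no sampling depth), phylogeny,
taxon–taxon interactions beyond closure, day-to-day parameter drift, and
non-Gaussian abundance noise.

Everything is a pure function of the design seed, drawn through independent
substreams (truth parameters, cow effects, noise, qPCR, fermentation), so
identical seeds give identical studies byte for byte.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale problem sizes chosen to
make the statistical properties measurable while keeping runs quick: 1000
replicates for type-I calibration, 50 fixtures for oracle equivalence, 60
replicates for the mixed-model Monte-Carlo, 100-taxon studies for class
recovery, 5 taxa × 500 samples for SparCC checks, 100 replicates × 199
permutations for Mantel calibration, and a 30-taxon single-kingdom default
pipeline with 20 bootstraps.  Sums of squares are declared zero below a
relative 1e-10; basis variances are floored at 1e-12; zero-variance columns
are detected with a scale-relative threshold (1e-12 × column max)².

## Known limitations

* Cosinor comparison tests are asymptotic Wald tests; with 8 distinct
  sampling phases and small cow numbers, p-values near the threshold should
  be read cautiously.
* SparCC at D = 5 taxa is near the identifiability limit of the
  basis-variance system; estimates below ~10 taxa rely heavily on the
  exclusion heuristic.
* The bootstrap p floor (1/101 at 100 bootstraps) limits how small network
  edge p-values can be; multiple-testing control for edges is not applied,
  matching the thresholding convention implemented here.
* Niche breadth uses mean abundance per community and therefore inherits
  compositional distortion from closure.
* The pipeline's classification on relative abundance conflates latent
  rhythms with closure-induced rhythms (see above); an absolute-abundance
  workflow (qPCR-scaled EAA tables) reduces but does not remove this.
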