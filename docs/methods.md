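# Methods

`dynatrauma` implements an analysis chain linking a candidate SNP genotype
to clinical outcomes and dynamic systemic inflammation in blunt-trauma
survivors: linkage-disequilibrium screening of candidate variants,
genotype-based cohort stratification, a clinical-outcome statistics battery
with normality-gated test selection, and dynamic network analysis (DyNA) of
31 circulating inflammatory mediators. Because the motivating cohort data
are not publicly deposited, the package ships a synthetic cohort generator
that emulates the study's data structure; every downstream stage is
exercised and tested against that generator.

## The synthetic cohort

**Genotypes.** Eight biallelic SNPs are cataloged with fixed major/minor
alleles and published minor-allele frequencies: three on chromosome 11
(rs10741668 A/G, MAF 0.29; rs2065418 T/G, MAF 0.27, in *MPPED2*;
rs10790334 T/C, MAF 0.18), three on chromosome 8 (rs2241777 C/A, MAF A
0.43; rs3134287 T/C, MAF 0.48; rs3098223 A/G, MAF 0.48), rs906790 A/G on
chromosome 13, and the gene-desert control variant rs7705676 T/C (MAF
0.31). No MAF is published for rs906790; 0.25 is used as a representative
common-variant default. Unblocked SNPs are drawn under Hardy–Weinberg
equilibrium; the chromosome-8 trio is drawn as two independent haplotypes
from a joint haplotype-frequency block built as a Markov chain along the
chromosome (adjacent pairwise D′ = 0.99; the flanking pair inherits
D′ ≈ 0.98 through conditional independence given the middle SNP), which
reproduces the strong-but-imperfect pairwise LD of a short real block.
Block marginals are validated against the catalog MAFs to 1e-9.

**Injury severity.** ISS = 1 + X with X negative-binomial (r = 7.6906,
p = 0.29681) truncated to ISS ≤ 54. These two parameters were fitted once
so the cohort mean is 19.2 and the severe fraction P(ISS ≥ 25) equals
94/413 ≈ 0.228; a two-parameter family cannot simultaneously match the
severe-subcohort conditional mean (34.3 reported; 30.3 implied), and the
cohort mean plus severe fraction were prioritized. The severe subcohort is
produced by filtering (or by sampling the truncated-to-[25, 54]
distribution directly when a severe-only cohort is requested); it is never
a separate draw with different parameters.

**Scalar outcomes.** The risk stratum is risk genotype AND ISS ≥ 25
(threshold inclusive). Hospital LOS, ICU LOS and days on ventilator (DOV)
are gamma-distributed with stratum means from the study's group summaries
(LOS 21.7 vs 15.9 d — the body-text values; the abstract's 21.8 ± 2 is the
same quantity rounded differently — DOV 9.2 vs 5.7 d) and SDs reconstructed
as SEM·√n (SEM 1.9 at n = 42 ⇒ SD ≈ 12.3 d for risk-group LOS). Invariants:
LOS ≥ max(ICU LOS, DOV) ≥ 0, enforced by capping ICU LOS and DOV at LOS
(this caps the realized DOV mean among ventilated patients at ≈ 7.7 d,
slightly below the configured 9.2 d), and ventilated ⇔ DOV > 0. Ventilation
and infection probabilities per stratum (defaults 0.85/0.70 and 0.57/0.40,
the latter pair from the reported infection rates) are needed to emit the
contingency outcomes and were chosen where unreported; under these
conditions the LOS difference at n = 42/52 is detected at α = 0.05 in
roughly 73–80% of replicate cohorts (Mann–Whitney path), with the
risk-group grand mean within 2 SEM of 21.7 d.

**Mediator panel.** All 31 analytes (Eotaxin, GM-CSF, IFN-α, IFN-γ, IL-1β,
IL-1RA, IL-2, sIL-2Rα, IL-4, IL-5, IL-6, IL-7, IL-8, IL-9, IL-10, IL-13,
IL-15, IL-17A, IL-17E/25, IL-21, IL-22, IL-23, IL-33, IP-10, MCP-1, MIG,
MIP-1α, MIP-1β, NO2−/NO3−, sST2, TNF-α; ASCII spellings in code) are
sampled at hours {0, 8, 16, 24, 48, 72, 96, 120, 144, 168} — three samples
inside the first 24 h, then daily. Nine mediators carry stratum-specific
means from the study's screen (Eotaxin and MCP-1 elevated in the risk
stratum; IFN-α, IL-2, IL-4, IL-9, IL-15, IL-17A, IL-23 lowered), with
per-observation log-normal noise whose CV is reconstructed per group from
the reported SEMs (CV = SEM·√n / mean, range ≈ 0.22–0.81); the remaining 22
share plausible plasma baselines in both strata (CV 0.5) and carry no group
signal. Concentrations follow mean × profile(t) with a decaying profile
(1 + 1.5·e^(−t/48 h), normalized to average 1) so overall means equal the
stratum means while a time main effect exists.

**Network coupling.** Within each daily window, all coupled mediators of
one (patient, timepoint) observation share a standard-normal latent factor
with group- and window-specific loading λ ∈ [0, 1); on the log scale this
induces cross-mediator correlation λ² between any two coupled mediators.
The default schedule sets the risk group's λ to 0.99 in windows d1 and
d4–d6, both groups to 0.985 in d2–d3, and the control group to 0.99 (risk
0.95) in d7, reproducing the qualitative complexity-trajectory pattern of
the study (risk networks denser early and on days 4–6, comparable on days
2–3, control denser at day 7). Because one factor couples all 31 mediators,
large cohorts saturate toward complete graphs; at the study's 42/52 group
sizes sampling noise keeps networks partial. A `coupled_mediators` subset
restricts the factor to named analytes when graded structure is wanted.

**MODScore and creatinine.** Daily Marshall MODScore is a rounded, clipped
[0, 24] latent value (ISS/10)·e^(−(d−1)/7) plus a risk-stratum shift
(default 1.5 points) and N(0, 1.2) noise. Plasma creatinine is log-normal
(CV 0.25) around 1.1·(1 + 0.2·e^(−(d−1)/3)) mg/dl plus a risk shift
(default 0.3 mg/dl).

**Missingness and determinism.** An optional MCAR dropout rate (default 0)
thins the mediator panel. One seed drives everything; it is fanned out via
`numpy` SeedSequence spawning into per-stage streams, so genotype, clinical
and time-series generation are each independently reproducible.

**What the generator does not emulate.** No raw assay physics
(fluorescence, array intensities), no mortality (the cohort is survivors
only), no within-patient autocorrelation of mediator levels beyond the
shared window factor, no informative missingness, and no demographic
confounding (age/sex carry no outcome effect). Passing tests therefore
demonstrate that the estimators recover what this generative model plants —
not that the biological claims hold in real cohorts.

## Linkage disequilibrium

For a SNP pair, patients reduce to a 3×3 joint minor-allele dosage table
(missing calls excluded and counted). Haplotype frequencies come from the
standard two-locus EM: only the double-heterozygote cell is
phase-ambiguous, and its expected cis/trans split is re-estimated each
iteration. The likelihood is not always unimodal: on small tables the
global maximum can lie on the boundary of the feasible f(AB) interval while
the equilibrium start converges to an interior stationary point (exact
equilibrium is itself a stationary saddle for the all-double-heterozygote
table). EM therefore runs from three deterministic starts — linkage
equilibrium and both ends of the feasible interval — and keeps the
highest-likelihood solution; ties resolve to D ≥ 0 and the exactly
symmetric degenerate case is flagged (`ambiguous_phase`). Convergence is
declared at a maximum frequency change below 1e-12 (up to 2000 iterations),
tight enough that converged solutions match a fine grid search to 1e-9 in
log-likelihood; non-convergence sets a flag rather than raising.

Coefficients use the classical definitions with A, B the minor alleles:
D = f(AB) − pA·pB; D′ = |D|/Dmax with Dmax = min(pA·qB, qA·pB) for D > 0,
else min(pA·pB, qA·qB); r² = D²/(pA·qA·pB·qB); χ² = n_haplotypes·r² with
df 1. Minor alleles are fixed in the catalog, not re-estimated per cohort,
so signs are stable across subcohorts. A monomorphic locus raises an
undefined-LD error, distinct from r² = 0. The second estimator, `dosage_r2`,
is the squared Pearson correlation of minor-allele dosages (composite r²) —
the simplest calculation one can do by hand on a genotype table; it needs
no phasing and matches gametic r² in expectation under Hardy–Weinberg.
Report output rounds D′ and r² to two decimals.

## Stratification

`single_snp_groups` builds mutually exclusive groups: a patient enters a
spec's group iff they carry that spec's risk call and no other spec's risk
call. `genotype_split` makes the two-arm risk-vs-control split at one SNP,
applying the inclusive ISS filter (when given) before the genotype split;
patients with missing calls are excluded with a count, a choice this
package makes explicitly since the original handling is unreported.
Heterozygote calls are stored in canonical alphabetical order ("GT", never
"TG"), so specs written either way are equivalent. A TG-vs-GG
sub-comparison is just another spec — no special casing.

## Outcome statistics

Two significance levels are fixed once and logged on every result: 0.05 for
clinical outcomes, 0.01 for the serial mediator screen. No further
multiple-testing correction is applied across the 31 mediators — the
stricter α is the correction, mirroring the original analysis plan.

* **Two groups:** D'Agostino–Pearson normality per group at p > 0.05 (the
  gate value is this package's choice); both normal → two-sided Student's
  t, otherwise two-sided Mann–Whitney U. Groups below 8 observations
  cannot be normality-tested and fall through to Mann–Whitney (logged).
  For group sizes ≤ 8 the Mann–Whitney p is exact by exhaustive
  permutation (mid-rank U; two-sided p is twice the smaller one-sided
  tail, capped at 1 — the convention of exact implementations such as R's
  `wilcox.test`, which differs from a symmetric |U − μ| count only under
  ties); above 8 the normal approximation with tie correction is used.
* **2×2 outcomes:** two-sided Fisher exact test.
* **Three or more groups:** all normal → one-way ANOVA with Tukey HSD;
  otherwise Kruskal–Wallis with Dunn's post hoc (z from pooled mid-ranks
  with tie correction, Bonferroni-adjusted by the number of pairwise
  comparisons; written in-package because no installed library provides
  Dunn's test).
* **Serial variables (mediators, MODScore, creatinine):** two-way
  fixed-effects ANOVA with group and time factors on all
  (patient, timepoint) observations, fit by OLS with type-II sums of
  squares (statsmodels), so unbalanced cells are handled. The headline p
  is the group main effect from the additive model; the time effect and
  the interaction (from a separate augmented fit) are secondary. Treating
  repeated measures as independent observations is a documented
  simplification — the original repeated-measures handling is unreported —
  and under the generator's observation-independent noise the test is
  correctly calibrated, which the suite verifies; on real data with
  within-patient correlation it would be anticonservative.

The 31-mediator screen runs the serial comparison per mediator at α = 0.01
and assigns a direction (elevated/lowered in risk) from the overall group
means only when significant.

## Dynamic network analysis

Time windows are daily: [0, 24), [24, 48), …, with the final window closed
on the right; the first window aggregates the sub-daily samples. Within a
window, all (patient, timepoint) observations of one group are pooled —
rather than per-patient means — to maximize usable data in the first-24 h
window; the alternative is a documented switch away from the default. Every
mediator pair gets a Pearson correlation on log10 concentrations (mediator
levels are log-normal, and correlating on the log scale keeps edge
detection invariant to each analyte's dynamic range and CV; `scale=
"linear"` switches to raw concentrations). Pairs with fewer than three
paired observations or zero variance are undefined (NaN, distinct from 0)
and can never create edges. An edge connects a pair with defined
|r| ≥ threshold (default 0.95, configurable); the sign is retained.

The network complexity score (NCS) of a window's network is the degree sum
divided by (n_mediators − 1): 0 for an edgeless network, n for a complete
graph on n mediators. Raw degree-sum and edge-count normalizations are
selectable so other conventions can be matched; no bit-compatibility with
the original Matlab implementation is claimed, since its exact threshold
and normalization are not published in the available text. Connectivity is
summarized per group as each mediator's total degree across windows; the
"most connected" set holds mediators at or above the 75th percentile
(linear interpolation) of the totals within their group.

## Pipeline

`run_paper_analysis` chains simulate → LD table (all pairs of the seven
candidates, both estimators) → exclusive single-SNP groups → rs2065418 TT
vs TG/GG splits at broad ISS and ISS ≥ 25 → outcome battery (LOS, ICU LOS,
DOV, ventilation, infection, MODScore, creatinine) → 31-mediator screen →
NCS trajectories, connectivity and heat-map matrices → the same outcome
battery and screen pointed at the control SNP rs7705676. All outputs are
UTF-8 CSV/JSON with fixed column orders; a manifest records the seed,
config hash and file checksums. Any stage failure removes the partial
outputs and raises a stage-tagged error.

## Problem sizes and verification

The test suite verifies, among others: Hardy–Weinberg and MAF recovery at
n = 10,000; LD recovery (D′, r² within ±0.05) from the D′ = 0.99 block at
n = 2,000 over 100 seeds; EM/grid-search likelihood equivalence on every
3×3 table up to n = 6 plus 300 random tables up to n = 20 (the exhaustive
census of all tables to n = 20 is computationally out of reach, and the
random sample covers the larger sizes); DyNA edge sets and NCS equal to
brute-force enumeration on panels of ≤ 6 mediators; screen sensitivity
(all nine planted mediators with correct directions) in ≥ 90% of 100
replicate 42/52 cohorts and a null false-flag rate within Monte-Carlo
error of 1%; exact-test agreement with enumeration for group sizes ≤ 8 and
type-I calibration of every test path over 1,000 null replicates (exact
discrete tests are allowed to be conservative); and the planted
window-coupling pattern appearing in the NCS trajectories at 500 patients
per group. `scripts/acceptance.py` recomputes the headline quantities at
moderate replicate counts (20–50) chosen to keep a single run under a few
minutes.

## Known limitations

* The two-way ANOVA ignores within-patient correlation (see above).
* DOV means are mildly shrunk by the LOS cap; the generator reports what
  it draws, not the configured mean, when the cap binds.
* The single shared latent factor makes network density nearly binary at
  very large n (complete vs empty); trajectory comparisons remain valid
  because only the group ordering per window is interpreted.
* LD reference values from external panels (e.g. 1000 Genomes) are not
  reproduced here; the VCF importer accepts such data, but no download is
  performed.
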