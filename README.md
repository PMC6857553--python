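# dynatrauma

SNP-stratified clinical outcome analysis and dynamic inflammatory network
analysis for blunt-trauma cohorts, with a synthetic cohort simulator.

Severe traumatic injury triggers a systemic inflammatory response whose
trajectory — and whose clinical consequences such as organ dysfunction,
prolonged ventilation and extended hospitalization — varies widely between
patients with similar injuries. One candidate explanation is common genetic
variation: in particular, the TT genotype of rs2065418 in the *MPPED2* gene
has been associated with worse outcomes in severely injured (ISS ≥ 25)
blunt-trauma survivors. This package re-implements, as a tested and
reusable pipeline, the analysis chain behind that kind of study, for
researchers who want to run it on their own cohort data or probe its
statistical behavior on simulated data:

* **Linkage disequilibrium** of candidate SNPs from unphased diploid
  genotypes: EM haplotype frequencies with
  D = f(AB) − p_A·p_B, D′ = D/D_max, r² = D²/(p_A q_A p_B q_B),
  χ² = n·r² (df 1), plus the phasing-free composite r² (squared Pearson
  correlation of minor-allele dosages).
* **Stratification**: mutually exclusive single-SNP groups, and
  risk-vs-control splits (e.g. rs2065418 TT vs TG/GG) with an inclusive
  injury-severity filter.
* **Outcome statistics**: normality-gated t / Mann–Whitney (exact at small
  n), Fisher exact, ANOVA + Tukey / Kruskal–Wallis + Dunn, and two-way
  (group × time) ANOVA for serial variables; dual significance levels
  (0.05 clinical, 0.01 mediators).
* **Dynamic network analysis (DyNA)**: per-window inter-mediator
  correlation networks (|r| ≥ 0.95 by default), network complexity score
  trajectories NCS = Σ degree / (n_mediators − 1), and per-mediator
  connectivity summaries with a third-quartile "most connected" set.
* **Synthetic cohort generator** reproducing the study's data structure:
  413 patients (ISS mean 19.2, ~94 severe), configurable haplotype blocks
  (chromosome-8 trio at D′ = 0.99), published stratum means for the nine
  separating mediators, and window-specific latent-factor coupling that
  drives the network dynamics.

See `docs/methods.md` for the full model description, parameter defaults
and design choices.

## Worked example

Run the full chain on a synthetic cohort (seed 1):

```python
from dynatrauma.pipeline import PipelineConfig, run_paper_analysis

report = run_paper_analysis(PipelineConfig(seed=1), "out/")
```

The severe subcohort (ISS ≥ 25) splits into 51 TT vs 58 TG/GG patients,
and the outcome battery prints:

```
    los_days   mann_whitney  risk   21.30  control   16.15  p=2.41e-02
icu_los_days              t  risk   10.75  control    6.82  p=1.92e-04
    dov_days   mann_whitney  risk    8.85  control    2.15  p=2.47e-07
  ventilated         fisher  risk    0.90  control    0.66  p=2.73e-03
   infection         fisher  risk    0.51  control    0.47  p=7.03e-01
    modscore  two_way_anova  risk    3.42  control    2.09  p=1.57e-46
  creatinine  two_way_anova  risk    1.52  control    1.19  p=1.18e-35
```

i.e. the planted effects are recovered: TT patients stay ~5 days longer,
are ventilated longer, and show elevated MODScore and creatinine over the
week, while infection (a weak planted difference at this n) is not
significant. The mediator screen at α = 0.01 flags exactly the nine
separating analytes with their directions — Eotaxin and MCP-1 elevated;
IFN-α, IL-2, IL-4, IL-9, IL-15, IL-17A and IL-23 lowered. The NCS
trajectories show the planted window pattern (risk networks dense in the
first 24 h and on days 4–6, both groups comparable on days 2–3, control
dense at day 7):

```
group   control   risk
d1         0.00  31.00
d2        30.93  30.93
d3        31.00  26.07
d4         0.00  31.00
d5         0.00  31.00
d6         0.00  31.00
d7        31.00   0.00
```

and the LD table recovers the chromosome-8 block from this cohort of 413:
rs2241777/rs3098223 D′ = 0.97, r² = 0.76 (dosage r² = 0.76).

The same steps are available as a CLI:

```bash
dynatrauma simulate --seed 1 --out data/
dynatrauma ld --genotypes data/genotypes.tsv \
    --pairs "rs2241777,rs3098223;rs2065418,rs10790334" --out ld.csv
dynatrauma stratify --genotypes data/genotypes.tsv --clinical data/clinical.csv \
    --snp rs2065418 --risk TT --iss-min 25 --out split.json
dynatrauma outcomes --panel data/panel_mediators.csv --daily data/panel_daily.csv \
    --clinical data/clinical.csv --split split.json --out outcomes.csv
dynatrauma dyna --panel data/panel_mediators.csv --daily data/panel_daily.csv \
    --split split.json --out dyna/
dynatrauma run-all --seed 1 --out report/
```

Genotypes can also be imported from a VCF of biallelic SNP records (phase
is discarded; `./.` becomes the missing call `NN`).

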