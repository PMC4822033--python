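# clonalshift

Analysis of paired pre-/post-chemotherapy tumour genomes: how does a short
course of neo-adjuvant therapy reshape a carcinoma's clonal architecture, and
does that reshaping track the clinical response?

The package implements, as a tested and reusable pipeline, the analysis used
to classify oesophageal adenocarcinomas sampled before and after two cycles
of neo-adjuvant chemotherapy into three clonal behaviours:

- **stable** — little change in clonal composition; losses and gains are
  compatible with tumour-sampling effects alone;
- **bottleneck** — a therapeutic genetic bottleneck: many mutations lost
  (including at high VAF, beyond what read sampling can explain), a
  non-trivial shared mutation set, and expansion of a clone that was uncommon
  before treatment;
- **polyclonal** — independently arising lineages, flagged by ≥3 distinct
  driver mutations in one gene behaving discordantly after therapy, or by
  hypermutators losing *and* gaining mutations across the VAF spectrum.

It is aimed at cancer-genomics analysts who have paired tumour/normal variant
call tables (plus optional SNP-array/logR data and clinical response grades)
and want the complete downstream analysis: empirical somatic filtering,
purity QC, cancer-cell-fraction (CCF) clustering, mutation-spectrum and
signature-shift analysis, arm-scale SCNA sharing, and the cohort association
statistics. A synthetic-cohort generator with full clonal truth makes every
stage testable without access to any controlled sequencing data.

## The model in brief

For a mutation at cancer cell fraction *f* in a tumour of purity *ρ* with
local total copy number *C*<sub>T</sub> and *m* mutated copies, the expected
variant allele frequency is

    E[VAF] = ρ f m / (ρ C_T + 2 (1 − ρ)),

and observed alt counts are Binomial(depth, E[VAF]). Somatic variants pass
an empirical filter battery (normal/tumour depth, normal VAF, alt-read and
tumour-VAF floors, population frequency, panel-of-normals, mappability), with
the evidence-strength rules relaxed to "at least one member of the pair
passes" so that genuinely lost or gained mutations survive filtering. Shared
high-coverage mutations (≥60× in one sample, low-VAF rescue, drivers always)
are clustered with a finite joint-binomial mixture fitted by EM, the number
of clones chosen by BIC — a deterministic, desk-scale stand-in for
Dirichlet-process CCF clustering. Purity is estimated from the clonal
(upper) VAF mode and refined from the clonal cluster. A mutation loss is
"not explainable by sampling" when P(alt < detection | Binomial(depth,
pre-VAF)) < 0.01. Spectrum shifts use exact conditional 2×6 tests
(meet-in-the-middle enumeration); signatures use multiplicative-update NMF
over the 96 trinucleotide channels with an automated
maximum-differentiation rank choice; arm-scale SCNAs come from MAD
winsorization, exact penalized-least-squares segmentation, ±0.15 logR calls,
and >half-arm aggregation. Cohort statistics include the Freeman–Halton
exact test on the 2×3 evolution-by-response table, Wilcoxon burden and T>A
tests, a median-split odds ratio, and the age–C>T correlation.

## Worked example

```python
from clonalshift import SimConfig, simulate_cohort, analyze_cohort, evolution_response_test

# the 2x3 evolution-by-response table: responders 2/1/8, non-responders 9/2/2
# across stable / polyclonal / bottleneck
p = evolution_response_test([[2, 1, 8], [9, 2, 2]])
print(f"evolution vs response: p = {p:.4f}")

cohort = simulate_cohort(SimConfig(n_patients=12, seed=7))
res = analyze_cohort(cohort, seed=7)
cols = ["patient_id", "scenario_truth", "category", "responder",
        "pre_burden", "post_burden", "lost_high_vaf_fraction"]
print(res["per_patient"][cols].to_string(index=False))
```

prints

```
evolution vs response: p = 0.0126
patient_id scenario_truth   category  responder  pre_burden  post_burden  lost_high_vaf_fraction
      P001         stable     stable      False         375          397                0.000000
      P002         stable     stable       True         337          357                0.000000
      P003         stable     stable      False         316          329                0.004049
      P004         stable     stable      False         387          407                0.000000
      P005     polyclonal polyclonal      False        7051         4913                0.462702
      P006     bottleneck bottleneck       True         389          271                0.382271
      P007     polyclonal polyclonal      False        7213         5100                0.410774
      P008     bottleneck bottleneck       True         318          233                0.372414
      P009         stable     stable       True         340          364                0.000000
      P010         stable     stable      False         356          373                0.003300
      P011         stable     stable       True         286          292                0.004149
      P012     bottleneck   excluded       True         309          207                0.403774
```

The exact test on the 2×3 table gives p = 0.0126 (0.013 at three decimals):
the split of responders and non-responders across the three clonal
behaviours is non-random. In the simulated cohort, every classifiable
patient's planted scenario is recovered; the polyclonal cases are the
microsatellite-unstable hypermutators (note the ~20× burden), the
bottleneck cases lose a third or more of their high-VAF mutations while a
minor clone expands, and P012 is excluded by the purity/histology/burden QC
rule — its degraded post-treatment sample would otherwise masquerade as
clonal change.

A thin CLI wraps the same functions:

```bash
clonalshift simulate --out cohort/ --seed 1
clonalshift filter --variants cohort/P001.variants.tsv --out P001.filtered.tsv
clonalshift report --cohort cohort/ --out report/ --seed 1
```

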