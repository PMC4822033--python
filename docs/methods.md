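# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `clonalshift` pipeline. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Read-count model and cancer cell fractions

All inference rests on one observation model. A mutation present in a
fraction *f* of cancer cells (the CCF), in a sample of purity *ρ*, at a locus
of total copy number *C*<sub>T</sub> with *m* mutated copies, has expected
variant allele frequency

    E[VAF] = ρ f m / (ρ C_T + 2 (1 − ρ)),

and the observed alt count is Binomial(depth, E[VAF]) with depth ~
Poisson(mean sample depth). `ccf_from_vaf` is the exact algebraic inverse;
CCFs above 1.5 (copy-number error) are clipped and flagged. Mutation
multiplicity is fixed at *m* = 1 unless the input specifies otherwise,
because integer total copy number is usually all that upstream callers
provide; this biases CCFs downward for mutations on amplified alleles, which
matters mainly for clonal mutations in high-gain regions (they then appear
super-clonal and are clipped rather than mis-ordered).

## Somatic filtering

Seven empirical rules, each an independent audit flag per tumour sample:

| rule | condition (fail) | default |
|---|---|---|
| R1_depth | normal depth < 10 **or** tumour depth < 8 | 10 / 8 |
| R2_normal_vaf | normal VAF ≥ 0.03 | 0.03 |
| R3_min_alt | alt reads < 4 | 4 |
| R4_min_vaf | tumour VAF ≤ 0.02 (fresh-frozen) / ≤ 0.05 (FFPE) | 0.02 / 0.05 |
| R5_popfreq | germline population frequency ≥ 0.01 | 0.01 |
| R6_pon | hit in local constitutional ("panel of normals") data | — |
| R7_mappability | segmental duplication or mappability < 0.8 | 0.8 |

Tie directions follow the rule statements exactly: a normal VAF of exactly
0.03 fails; a tumour VAF of exactly 0.02 fails for FF. The depth rule is
read as a joint reliability requirement (either insufficient normal or
insufficient tumour coverage invalidates the comparison at that site).
R5/R6/R7 are consumed as input annotations — no external databases ship with
the package.

Because the scientific object is the pre/post *pair*, the evidence-strength
rules R3 and R4 are relaxed: a variant is retained for the pair iff both
samples are clean on R1/R2/R5/R6/R7 and **at least one** of pre/post is clean
on R3 and R4. This keeps genuinely lost (pre-only) and gained (post-only)
mutations in the analysis; the retained set is provably a superset of the
strict both-pass set, and filtering is idempotent and monotone in every
threshold (property-tested).

## Purity estimation and post-treatment QC

Each VAF is mapped to the purity it would imply were the mutation clonal at
multiplicity 1 (for diploid loci, simply 2×VAF). A Gaussian KDE over
implied purities is scanned for local maxima, and the **upper** mode of
non-negligible height (≥ 25% of the density maximum) is the estimate —
sub-clonal mutations imply lower purities and form lower modes, so the upper
mode, not the global one, identifies the clonal cluster. Fewer than 20
usable VAFs returns "not estimable". On clonal simulations (500 diploid
mutations, 100×) the median absolute error is ≈0.01 across purities 0.3–0.9.

At moderate depth with sub-clonal structure, binomial noise (implied-purity
sd ≈ 0.17 at 75×) merges density modes and biases the KDE estimate downward.
The pipeline therefore refines the estimate after clone clustering: the
highest-VAF cluster that is not negligibly small (≥5 members and ≥5% of
clustered mutations) is taken as clonal and its implied purity used. The
KDE estimate remains the fallback when clustering is unavailable.

Post-treatment samples are excluded when at least 2 of 3 features fire
(each togglable): estimated purity drop below 0.5× the pre-treatment purity;
histological tumour content < 20% (strict — exactly 20% does not fire); and
post-treatment burden below 0.2× the pre-treatment burden. The rule is
monotone: worsening a feature never un-excludes. The 2-of-3 default reflects
that no single feature is reliable alone — a real biological bottleneck also
collapses burden.

## Clone clustering

Mutations enter clustering when shared with ≥60× coverage in at least one
sample, when detected in exactly one sample with allelic ratio < 0.03 in the
other (the rescue that keeps lost/new clones), or when annotated as drivers
(always, regardless of coverage; the shipped driver list is user-replaceable).
Hypermutators are down-sampled to 500 mutations (seeded, drivers kept).

The clustering model is a finite mixture of joint binomial distributions
over the (pre, post) alt/depth pairs, fitted by EM. This deliberately
replaces Dirichlet-process MCMC CCF clustering: for two-sample data the
finite mixture is adequate, deterministic given a seed, and desk-scale. As a
consequence the MCMC settings of such tools do not transfer; the EM defaults
are 20 restarts (component VAFs initialised from randomly chosen
observations), ≤500 iterations, relative log-likelihood tolerance 1e-6, and
component count 1..8 chosen by BIC with the scan stopped after BIC worsens
twice. All restarts run as one vectorised batch. Cluster VAF centres are
converted to CCF coordinates with the refined purities. On planted two-clone
data ((1.0, 1.0) vs (0.6, 0.05), 200 mutations each at 100×) the centres are
recovered within 0.1 with ≥95% correct assignment, stably across seeds.

## Evolution classification

Applied in order: **excluded** (QC) → **polyclonal** → **bottleneck** →
**stable**. The criteria are qualitative in origin; the package makes every
cutoff explicit, configurable, and reported alongside each call:

- *polyclonal*: some gene carries ≥3 distinct somatic mutations with
  discordant trajectories (≥1 lost, ≥1 shared/gained) — the multiple-driver
  pattern of independent lineages; or a hypermutator (MSI or pre-burden
  ≥2000) loses **and** gains ≥10 mutations at VAF ≥ 0.10.
- *bottleneck*: all three of (i) ≥25% of high-VAF (pre-VAF ≥ 0.10) mutations
  lost and not explainable by sampling, (ii) ≥20 shared mutations, and
  (iii) an expanding minor clone — a cluster of ≥3 mutations with pre-CCF
  ≤ 0.2 and post-CCF ≥ 0.5 in which ≥10% of members were detectable
  pre-treatment. The detectability gate separates genuine minor clones
  (≥ ~20% detectable even when the cluster also absorbs newly arisen
  mutations) from clusters of wholly new post-treatment mutations, whose
  pre-treatment detectability is error-level (~0.3% under the 1e-3 error
  model); 0.10 sits between those regimes with wide margins.
- a loss is "not explainable by sampling" when P(alt < k | Binomial(post
  depth, pre-VAF)) < 0.01, with k the smallest alt count that would have
  counted as detection (ceil(0.02 × post depth)) — i.e. the probability that
  an unchanged mutation would have been missed anyway.

Trajectories use a detection floor of VAF 0.02 (the FF filter floor):
pre-only / post-only / shared.

## Spectra and signatures

Channels follow the standard 96-context convention (purine references
reverse-complemented to the pyrimidine strand), ordered alphabetically by
class (C>A, C>G, C>T, T>A, T>C, T>G), then 5′ base, then 3′ base; the
6-class marginal is always the row-sum collapse of the 96 vector.

Per-patient spectrum shifts compare mutations that definitely existed before
therapy (pre-only + shared) against post-treatment-only mutations on the
2×6 class table, with the exact conditional test (two-sided by probability
ordering). Enumeration is meet-in-the-middle over column compositions —
exact and fast for table totals into the hundreds where naive recursion over
~10⁷ tables is not; totals above 200 fall back to seeded Monte-Carlo
(10⁵ central-hypergeometric draws, add-one estimator). Ties in table
probability are included using a 1e-12 relative log-probability window;
for the integer totals at which the exact branch runs, genuinely distinct
table probabilities differ by more than this, so the tie rule matches exact
rational arithmetic (oracle-tested). The cohort-level ("en masse") test is
the ordinary chi-square on the pooled 2×6 table. The same enumeration
engine provides the Freeman–Halton exact test for the 2×3
evolution-by-response table; on the reconstructed cohort table
[[2,1,8],[9,2,2]] it gives p = 0.012609.

Signatures are extracted by NMF (multiplicative updates, Frobenius loss —
standard and stable at this scale; scikit-learn backend) on the samples×96
count matrix, best of several seeded restarts, signature columns normalised
to sum to 1 with exposures rescaled. The signature count is scanned over
2..8 and chosen by an automated "maximum differentiation" criterion:
(i) *admissibility* — adding components past the true rank only absorbs
sampling noise, so the per-rank error drops in the tail of the scan estimate
the noise-level improvement, and a rank is admissible once every later drop
is ≤2× the median tail drop (a profile with no elbow admits every rank);
(ii) among admissible ranks, maximise the minimum pairwise cosine distance
between fitted signatures, with scores within 0.15 treated as ties
(duplicate-level separation) resolving to the smallest rank. Per-sample
predominant signatures are the argmax exposure share (ties to the lowest
index, for determinism); samples under 50 mutations are not assessable, and
a signature change requires two assessable, differing labels.

## Arm-scale SCNAs

Per-probe logR values are winsorized to median ± 2.5 × MAD (MAD scaled by
1.4826 for normal consistency; the constant is a package default, declared
rather than inherited from any external tool). Segmentation minimises
Σ RSS(segment) + γ·(number of breakpoints) exactly, by an O(n²) dynamic
programme (oracle-tested against exhaustive partition minimisation). γ is in
squared-logR units: a breakpoint must lower the RSS by more than γ. The
default γ = 10 rejects noise-level splits (expected spurious RSS gain
≈ 2σ²·ln n ≈ 0.15 at σ = 0.1, n = 1000) while accepting arm-scale steps of
|logR| ≥ 0.15 over ≥ ~900 probe-equivalents of evidence (n·Δ²/4 ≥ γ).
Segments are called gain/loss at logR beyond ±0.15 (strict; the boundary is
neutral), and an arm event exists when same-direction segments cover more
than half the arm. Pre/post sharing is the Jaccard fraction on
(arm, direction) identities — arm-scale events are categories, so identity,
not breakpoint overlap, is the right notion of "the same SCNA". A separate
input path accepts absolute-copy-number segment tables and thresholds them
at deviation > 1 from the length-weighted genome mean.

## Cohort statistics

Wilcoxon signed-rank (paired burdens; exact when n ≤ 25 with no zero
differences or ties, else normal approximation with continuity correction),
exact rank-sum for T>A fraction by response with a median-split odds ratio
(Haldane 0.5 correction, flagged, when a cell is empty), Spearman correlation
for age vs C>T fraction (robust on the skewed fraction scale; Pearson by
flag), and 2×2 Fisher for signature change vs response. Tests are two-sided.
No multiple-testing correction is applied to headline p-values (they are
reported nominally, as is conventional for a descriptive cohort battery); a
Benjamini–Hochberg column is emitted for transparency.

## The synthetic cohort

The generator is first-class, tested code, and its defaults are the study
conditions the pipeline targets: 30 patients; scenario mix 11:10:3
(stable:bottleneck:polyclonal) among classifiable cancers; mean burden 373
(hypermutators ×20); exome depth 75× (deep-panel mode 1,800×); purities
around 0.65 with ±0.1 per-patient jitter; hypertriploid genomes (total copy
number 3; MSI cases hyperdiploid at 2); 18 large SCNAs per genome at
|logR| 0.3–0.5 with probe noise sd 0.1; and 20% of patients with degraded
post-treatment samples (purity 0.05–0.25, histology < 15%) to exercise the
QC exclusion.

Clone trees: stable patients draw 2–6 clones by stick-breaking attachment
(child claims a uniform share of its parent's unallocated cell fraction, so
tree consistency holds by construction) and survival ≡ 1. Bottleneck
patients have a doomed major clone (CCF 0.55–0.8, survival ~0.002), an
optional nested sub-clone, and a minor survivor (CCF 0.08–0.18, survival
0.5–1). Polyclonal patients have two founder lineages (CCF ≈ 0.44–0.52
each) with three same-gene TP53 drivers planted across them, one lineage
lost after therapy; two-thirds are MSI hypermutators. Treatment multiplies
each clone's private cell population by its survival factor, renormalises,
and recomputes CCFs as subtree sums (extinction below CCF 1e-4 — far below
any detectable VAF at the simulated depths).

Spectra: three planted 96-channel signatures (ageing-like C>T-at-CpG with
.TT>.GT; C>A-rich; T>C-at-.TT with C>A) plus a uniform T>A component. The
ageing weight increases with patient age (coupling age to C>T fraction);
responders receive a T>A excess calibrated so that, over the baseline ~4.5%
T>A content of the signatures, responder/non-responder medians land near
7% / 5%. Post-treatment-only mutations (Poisson, mean 30; hypermutators
×20) draw from a mixture shifted from the ageing toward the C>A component
(shift strength 0.5 / 0.3 / 0.15 for bottleneck / polyclonal / stable),
emulating the chemotherapy-associated C>T→C>A shift. Clinical response is
drawn per scenario (bottleneckers mostly Mandard 2–3, stable mostly 4–5,
polyclonal one-third responders), which induces the evolution-by-response
association at the cohort level.

Realistic nuisance structure: ~1% of variants each receive population-
frequency, panel-of-normals, segmental-duplication or low-mappability
annotations, and ~20 germline-leak variants per patient (normal VAF ≈ 0.5)
are appended — all removed by the filters. Positions live on a synthetic
22-autosome genome with per-chromosome arm tables (a stand-in coordinate
system, not the human genome).

Not emulated: read-level artefacts (the binomial model has no base-quality
or alignment error structure), FFPE deamination beyond the VAF-threshold
difference, indels, mutation multiplicities > 1, focal SCNAs, normal
contamination by tumour, and spatial heterogeneity beyond the pairwise
concordance interface. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to alignment- or chemistry-level artefacts in real data.

## Problem sizes and determinism

The test suite and acceptance script run the classification experiment at
100 patients per scenario (75×, purity 0.6), purity recovery at 4 purity
levels × 50 replicates (500 mutations, 100×), signature recovery on 30
samples of 2,000–4,000 mutations, null calibration of the shift test on
1,000 replicate pairs (burdens 100/80), and SCNA recovery on genomes of
1,000 probes/arm — sizes chosen to give stable estimates on a single CPU in
minutes. Every stochastic component takes an explicit seed; identical
configuration and seed give byte-identical cohort files and reports.

## Known limitations

- Purity for truly polyclonal tumours is under-estimated by design (no
  cluster is clonal), inflating founder CCFs toward the clip bound; the
  polyclonality call itself relies on driver trajectories and
  loss-and-gain patterns, not CCF magnitudes.
- The pre-treatment sub-clone frequency distribution in the generator is a
  stand-in (stick-breaking with uniform shares); real cohorts have unknown
  and heterogeneous clone-size distributions.
- The boundary between "bottleneck" and "no major clonal change" is
  intrinsically a judgement call; the defaults here are explicit stand-ins,
  reported with every call so that downstream users can re-threshold.
- The exact 2×6 test's enumeration cap (total ≤ 200) means very high-burden
  per-patient comparisons use Monte-Carlo p-values (seeded, 10⁵ draws).
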