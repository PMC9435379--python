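# Methods

`snpmeta` pools case–control association evidence for a biallelic SNP from
study-level genotype counts. This note records the statistical model, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Input model and schema

One row per (study × SNP): labels (`study_id`, `snp_id`, `population`,
`subgroup`, `cohort_id`), arm sizes `n_case`/`n_control`, genotype counts
`case_AA case_AG case_GG control_AA control_AG control_GG`, and optionally a
published summary effect `or_point or_ci_low or_ci_high` for studies that
report no counts. `NR` and the empty string are the only missing tokens. A
row may carry counts or a summary effect, not both; a row with neither is
accepted by validation but excluded from every analysis with a logged
reason, so incompletely reported studies remain visible in the accounting.

`cohort_id` exists because one genotyped cohort can contribute rows for
several SNPs: grand participant totals count each cohort once, while
per-SNP totals sum rows as printed. In the packaged fixture the two Su rows
share one `cohort_id`, which is what makes the fixture's totals
(55,829 participants; 39,231 cases; 16,598 controls) come out right.

The coded allele is A exactly as each source table prints it. No risk-allele
harmonisation is attempted across studies — there is no reliable way to
infer strand or risk orientation from counts alone — but
`io_studies.flip_alleles` can reverse individual rows explicitly.

## Genetic-model contrasts

For genotype counts (AA, AG, GG) the four 2×2 contrasts are

* allele: A vs G with A = 2·AA + AG, two alleles per person, treated as
  independent observations (standard for this contrast; exact when
  genotypes are at Hardy–Weinberg proportions);
* recessive: AA vs AG+GG; dominant: AA+AG vs GG (person level);
* additive: AA vs GG, discarding heterozygotes. This is the genotypic
  extreme-homozygote contrast, implemented literally as the originating
  analysis labels it; it is *not* a Cochran–Armitage trend test, and no
  trend test is offered.

A brute-force per-individual expansion oracle in the test suite guarantees
the collapsed tables equal what explicit enumeration of individuals gives.

## Per-study estimation

The crude OR (a·d)/(b·c) is paired with the Woolf variance
1/a + 1/b + 1/c + 1/d on the log scale — the universal default for 2×2
meta-analysis inputs. A zero cell triggers the Haldane–Anscombe correction
(+0.5 to all four cells, point estimate and variance) and flags the
estimate; a fully empty margin is an error rather than a number. Reported
effects are converted back to (log-OR, SE) via SE = (ln hi − ln lo)/(2·1.96).
All 95% intervals use 1.96 exactly, matching conventional reporting rather
than a re-derived quantile.

Hardy–Weinberg equilibrium is tested per study arm with the plain
1-df chi-square against expected counts (n·p̂², 2n·p̂q̂, n·q̂²), no continuity
correction. HWE deviation is reported, never silently acted on: exclusion
on control-arm HWE failure is available behind an explicit p-threshold
option and is off by default, because which studies (if any) should be
dropped on HWE grounds is a substantive judgement the data alone do not
settle.

## Heterogeneity, pooling, method selection

Cochran's Q is computed with inverse-variance (Woolf) weights on the
log-OR scale for every model — including when the point pooling is
Mantel–Haenszel, which supplies no per-study variances —
and I² = max(0, (Q − df)/Q) × 100, clamped to [0, 100].

The default decision rule selects DerSimonian–Laird random effects when
Q's p < 0.05 **or** I² > 50%, and Mantel–Haenszel fixed effect otherwise.
Both thresholds and the any/all conjunction are configurable
(`HeterogeneityRule`); the conjunctive p < 0.1 variant seen in some
protocols is covered by tests.

MH pooling uses OR_MH = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) with the
Robins–Breslow–Greenland variance for the CI (valid under sparse-data
asymptotics). The MH point estimate always uses raw cells; a zero cell is
corrected only inside the variance sums. Reported weights are the
normalised MH weights bᵢcᵢ/nᵢ. DL estimates
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) and pools with weights 1/(seᵢ² + τ²);
at τ² = 0 it coincides with inverse-variance fixed pooling to machine
precision (tested). Pooled p-values are two-sided normal tests on the log
scale. No Hartung–Knapp adjustment and no REML/Paule–Mandel τ² are offered.

A subgroup with one usable study returns that study's crude estimate with
heterogeneity marked not computable. Rows lacking counts cannot enter the
recessive/dominant/additive contrasts and are excluded there with a reason;
under the allele model a summary-effect row joins inverse-variance random
effects when the rule selects DL, and is excluded (logged) when the
count-based MH path is taken.

Analyses are stratified per SNP by default. Pooling *different SNPs* into
one meta-analysis — which the packaged fixture's source analysis did — is
statistically unusual, so it requires the explicit `combine_snps` flag
(`--combine-snps` on the CLI); internal labels are then keyed `study:snp`
because one cohort may contribute a row per SNP.

## Small-study bias

Egger's test is the classical unweighted OLS of the standardised effect
θᵢ/seᵢ on precision 1/seᵢ, intercept t-tested on k − 2 df; it needs k ≥ 3
and is skipped (logged, not fatal) below that. Funnel data are exported as
(log-OR, SE) pairs untransformed. One Egger test is run per
(model × subgroup) over the same study set pooled there. No trim-and-fill
or Begg test.

## Synthetic generator

`SyntheticScenario` emulates exactly the sampling structure the analysis
assumes: control genotypes multinomial at Hardy–Weinberg proportions for a
control allele frequency `p_control` (default 0.3, a common-variant
frequency typical of the fixture's SNPs), optionally distorted by an
inbreeding-style coefficient f → (p²+fpq, 2pq(1−f), q²+fpq); study-level
log-OR drawn Normal(ln OR, τ²); case allele odds = control odds × study OR
with case genotypes at Hardy–Weinberg for the implied case frequency; arm
sizes default 1,000/arm, k per scenario. Study j's stream is seeded by
(seed, j), so removing a study leaves the others' draws unchanged. Because
the disease model is allelic, the allele contrast's true OR is the scenario
parameter itself; the other contrasts have derived truths computable from
the genotype probabilities (`true_contrast_or`), e.g. the AA-vs-GG contrast
has true OR equal to or_allele².

The generator does **not** emulate covariate confounding, genotyping error,
linkage disequilibrium between SNPs, selective publication, or allele-coding
heterogeneity across studies. Passing calibration on it therefore shows the
estimators are correct and nominally calibrated under the assumed sampling
model — not that real literature pooling is free of those biases.

## Calibration experiments and sizes

`snpmeta.calibration` drives seeded Monte-Carlo checks used by the tests
and the reproduction script: Cochran's Q and HWE type-I error at α = 0.05
(2,000 replicates, k = 10, 1,000/arm); MH 95% CI coverage of true per-allele
OR ∈ {1.0, 1.2, 1.5} (2,000 replicates each); and mean DL τ̂² over 1,000
replicates of k = 20 studies with known SEs drawn uniform on [0.1, 0.3] and
true τ² = 0.04. These sizes put the Monte-Carlo standard error around half
a percentage point for the rates, comfortably inside the ±1.5-point bands
asserted, while the whole suite stays fast.

## Replication of the packaged fixture and its known divergence

Running the pipeline on the fixture with `combine_snps` reproduces the
structure of the originating analysis: 12 pooled results (4 models ×
Asian/non-Asian/pooled) with the count-free Bevan row excluded with a
logged reason. The *numbers* deliberately do not reproduce the summary
table originally published for these studies: that table's pooled CIs are
several times wider than any standard fixed-effect pooling of its own
genotype counts yields, one printed interval is an evident misprint, and
the per-study allele orientation used there is unstated. The pipeline
reports its own count-based values and attaches a fixed divergence note
(`pipeline.RECOMPUTATION_NOTE`) to every report instead of forcing
agreement.

## Numerical conventions and degenerate inputs

Tie-breaks and edge cases: q = 0 ⇒ I² = 0; Q below df clamps both I² and
τ² at 0; monomorphic samples return a flagged chi2 = 0, p = 1 HWE result;
empty subgroups, all-degenerate table sets, k < 2 pooling and k < 3 Egger
raise typed errors. Reports contain no timestamps, so a rerun with the same
inputs is byte-identical. All TSV/JSON output is UTF-8 with "." decimals.
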