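# Methods

## The score model

A sample's weighted gene score over a panel *P* is wGS = Σ_{i∈P} c_i·β_i,
with c_i the count of the LDL-c-raising allele and β_i the signed
per-allele effect in mmol/L.  The score is a pure burden sum: no
standardisation, no variance-explained scaling.  Its analytic range over a
panel is [Σ min(0, 2β_i), Σ max(0, 2β_i)]; with the shipped weights the
only negative contribution comes from rs7412, whose counted (ε2-defining)
T allele lowers LDL-c, so an E2/E2 homozygote can carry a negative score.

**APOE.**  Two conventions are implemented because published small-panel
scores differ on this point.  The default treats rs429358 and rs7412 as two
additive terms, which keeps the "11 SNPs" arithmetic of the full panel.
The alternative replaces the pair with one configured contribution per
ε-diplotype.  Diplotypes are called from the two-site genotype under a
no-ε1 (no-recombinant) assumption: the double heterozygote is phased as
E2/E4; genotype pairs only explicable by an ε1 haplotype — and pairs with
either site missing — are `indeterminate` and treated as missing.

**Missing data.**  The default policy excludes a sample from a panel's
score whenever any panel dosage is missing (the sample is retained in the
output, flagged incomplete, so denominators are explicit).  This mirrors
clinical practice where incompletely genotyped patients are dropped from
score-based denominators.  A `renormalize` policy (partial sum scaled by
panel size / SNPs observed) is provided for sensitivity analysis; the two
agree exactly on complete samples.

## Panels

`wGS11` is the full genotyped assay; `wGS8` keeps the seven SNPs retained
by stepwise association (ABCG8 rs4299376, APOE rs7412, CELSR2-SORT1
rs629301, PCSK9 rs2479409, LDLR rs6511720, APOB rs1367117, MYLIP rs3757354)
plus rs429358 so ε-genotypes stay resolvable; `wGS6` is the published
six-SNP refinement.  The panels are nested (wGS6 ⊂ wGS8 ⊂ wGS11), which the
score-difference operation exploits: for nested panels the per-sample
difference equals the score over the set-difference SNPs, by linearity.

## Weights

The exact consortium per-allele betas are not redistributable here, so the
shipped `data/default_weights.json` is a synthetic placeholder holding
GLGC-orientation approximations (0.014–0.18 mmol/L per allele; rs7412 at
−0.40).  All pipeline logic takes the weight table as input; replacing the
file replaces the science.  Under these placeholder magnitudes the expected
control-population score is ≈ 0.74 with SD ≈ 0.21 for the 8-SNP panel —
the scale on which such scores are reported for European populations.

## Synthetic cohort

The generator emulates the study conditions: 503 European population
controls, 420 mutation-negative (FH/M−) and 250 mutation-positive (FH/M+)
clinically diagnosed patients.

* **Controls** are drawn in Hardy–Weinberg equilibrium, dosage ~
  Binomial(2, p) independently per SNP, at approximate 1000G European
  effect-allele frequencies.
* **Patients, frequency-shift mode (default)** are HWE draws at
  group-shifted frequencies.  The FH/M− shifts were set on the allele
  odds-ratio scale reported for such cohorts (largest at ABCG8 rs4299376,
  implied allele OR ≈ 1.6; ε2 depleted), and FH/M+ gets ≈ 40% of each
  shift, reproducing the EUR < FH/M+ < FH/M− score ordering.
* **Patients, liability-threshold mode** are drawn at *control*
  frequencies; a latent LDL-c liability Σ c_iβ_i + N(0, σ) with residual
  σ = 0.8 mmol/L is computed and the top 5% tail kept (50% for FH/M+,
  whose hypercholesterolemia is mutation-driven).  Enrichment is then
  endogenous — nothing about case allele frequencies is hard-coded — with
  expected mean-score gap Var(wGS)/SD(liability)·λ(q) ≈ 0.11 at q = 0.05,
  the scale the frequency-shift mode encodes directly.  The selection-gap
  monotonicity over q ∈ {0.2, 0.1, 0.05} is a tested property.
* **Phenotypes.**  FH/M+ samples get a mutation gene from a 231:19
  LDLR:APOB split.  DLCN components are independent Bernoulli draws at the
  group margins; the DLCN point total is drawn uniformly inside the band of
  a diagnostic class (<3, possible 3–5, probable 6–8, definite >8) sampled
  from group-specific class proportions, so score and class never disagree.
  Age is Gaussian per group (FH/M+ younger), sex ≈ 46% male.  Patient
  genotypes carry a 0.4% per-cell missing rate, so ≈ 4% of patients are
  incomplete under the default missing policy — the realistic "403 of 420
  scoreable" situation.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs (the panel is one SNP per locus by design), dependence between
DLCN components (margins only — no copula), family structure, and any
LDL-c measurement model.  Tests passing on synthetic data therefore
validate the pipeline's statistics and bookkeeping, not the biological
effect sizes of any real population.

## Statistical choices

* **HWE:** chi-square goodness of fit (1 df) against expectations from the
  observed allele frequency; the exact conditional test (enumeration over
  heterozygote counts, two-sided by probability mass) replaces it whenever
  an expected count is below 5.
* **Allele association:** Pearson chi-square on the 2×2 allele-count table,
  without continuity correction (standard association-testing practice);
  Fisher's exact test when any expected cell is below 5 or any observed
  cell is zero.
* **Stepwise refinement:** bidirectional selection on the additive-dosage
  logistic model, Wald-p driven with enter 0.05 / remove 0.10 (an
  AIC-driven mode is available).  The entry/removal rule is a package
  choice — reported Wald p-values motivate the p-driven default.
  Quasi-separation is flagged on the result, never silently ignored.
* **Group comparison:** Shapiro–Wilk gate at α = 0.05 per group; Welch's
  t-test when both groups pass (unequal variances assumed, matching R's
  `t.test` default), Wilcoxon–Mann–Whitney otherwise; ANOVA /
  Kruskal–Wallis plus pairwise post-hocs beyond two groups.  Fully tied
  data short-circuit to p = 1.
* **Trend:** Cochran–Armitage with integer category scores, standardised by
  the exact permutation mean/variance, hence affine-invariant in the
  scores; for K = 2 it reduces to the 2×2 chi-square times (N−1)/N.
* **Adjusted associations:** logistic `component ~ wGS + age + sex`.
* **Multiplicity:** raw p-values throughout, matching how such panels are
  reported; no correction is applied.

## Cutoffs and ROC

Percentile thresholds use numpy's default linear-interpolation ("type 7")
quantile; the convention is declared because results are sensitive to it by
at most one order statistic (a tested bound).  "Above the cutoff" is strict
(`score > t`), the conservative reading, configurable to inclusive.

ROC curves sweep midpoints between adjacent distinct pooled scores, with
operating points computed from the score values themselves (midpoints can
collide with near-equal floats).  Every curve's trapezoid AUC is
cross-checked against the Mann–Whitney identity U/(n₁n₀) with tie credit ½
and must agree to 1e-10 — a hard internal assertion, not a test-only
property.  Youden's optimum is the sweep maximum of sens + spec − 1 with
ties broken toward the higher threshold (higher specificity).  AUCs are
compared with a placement-value (DeLong-type) covariance test, paired by
default; the choice of this test over alternatives is a package assumption.
Degenerate inputs (all scores equal) yield AUC 0.5 with an explicit flag.

## Fraction estimator

combined% = M + (100 − M)·r/100.  M is computed from cohort counts
(mutation-positives over all FH patients in the stratum; controls never
enter the denominator); r is the share of *scoreable* mutation-negative
patients above the cutoff — patients with missing scores are excluded from
the denominator, and the report says so.  Percentages are carried at full
precision and rounded to one decimal only at report time, so
37.3/46.4 → 66.4 and 50.7/51.1 → 75.9 by the same arithmetic path the
report uses.  DLCN strata are `all`, `definite` (>8), `probable` (6–8) and
`probable+definite` (≥6).  No uncertainty interval is attached to the
combined percentage; a bootstrap over samples would be the natural
extension.

## Determinism and problem sizes

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawns (one stream per group), so a fixed
config yields byte-identical TSVs and JSON reports.  The test suite runs
its distributional checks at the study's own scale (hundreds of samples
per group, 20–50 seeds per property, 10⁵ draws for the permutation
comparison), which keeps the full suite under a minute on one CPU while
leaving each power-style assertion with a comfortable margin over its
threshold.

## Known limitations

* The placeholder betas make absolute score values illustrative; only the
  machinery, not the clinical thresholds, transfers to real data.
* Stepwise variable selection inherits the usual instabilities near the
  entry threshold; the AIC mode and the reported selection order are
  provided to make this visible.
* The DeLong comparison assumes large-sample normality of the AUC
  difference; very small groups should rely on the reported AUCs, not the
  p-value.
* No multi-allelic VCF support, no imputation, no liftover: matching is by
  rsid with exact allele sets, and ambiguous strand flips are rejected
  rather than guessed.
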