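# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions and the open design choices behind `dioecy`.

## The problem

In a dioecious tree population, sex is a binary phenotype controlled by a
compact XY-type sex-determining region (SDR): at a fully sex-linked SNP,
females carry the homozygous-reference (XX) class and males the heterozygous
(XY) class. Three analyses hang together: (i) find sex-linked SNPs by a
genome-wide association scan against sex; (ii) use the reliable ones as a
molecular sexing panel for unsexed individuals; (iii) test quantitative
traits for sexual dimorphism while correcting for the strong geographic
population structure these species show. Because sampled individuals differ
systematically along a latitudinal cline, any sex-by-geography sampling
imbalance can masquerade as dimorphism; the package treats that confound as a
first-class object (it can be simulated, demonstrated and corrected).

## Association scan

- **Filters.** A SNP enters the scan when its minor-allele frequency
  (computed on non-missing calls as `min(f_ALT, 1 − f_ALT)`) is ≥ 0.05 and
  its call rate is ≥ 0.9; both thresholds are parameters.
- **Trend test (default).** The Cochran–Armitage/score statistic `N·r²`,
  where `r` is the Pearson correlation between ALT dosage and the 0/1 sex
  indicator over complete cases, referred to χ² with 1 df. With
  population-structure correction, `r` is the partial correlation after
  projecting dosage and sex on the top-k genotype principal components — the
  standard score-test-with-nuisance-covariates form. The statistic is
  symmetric in the sex labels and reaches its ceiling `N` at full linkage.
- **Logistic alternative.** A per-SNP logistic regression of sex on
  intercept (+ PCs) + dosage, tested by likelihood ratio (1 df). Fully
  sex-linked SNPs separate the classes perfectly, so the MLE diverges; the
  implementation detects complete separation (non-overlapping dosage ranges),
  caps the full-model log-likelihood at its supremum 0, reports
  `p = χ²₁-tail(−2·ll_null)` and sets a separation flag. The signal of
  interest is exactly these SNPs, so they are reported as maximally
  significant rather than failing. The trend test is the default because it
  is well-defined under separation and discovers the same fully linked
  markers.
- **PCA.** Dosages are mean-imputed per SNP, standardized, and decomposed by
  SVD. Sex-associated SNPs are excluded from the decomposition (found by an
  unadjusted first pass at the same Bonferroni level), so the components
  capture geography, not the SDR. Signs are fixed so each component's
  largest-magnitude loading is positive, making results run-reproducible.
- **Multiplicity.** Bonferroni at `α/m` with `m` = the number of SNPs
  actually tested after filters. Note that at α = 0.05 over 2,248,597 tests
  the exact threshold is 2.2236 × 10⁻⁸; reported thresholds in the
  literature are sometimes rounded upward (2.26 × 10⁻⁸), a discrepancy the
  package sidesteps by always computing the division exactly.

## Sexing panel and caller

- **Profiling.** Per candidate SNP and sex, the modal genotype class over
  non-missing training calls and the fraction matching it ("concordance").
  Ties break toward the lower dosage code. A marker is *strongly predictive*
  when both concordances are ≥ 0.90 (inclusive) and the two classes differ.
  "Strict allelic variability" is operationalized as exact genotype-class
  match to the per-sex majority class; no algebraic definition beyond this is
  assumed.
- **Cross-source concordance.** For samples genotyped by two sources, a
  panel SNP passes when the fraction of non-missing genotype-class
  disagreements is ≤ 0.05. A rate rule is primary; an optional strict
  integer cap (`max_mismatch_count`) is available because a "3 of 92" style
  cap is stricter than floor(0.05·92) = 4.
- **Calling.** Each panel marker with a non-missing genotype votes female,
  male, or abstains (genotype matches neither class). With `n_inf`
  informative markers: *undetermined* if `n_inf < min_markers` (default 5);
  *female*/*male* if that vote fraction ≥ τ (default 0.9); otherwise
  *putative recombinant*. τ and `min_markers` are conventions, exposed as
  flags; a true SDR recombinant carrying a partially swapped haplotype
  produces a mixed vote and lands in the recombinant class by construction.
  Calling is deterministic and order-independent, and swapping the training
  labels swaps female/male calls exactly.

## Dimorphism battery

- **Engines.** Traits with clonal ramet replication use a Gaussian linear
  mixed model with a genotype random intercept (statsmodels `MixedLM`);
  unreplicated traits use OLS. All fits are maximum likelihood, *not* REML,
  because likelihood-ratio tests comparing fixed-effect structures are
  invalid under REML. `BIC = −2 logL + k ln n` with `k` counting mean
  parameters plus variance components (1 for LM, 2 for LMM).
- **Pipeline per trait.** (1) engine by replication; (2) BIC selection of
  geographic covariates (subsets of latitude/longitude, or PC1/PC2 in `pcs`
  mode; planting year enters as a fixed effect when present with > 1 level);
  (3) sex×geography interaction screened by LRT and retained only below 0.05
  — if retained, the sex LRT removes sex and its interactions together
  (marginality, df = 1 + #interactions); (4) LRT for sex; (5) ω² for sex and
  geography on genotype-mean collapsed OLS fits; (6) nominal significance and
  cross-stratum repeatability flags. Benjamini–Hochberg q-values are added
  across a battery as a convenience; the repeatability verdict (significant
  in *every* stratum) is the primary robustness filter.
- **ω².** `ω² = (SS_term − df_term·MS_err)/(SS_total + MS_err)` with type-II
  sums of squares (RSS of the model without the term, all others retained,
  minus full-model RSS) and `SS_total = Σ(y − ȳ)²`. The raw value is
  preserved; the reported value is clamped to [0, 1] so null effects print
  as 0. It is computed on genotype means because effect-size comparison
  across sites is done at the genotype level; a mixed-model variance-ratio
  analogue is deliberately out of scope.
- **Warming experiment.** Paired 2×2 chilling-scenario × forcing-temperature
  design, genotype random intercept, ML; LRTs for scenario×temperature, sex,
  sex×scenario and sex×temperature. A missing design cell is an error, not a
  degraded fit.
- **Numerical notes.** MixedLM optimizers are tried in sequence (lbfgs,
  bfgs, cg, powell, nm) because large-valued covariates such as raw latitude
  can produce a singular Hessian in the default optimizer; a genotype
  variance below 10⁻⁴ of the total marks a boundary fit instead of raising.
  LRT statistics are clamped at 0 and identical specs give p = 1. Candidate
  models in BIC selection are always fit on the identical complete-case row
  set; rank-deficient designs raise an error naming the collinear terms.

## Synthetic populations

The generator emulates the study conditions the analyses assume:

- ~1:1 sex ratio (`sex_ratio = 0.5`), latitudes uniform over 44.0–59.6 °N
  (a realistic northern-temperate riparian collection window; collection
  density along the cline is not modelled).
- Background SNP j: baseline ALT frequency `p0_j ~ U(maf_range)` with
  `maf_range = (0.05, 0.5)`, latitudinal slope `b_j ~ N(0, cline_sd²)` on
  the logit scale with `cline_sd = 0.05` per degree — moderate clines that
  put most of PC1 on latitude without fixing alleles at the range edges.
  Genotypes are binomial(2, p(lat)); no linkage disequilibrium between
  background SNPs is simulated.
- SDR: 12 fully sex-linked markers by default (females 0, males 1);
  `sdr_error_rate = 0.01` flips a marker to the opposite-sex class,
  matching the dominant 99–100 % per-sex concordance regime of real sexing
  panels; `recombinant_fraction = 0.005` keeps recombinants under 1 %.
  A recombinant carries the opposite-sex class on a contiguous half of the
  SDR markers. The genotypic architecture of natural SDR recombinants is
  unknown; the block swap is a declared convention chosen to produce the
  mixed-vote signature a caller must flag, not an inference about real
  haplotypes.
- `missing_rate = 0.02` per call; one root seed with named per-stage child
  streams (sex, geography, background, SDR, missingness, traits), so
  identical configuration gives byte-identical VCF and CSV output.
- Traits: `y = μ + β_lat·lat + δ_sex·1[male] + β_int·lat·1[male] + G + ε`
  with `G ~ N(0, σ_G²)` shared across all ramets and sites of a clone and
  `ε ~ N(0, σ_E²)` per planted tree. The factorial design adds scenario,
  temperature and interaction effects (fields `beta_scenario`,
  `beta_temperature`, `beta_scenario_temperature`) with the same genotype
  random effect. `confound_sex_lat` implements *sampling* bias: a genotype
  enters the phenotyped set with probability `expit(±c·(lat − lat_mid))`
  (sign by sex), leaving the underlying population untouched — this is the
  mechanism by which geographically uneven sexing produces spurious
  dimorphism, and the latitude covariate removes it.

What the generator does **not** emulate: linkage disequilibrium and
coalescent ancestry, multi-allelic or structural variation, genotyping-error
correlation between SNPs, spatial autocorrelation within plantations,
non-Gaussian trait distributions, and genotype-by-environment covariance
beyond site-independent noise. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under its stated model, not
that real data meet those assumptions.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on simulated data at
sizes chosen to make every check sharp but quick on a single CPU: scans use
126 samples with 10,000 background + 12 SDR SNPs; calibration uses 1000 null
replicates per test; the homomorphic battery uses 96 traits × 3 sites × 300
genotypes; caller recovery uses a 500/500 train/held-out split; ω² recovery
uses 200 replicates at n = 2000. All randomness flows from a single seed.

## Known limitations

- The logistic engine reports a capped, flagged p under separation rather
  than an exact conditional test (e.g. Firth correction is not implemented).
- LRT p-values for mixed models use the χ² reference; no Satterthwaite or
  Kenward–Roger small-sample correction is attempted, so small-n LMM p-values
  are asymptotic.
- The trend-test χ² reference is continuous while the exact permutation null
  of integer dosages at small n is discrete with atoms; tests compare against
  the permutation bracket [P(T > t), P(T ≥ t)].
- `multi_site_battery` collapses to genotype means per stratum; it does not
  fit a joint multi-site model with genotype-by-site terms.
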