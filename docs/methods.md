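# Methods

## Model and procedure

META-GSA pools per-study gene-set-analysis p-values `p_GS,s` with the
weighted Fisher statistic `M0 = −2 Σ_s w_s ln p_GS,s`, where the weight of
study *s* measures how well its gene-level association pattern agrees with
the other studies'. The pipeline has four stages.

**1. Marker → gene (PDRs).** Each gene in each study receives a p-value
`p_g,s` and a direction `d_g,s ∈ [−1, 1]`, combined into the directed
reversed p-value `p' = d · (1 − p)`. Three aggregation strategies are
provided (`aggregation=`):

* `best` — the gene's most significant marker represents it
  (`p_g = min_m p_m`; ties broken toward the lexicographically smallest
  marker id). If studies select different representative markers, the
  direction is `sign(θ)` times the mean signed allele correlation *r*
  between this study's marker and every other study's selection, so a
  representative in linkage equilibrium with the other selections
  contributes nothing (`d = 0 ⇒ p' = 0`). A missing cross-study LD entry
  is an error — silently assuming r = 0 would annihilate the gene.
* `all` — LD-weighted Fisher combination over all markers of the gene,
  `C = −2 Σ v_m ln p_m` with redundancy weights
  `v_m = 1/Σ_{m'∈block(m)} r²(m', m)`; the direction is the v-weighted
  mean of the marker signs, normalized by Σv so |d| ≤ 1 and the PDR stays
  in [−1, 1].
* `promising` — the same restricted to markers with p < 0.05; a gene with
  no promising marker gets (p = 1, d = 0), flagged.

LD blocks are the connected components of the within-gene marker graph
thresholded at r² ≥ 0.5 (single linkage; configurable; blocks never span
genes). `C` is referred to χ² with df = 2·Σv by default, by analogy with
the unweighted Fisher method (n independent markers, Σv = n, df = 2n);
this also makes a single-marker gene reduce exactly to its marker
(`p_g = p_m`). A strict `df_mode="sumv"` is available for the reading in
which Σv itself sets the degrees of freedom.

Before PDRs are formed, gene directions are re-oriented along the profile
of reference directions: for each gene whose mean direction across studies
is negative, all entries are negated. A mean of exactly zero leaves the
gene unchanged — deterministic and unbiased. The operation is idempotent.

**2. Concordance → weights.** Pairwise Kendall τ-b between the study
columns of the GS PDR matrix (τ-b because PDRs tie at 0; Pearson and
Spearman are available as sensitivity options). PCA of the τ matrix gives
the first-component loadings PC1 and eigenvalue EV1; `EV1/n_s` is the
effective number of studies, and `w_s = PC1_s/ΣPC1 · EV1/n_s`, so
Σw = EV1/n_s. The τ matrix need not be positive semidefinite; only the
leading eigenpair is consumed, with the sign fixed so the loading sum is
positive.

*Degenerate case.* The normalization is undefined when ΣPC1 ≈ 0. This is
reachable in routine inputs: two studies with τ < 0 have
PC1 = (1, −1)/√2, and equal negative pairwise τ's leave the whole top
eigenspace orthogonal to the ones-vector. Rather than fail, the weights
fall back deterministically to the equal split `w_s = EV1/n_s²`, which
preserves the weight-sum identity; the fallback applies identically inside
the permutation null, which therefore absorbs the convention. A warning is
also emitted when |w| becomes large (mixed-sign loadings with a small
sum), a regime in which the statistic is unstable — see Limitations.

**3. Permutation test.** Because the weights are data-driven, possibly
negative and do not sum to one, M0 is not χ²-distributed. Each permutation
draws `gs_size` genes uniformly from the universe (GS ∪ complement),
recomputes τ/PCA weights on that random profile, draws per-study p-values
from U(0,1) and evaluates M. The p-value uses the add-one estimator
`(#{M_j ≥ M0} + 1)/(n_perm + 1)`, never exactly zero. Observed `p_GS,s = 0`
inputs are clamped to `1/(2·n_perm)` — finite statistic, matched to the
resolution of the permutation grid. Defaults: 9,999 permutations for a
single gene set, 999 per set in the power study. An optional sequential
early-stopping rule (off by default) stops once the 99% CI of the running
estimate lies above 0.25 after ≥ 200 permutations; it saves time on
clearly non-significant sets at the cost of coarse p-values for them.

**4. Multiplicity.** Across many gene sets, π₀ is estimated by the
Storey–Tibshirani bootstrap (λ grid 0.05…0.95 step 0.05, 100 bootstrap
draws, estimate clipped into (0, 1] with lower bound 1/n) and
`p_meta = min(1, p_permut · n_GS · π₀)`. With a single gene set π₀ = 1 (no
correction). Note the bootstrap targets the minimum of π̂₀(λ), which
biases the estimate slightly low — about 0.05 at 2,000 sets with the
default grid.

## The simulator

`simulate_gwas` emulates per-study case-control GWAS panels: diallelic
markers (one per gene), genotypes in Hardy-Weinberg equilibrium at minor
allele frequency 0.30, binary phenotype of prevalence 5%, 500 cases and
500 controls per study — the defaults of the 20-scenario power study in
`power_study.scenario_registry()`. Association is injected through a
log-additive penetrance model `f_j = f0 · RR^j` (j copies of the risk
allele), with `f0` solved so that `Σ_j f_j P_j` equals the prevalence
exactly; scenarios with `f0·RR² > 1` are rejected. Which allele carries
the risk is randomized with probability ½ per associated marker — keeping
the minor-allele frequency at 0.30 while preventing a systematic
minor-allele-risk orientation. By default the drawn orientation is shared
by all studies (the same variant is the risk variant everywhere), which is
what makes association patterns concordant across studies and gives the
concordance weighting something to detect; `shared_direction=False`
re-randomizes per study and destroys that concordance. Marker analysis
uses the two-sided Cochran–Armitage trend test (scores 0/1/2), a
per-allele log odds ratio from the allele-dosage 2×2 table
(Haldane–Anscombe 0.5 correction when a cell is empty, Woolf standard
error), `d = +1` iff OR ≥ 1, and a 1-df χ² HWE filter in controls at
p < 1e-7. The per-study GSA is the one-sided Wilcoxon rank-sum test for
enrichment of low marker p-values in the 10-gene set against the 90
remaining genes (exact null for small untied groups, otherwise normal
approximation with tie and continuity corrections); pooledGWAS-GSA uses
DerSimonian–Laird random-effects pooling of the per-marker log odds
ratios.

What the simulator does **not** emulate: LD between the simulated markers
(every gene has exactly one marker; multi-marker aggregation and LD
weighting are exercised by unit tests, not by the power study), covariate
adjustment, population stratification, genotyping error, and imperfect
SNP-to-gene annotation. Passing power simulations therefore demonstrate
the statistical machinery under an idealized architecture, not performance
on real GWAS panels.

## Problem sizes and reproducibility

The power scenarios are run at 500 replicates with 999 permutations per
replicate in `scripts/acceptance.py`; the test suite uses 150–400
replicates per scenario so the whole suite stays in the minutes range on
one CPU. All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning — one child per replicate — so
results are bit-reproducible for a fixed seed and independent of batching.
Monte Carlo uncertainty at 500 replicates is about ±1 percentage point
(SE) near a 5% rate and ±2.2 near 50%.

## Numerical conventions

* Kendall τ-b is computed from pairwise sign products with tie-corrected
  normalization (validated against `scipy.stats.kendalltau`); a constant
  profile column has no rank information and gets τ = 0 with a warning.
* Permutation subsets are drawn by partial argsort of uniform keys —
  uniform over subsets without replacement.
* Non-finite null statistics (possible only in pathological weight draws)
  count as extreme, which is conservative.
* SPP clamps p = 0 at 1e-300 (its χ² tail is analytic; there is no
  permutation grid to match).
* Re-orientation ties (gene mean direction exactly 0) leave the gene
  unchanged; representative-marker ties pick the smallest marker id.
* DerSimonian–Laird: `τ² = max(0, (Q − (k−1))/C)`; with Q ≤ k−1 the
  estimator reduces to the fixed-effect inverse-variance pool. A single
  study is passed through with a warning.

## Known limitations

* **Weight explosion.** When a gene set's PDR profiles are mutually
  discordant, the PC1 loadings mix signs and their sum can be small, so
  Eq-5-type weights become arbitrarily large (|w| in the tens). The
  permutation null uses the same rule and absorbs much of the effect, but
  two consequences remain: the null distribution acquires heavy tails
  (which costs power at intermediate signal strengths and intermediate
  study counts), and an observed set whose profile is atypically
  discordant relative to the permutation universe can produce a large
  mixed-sign statistic. A magnitude warning is emitted; treat such results
  with caution.
* **Exchangeability assumption.** The permutation null draws gene sets
  uniformly from the whole universe. If the universe contains a large
  fraction of strongly associated, concordant genes, random draws are not
  exchangeable with a null set and calibration degrades; with a
  predominantly null universe (the usual genome-wide situation, and the
  null simulation scenarios, where empirical type-I error is 3.4–5.6% at
  α = 5%) the test is well calibrated.
* **Saturation under the default scenarios.** Under the registry defaults
  (500+500 subjects, MAF 0.30), a marker with per-allele RR 1.5 carries a
  trend-test z of ≈ 4.6, so per-study GSA p-values are already small and
  the pooled tests saturate near 100% power in the stronger scenarios;
  the interesting power gradations occur at RR ≤ 1.2 or with far smaller
  per-study samples. The simulator exposes `n_cases`/`n_controls`/`rr` so
  weaker-information regimes can be explored directly.
* META-GSA produces p-values only — no pooled effect estimate — and is of
  limited use for pleiotropy questions, since it rewards concordance of
  gene effects across all studies.
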