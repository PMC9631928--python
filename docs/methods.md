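# Methods

## Data model

One *study* is an independent case-control comparison at a biallelic SNP
with major allele G and minor allele C.  A study carries declared arm
sizes (`n_case`, `n_control`) and, when published, genotype counts
(GG/GC/CC) per arm; studies without counts may carry a precomputed
log-OR and SE instead, which only the allele model accepts (that is the
scale such published effects are usually on).  Raw inputs are integer
counts only; continuity corrections are applied at estimation time and
never stored, so the input file stays auditable.

The bundled fixture reproduces the published rs9349407 study table
verbatim.  Validation distinguishes *errors* (negative counts or totals,
half-specified precomputed effects) from *warnings* (genotype totals
that disagree with the declared arm total).  Warnings never block an
analysis: published tables routinely contain partially genotyped arms,
and the "correct" figure is unknowable downstream.  The fixture itself
triggers six such warnings; they are reported, not repaired, because
provenance beats convenience.  Duplicate study labels (two rows from one
article) are suffixed `_a`/`_b` in row order so leave-one-out output has
unique keys.  One fixture row whose source article is cited but never
named in the text we had access to is labelled `Unnamed`.

## Contrasts and per-study effects

Genetic models map genotype counts to a 2×2 exposure × status table:
dominant GG+GC vs CC, recessive GG vs GC+CC, additive GG+CC vs GC, and
allele C vs G with each subject contributing two alleles (autosomal
diploid counting; no X-linkage allowance).  The allele exposure defaults
to the minor allele C so that OR > 1 reads "C increases risk"; a flag
produces the opposite (G vs C) labelling, since published headings use
both conventions for the same contrast.

`odds_ratio` uses the cross-product with the Woolf SE.  Zero-cell
policy: add the correction (default 0.5) to **all four** cells whenever
**any** cell is zero — the default of mainstream meta-analysis software —
applied per study at estimation time.  A table whose exposure column or
reference column is zero in *both* arms contains no information about
the odds ratio; such studies are marked dropped (with a reason) rather
than estimated or raised, and pipelines exclude them from pooling while
reporting them in the drop list.  The correction is idempotent: tables
without zeros are never altered.

All 95% intervals use the normal quantile at full precision
(1.959963985…), not 1.96, so that OR → CI → P round-trips reproduce
exactly; display formatting (2 decimals for ORs, scientific 3 significant
digits for P) is applied only at export.

## Pooling and heterogeneity

* **Inverse variance (fixed):** weights `w_i = 1/se_i²`; pooled
  `θ̂ = Σwθ/Σw`, `SE = 1/√Σw`.
* **Mantel–Haenszel (fixed):** `OR_MH = Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i)`
  with the Robins–Breslow–Greenland variance for `ln OR_MH`.  Tables with
  a zero cell get the same any-zero 0.5 correction inside the MH sums;
  this keeps the estimator defined when a study has an empty cell and
  matches the per-study effects used for Q.  The pipeline default is MH
  for genotype-count inputs and IV when any precomputed effect is mixed
  in (MH needs raw tables).
* **DerSimonian–Laird (random):** moment estimator
  `τ² = max(0, (Q − (K−1))/(Σw − Σw²/Σw))` with IV weights, then weights
  `1/(se_i² + τ²)`.  τ² = 0 collapses DL to IV exactly.  No
  Hartung–Knapp adjustment: plain normal CIs, consistent with the
  printed-CI/P round-trips the package verifies.

Cochran's `Q = Σ w_i (θ_i − θ̂)²` with IV weights, `df = K−1`, `p_Q` from
the upper chi-square tail, and `I² = max(0, (Q − df)/Q) × 100`.  In MH
pooling, Q is computed with IV weights **against the MH centre** (the
common software convention); this can shift I² slightly relative to an
IV-centred Q, which is why it is stated here.  Model selection follows
the conventional rule: random effects iff `p_Q < 0.10` and `I² > 50%`,
both strict, applied per model and re-applied to each leave-one-out
subset.  The pooled `Z = θ̂/SE` with two-sided normal P.

## Robustness diagnostics

* **Leave-one-out** re-pools each (K−1)-subset with the same selection
  policy; requires K ≥ 3 so every subset is still assessable for
  heterogeneity.
* **Funnel coordinates** are (log-OR, SE) with the side taken relative to
  the fixed-effect centre; a study exactly at the centre counts as
  *right* (documented tie-break).
* **Egger:** OLS of `θ_i/se_i` on `1/se_i` (statsmodels), two-sided
  t-test of the intercept on k−2 df.  Constant precision makes the
  regression rank-deficient and is rejected as degenerate.
* **Begg:** Kendall's tau between variance-stabilized deviates
  `(θ_i − θ̂)/√(se_i² − 1/Σw)` and the variances `se_i²`
  (scipy `kendalltau`): the exact null for k ≤ 10 without ties, the
  tie-corrected normal approximation otherwise.  Fully tied variances
  carry no ordering information: tau is reported as 0 with P = 1.
* **Trim-and-fill (Duval–Tweedie, L0):** iterate (i) fixed-effect centre
  of the currently untrimmed studies, (ii) rank |θ − centre| over all
  studies (ties broken by input order, for reproducibility),
  (iii) `k0 = max(0, round((4·T − n(n+1))/(2n−1)))` where T is the rank
  sum on the over-represented side, (iv) trim the k0 most extreme studies
  on that side; stop when k0 stabilizes.  Then fill k0 mirror images
  (reflected log-OR, same SE) on the missing side and re-pool all n + k0
  studies under both fixed and random effects; the reported `adjusted`
  result applies the usual selection rule.  `side` names the side being
  *filled*; `auto` picks the side with the smaller rank-sum of centred
  effects.  R0 and random-effects centring are deliberately not offered:
  one well-characterized estimator is easier to trust than two ambiguous
  ones.

## Synthetic data generator

The generator emulates exactly the sampling structure the pooling model
assumes: k independent studies; control genotypes multinomial under
Hardy–Weinberg proportions `((1−p)², 2p(1−p), p²)` at control MAF p;
per-study true log-OR `θ_j ~ Normal(ln OR, τ²)`; case genotypes
multinomial with HWE weights tilted by `exp(d·θ_j)` for d copies of C.
Under this log-additive model the case arm is again HWE at a shifted
allele frequency, so the induced allele-model odds ratio is `exp(θ_j)`
*exactly*; `induced_log_or` gives the closed-form induced effect for the
other models so tests can target any contrast.  Arm sizes are drawn
uniformly from inclusive ranges before genotypes.  Each study uses a
deterministic substream keyed by (seed, study index), so appending
studies never perturbs earlier ones and every table is reproducible from
its seed.

Defaults (MAF 0.3, per-allele OR 1.3, τ² 0.04, arms 500–2000) describe a
moderately heterogeneous candidate-gene scenario of the kind the fixture
represents: a common variant with a modest effect and realistic
study-to-study spread.  What the generator does **not** model —
population stratification, genotyping error, HWE violations in controls,
case-control matching or ascertainment — bounds what passing tests show:
they validate the estimators under their own assumptions, not robustness
to misspecified real data (the fixture's inconsistent rows exercise the
validator path instead).

## Verification strategy and problem sizes

Every estimator is checked two ways: hand-derived worked examples frozen
into unit tests, and brute-force direct-summation oracles over a random
grid of ≥100 small study sets (k ≤ 3) agreeing to 1e-10.  Stochastic
calibration uses one 200-study simulation for parameter recovery (pooled
OR within 3% of truth; τ̂² near 0.04) and 2,000 replicate 10-study null
meta-analyses for the pooled Z-test's type-I error (expected within
[0.03, 0.07] at α = 0.05); these sizes keep the whole suite and the
acceptance script to a few seconds while leaving the binomial noise well
inside the asserted bands.  Trim-and-fill is validated by construction:
deleting the two left-most studies of a funnel-symmetric 9-study set and
asking the procedure to recover them (it returns k0 = 2 and the deleted
effects to machine precision, because the reflection is exact for this
configuration).

## Known limitations

* The published pooled subgroup results for the bundled fixture are not
  reproducible from the printed counts: four studies lack counts
  entirely and several printed rows are internally inconsistent, so the
  package validates the pipeline on this data by properties (oracle
  equivalence, parameter recovery) rather than by matching those printed
  values.
* τ² estimation is DL-only; REML and Paule–Mandel are out of scope, as
  are meta-regression, Hartung–Knapp CIs, multivariate meta-analysis and
  PET-PEESE-style bias adjustments.
* No Hardy–Weinberg equilibrium *testing* of control arms is performed
  (a deliberate omission; the generator can only produce HWE-consistent
  controls anyway).
* Plot rendering is out of scope: funnel/forest/leave-one-out tables are
  exported as CSV for external plotting.
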