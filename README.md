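# admeta — case-control SNP meta-analysis

`admeta` is a small, tested toolkit for meta-analysing case-control
genetic-association studies at a single biallelic SNP (major allele G,
minor allele C).  It was built around a concrete use case — pooling the
published Chinese case-control studies of the *CD2AP* rs9349407
polymorphism in Alzheimer's disease (11 studies; 4,173 cases and 6,137
controls), whose per-study table ships as a bundled fixture — but every
stage is generic and works on any study table in the same CSV schema.

It is aimed at epidemiologists and statistical geneticists who want the
whole classical pipeline as composable, inspectable Python instead of a
point-and-click tool:

1. **Genetic-model contrasts.**  Genotype counts are collapsed into
   exposure × status 2×2 tables under the allele (C vs G), dominant
   (GG+GC vs CC), recessive (GG vs GC+CC) and additive (GG+CC vs GC)
   models.  Per-study odds ratios use the cross-product
   OR = ad/(bc) with the Woolf standard error
   `SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)` and a 0.5 continuity
   correction added to all four cells whenever any cell is zero.
2. **Pooling.**  Fixed effect by Mantel–Haenszel
   (`OR_MH = Σ a_i d_i/n_i / Σ b_i c_i/n_i`, Robins–Breslow–Greenland
   variance) on raw tables or inverse variance on log-ORs; random effects
   by DerSimonian–Laird,
   `τ² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw))`, weights `1/(se² + τ²)`.
3. **Heterogeneity and model selection.**  Cochran's Q,
   `I² = max(0, (Q − (K−1))/Q) × 100%`, and the conventional rule:
   random effects iff `p_Q < 0.10` **and** `I² > 50%` (strict).
4. **Robustness.**  Leave-one-out sensitivity analysis; funnel-plot
   coordinates; Egger's regression of `θ/se` on `1/se` (intercept t-test,
   k−2 df); the Begg–Mazumdar Kendall rank correlation between
   variance-stabilized deviates and study variances; and Duval–Tweedie
   trim-and-fill with the L0 estimator and fixed-effect centring.
5. **Synthetic data.**  A Hardy–Weinberg case-control generator with
   known truth (control MAF, per-allele OR, between-study τ²) so that
   pooling, the Z-test's calibration, and trim-and-fill recovery can be
   validated end to end without external data.

## Worked example

The bundled fixture reproduces the published per-study table verbatim —
including its internal inconsistencies, which the validator reports
rather than corrects:

```bash
$ admeta validate --input table1.csv
...
[warning] Tao: control genotype total 338 differs from declared n_control 383
[warning] Liu_b: control genotype total 190 differs from declared n_control 290
11 studies: 0 error(s), 6 warning(s)

$ admeta run --input table1.csv --out out/
allele: k=7 method=random_dl I2=90.7% OR=0.98 [0.65, 1.48] P=9.24E-01
dominant: k=6 method=random_dl I2=57.8% OR=0.63 [0.29, 1.35] P=2.32E-01
recessive: k=7 method=random_dl I2=92.9% OR=1.13 [0.67, 1.90] P=6.59E-01
additive: k=7 method=random_dl I2=92.0% OR=1.18 [0.71, 1.95] P=5.22E-01
wrote 13 file(s) to out/
```

Reading the output: only 7 of the 11 studies published genotype counts
(the dominant model additionally drops one study whose reference
category is empty in both arms, so k=6 there).  Heterogeneity is high
(I² ≈ 91% on the allele model), so the selection rule picks
DerSimonian–Laird random effects, and the pooled allele odds ratio from
the genotype-complete subset is 0.98 [0.65, 1.48] — compatible with no
effect.  Note this is *not* the published 11-study pooled estimate
(OR 1.33): four studies' counts were never released, and several printed
rows are internally inconsistent, so the published subgroup results are
not reproducible from the printed table alone.  Users who obtain the
missing per-study allele log-ORs can supply them through the optional
`log_or`/`se` CSV columns to run the full 11-study allele analysis.

`out/` contains `report.json` (full precision) plus per-model
`forest_*.csv`, `funnel_*.csv` and `loo_*.csv` tables ready for plotting.

The same pipeline is available as a library:

```python
import admeta

table = admeta.load_fixture()
report = admeta.run_analysis(table)
sec = report.per_model["allele"]
print(sec.selected, sec.het.i2, sec.selected_result.or_value)
# random 90.73561893553045 0.9803948226914708
```

And synthetic studies with known truth:

```bash
$ admeta simulate --k 8 --maf 0.3 --or 1.3 --tau2 0.04 --seed 42 --out sim.csv
wrote 8 studies (9313 cases / 9860 controls) to sim.csv
```

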