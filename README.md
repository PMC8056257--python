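# pleiocfdr

Pleiotropy-informed conditional false discovery rate (cFDR / ccFDR) analysis
of paired GWAS summary statistics.

Many complex-trait pairs — the motivating example here is appendicular lean
mass (ALM) and bone mineral density (BMD) — share genetic architecture.
When two GWAS of correlated traits are available, a SNP's evidence in one
trait can be re-weighted by its evidence in the other, increasing discovery
for the principal trait without recruiting a single additional sample.
`pleiocfdr` implements that analysis end to end for two summary-statistic
tables: harmonization on common SNPs, MAF-aware LD pruning, stratified Q–Q
enrichment diagnostics, per-SNP cFDR in both conditioning directions, the
conjunction ccFDR for pleiotropic discovery, replicate-vs-novel annotation
against a known-association catalog, SNP-to-gene mapping, and expression-
based validation statistics — plus a synthetic two-trait generator with
truth labels so every stage can be calibrated without any external data.

## The statistic

For SNP *i* with principal-trait p-value *p<sub>i</sub>* and conditional-trait
p-value *q<sub>i</sub>*, the empirical-count conditional FDR is

```
cFDR_i = min(1,  p_i · #{j : q_j ≤ q_i} / #{j : p_j ≤ p_i  and  q_j ≤ q_i})
```

— the nominal p-value rescaled by the empirical CDF ratio F̂(q) / F̂(p, q),
with the null proportion conservatively set to 1 and counts inclusive of
SNP *i* itself. With every *q* = 1 this reduces exactly to the unconditional
estimator *p·N*/rank. The conjunction ccFDR, an estimate of the probability
that a SNP is associated with *neither* trait, is the elementwise maximum of
the two direction-specific cFDRs. Significance uses a strict 0.05 cut-off;
Manhattan plots draw the reference line at −log₁₀(0.05) = 1.3.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (4,000 SNPs, 94% null / 2% per-trait / 2% pleiotropic, effect
correlation 0.8) and write their tables under `results/`:

```
$ python analysis/01_simulate_cohorts.py
$ python analysis/02_merge_and_prune.py
merged on common SNPs: 4000
LD pruning at r2 > 0.2: kept 1306, removed 2694 (kept + removed = 4000)
$ python analysis/04_cfdr_ccfdr.py
significant at 0.05: 23 lean-mass (cFDR LM|BMD), 19 bone-density (cFDR BMD|LM), 10 pleiotropic (ccFDR)
Manhattan reference line at 1.3
against truth: realized FDP of lean-mass calls = 0.000; true positives 23 (conditional) vs 17 (unconditional)
$ python analysis/05_annotate_novel.py
lean-mass cFDR: 23 significant = 9 direct replicates + 0 LD-block replicates + 14 novel
pleiotropic ccFDR: 10 significant = 4 direct replicates + 0 LD-block replicates + 6 novel
$ python analysis/06_expression_validation.py
4 genes detected in the expression matrix; 3 differ between young and old (rank-sum p < 0.05), ...
```

Read: conditioning on the second trait lifted the true-positive count from
17 to 23 on this replicate; of the 23 lean-mass calls, 9 re-identify
catalog SNPs and 14 are novel candidates; three of the four genes annotated
by significant SNPs validate in the 16-vs-12 muscle expression comparison.
`analysis/03_enrichment_qq.py` prints the stratified Q–Q deflection areas
that justify the conditioning in the first place.

The same stages are available as a CLI (`pleiocfdr simulate|merge|prune|
qq|cfdr|annotate|validate-expression|run`) and as a single configurable
pipeline (`pleiocfdr run --config run.yaml`).

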