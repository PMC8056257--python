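# Methods

## Model and procedure

`pleiocfdr` analyses two GWAS summary-statistic tables for correlated
traits. After merging on the exact intersection of SNP ids (p1/direction
from the principal trait, p2/direction from the conditional trait) and LD
pruning, the core quantity is the per-SNP conditional FDR

cFDR(p, q) = min(1, p · F̂(q) / F̂(p, q)),

estimated in count form: F̂(q) = #{j : q_j ≤ q}/N and
F̂(p, q) = #{j : p_j ≤ p, q_j ≤ q}/N over the merged, pruned table. It
approximates the posterior probability that a SNP is null for the
principal trait given that both of its p-values are at least as extreme as
observed, under three working assumptions: (i) SNPs are quasi-independent
(hence pruning precedes estimation), (ii) null principal-trait p-values
are uniform (genomic control is assumed done upstream by the source
GWAS), and (iii) the null proportion is conservatively set to 1. Both
conditioning directions are computed; the conjunction ccFDR — the
estimated probability of association with neither trait — is their
elementwise maximum. Significance is strict (< 0.05 by default), and
Manhattan exports carry the reference line at −log₁₀(threshold) rounded
to one decimal (1.3 at 0.05).

Counts are inclusive of the index SNP, so the denominator is ≥ 1, the
single-SNP case returns its own p-value, and tied p-values share the
largest qualifying count. With all conditional p-values equal to 1 the
estimator collapses exactly to the unconditional p·N/rank baseline, which
is also exposed directly for power comparisons.

The optimized implementation sorts by the principal p-value and counts
2-D dominances with a Fenwick tree (O(N log N)); tie groups are inserted
before being queried so inclusive-tie semantics hold exactly. A numba
jit compiles the kernel when available; the pure-Python fallback executes
the identical code. Both are checked against an O(N²) brute-force
counting oracle in the test suite, which requires exact equality.

## Calibration of thresholded cFDR calls

A caution that the acceptance suite measures directly: declaring all SNPs
with cFDR < α significant does not guarantee a realized false-discovery
proportion ≤ α. Each SNP's cFDR estimates the FDR of its own
(p, q)-rectangle — conservatively, because the null proportion is set to 1
and the marginal F̂(q) over-counts the null q-mass — but the called set is
the *union* of such rectangles along the cFDR level curve, and the local
false-discovery density near that boundary exceeds the rectangle averages
(Liley & Wallace, PLoS Genet 2015, analyse exactly this selection effect
and repair it with v-values, which are out of scope here). Which force
wins depends on the genetic architecture: with rare, strong effects the
built-in conservativity dominates and realized FDP lands below the
cut-off; with the denser moderate-effect mixture used by this package's
generator defaults (6% non-null mass, effect-mean sd 3), the union effect
dominates and the realized FDP of cFDR < 0.05 calls averages roughly 0.10
(`scripts/acceptance.py` recomputes this; the unconditional baseline on
the same replicates stays near 0.045). The power comparison is unaffected:
conditional calls recover at least as many true principal-trait
associations as the unconditional baseline whenever a positively
correlated pleiotropic component is present.

An optional `monotone` flag enforces lookup-table semantics (cFDR
non-decreasing in the principal p-value via suffix minima over the
p-sorted order); it is off by default because per-SNP counting is directly
oracle-checkable.

## Pipeline stages and their parameters

| parameter | default | meaning |
|---|---|---|
| prune `r2_threshold` | 0.2 | strict cut: pairs with r² > 0.2 lose their smaller-MAF member |
| significance threshold | 0.05 | strict cut for cFDR, ccFDR and baseline calls |
| Q–Q strata | 1, 0.1, 0.01, 0.001 | conditional-trait p cutoffs (configurable) |
| Q–Q quantile convention | k/(n+1) | keeps −log₁₀ finite at the extreme order statistic; (k−0.5)/n available |
| novelty `block_r2` | 0.8 | inclusive: best r² ≥ 0.8 to a catalog SNP ⇒ replicate-by-LD |
| gene `flank_bp` | 10 kb | a SNP maps to genes whose flanked interval contains it |

r² is the squared Pearson correlation of genotype dosages (composite LD);
phase-based measures are out of scope. Pruning is greedy and
deterministic: pairs above threshold are processed in (chromosome,
position-of-a, position-of-b, id) order, the smaller-MAF member is
removed, equal MAFs remove the lexicographically larger id, and an
exhaustive post-scan asserts the kept set is edge-free, which also makes
the operation idempotent. Because the processing order of a PLINK-style
windowed pruner is implementation-defined, kept-set *membership* (not the
edge-free guarantee) can differ from other tools on the same input.

Novelty classification partitions every significant SNP into exactly one
of replicate-direct (in the catalog), replicate-by-LD (best r² to the
catalog ≥ block threshold; unrecorded pairs count as r² = 0) or novel, so
replicates + novel always equals the significant-set size. Gene labels
join all overlapped symbols with "/" in annotation order. BED input
(0-based half-open) is converted to 1-based inclusive coordinates
internally.

Expression validation implements two statistics. The two-group Wilcoxon
rank-sum test is exact — a dynamic-programming enumeration of the null
rank-sum distribution, two-sided p = twice the smaller inclusive tail,
capped at 1 — whenever the pooled sample is ≤ 20 with no ties (the
16-vs-12 young/old design therefore takes the mid-rank normal
approximation with tie and continuity corrections, via
scipy.stats.mannwhitneyu); the method tag records which path ran. The
trait correlation is Pearson by default (Spearman optional) with a
two-sided t-test on n−2 degrees of freedom; zero-variance inputs return a
flagged undefined result instead of NaN. No multiple-testing correction
is applied by default — per-gene p < 0.05 is "nominal" validation —
with Benjamini–Hochberg available behind a flag.

Merging takes positional metadata from the principal-trait table, logs
discrepancies, and attempts no allele-frame harmonization (a strict mode
counts allele disagreements); directions are descriptive codes from the
beta sign, with beta = 0 or missing coded "0" and retained in all
statistics. Malformed input rows (p ∉ (0,1], MAF ∉ (0,0.5], bad position,
duplicate id) are moved to a per-file rejection ledger with reasons,
never silently dropped: kept + rejected always equals rows parsed.

## The synthetic generator

The generator is a four-component z-score mixture, not a genotype-level
simulator: each SNP is null for both traits, non-null for one, or
pleiotropic, with mixture fractions (0.94, 0.02, 0.02, 0.02) by default.
Non-null traits draw a latent effect mean μ ~ N(0, σ²) with σ = 3 —
typical non-null SNPs reach suggestive, not saturating, significance at
the simulated scale — and pleiotropic SNPs draw their two means jointly
with correlation ρ (default 0.8; negative ρ models opposite-direction
pleiotropy, which does occur among real cross-trait loci). Observed
z = μ + N(0,1), p = 2Φ(−|z|) computed via erfc so no p underflows to 0,
and the reported beta is the standardized z itself. This targets exactly
what the estimator consumes — paired p-values with pleiotropy-driven
dependence and exact truth labels for FDP/power measurement.

LD structure is generated separately, because the z-mixture is
independent by construction: SNPs are partitioned into blocks (sizes
uniform on a configurable range), and discrete 0/1/2 dosages are drawn
from two thresholded latent haplotypes per individual whose within-block
correlation is *numerically inverted* (Owen's-T closed form for the
bivariate-normal orthant probability, brentq root-finding) so the
realized dosage r² matches the configured within-block level by
construction rather than by tuning. All SNPs in a block share one panel
MAF, as high-LD tags do in real panels. Expression matrices are i.i.d.
normal baselines with configurable group shifts and trait-coupled genes
under a 16-vs-12 two-group design.

What the generator does not emulate — and hence what passing tests do not
establish about real data: realistic human LD maps and MAF–LD coupling,
ancestry structure, sample-overlap-induced correlation between the two
GWAS (the intended use case is non-overlapping cohorts), winner's-curse
in the catalog, or probe-level expression artifacts (gene-level input is
assumed pre-aggregated). All randomness flows from one seed through
numpy SeedSequence spawning, so every stage is bit-for-bit reproducible
and independently re-derivable.

## Problem sizes

The analysis drivers use 4,000 SNPs with a 200-individual panel — enough
for every stage, including all-pairs LD, to run in seconds while leaving
dozens of significant SNPs to annotate. Calibration quantities use 25
replicates of 100,000 independent SNP pairs (FDP), 20 replicates of
50,000 (power), and 10–12 replicates of 20,000 (Q–Q deflection); these
sizes give Monte-Carlo standard errors well inside the tolerances the
tests assert.

## Known limitations

- Thresholded per-SNP cFDR is not a guaranteed-FDR procedure (above);
  users needing exact control should treat calls as a ranked candidate
  list, as the downstream annotation stages do.
- π0 is fixed at 1; no local-fdr, covariate-weighted or v-value variants.
- Allele-frame harmonization against a reference panel, imputation,
  liftover and genomic control are all assumed done upstream.
- `classify_novelty` scans catalog pairs linearly per query; it is sized
  for hundreds of significant SNPs against catalog snapshots, not for
  genome-wide proxy search.
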