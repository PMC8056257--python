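"""Synthetic two-trait GWAS data with known pleiotropic structure.

The generative model is a four-component z-score mixture: each SNP is null
for both traits (component "00"), non-null for one trait only ("10"/"01"),
or pleiotropic ("11").  A non-null trait draws a latent effect mean
mu ~ N(0, sigma^2); for pleiotropic SNPs the two means are drawn jointly
with correlation rho.  Observed z = mu + e with standard-normal noise, the
two-sided p-value is 2*Phi(-|z|), and the reported beta is the z-score
itself (a standardized, unitless effect), so the effect direction is the z
sign.  This targets exactly what the counting-based cFDR estimator
consumes — paired p-values with a pleiotropy-driven dependence — while a
separate block-structured dosage panel serves the LD-based stages
(pruning, novelty).

Truth labels are emitted alongside, so the empirical false-discovery
proportion of any calling procedure can be computed exactly.

All randomness flows from a single seed through numpy SeedSequence
spawning, so each stage is independently reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gwas_io import SummaryStatsTable
from .ld_tools import DosagePanel, LDPairSet, compute_r2

COMPONENTS = ("00", "10", "01", "11")


@dataclass
class SimConfig:
    """Study conditions for the joint-GWAS generator.

    pi : mixture fractions (null, trait-1-only, trait-2-only, pleiotropic).
        Default 94% null with 2% in each non-null class — a polygenic
        regime with a modest shared component.
    sigma : sd of non-null latent z-score means (default 3, i.e. typical
        non-null SNPs reach genome-wide-suggestive signal without
        saturating).
    rho : correlation of the two latent means for pleiotropic SNPs.
    maf_range : minor-allele-frequency range, uniform (common variants).
    n_chrom : SNPs are laid out over this many chromosomes.
    block_size_range : inclusive range of LD-block sizes for the panel.
    within_block_r2 : target realized dosage r^2 inside a block.
    n_individuals : panel size (reference-panel scale, not GWAS scale).
    """

    n_snps: int = 10_000
    pi: tuple = (0.94, 0.02, 0.02, 0.02)
    sigma: float = 3.0
    rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    n_chrom: int = 22
    block_size_range: tuple = (1, 10)
    within_block_r2: float = 0.8
    n_individuals: int = 200
    seed: int = 0

    def validate(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("mixture fractions must be 4 nonnegative values summing to 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    # 2*Phi(-|z|) via erfc for accuracy deep in the tail; never exactly 0
    return special.erfc(np.abs(z) / np.sqrt(2.0))


def simulate_joint_gwas(
    config: SimConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, pd.DataFrame]:
    """Generate paired summary-statistic tables sharing SNP ids, plus truth.

    Returns (trait-1 table, trait-2 table, truth frame).  The truth frame
    carries the per-SNP component label and latent means — the oracle for
    empirical-FDR and power evaluation.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_comp, ss_mu, ss_noise, ss_maf, ss_pos = root.spawn(5)
    n = config.n_snps

    comp = np.random.default_rng(ss_comp).choice(4, size=n, p=np.asarray(config.pi))
    rng_mu = np.random.default_rng(ss_mu)
    mu1 = np.zeros(n)
    mu2 = np.zeros(n)
    is1 = comp == 1
    is2 = comp == 2
    is11 = comp == 3
    mu1[is1] = rng_mu.normal(0.0, config.sigma, is1.sum())
    mu2[is2] = rng_mu.normal(0.0, config.sigma, is2.sum())
    if is11.any():
        cov = config.sigma**2 * np.array([[1.0, config.rho], [config.rho, 1.0]])
        joint = rng_mu.multivariate_normal([0.0, 0.0], cov, size=int(is11.sum()),
                                           method="cholesky" if abs(config.rho) < 1 else "svd")
        mu1[is11] = joint[:, 0]
        mu2[is11] = joint[:, 1]

    rng_noise = np.random.default_rng(ss_noise)
    z1 = mu1 + rng_noise.standard_normal(n)
    z2 = mu2 + rng_noise.standard_normal(n)
    p1 = _two_sided_p(z1)
    p2 = _two_sided_p(z2)
    maf = np.random.default_rng(ss_maf).uniform(*config.maf_range, size=n)

    # genomic layout: contiguous runs per chromosome, jittered spacing
    rng_pos = np.random.default_rng(ss_pos)
    chrom = 1 + (np.arange(n) * config.n_chrom) // n
    spacing = rng_pos.integers(1_000, 10_000, size=n)
    pos = np.empty(n, dtype=np.int64)
    for c in range(1, config.n_chrom + 1):
        m = chrom == c
        pos[m] = np.cumsum(spacing[m])

    snp_id = np.array([f"rs{i:07d}" for i in range(1, n + 1)])
    base = {"snp_id": snp_id, "chrom": chrom.astype(str), "pos": pos, "maf": maf}
    t1 = SummaryStatsTable(
        df=pd.DataFrame({**base, "beta": z1, "p_value": p1})[
            ["snp_id", "chrom", "pos", "beta", "p_value", "maf"]],
        trait_name="trait1",
    )
    t2 = SummaryStatsTable(
        df=pd.DataFrame({**base, "beta": z2, "p_value": p2})[
            ["snp_id", "chrom", "pos", "beta", "p_value", "maf"]],
        trait_name="trait2",
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "component": np.array(COMPONENTS)[comp],
            "mu1": mu1,
            "mu2": mu2,
            "z1": z1,
            "z2": z2,
        }
    )
    return t1, t2, truth


def null_mask(truth: pd.DataFrame, trait: int) -> np.ndarray:
    """Boolean mask of SNPs null for the given trait (1 or 2)."""
    comp = truth["component"].to_numpy()
    if trait == 1:
        return np.isin(comp, ("00", "01"))
    if trait == 2:
        return np.isin(comp, ("00", "10"))
    raise ValueError("trait must be 1 or 2")


def empirical_fdp(called: np.ndarray, truth: pd.DataFrame, trait: int) -> float:
    """False-discovery proportion of a call vector against truth labels:
    #{called and null} / max(1, #called)."""
    called = np.asarray(called, dtype=bool)
    nulls = null_mask(truth, trait)
    return float((called & nulls).sum() / max(1, called.sum()))


def _allele_corr(c: float, t: float, f: float) -> float:
    """Correlation of two same-threshold indicators of standard normals with
    latent correlation c: the bivariate-normal orthant probability
    P(Z1<t, Z2<t) in Owen's-T closed form (equal thresholds, t != 0)."""
    if c <= 0:
        return 0.0
    p11 = f - 2.0 * special.owens_t(t, np.sqrt((1.0 - c) / (1.0 + c)))
    return (p11 - f * f) / (f * (1.0 - f))


def _latent_corr_for_r2(target_r2: float, f: float) -> float:
    """Invert the copula attenuation: latent correlation giving dosage
    r^2 = target_r2 at panel MAF f."""
    if target_r2 <= 0:
        return 0.0
    r_target = np.sqrt(target_r2)
    t = stats.norm.ppf(f)
    hi = 0.9999
    if _allele_corr(hi, t, f) <= r_target:
        return hi
    return float(optimize.brentq(lambda c: _allele_corr(c, t, f) - r_target, 0.0, hi,
                                 xtol=1e-6))


def simulate_ld_panel(
    snps: pd.DataFrame, config: SimConfig
) -> tuple[DosagePanel, LDPairSet, np.ndarray]:
    """Block-structured genotype-dosage panel plus its realized LD.

    SNPs (in input order) are partitioned into blocks with sizes drawn from
    ``block_size_range``; within a block all SNPs share one panel MAF and a
    per-individual latent haplotype signal whose correlation is numerically
    chosen so the realized dosage r^2 matches ``within_block_r2``; blocks
    are mutually independent.  Dosages are discrete 0/1/2 counts from two
    thresholded latent haplotypes per individual.

    Returns (panel, realized all-pairs LDPairSet, block index per SNP).
    """
    n = len(snps)
    lo, hi = config.block_size_range
    if lo < 1 or hi < lo:
        raise ValueError("block_size_range must be a nonempty positive range")
    if lo > n:
        raise ValueError("block size exceeds number of SNPs")
    root = np.random.SeedSequence(config.seed).spawn(7)[6]
    rng = np.random.default_rng(root)

    sizes = []
    total = 0
    while total < n:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, n - total)
        sizes.append(s)
        total += s
    block_of = np.repeat(np.arange(len(sizes)), sizes)

    n_ind = config.n_individuals
    dosage = np.empty((n_ind, n), dtype=float)
    start = 0
    for s in sizes:
        f = rng.uniform(max(config.maf_range[0], 0.05), config.maf_range[1])
        t = stats.norm.ppf(f)
        c = _latent_corr_for_r2(config.within_block_r2, f) if s > 1 else 0.0
        for hap in range(2):
            latent = rng.standard_normal(n_ind)[:, None]
            eps = rng.standard_normal((n_ind, s))
            z = np.sqrt(c) * latent + np.sqrt(1.0 - c) * eps
            allele = (z < t).astype(float)
            if hap == 0:
                dosage[:, start:start + s] = allele
            else:
                dosage[:, start:start + s] += allele
        start += s

    panel = DosagePanel(
        snp_ids=list(snps["snp_id"]),
        matrix=dosage,
        chrom=snps["chrom"].to_numpy() if "chrom" in snps else None,
        pos=snps["pos"].to_numpy() if "pos" in snps else None,
    )
    ld = compute_r2(panel, window_bp=None)
    return panel, ld, block_of


def catalog_from_truth(
    snps: pd.DataFrame, truth: pd.DataFrame, components=("11",), fraction: float = 0.5,
    seed: int = 0, trait: str = "",
) -> pd.DataFrame:
    """Sample a known-association catalog from the simulated truth: a random
    fraction of the SNPs in the given components, as (snp_id, chrom, pos,
    trait) — stands in for a prior-GWAS catalog snapshot."""
    rng = np.random.default_rng(seed)
    pool = truth.loc[truth["component"].isin(components), "snp_id"]
    take = pool[rng.random(len(pool)) < fraction]
    sub = snps[snps["snp_id"].isin(set(take))][["snp_id", "chrom", "pos"]].copy()
    sub["trait"] = trait
    return sub.reset_index(drop=True)


@dataclass
class ExpressionDesign:
    """Two-group expression study design (defaults mirror a 16-young vs
    12-old muscle-biopsy comparison with a continuous bone-density trait)."""

    n_group_a: int = 16
    n_group_b: int = 12
    group_labels: tuple = ("young", "old")
    effect_genes: tuple = ()
    effect_size: float = 2.0  # group shift in baseline-sd units
    trait_genes: tuple = ()
    trait_r: float = 0.5  # target expression-trait correlation
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0


def simulate_expression(genes, design: ExpressionDesign):
    """Genes x samples expression matrix with group effects and optional
    trait coupling, plus sample metadata (sample, group, trait).

    Baseline expression is N(baseline_mean, baseline_sd^2) i.i.d.;
    ``effect_genes`` are shifted by ``effect_size`` sd in group B;
    ``trait_genes`` are linearly coupled to the continuous trait so their
    population expression-trait correlation is ``trait_r``.
    """
    genes = list(genes)
    if design.n_group_a < 1 or design.n_group_b < 1:
        raise ValueError("group sizes must be at least 1")
    unknown = set(design.effect_genes) - set(genes)
    if unknown:
        raise ValueError(f"effect genes not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(design.seed)
    n_samp = design.n_group_a + design.n_group_b
    samples = [f"s{i:03d}" for i in range(1, n_samp + 1)]
    group = np.array([design.group_labels[0]] * design.n_group_a
                     + [design.group_labels[1]] * design.n_group_b)
    trait = rng.standard_normal(n_samp)

    values = rng.normal(design.baseline_mean, design.baseline_sd, size=(len(genes), n_samp))
    gidx = {g: i for i, g in enumerate(genes)}
    shift = design.effect_size * design.baseline_sd
    for g in design.effect_genes:
        values[gidx[g], group == design.group_labels[1]] += shift
    if design.trait_genes and abs(design.trait_r) > 0:
        b = design.trait_r / np.sqrt(1.0 - design.trait_r**2) * design.baseline_sd
        for g in design.trait_genes:
            if g in gidx:
                values[gidx[g]] += b * trait

    expr = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"group": group, "trait": trait}, index=samples)
    meta.index.name = "sample"
    return expr, meta
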