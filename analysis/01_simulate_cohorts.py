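#!/usr/bin/env python
"""Generate the synthetic study inputs: two-trait GWAS summary statistics
with a known four-component pleiotropic mixture, a block-LD reference
panel, a prior-findings catalog, gene intervals, and a two-group
expression matrix with a continuous trait.

Writes everything under results/data/ in the same text formats the
pipeline reads, plus truth labels for downstream calibration checks.
"""

from pathlib import Path

import pandas as pd

from pleiocfdr import annotate as ann
from pleiocfdr import gwas_io, ld_tools
from pleiocfdr import synthetic_data as sd

SEED = 2026
N_SNPS = 4_000  # desk-scale stand-in for the ~10^6-SNP real inputs

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

cfg = sd.SimConfig(n_snps=N_SNPS, pi=(0.94, 0.02, 0.02, 0.02), sigma=3.0,
                   rho=0.8, within_block_r2=0.9, block_size_range=(1, 5),
                   seed=SEED)
lean, bone, truth = sd.simulate_joint_gwas(cfg)
lean.trait_name, bone.trait_name = "lean_mass", "bone_density"
gwas_io.write_summary_stats(lean, OUT / "lean_mass.tsv")
gwas_io.write_summary_stats(bone, OUT / "bone_density.tsv")
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
print(f"simulated {N_SNPS} SNPs x 2 traits "
      f"(components: {truth['component'].value_counts().to_dict()})")

panel, ld, _ = sd.simulate_ld_panel(lean.df, cfg)
ld_tools.write_dosage_panel(panel, OUT / "panel.tsv")
# absent pairs are treated as unlinked, so negligible r2 need not be stored
ld_trim = ld_tools.LDPairSet(df=ld.df[ld.df["r2"] >= 0.01].reset_index(drop=True))
ld_tools.write_ld_file(ld_trim, OUT / "pairs.ld", positions=lean.df)
n_high = int((ld.df["r2"] > 0.2).sum())
print(f"LD panel: {panel.n_individuals} individuals, "
      f"{len(ld_trim)} pairs recorded at r2 >= 0.01, {n_high} with r2 > 0.2")

# catalog: half of the true pleiotropic/trait-1 SNPs pose as prior findings
cat = sd.catalog_from_truth(lean.df, truth, components=("11", "10"),
                            fraction=0.5, seed=SEED, trait="LM")
ann.write_catalog(ann.KnownCatalog(df=cat), OUT / "catalog.tsv")
print(f"known-association catalog: {len(cat)} SNPs")

# gene intervals tiling a subset of SNP positions (BED, 0-based half-open)
anchors = lean.df.iloc[::25]
rows = [(c, max(0, p - 5_000), p + 5_000, f"GENE{i}")
        for i, (c, p) in enumerate(zip(anchors["chrom"], anchors["pos"]))]
pd.DataFrame(rows).to_csv(OUT / "genes.bed", sep="\t", header=False, index=False)
print(f"gene annotation: {len(rows)} intervals")

# expression effects sit on genes that annotate truly trait-associated SNPs,
# so validation has real signal to find
genes = [f"GENE{i}" for i in range(len(rows))]
intervals = ann.read_gene_bed(OUT / "genes.bed")
comp = truth.set_index("snp_id")["component"]


def genes_touching(components):
    hit = lean.df[comp.loc[lean.df["snp_id"]].isin(components).to_numpy()]
    assigned = ann.map_genes(hit, intervals, flank_bp=10_000)
    return tuple(sorted({g for gl in assigned["genes"] for g in gl}))


effect = genes_touching(("10", "11"))
coupled = genes_touching(("01", "11"))
design = sd.ExpressionDesign(effect_genes=effect, effect_size=1.5,
                             trait_genes=coupled, trait_r=0.5, seed=SEED)
expr, meta = sd.simulate_expression(genes, design)
expr.to_csv(OUT / "expression.tsv", sep="\t")
meta.to_csv(OUT / "expression_meta.tsv", sep="\t")
print(f"expression: {expr.shape[0]} genes x {expr.shape[1]} samples "
      f"({design.n_group_a} young vs {design.n_group_b} old)")
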