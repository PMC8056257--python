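#!/usr/bin/env python
"""Harmonize the two summary-statistic tables on their common SNPs and
LD-prune the merged set at r2 > 0.2, deleting the smaller-MAF member of
each high-LD pair, so downstream counting sees quasi-independent markers.
"""

from pathlib import Path

from pleiocfdr import gwas_io, ld_tools

DATA = Path("results/data")
OUT = Path("results")

lean = gwas_io.read_summary_stats(DATA / "lean_mass.tsv", trait_name="lean_mass")
bone = gwas_io.read_summary_stats(DATA / "bone_density.tsv", trait_name="bone_density")
print(f"read {len(lean)} lean-mass and {len(bone)} bone-density SNPs "
      f"(rejected {lean.n_rejected} / {bone.n_rejected})")

merged = gwas_io.harmonize(lean, bone)
gwas_io.write_merged(merged, OUT / "merged.tsv")
print(f"merged on common SNPs: {len(merged)}")

ld = ld_tools.read_ld_file(DATA / "pairs.ld")
kept, removed = ld_tools.prune_ld(merged.df, ld, r2_threshold=0.2)
pruned = gwas_io.MergedPairTable(
    df=merged.df[merged.df["snp_id"].isin(kept)].reset_index(drop=True),
    trait1=merged.trait1, trait2=merged.trait2)
gwas_io.write_merged(pruned, OUT / "merged_pruned.tsv")
removed.to_csv(OUT / "pruned_removed.tsv", sep="\t", index=False)
print(f"LD pruning at r2 > 0.2: kept {len(kept)}, removed {len(removed)} "
      f"(kept + removed = {len(kept) + len(removed)})")
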