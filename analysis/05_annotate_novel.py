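#!/usr/bin/env python
"""Replicate-vs-novel bookkeeping: significant SNPs are compared with the
known-association catalog through LD blocks (r2 >= 0.8) — a SNP in the
catalog or in high LD with a catalog SNP replicates prior findings, the
rest are novel candidates.  Novel and significant SNPs are then mapped to
genes by flanked interval overlap, producing "GENE1/GENE2"-style labels.
"""

from pathlib import Path

import pandas as pd

from pleiocfdr import annotate as ann
from pleiocfdr import ld_tools

DATA = Path("results/data")
OUT = Path("results")

table = pd.read_csv(OUT / "cfdr.tsv", sep="\t", dtype={"SNP": str, "CHR": str})
catalog = ann.read_catalog(DATA / "catalog.tsv")
ld = ld_tools.read_ld_file(DATA / "pairs.ld")

for sig_col, tag in (("SIG_1G2", "lean-mass cFDR"), ("SIG_CONJ", "pleiotropic ccFDR")):
    sig = table.loc[table[sig_col], "SNP"]
    calls = ann.classify_novelty(sig, catalog, ld, block_r2=0.8)
    calls.to_csv(OUT / f"novelty_{sig_col.lower()}.tsv", sep="\t", index=False)
    c = ann.novelty_counts(calls)
    print(f"{tag}: {c['n_significant']} significant = "
          f"{c['n_replicate_direct']} direct replicates "
          f"+ {c['n_replicate_ld']} LD-block replicates + {c['n_novel']} novel")

genes = ann.read_gene_bed(DATA / "genes.bed")
sig = table.loc[table["SIG_1G2"] | table["SIG_CONJ"]]
assign = ann.map_genes(
    sig.rename(columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos"}),
    genes, flank_bp=10_000)
assign.assign(genes=assign["genes"].str.join("/"),
              relations=assign["relations"].str.join("/")).to_csv(
    OUT / "gene_assignments.tsv", sep="\t", index=False)
mapped = assign[assign["label"] != ""]
print(f"gene mapping: {len(mapped)}/{len(assign)} significant SNPs map to a gene "
      f"({sorted(set(g for gl in assign['genes'] for g in gl))[:6]} ...)")
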