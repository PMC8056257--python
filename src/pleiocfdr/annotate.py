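"""Novelty classification against a known-association catalog and SNP-to-gene
interval mapping.

A significant SNP is a *direct replicate* if it appears in the catalog, a
*replicate by LD* if its best r² to any catalog SNP reaches the LD-block
threshold (0.8, inclusive), and *novel* otherwise — the local equivalent of
the SNAP/LDlink proxy-search bookkeeping.  Gene mapping assigns a SNP to
every gene whose flanked interval contains its position and joins symbols
as "GENE1/GENE2"-style labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld_tools import LDPairSet, max_r2_to_set

STATUS_DIRECT = "replicate-direct"
STATUS_LD = "replicate-ld"
STATUS_NOVEL = "novel"


@dataclass
class KnownCatalog:
    """Previously confirmed trait-associated SNPs (id, chrom, pos, trait)."""

    df: pd.DataFrame

    def __post_init__(self):
        if self.df["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids in catalog")

    @property
    def ids(self) -> set:
        return set(self.df["snp_id"])

    def __len__(self) -> int:
        return len(self.df)


def read_catalog(path) -> KnownCatalog:
    """Read a catalog TSV with columns SNP, CHR, BP (TRAIT optional)."""
    raw = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    df = raw.rename(columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "TRAIT": "trait"})
    if "trait" not in df.columns:
        df["trait"] = ""
    return KnownCatalog(df=df[["snp_id", "chrom", "pos", "trait"]])


def write_catalog(catalog: KnownCatalog, path) -> None:
    out = catalog.df.rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "trait": "TRAIT"}
    )
    out.to_csv(path, sep="\t", index=False)


def classify_novelty(
    significant, catalog: KnownCatalog, ld: LDPairSet, block_r2: float = 0.8
) -> pd.DataFrame:
    """Classify each significant SNP as replicate (direct or by LD) or novel.

    LD pairs absent from ``ld`` are treated as r² = 0, so a SNP with no
    recorded LD to the catalog is novel.  The block threshold comparison is
    inclusive (best r² >= block_r2 replicates).

    Returns a DataFrame (snp_id, status, best_catalog_match, best_r2); every
    input SNP receives exactly one status.
    """
    if not (0 <= block_r2 <= 1):
        raise ValueError("block_r2 must lie in [0, 1]")
    catalog_ids = catalog.ids
    rows = []
    for snp in sorted(set(significant)):
        if snp in catalog_ids:
            rows.append((snp, STATUS_DIRECT, snp, 1.0))
            continue
        best_r2, best_match = 0.0, None
        for ref in catalog_ids:
            r2 = ld.r2(snp, ref)
            if r2 > best_r2:
                best_r2, best_match = r2, ref
        status = STATUS_LD if best_r2 >= block_r2 else STATUS_NOVEL
        rows.append((snp, status, best_match, best_r2))
    return pd.DataFrame(rows, columns=["snp_id", "status", "best_catalog_match", "best_r2"])


def novelty_counts(calls: pd.DataFrame) -> dict:
    """Status counts; replicates + novel always sum to the significant-set size."""
    counts = calls["status"].value_counts().to_dict()
    return {
        "n_significant": len(calls),
        "n_replicate_direct": counts.get(STATUS_DIRECT, 0),
        "n_replicate_ld": counts.get(STATUS_LD, 0),
        "n_novel": counts.get(STATUS_NOVEL, 0),
    }


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open), returning a frame
    with 1-based inclusive start/end columns (gene, chrom, start, end)."""
    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "gene": str},
    )
    df = pd.DataFrame(
        {
            "gene": raw["gene"],
            "chrom": raw["chrom"].astype(str),
            "start": raw["start"].astype(np.int64) + 1,  # BED -> 1-based inclusive
            "end": raw["end"].astype(np.int64),
        }
    )
    bad = df[df["end"] < df["start"]]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"malformed gene interval: {rec['gene']} {rec['chrom']}:{rec['start']}-{rec['end']}"
        )
    return df


def map_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 10_000
) -> pd.DataFrame:
    """Map SNPs to genes whose flanked interval covers the SNP position.

    ``genes`` uses 1-based inclusive coordinates (see :func:`read_gene_bed`).
    A SNP within [start, end] has relation "within", within the flank
    "near".  The label joins matched symbols with "/" in annotation order;
    SNPs matching nothing get an empty label.

    Returns a DataFrame (snp_id, genes, relations, label).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be nonnegative")
    if (genes["end"] < genes["start"]).any():
        rec = genes[genes["end"] < genes["start"]].iloc[0]
        raise ValueError(f"malformed gene interval: {rec['gene']}")
    from .gwas_io import normalize_chrom

    gnorm = genes.assign(_chrom=genes["chrom"].map(normalize_chrom))
    rows = []
    for snp, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        c = normalize_chrom(chrom)
        sub = gnorm[gnorm["_chrom"] == c]
        hit = sub[(sub["start"] - flank_bp <= pos) & (pos <= sub["end"] + flank_bp)]
        names, relations = [], []
        for _, g in hit.iterrows():
            names.append(g["gene"])
            relations.append("within" if g["start"] <= pos <= g["end"] else "near")
        rows.append((snp, names, relations, "/".join(names)))
    return pd.DataFrame(rows, columns=["snp_id", "genes", "relations", "label"])
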