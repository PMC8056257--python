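"""Reading, validation and harmonization of GWAS summary-statistic tables.

Two per-trait tables (SNP id, chromosome, position, signed effect, p-value,
MAF) are parsed into :class:`SummaryStatsTable` objects and merged on the
exact intersection of SNP ids into a :class:`MergedPairTable`, the substrate
of all downstream conditional-FDR computation.  Malformed rows are never
silently kept or silently dropped: every input row ends up either in the
table or in its ``rejected`` ledger with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical internal column names of a summary-stats frame
CANONICAL_COLS = ["snp_id", "chrom", "pos", "beta", "p_value", "maf"]


@dataclass
class Dialect:
    """Column-name mapping from a summary-stats file to canonical fields.

    GWAS consortia name columns inconsistently (the lean-mass release calls
    the signed effect "Effect", the bone-density release calls it "Beta");
    a Dialect adapts either convention without touching the parser.
    """

    snp: str = "SNP"
    chrom: str = "CHR"
    pos: str = "BP"
    beta: str = "BETA"
    p: str = "P"
    maf: str = "MAF"
    allele_ref: str | None = None
    allele_alt: str | None = None
    sep: str = r"\s+"

    def required(self) -> dict[str, str]:
        return {
            "snp_id": self.snp,
            "chrom": self.chrom,
            "pos": self.pos,
            "beta": self.beta,
            "p_value": self.p,
            "maf": self.maf,
        }


@dataclass
class SummaryStatsTable:
    """One trait's per-SNP association records plus a rejection ledger."""

    df: pd.DataFrame
    trait_name: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "snp_id", "reason"])
    )

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MergedPairTable:
    """SNPs common to both traits with paired p-values and effect directions."""

    df: pd.DataFrame  # snp_id chrom pos p1 p2 beta1 beta2 dir1 dir2 maf
    trait1: str = "trait1"
    trait2: str = "trait2"

    def __len__(self) -> int:
        return len(self.df)


def assign_direction(beta) -> str:
    """Direction code of a signed effect: "+" if beta>0, "-" if beta<0, else "0".

    Non-finite or missing betas are treated as missing and coded "0".
    """
    if beta is None:
        return "0"
    beta = float(beta)
    if not np.isfinite(beta):
        return "0"
    if beta > 0:
        return "+"
    if beta < 0:
        return "-"
    return "0"


def directions(betas) -> np.ndarray:
    """Vectorized :func:`assign_direction`."""
    b = np.asarray(betas, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.select([~np.isfinite(b), b > 0, b < 0], ["0", "+", "-"], default="0")


def normalize_chrom(label) -> str:
    """Normalize a chromosome label for comparison ("chr1" == "1")."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def _chrom_sort_key(label: str) -> tuple[int, str]:
    s = normalize_chrom(label)
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if s.isdigit():
        return (int(s), "")
    if s in special:
        return (special[s], "")
    return (1000, s)


def read_summary_stats(
    path, dialect: Dialect | None = None, trait_name: str = ""
) -> SummaryStatsTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    Well-formed rows are kept; rows with unparseable numbers, p outside
    (0, 1], MAF outside (0, 0.5], non-positive positions, empty SNP ids or
    duplicated SNP ids are moved to the ``rejected`` ledger with a reason.
    A non-finite beta does not reject the row (the SNP still carries valid
    p and MAF); its direction is coded "0" downstream.

    Raises
    ------
    KeyError
        if a required column named by the dialect is absent.
    ValueError
        if the file has no data rows.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=dialect.sep, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty summary-statistics file: {path}") from None
    if raw.empty:
        raise ValueError(f"no data rows in summary-statistics file: {path}")

    for canon, col in dialect.required().items():
        if col not in raw.columns:
            raise KeyError(
                f"required column {col!r} (for field {canon!r}) missing from {path}"
            )

    df = pd.DataFrame(
        {
            "snp_id": raw[dialect.snp].astype(str).str.strip(),
            "chrom": raw[dialect.chrom].astype(str).str.strip(),
            "pos": pd.to_numeric(raw[dialect.pos], errors="coerce"),
            "beta": pd.to_numeric(raw[dialect.beta], errors="coerce"),
            "p_value": pd.to_numeric(raw[dialect.p], errors="coerce"),
            "maf": pd.to_numeric(raw[dialect.maf], errors="coerce"),
        }
    )
    for canon, col in (("allele_ref", dialect.allele_ref), ("allele_alt", dialect.allele_alt)):
        if col is not None and col in raw.columns:
            df[canon] = raw[col].astype(str).str.strip()

    reason = pd.Series("", index=df.index, dtype=str)

    def flag(mask, why):
        new = mask & (reason == "")
        reason[new] = why

    flag(df["snp_id"].isin(["", "nan", "NA"]), "missing snp id")
    flag(df["p_value"].isna(), "p not a number")
    flag(~df["p_value"].isna() & ~((df["p_value"] > 0) & (df["p_value"] <= 1)), "p out of range")
    flag(df["maf"].isna(), "maf not a number")
    flag(~df["maf"].isna() & ~((df["maf"] > 0) & (df["maf"] <= 0.5)), "maf out of range")
    flag(df["pos"].isna() | (df["pos"] < 1), "position invalid")
    flag(df.duplicated(subset="snp_id", keep="first") & (reason == ""), "duplicate snp id")

    bad = reason != ""
    rejected = pd.DataFrame(
        {"row": df.index[bad], "snp_id": df.loc[bad, "snp_id"].values, "reason": reason[bad].values}
    ).reset_index(drop=True)
    kept = df[~bad].reset_index(drop=True)
    kept["pos"] = kept["pos"].astype(np.int64)

    n_noeffect = int((~np.isfinite(kept["beta"].to_numpy(dtype=float))).sum())
    if n_noeffect:
        logger.warning("%s: %d rows with missing/non-finite beta kept with direction '0'",
                       path.name, n_noeffect)
    if len(rejected):
        logger.info("%s: rejected %d/%d rows (%s)", path.name, len(rejected), len(df),
                    rejected["reason"].value_counts().to_dict())

    assert len(kept) + len(rejected) == len(df)
    return SummaryStatsTable(df=kept, trait_name=trait_name or path.stem, rejected=rejected)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table as TSV with canonical headers (round-trips through
    :func:`read_summary_stats` with the default dialect)."""
    out = table.df.rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "beta": "BETA",
                 "p_value": "P", "maf": "MAF"}
    )
    out.to_csv(path, sep="\t", index=False)


def harmonize(
    table_a: SummaryStatsTable,
    table_b: SummaryStatsTable,
    strict_alleles: bool = False,
) -> MergedPairTable:
    """Merge two per-trait tables on the exact intersection of SNP ids.

    p1/dir1 come from ``table_a`` (the principal trait), p2/dir2 from
    ``table_b``; positional metadata is taken from ``table_a`` and
    discrepancies against ``table_b`` are logged, never fatal.  Output order
    is deterministic: (chromosome, position, snp_id).

    No allele-frame harmonization is attempted: the merge is by id only and
    directions are descriptive.  With ``strict_alleles=True`` and allele
    columns present in both tables, disagreements are counted and logged.
    """
    for t in (table_a, table_b):
        if t.df["snp_id"].duplicated().any():
            raise ValueError(f"duplicate snp ids in table {t.trait_name!r}")

    a = table_a.df
    b = table_b.df
    m = a.merge(b, on="snp_id", how="inner", suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError(
            f"no common SNPs between {table_a.trait_name!r} and {table_b.trait_name!r}"
        )

    chrom_a = m["chrom_1"].map(normalize_chrom)
    chrom_b = m["chrom_2"].map(normalize_chrom)
    n_mismatch = int(((chrom_a != chrom_b) | (m["pos_1"] != m["pos_2"])).sum())
    if n_mismatch:
        logger.warning("harmonize: %d/%d SNPs with positional metadata discrepancies "
                       "(kept %s coordinates)", n_mismatch, len(m), table_a.trait_name)
    if strict_alleles and "allele_ref_1" in m.columns and "allele_ref_2" in m.columns:
        n_allele = int((m["allele_ref_1"].str.upper() != m["allele_ref_2"].str.upper()).sum())
        if n_allele:
            logger.warning("harmonize: %d/%d SNPs with effect-allele mismatch (strict mode; "
                           "rows kept, directions unflipped)", n_allele, len(m))

    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"],
            "chrom": m["chrom_1"].map(normalize_chrom),
            "pos": m["pos_1"].astype(np.int64),
            "p1": m["p_value_1"].astype(float),
            "p2": m["p_value_2"].astype(float),
            "beta1": m["beta_1"].astype(float),
            "beta2": m["beta_2"].astype(float),
            "dir1": directions(m["beta_1"]),
            "dir2": directions(m["beta_2"]),
            "maf": m["maf_1"].astype(float),
        }
    )
    key = out["chrom"].map(_chrom_sort_key)
    out = (
        out.assign(_ck=key)
        .sort_values(["_ck", "pos", "snp_id"], kind="mergesort")
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return MergedPairTable(df=out, trait1=table_a.trait_name, trait2=table_b.trait_name)


def write_merged(merged: MergedPairTable, path) -> None:
    """Write the merged table as TSV (SNP CHR BP P1 P2 DIR1 DIR2 MAF)."""
    out = merged.df.rename(
        columns={"snp_id": "SNP", "chrom": "CHR", "pos": "BP", "p1": "P1", "p2": "P2",
                 "dir1": "DIR1", "dir2": "DIR2", "maf": "MAF"}
    )[["SNP", "CHR", "BP", "P1", "P2", "DIR1", "DIR2", "MAF"]]
    out.to_csv(path, sep="\t", index=False)


def read_merged(path, trait1: str = "trait1", trait2: str = "trait2") -> MergedPairTable:
    """Read a merged table written by :func:`write_merged`."""
    raw = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    df = raw.rename(
        columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "P1": "p1", "P2": "p2",
                 "DIR1": "dir1", "DIR2": "dir2", "MAF": "maf"}
    )
    for c in ("beta1", "beta2"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[["snp_id", "chrom", "pos", "p1", "p2", "beta1", "beta2", "dir1", "dir2", "maf"]]
    return MergedPairTable(df=df, trait1=trait1, trait2=trait2)
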