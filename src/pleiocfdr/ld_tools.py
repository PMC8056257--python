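"""Pairwise linkage disequilibrium: r² computation, MAF-aware greedy pruning,
and LD-block membership queries.

r² is the squared Pearson correlation of genotype dosages (composite LD);
haplotype-phase D'/r² is out of scope.  Pruning removes, for every pair with
r² above the threshold (strictly, default 0.2), the member with the smaller
minor allele frequency, until no high-LD pair survives — the standard
quasi-independence filter applied before counting-based FDR estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LD_FILE_COLS = ["CHR_A", "BP_A", "SNP_A", "CHR_B", "BP_B", "SNP_B", "R2"]


def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class LDPairSet:
    """Sparse pairwise r² values keyed by unordered SNP-id pairs."""

    df: pd.DataFrame  # snp_a snp_b r2 (snp_a < snp_b), optional chr/bp columns
    source: str = "computed"
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.df):
            a = self.df["snp_a"].to_numpy()
            b = self.df["snp_b"].to_numpy()
            if (a >= b).any():
                raise ValueError("LDPairSet requires snp_a < snp_b for every pair")
            if self.df.duplicated(subset=["snp_a", "snp_b"]).any():
                raise ValueError("duplicate unordered pair in LDPairSet")
        self._index = dict(
            zip(zip(self.df["snp_a"], self.df["snp_b"]), self.df["r2"].astype(float))
        )

    def __len__(self) -> int:
        return len(self.df)

    def r2(self, a: str, b: str, default: float = 0.0) -> float:
        """r² of a pair; pairs never recorded are treated as unlinked."""
        if a == b:
            return 1.0
        return self._index.get(_ordered(a, b), default)

    @classmethod
    def from_pairs(cls, pairs, source: str = "computed") -> "LDPairSet":
        """Build from an iterable of (snp_a, snp_b, r2) triples."""
        rows = [(*_ordered(a, b), float(r)) for a, b, r in pairs]
        df = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
        df = df.drop_duplicates(subset=["snp_a", "snp_b"]).reset_index(drop=True)
        return cls(df=df, source=source)


def read_ld_file(path) -> LDPairSet:
    """Read a PLINK ``.ld``-style whitespace table
    (CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2)."""
    raw = pd.read_csv(path, sep=r"\s+", dtype={"SNP_A": str, "SNP_B": str, "CHR_A": str, "CHR_B": str})
    missing = [c for c in LD_FILE_COLS if c not in raw.columns]
    if missing:
        raise KeyError(f"LD file {path} missing columns {missing}")
    swap = raw["SNP_A"] > raw["SNP_B"]
    a = np.where(swap, raw["SNP_B"], raw["SNP_A"])
    b = np.where(swap, raw["SNP_A"], raw["SNP_B"])
    df = pd.DataFrame({"snp_a": a, "snp_b": b, "r2": raw["R2"].astype(float)})
    df = df.drop_duplicates(subset=["snp_a", "snp_b"]).reset_index(drop=True)
    return LDPairSet(df=df, source="file")


def write_ld_file(ld: LDPairSet, path, positions: pd.DataFrame | None = None) -> None:
    """Write PLINK ``.ld``-style; positions (snp_id, chrom, pos) fill
    CHR/BP columns when supplied, else 0."""
    if positions is not None:
        posmap = positions.set_index("snp_id")
    out = pd.DataFrame({"SNP_A": ld.df["snp_a"], "SNP_B": ld.df["snp_b"], "R2": ld.df["r2"]})
    for side in ("A", "B"):
        ids = out[f"SNP_{side}"]
        if positions is not None:
            out[f"CHR_{side}"] = ids.map(posmap["chrom"]).fillna("0").astype(str)
            out[f"BP_{side}"] = ids.map(posmap["pos"]).fillna(0).astype(np.int64)
        else:
            out[f"CHR_{side}"] = "0"
            out[f"BP_{side}"] = 0
    out[LD_FILE_COLS].to_csv(path, sep="\t", index=False)


@dataclass
class DosagePanel:
    """Small reference panel of allele dosages (individuals x SNPs, in [0, 2])."""

    snp_ids: list
    matrix: np.ndarray
    individual_ids: list = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix must be individuals x SNPs")
        if not np.isfinite(self.matrix).all():
            raise ValueError("dosage matrix contains non-finite values")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i}" for i in range(self.matrix.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]


def read_dosage_panel(path) -> DosagePanel:
    """Read a dosage TSV: rows = individuals (first column id), columns = SNPs."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    return DosagePanel(
        snp_ids=list(raw.columns), matrix=raw.to_numpy(dtype=float),
        individual_ids=list(raw.index.astype(str)),
    )


def write_dosage_panel(panel: DosagePanel, path) -> None:
    pd.DataFrame(panel.matrix, index=panel.individual_ids, columns=panel.snp_ids).to_csv(
        path, sep="\t", index_label="IID"
    )


def compute_r2(panel: DosagePanel, window_bp: int | None = 1_000_000) -> LDPairSet:
    """Pairwise r² (squared Pearson correlation of dosage vectors).

    ``window_bp`` restricts to same-chromosome pairs within the window when
    the panel carries positions; pass ``None`` for all pairs.  Zero-variance
    columns are excluded with a warning.

    Raises
    ------
    ValueError
        with fewer than 2 individuals.
    """
    if panel.n_individuals < 2:
        raise ValueError("r2 computation requires at least 2 individuals")
    X = panel.matrix
    var = X.var(axis=0)
    usable = var > 0
    if not usable.all():
        dropped = [s for s, u in zip(panel.snp_ids, usable) if not u]
        warnings.warn(f"compute_r2: excluding {len(dropped)} zero-variance SNP(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    ids = [s for s, u in zip(panel.snp_ids, usable) if u]
    Xu = X[:, usable]
    corr = np.corrcoef(Xu, rowvar=False)
    if corr.ndim == 0:  # single usable SNP
        return LDPairSet(df=pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))
    r2 = np.clip(corr**2, 0.0, 1.0)

    iu, ju = np.triu_indices(len(ids), k=1)
    if window_bp is not None and panel.pos is not None:
        pos = np.asarray(panel.pos)[usable]
        chrom = (np.asarray(panel.chrom)[usable] if panel.chrom is not None
                 else np.zeros(len(ids)))
        keep = (chrom[iu] == chrom[ju]) & (np.abs(pos[iu] - pos[ju]) <= window_bp)
        iu, ju = iu[keep], ju[keep]
    return LDPairSet.from_pairs(
        ((ids[i], ids[j], r2[i, j]) for i, j in zip(iu, ju)), source="computed"
    )


def prune_ld(
    snps: pd.DataFrame, ld: LDPairSet, r2_threshold: float = 0.2
) -> tuple[set, pd.DataFrame]:
    """Greedy MAF-aware LD pruning.

    For every pair with r² strictly above ``r2_threshold`` (processed in a
    deterministic order: chromosome, positions, then ids, when coordinates
    are available), the member with the smaller MAF is removed; equal MAFs
    remove the lexicographically larger id.  The kept set is verified
    edge-free by an exhaustive scan before returning.

    Parameters
    ----------
    snps : DataFrame with columns snp_id, maf (chrom/pos optional, used only
        for the processing order).
    ld : LDPairSet covering the relevant pairs.
    r2_threshold : strict lower bound for removal (default 0.2).

    Returns
    -------
    (kept ids as a set, removed DataFrame with columns snp_id, reason)
    """
    if r2_threshold < 0:
        raise ValueError("r2 threshold must be nonnegative")
    ids = set(snps["snp_id"])
    referenced = set(ld.df["snp_a"]) | set(ld.df["snp_b"])
    unknown = referenced - ids
    if unknown:
        raise ValueError(f"LD pairs reference SNPs absent from the table: "
                         f"{sorted(unknown)[:5]}")
    maf = dict(zip(snps["snp_id"], snps["maf"].astype(float)))

    hot = ld.df[ld.df["r2"] > r2_threshold]
    if len(hot) and {"chrom", "pos"}.issubset(snps.columns):
        cpos = snps.set_index("snp_id")[["chrom", "pos"]]
        order = hot.assign(
            _chrom=hot["snp_a"].map(cpos["chrom"]).astype(str),
            _pa=hot["snp_a"].map(cpos["pos"]),
            _pb=hot["snp_b"].map(cpos["pos"]),
        ).sort_values(["_chrom", "_pa", "_pb", "snp_a", "snp_b"], kind="mergesort")
    else:
        order = hot.sort_values(["snp_a", "snp_b"], kind="mergesort")

    kept = set(ids)
    removed_rows = []
    for a, b in zip(order["snp_a"], order["snp_b"]):
        if a not in kept or b not in kept:
            continue
        if maf[a] < maf[b]:
            drop, other = a, b
        elif maf[b] < maf[a]:
            drop, other = b, a
        else:
            drop, other = (max(a, b), min(a, b))
        kept.discard(drop)
        removed_rows.append((drop, f"r2>{r2_threshold:g} vs {other}"))
    removed = pd.DataFrame(removed_rows, columns=["snp_id", "reason"])

    # contract check: no surviving high-LD pair
    for a, b, r2 in zip(ld.df["snp_a"], ld.df["snp_b"], ld.df["r2"]):
        if r2 > r2_threshold:
            assert not (a in kept and b in kept), f"pruning left pair {a}-{b} r2={r2}"
    assert kept | set(removed["snp_id"]) == ids
    return kept, removed


def max_r2_to_set(query: str, reference_ids, ld: LDPairSet) -> float:
    """Maximum r² linking ``query`` to any id in ``reference_ids``.

    1.0 if the query itself is in the reference set; 0.0 if no pair is
    recorded (unrecorded pairs are treated as unlinked).
    """
    reference_ids = set(reference_ids)
    if query in reference_ids:
        return 1.0
    best = 0.0
    for ref in reference_ids:
        best = max(best, ld.r2(query, ref))
    return best
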